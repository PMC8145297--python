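"""Synthetic plate generator: conversion model, kinetics, determinism."""

import math

import numpy as np
import pytest

from rtquic.calling import call_sample, call_plate, plate_threshold
from rtquic.metrics import compute_metrics
from rtquic.model import RuleConfig, TimeGrid, ValidationError
from rtquic.simulate import (
    KineticParams,
    SampleTruth,
    SimConfig,
    analytic_endpoint,
    conversion_probability,
    preset_configs,
    simulate_plate,
    simulate_well,
    titre_for_endpoint,
)

GRID = TimeGrid.hourly(40.0)
NOISELESS = KineticParams(baseline_rfu_sd=0.0, plateau_rfu_sd=0.0,
                          lag_jitter_sd_h=0.0, read_noise_sd_rfu=0.0)


class TestConversionProbability:
    @pytest.mark.parametrize(
        "dose,expected",
        [(0.0, 0.0), (1.0, 1.0 - math.exp(-1.0)), (10.0, 1.0 - math.exp(-10.0))],
    )
    def test_closed_form(self, dose, expected):
        assert conversion_probability(dose) == pytest.approx(expected, rel=1e-12)

    def test_monotone_and_negative_dose_rejected(self):
        # strictly increasing below float saturation of 1 - exp(-d)
        doses = np.logspace(-3, 1, 25)
        probs = [conversion_probability(d) for d in doses]
        assert all(b > a for a, b in zip(probs, probs[1:]))
        with pytest.raises(ValidationError):
            conversion_probability(-0.1)

    def test_empirical_conversion_matches_poisson_model(self):
        """Dose-response over 500 wells per dose within 3 binomial SDs."""
        for dose in (0.3, 1.0, 3.0):
            truth = SampleTruth("s", log10_titre=math.log10(dose) + 4,
                                inhibition_exponent_set=frozenset())
            n = 500
            converted = 0
            for rep in range(n):
                rng = np.random.default_rng((int(dose * 1000), rep))
                _, wt = simulate_well(truth, -4, KineticParams(), GRID, rng)
                converted += wt.converted
            p = conversion_probability(dose)
            tol = 3 * math.sqrt(p * (1 - p) / n)
            assert abs(converted / n - p) <= tol


class TestSimulateWell:
    def test_unseeded_well_is_flat_baseline(self):
        truth = SampleTruth("ctrl", log10_titre=float("-inf"), p_spontaneous=0.0)
        rec, wt = simulate_well(truth, -3, KineticParams(), GRID,
                                np.random.default_rng(0))
        assert not wt.converted and wt.true_lag_h is None
        k = KineticParams()
        assert abs(rec.fluorescence.mean() - k.baseline_rfu_mean) < 5 * k.baseline_rfu_sd
        assert rec.fluorescence.std() < 5 * k.read_noise_sd_rfu + k.baseline_rfu_sd

    def test_small_tau_zero_noise_gives_near_step_at_lag(self):
        kin = KineticParams(baseline_rfu_sd=0.0, plateau_rfu_sd=0.0,
                            lag_jitter_sd_h=0.0, read_noise_sd_rfu=0.0,
                            growth_tau_h=1e-3)
        truth = SampleTruth("s", log10_titre=9.0,
                            inhibition_exponent_set=frozenset())
        rec, wt = simulate_well(truth, -3, kin, GRID, np.random.default_rng(1))
        assert wt.converted
        before = rec.fluorescence[GRID.times_h < wt.true_lag_h - 0.5]
        after = rec.fluorescence[GRID.times_h > wt.true_lag_h + 0.5]
        assert np.allclose(before, kin.baseline_rfu_mean)
        assert np.allclose(after, kin.plateau_rfu_mean)

    def test_noiseless_lag_strictly_increases_with_dilution(self):
        truth = SampleTruth("s", log10_titre=5.52,
                            inhibition_exponent_set=frozenset())
        lags = []
        for e in range(-3, -8, -1):
            dose = truth.effective_dose(e)
            if dose <= 0:
                continue
            lags.append(NOISELESS.lag_midpoint_h(dose))
        assert all(b > a for a, b in zip(lags, lags[1:]))

    def test_inhibition_lengthens_lag_and_lowers_plateau(self):
        kin = NOISELESS
        inhibited = SampleTruth("s", log10_titre=5.0)
        free = SampleTruth("s", log10_titre=5.0,
                           inhibition_exponent_set=frozenset())
        rec_i, wt_i = simulate_well(inhibited, -3, kin, GRID,
                                    np.random.default_rng(2))
        rec_f, wt_f = simulate_well(free, -3, kin, GRID,
                                    np.random.default_rng(2))
        assert wt_i.effective_dose < wt_f.effective_dose
        assert wt_i.true_lag_h > wt_f.true_lag_h
        assert rec_i.fluorescence.max() < rec_f.fluorescence.max()


class TestSimulatePlate:
    def test_same_seed_same_plate_byte_identical(self):
        cfg = preset_configs("study-6m", rng_seed=9)[0]
        a = simulate_plate(cfg)
        b = simulate_plate(cfg)
        for wid in a.plate.wells:
            assert np.array_equal(a.plate.wells[wid].fluorescence,
                                  b.plate.wells[wid].fluorescence)
        assert a.well_truth == b.well_truth
        assert a.sample_endpoints == b.sample_endpoints

    def test_adding_a_sample_leaves_existing_wells_untouched(self):
        base = preset_configs("study-1m", rng_seed=4)[0]
        extra = SampleTruth("extra", log10_titre=5.0)
        grown = SimConfig(
            plate_id=base.plate_id,
            samples=base.samples + (extra,),
            dilution_exponents={**base.dilution_exponents, "extra": (-3,)},
            rng_seed=base.rng_seed,
        )
        a = simulate_plate(base)
        b = simulate_plate(grown)
        truth_a = a.truth_by_well()
        for wt in b.well_truth:
            if wt.sample_id == "extra":
                continue
            # same (sample, dilution, replicate) -> identical trace, even
            # though well positions shifted
            match = [
                t for t in a.well_truth
                if (t.sample_id, t.dilution_exponent, t.replicate_index)
                == (wt.sample_id, wt.dilution_exponent, wt.replicate_index)
            ]
            assert len(match) == 1
            assert np.array_equal(
                b.plate.wells[wt.well_id].fluorescence,
                a.plate.wells[match[0].well_id].fluorescence,
            )
        del truth_a

    def test_duplicate_sample_ids_rejected(self):
        s = SampleTruth("dup", log10_titre=3.0)
        with pytest.raises(ValidationError):
            SimConfig(plate_id="p", samples=(s, s),
                      dilution_exponents={"dup": (-3,)}, rng_seed=0)

    def test_high_dose_sample_converts_all_wells(self):
        # effective dose 10^3 at 10^-3: conversion probability ~ 1
        truth = SampleTruth("hot", log10_titre=6.0,
                            inhibition_exponent_set=frozenset())
        cfg = SimConfig(plate_id="p", samples=(truth,),
                        dilution_exponents={"hot": (-3,)}, rng_seed=123)
        res = simulate_plate(cfg)
        assert all(t.converted for t in res.well_truth)

    def test_analytic_endpoint_matches_binomial_hand_calc(self):
        # dose 3.31 at the endpoint: P(convert)=0.9636, P(>=2 of 4) ~ 0.9997;
        # a decade further: dose 0.331, P(>=2 of 4) ~ 0.317 < 1/2
        truth = SampleTruth("s", log10_titre=titre_for_endpoint(-5),
                            inhibition_exponent_set=frozenset())
        assert analytic_endpoint(truth, range(-3, -9, -1)) == -5

    def test_preset_endpoint_pattern_matches_design(self):
        expected = {
            "12M-#1-brain": -5, "12M-#2-brain": -8, "12M-#3-brain": -5,
            "12M-Con-brain": None,
            "12M-#1-colon": -5, "12M-#2-colon": -5, "12M-#3-colon": -5,
            "12M-Con-colon": None,
        }
        seen = {}
        for cfg in preset_configs("study-12m", rng_seed=0):
            seen.update(simulate_plate(cfg).sample_endpoints)
        assert seen == expected

    def test_oversized_design_rejected(self):
        samples = tuple(
            SampleTruth(f"s{i}", log10_titre=4.0) for i in range(5)
        )
        cfg_kwargs = dict(
            plate_id="big",
            samples=samples,
            dilution_exponents={f"s{i}": tuple(range(-3, -9, -1)) for i in range(5)},
            rng_seed=0,
        )
        cfg = SimConfig(**cfg_kwargs)  # 120 wells
        with pytest.raises(ValidationError, match="96"):
            simulate_plate(cfg)


def test_endpoint_adjacent_groups_show_partial_wells():
    """Near the endpoint, positive groups of 2 or 3 (not 4) wells occur."""
    partials = 0
    for seed in range(6):
        for cfg in preset_configs("study-3m", rng_seed=seed):
            res = simulate_plate(cfg)
            result = call_plate(res.plate)
            for c in result.calls:
                if c.is_positive and c.n_positive_wells in (2, 3):
                    partials += 1
    assert partials > 0


def test_spontaneous_positives_are_late_and_single(plate_factory):
    """Unseeded wells converting spontaneously rise in the final third."""
    truth = SampleTruth("ctrl", log10_titre=float("-inf"), p_spontaneous=0.05)
    lags = []
    for rep in range(400):
        rng = np.random.default_rng((77, rep))
        _, wt = simulate_well(truth, -3, KineticParams(), GRID, rng)
        if wt.converted:
            assert wt.spontaneous
            lags.append(wt.true_lag_h)
    assert lags, "expected some spontaneous conversions at p=0.05"
    assert min(lags) >= 40.0 * 2 / 3
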