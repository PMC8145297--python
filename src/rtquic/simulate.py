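"""Synthetic RT-QuIC plate generator with known ground truth.

The study's raw fluorescence data are not deposited, so the pipeline is
exercised against a generative stand-in that reproduces the assay's
phenomenology: sigmoidal seeded responses with dose-dependent lag, flat
negatives, partial-well positivity near the endpoint dilution, occasional
late single-well spontaneous positives, attenuated responses at the least
dilute (10^-3) seeding due to reaction inhibitors, and instrument saturation.

Mechanistically the generator is deliberately minimal:

* **Single-hit Poisson conversion.**  A well seeded with effective dose d
  (expected seeding units per reaction) converts with probability
  1 - exp(-d).  This one assumption yields all-or-none conversion at high
  dose and the observed 2-or-3-of-4 partial positivity within a decade of
  the endpoint.  Unseeded wells convert with a small spontaneous
  probability instead.
* **Logistic growth.**  A converted well follows
  F(t) = B + (P - B) / (1 + exp(-(t - T_lag)/tau)) plus Gaussian read noise,
  clipped to the instrument range [0, saturation].
* **Log-dose lag.**  T_lag = alpha + beta * max(0, -log10 d)
  + beta_hi * min(0, -log10 d) + jitter.  Below one seeding unit per well
  the lag grows by ``beta`` hours per decade of dose shortfall; above it the
  lag keeps shrinking, but only by the small ``beta_hi`` per decade, so lag
  is strictly decreasing in dose while saturating wells still cross in the
  14-20 h band.

Every well draws from its own counter-keyed RNG substream, keyed by
(plate, sample, dilution, replicate): adding or removing a well never
perturbs any other well's draws, and identical configs are byte-identical.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .model import (
    DEFAULT_ANALYSIS_WINDOW_H,
    DEFAULT_SATURATION_RFU,
    PlateRun,
    SampleMeta,
    TimeGrid,
    ValidationError,
    WellMeta,
    WellRecord,
)

__all__ = [
    "KineticParams",
    "SampleTruth",
    "SimConfig",
    "WellTruth",
    "SimResult",
    "conversion_probability",
    "simulate_well",
    "simulate_plate",
    "analytic_endpoint",
    "preset_configs",
    "simulate_study_cohort",
    "PRESET_NAMES",
]

NEG_INF = float("-inf")

_ROWS = "ABCDEFGH"
_COLS = range(1, 13)
PLATE_CAPACITY = 96


@dataclass(frozen=True)
class KineticParams:
    """Kinetic and noise parameters of the synthetic fluorescence model.

    Defaults are calibrated to the two instrument anchors the assay fixes —
    per-plate thresholds (pooled baseline mean + 10 SD) landing in the
    15,000-25,000 RFU band and saturation at 260,000 RFU — and to the
    narrative lag ranges: threshold crossing at 14-20 h for wells seeded well
    above endpoint, stretching to ~22-34 h within a decade of the endpoint.
    They are calibration choices, not measured values.
    """

    baseline_rfu_mean: float = 10_000.0
    baseline_rfu_sd: float = 800.0
    plateau_rfu_mean: float = 230_000.0
    plateau_rfu_sd: float = 15_000.0
    growth_tau_h: float = 1.2
    lag_intercept_h: float = 20.0
    lag_slope_h_per_log10: float = 4.5
    lag_slope_high_dose_h_per_log10: float = 0.25
    lag_jitter_sd_h: float = 0.5
    read_noise_sd_rfu: float = 500.0

    def __post_init__(self) -> None:
        for name in (
            "baseline_rfu_mean", "plateau_rfu_mean", "growth_tau_h",
            "lag_intercept_h", "lag_slope_h_per_log10",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"KineticParams.{name} must be positive")
        for name in (
            "baseline_rfu_sd", "plateau_rfu_sd", "lag_jitter_sd_h",
            "read_noise_sd_rfu", "lag_slope_high_dose_h_per_log10",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"KineticParams.{name} must be >= 0")
        if self.plateau_rfu_mean <= self.baseline_rfu_mean:
            raise ValidationError("plateau mean must exceed baseline mean")

    def lag_midpoint_h(self, effective_dose: float) -> float:
        """Deterministic logistic-midpoint lag for a given effective dose.

        Strictly decreasing in dose: ``lag_slope_h_per_log10`` hours per
        decade below one seeding unit, ``lag_slope_high_dose_h_per_log10``
        per decade above it.
        """
        if effective_dose <= 0:
            raise ValidationError("lag is undefined for non-positive dose")
        shortfall = -math.log10(effective_dose)
        return (
            self.lag_intercept_h
            + self.lag_slope_h_per_log10 * max(0.0, shortfall)
            + self.lag_slope_high_dose_h_per_log10 * min(0.0, shortfall)
        )


@dataclass(frozen=True)
class SampleTruth:
    """Ground-truth seeding parameters for one simulated sample.

    ``log10_titre`` is log10 of the expected seeding units delivered per
    reaction at dilution 10^0, so the effective dose at exponent e is
    10^(log10_titre + e); ``-inf`` makes an unseeded (control) sample.
    Inhibition at the exponents in ``inhibition_exponent_set`` (default
    {-3}) multiplies the dose by ``inhibition_dose_factor`` and shrinks the
    plateau toward baseline by ``inhibition_plateau_factor`` — incomplete
    removal of reaction inhibitors at the least dilute seeding shows up as
    both a longer lag and a lower RFU_max/RFU_initial ratio.
    """

    sample_id: str
    log10_titre: float
    p_spontaneous: float = 0.02
    inhibition_exponent_set: frozenset[int] = frozenset({-3})
    inhibition_dose_factor: float = 0.5
    inhibition_plateau_factor: float = 0.6
    meta: SampleMeta | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_spontaneous <= 0.05):
            raise ValidationError("p_spontaneous must lie in [0, 0.05]")
        for name in ("inhibition_dose_factor", "inhibition_plateau_factor"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValidationError(f"{name} must lie in (0, 1]")
        object.__setattr__(
            self, "inhibition_exponent_set",
            frozenset(int(e) for e in self.inhibition_exponent_set),
        )

    @property
    def is_seeded(self) -> bool:
        return self.log10_titre > NEG_INF

    def effective_dose(self, dilution_exponent: int) -> float:
        """Expected seeding units per reaction at a dilution, after any
        inhibition attenuation at that dilution."""
        if not self.is_seeded:
            return 0.0
        dose = math.pow(10.0, self.log10_titre + dilution_exponent)
        if int(dilution_exponent) in self.inhibition_exponent_set:
            dose *= self.inhibition_dose_factor
        return dose

    def resolved_meta(self) -> SampleMeta:
        if self.meta is not None:
            return self.meta
        return SampleMeta(
            sample_id=self.sample_id,
            subject_id=self.sample_id,
            genotype="transgenic" if self.is_seeded else "non_carrier",
        )


@dataclass(frozen=True)
class SimConfig:
    """Full specification of one simulated plate."""

    plate_id: str
    samples: tuple[SampleTruth, ...]
    dilution_exponents: dict[str, tuple[int, ...]]
    rng_seed: int
    kinetic: KineticParams = field(default_factory=KineticParams)
    replicates: int = 4
    run_length_h: float = DEFAULT_ANALYSIS_WINDOW_H
    read_interval_h: float = 1.0
    saturation_rfu: float = DEFAULT_SATURATION_RFU

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(ids) != len(set(ids)):
            raise ValidationError("duplicate sample ids in SimConfig")
        if self.replicates < 1:
            raise ValidationError("replicates must be >= 1")
        missing = [sid for sid in ids if sid not in self.dilution_exponents]
        if missing:
            raise ValidationError(
                "samples without dilution series: " + ", ".join(missing)
            )
        for sid, exps in self.dilution_exponents.items():
            if not exps:
                raise ValidationError(f"sample {sid}: empty dilution series")
            if any(e > 0 for e in exps):
                raise ValidationError(f"sample {sid}: dilution exponents must be <= 0")

    @property
    def n_wells(self) -> int:
        return sum(
            len(self.dilution_exponents[s.sample_id]) * self.replicates
            for s in self.samples
        )


@dataclass(frozen=True)
class WellTruth:
    """Per-well generative ground truth."""

    well_id: str
    sample_id: str
    dilution_exponent: int
    replicate_index: int
    converted: bool
    spontaneous: bool
    effective_dose: float
    true_lag_h: float | None


@dataclass
class SimResult:
    """A simulated plate together with its truth tables."""

    plate: PlateRun
    well_truth: list[WellTruth]
    sample_endpoints: dict[str, int | None]

    def truth_by_well(self) -> dict[str, WellTruth]:
        return {t.well_id: t for t in self.well_truth}


def conversion_probability(effective_dose: float) -> float:
    """Single-hit Poisson conversion probability, 1 - exp(-dose).

    With the effective dose read as the expected number of competent seeding
    units delivered to the well, conversion occurs when at least one unit is
    present: monotone in dose, 0 at dose 0, ~0.632 at one unit per well.
    """
    if effective_dose < 0:
        raise ValidationError("effective dose must be >= 0")
    return float(-math.expm1(-effective_dose))


def analytic_endpoint(
    truth: SampleTruth,
    exponents: Sequence[int],
    replicates: int = 4,
    min_positive_replicates: int = 2,
) -> int | None:
    """Most dilute tested exponent where the replicate rule succeeds in
    expectation: P(at least ``min_positive_replicates`` of ``replicates``
    wells convert) >= 1/2.  ``None`` when no tested dilution qualifies."""
    best: int | None = None
    for e in sorted(set(int(x) for x in exponents), reverse=True):
        p = conversion_probability(truth.effective_dose(e))
        prob_positive = sum(
            math.comb(replicates, k) * p**k * (1 - p) ** (replicates - k)
            for k in range(min_positive_replicates, replicates + 1)
        )
        if prob_positive >= 0.5:
            best = e
    return best


def _well_rng(rng_seed: int, plate_id: str, sample_id: str,
              dilution_exponent: int, replicate_index: int) -> np.random.Generator:
    """Independent substream per well; keys are stable CRC32 hashes so the
    stream depends only on the well's identity, never on simulation order."""
    key = (
        int(rng_seed) & 0xFFFFFFFF,
        zlib.crc32(plate_id.encode("utf-8")),
        zlib.crc32(sample_id.encode("utf-8")),
        int(dilution_exponent) + 64,
        int(replicate_index),
    )
    return np.random.default_rng(np.random.SeedSequence(key))


def simulate_well(
    truth: SampleTruth,
    dilution_exponent: int,
    kinetic: KineticParams,
    grid: TimeGrid,
    rng: np.random.Generator,
    well_id: str = "A1",
    replicate_index: int = 1,
    saturation_rfu: float = DEFAULT_SATURATION_RFU,
) -> tuple[WellRecord, WellTruth]:
    """Simulate one well: conversion draw, then kinetics.

    A seeded well converts with the single-hit probability of its effective
    dose; an unseeded well converts spontaneously with ``p_spontaneous``, in
    which case the lag midpoint is drawn uniformly over the final third of
    the run (late, isolated responses are exactly what the spontaneous
    channel emulates).  Non-converted wells are baseline plus read noise.
    """
    times = grid.times_h
    baseline = float(rng.normal(kinetic.baseline_rfu_mean, kinetic.baseline_rfu_sd))
    baseline = max(baseline, 0.0)
    dose = truth.effective_dose(dilution_exponent)
    if truth.is_seeded:
        p_convert = conversion_probability(dose)
        spontaneous_channel = False
    else:
        p_convert = truth.p_spontaneous
        spontaneous_channel = True
    converted = bool(rng.random() < p_convert)

    lag: float | None = None
    if converted:
        if spontaneous_channel:
            run_end = grid.max_h
            lag = float(rng.uniform(run_end * 2.0 / 3.0, run_end))
        else:
            lag = kinetic.lag_midpoint_h(dose) + float(
                rng.normal(0.0, kinetic.lag_jitter_sd_h)
            )
        plateau = float(rng.normal(kinetic.plateau_rfu_mean, kinetic.plateau_rfu_sd))
        plateau = max(plateau, baseline + 1.0)
        if int(dilution_exponent) in truth.inhibition_exponent_set and truth.is_seeded:
            plateau = baseline + (plateau - baseline) * truth.inhibition_plateau_factor
        with np.errstate(over="ignore"):  # exp overflow -> signal = baseline
            signal = baseline + (plateau - baseline) / (
                1.0 + np.exp(-(times - lag) / kinetic.growth_tau_h)
            )
    else:
        signal = np.full_like(times, baseline)

    noise = rng.normal(0.0, kinetic.read_noise_sd_rfu, size=len(times))
    trace = np.clip(signal + noise, 0.0, saturation_rfu)
    record = WellRecord(well_id=well_id, fluorescence=trace)
    wt = WellTruth(
        well_id=well_id,
        sample_id=truth.sample_id,
        dilution_exponent=int(dilution_exponent),
        replicate_index=replicate_index,
        converted=converted,
        spontaneous=converted and spontaneous_channel,
        effective_dose=dose,
        true_lag_h=lag,
    )
    return record, wt


def simulate_plate(
    config: SimConfig,
    min_positive_replicates: int = 2,
) -> SimResult:
    """Simulate a whole plate from a :class:`SimConfig`.

    Wells are laid out row-major (A1, A2, ... H12) in sample order.  The
    result carries per-well conversion truth and, per sample, the analytic
    endpoint of the ``min_positive_replicates``-of-n rule.  Deterministic
    given ``rng_seed``; each well's draws come from its own keyed substream.
    """
    if config.n_wells > PLATE_CAPACITY:
        raise ValidationError(
            f"plate {config.plate_id}: {config.n_wells} wells exceed the "
            f"{PLATE_CAPACITY}-well plate; split the design across plates"
        )
    grid = TimeGrid.hourly(config.run_length_h, config.read_interval_h)
    well_ids = [f"{r}{c}" for r in _ROWS for c in _COLS]
    wells: dict[str, WellRecord] = {}
    metas: dict[str, WellMeta] = {}
    truths: list[WellTruth] = []
    sample_meta: dict[str, SampleMeta] = {}
    endpoints: dict[str, int | None] = {}
    i = 0
    for sample in config.samples:
        sm = sample.resolved_meta()
        sample_meta[sample.sample_id] = sm
        exps = config.dilution_exponents[sample.sample_id]
        endpoints[sample.sample_id] = analytic_endpoint(
            sample, exps, config.replicates, min_positive_replicates
        )
        for e in exps:
            for rep in range(1, config.replicates + 1):
                wid = well_ids[i]
                i += 1
                rng = _well_rng(config.rng_seed, config.plate_id,
                                sample.sample_id, e, rep)
                rec, wt = simulate_well(
                    sample, e, config.kinetic, grid, rng,
                    well_id=wid, replicate_index=rep,
                    saturation_rfu=config.saturation_rfu,
                )
                wells[wid] = rec
                truths.append(wt)
                metas[wid] = WellMeta(
                    well_id=wid,
                    sample_id=sample.sample_id,
                    dilution_exponent=int(e),
                    replicate_index=rep,
                    is_control=sm.is_non_carrier,
                )
    plate = PlateRun(
        plate_id=config.plate_id,
        time_grid=grid,
        wells=wells,
        well_meta=metas,
        sample_meta=sample_meta,
        saturation_rfu=config.saturation_rfu,
        analysis_window_h=min(DEFAULT_ANALYSIS_WINDOW_H, grid.max_h),
    )
    return SimResult(plate=plate, well_truth=truths, sample_endpoints=endpoints)


# ---------------------------------------------------------------------------
# Study-shaped presets
# ---------------------------------------------------------------------------

#: log10 effective dose at the analytic 2-of-4 endpoint.  10^0.52 ~ 3.3
#: seeding units makes the endpoint dilution robustly positive while one
#: decade further (~0.33 units) has P(2+ of 4 convert) ~ 0.32 < 1/2.
_ENDPOINT_MARGIN = 0.52

#: When the endpoint itself is an inhibited dilution, the next (uninhibited)
#: dilution sees dose/(10*factor) rather than dose/10, so the endpoint's
#: effective dose must stay below ~2.4 units for the rule to fail there in
#: expectation; 10^0.301 = 2.0 units balances both sides.
_ENDPOINT_MARGIN_INHIBITED = math.log10(2.0)


def titre_for_endpoint(endpoint_exponent: int | None,
                       inhibited_at: frozenset[int] = frozenset({-3}),
                       inhibition_dose_factor: float = 0.5) -> float:
    """log10 titre whose analytic 2-of-4 endpoint is ``endpoint_exponent``.

    When the target endpoint is itself an inhibited dilution the titre
    compensates for the dose attenuation so the *effective* dose at the
    endpoint sits at the calibrated margin.  ``None`` (ND) gives an
    unseeded sample.
    """
    if endpoint_exponent is None:
        return NEG_INF
    if int(endpoint_exponent) in inhibited_at:
        return (
            -float(endpoint_exponent)
            + _ENDPOINT_MARGIN_INHIBITED
            - math.log10(inhibition_dose_factor)
        )
    return -float(endpoint_exponent) + _ENDPOINT_MARGIN


# (subject, tissue) -> (endpoint exponent or None, tested dilution exponents)
# mirroring the study cohort: three carriers and one non-carrier control per
# age, brains and colons, controls seeded at 10^-3 only.
_COHORT_DESIGN: dict[str, list[tuple[str, str, int | None, tuple[int, ...]]]] = {
    "study-12m": [
        ("12M-#1", "brain", -5, (-3, -4, -5, -6, -7, -8)),
        ("12M-#2", "brain", -8, (-3, -4, -5, -6, -7, -8)),
        ("12M-#3", "brain", -5, (-3, -4, -5, -6, -7, -8)),
        ("12M-Con", "brain", None, (-3,)),
        ("12M-#1", "colon", -5, (-3, -4, -5)),
        ("12M-#2", "colon", -5, (-3, -4, -5)),
        ("12M-#3", "colon", -5, (-3, -4, -5)),
        ("12M-Con", "colon", None, (-3,)),
    ],
    "study-6m": [
        ("6M-#1", "brain", None, (-3, -4, -5)),
        ("6M-#2", "brain", -3, (-3, -4, -5)),
        ("6M-#3", "brain", None, (-3, -4, -5)),
        ("6M-Con", "brain", None, (-3,)),
        ("6M-#1", "colon", -5, (-3, -4, -5)),
        ("6M-#2", "colon", -5, (-3, -4, -5)),
        ("6M-#3", "colon", -3, (-3, -4, -5)),
        ("6M-Con", "colon", None, (-3,)),
    ],
    "study-3m": [
        ("3M-#1", "brain", None, (-3, -4, -5)),
        ("3M-#2", "brain", None, (-3, -4, -5)),
        ("3M-#3", "brain", None, (-3, -4, -5)),
        ("3M-Con", "brain", None, (-3,)),
        ("3M-#1", "colon", -4, (-3, -4, -5)),
        ("3M-#2", "colon", -3, (-3, -4)),
        ("3M-#3", "colon", -3, (-3, -4)),
        ("3M-Con", "colon", None, (-3,)),
    ],
    "study-1m": [
        ("1M-#1", "colon", None, (-3, -4)),
        ("1M-#2", "colon", None, (-3, -4)),
        ("1M-#3", "colon", None, (-3, -4)),
        ("1M-Con", "colon", None, (-3,)),
    ],
}

PRESET_NAMES = tuple(_COHORT_DESIGN)

_AGE_BY_PRESET = {"study-12m": 12, "study-6m": 6, "study-3m": 3, "study-1m": 1}


def preset_configs(
    name: str,
    rng_seed: int,
    kinetic: KineticParams | None = None,
) -> list[SimConfig]:
    """Build the per-tissue plate configs for a study-shaped preset.

    Each preset covers one age group (three carrier subjects plus one
    non-carrier control), with one plate per tissue and per-sample titres
    set so the analytic endpoints reproduce the cohort's endpoint pattern.
    """
    if name not in _COHORT_DESIGN:
        raise ValidationError(
            f"unknown preset {name!r}; choose from {', '.join(PRESET_NAMES)}"
        )
    kinetic = kinetic or KineticParams()
    age = _AGE_BY_PRESET[name]
    by_tissue: dict[str, list[tuple[str, int | None, tuple[int, ...]]]] = {}
    for subject, tissue, endpoint, exps in _COHORT_DESIGN[name]:
        by_tissue.setdefault(tissue, []).append((subject, endpoint, exps))
    configs = []
    for tissue, entries in by_tissue.items():
        samples = []
        dilutions: dict[str, tuple[int, ...]] = {}
        for subject, endpoint, exps in entries:
            sid = f"{subject}-{tissue}"
            non_carrier = subject.endswith("Con")
            samples.append(
                SampleTruth(
                    sample_id=sid,
                    log10_titre=titre_for_endpoint(endpoint),
                    meta=SampleMeta(
                        sample_id=sid,
                        subject_id=subject,
                        age_months=age,
                        genotype="non_carrier" if non_carrier else "transgenic",
                        tissue=tissue,
                        homogenate_percent=10.0 if tissue == "brain" else 5.0,
                    ),
                )
            )
            dilutions[sid] = tuple(int(e) for e in exps)
        configs.append(
            SimConfig(
                plate_id=f"{name}-{tissue}",
                samples=tuple(samples),
                dilution_exponents=dilutions,
                rng_seed=int(rng_seed),
                kinetic=kinetic,
            )
        )
    return configs


def simulate_study_cohort(
    rng_seed: int,
    presets: Iterable[str] = PRESET_NAMES,
    kinetic: KineticParams | None = None,
) -> list[SimResult]:
    """Simulate the full study-shaped cohort (all presets, one seed)."""
    results = []
    for name in presets:
        for config in preset_configs(name, rng_seed, kinetic=kinetic):
            results.append(simulate_plate(config))
    return results
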