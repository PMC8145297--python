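"""Per-plate threshold computation and replicate-based positivity calling.

The positivity threshold is computed plate by plate: the first
``n_baseline_reads`` (default five) readings of every non-excluded well are
pooled into one set, and the threshold is that pool's mean plus
``sd_multiplier`` (default 10) sample standard deviations.  Controls are
seeded reactions like any other and are pooled by default.  A sample x
dilution group is called positive when at least ``min_positive_replicates``
(default 2) of its replicate wells cross the threshold; a group where exactly
one well crossed is negative but flagged as a spontaneous positive, preserving
the audit trail for late single-well conversions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .metrics import WellMetrics, compute_metrics
from .model import PlateRun, RuleConfig, ValidationError

__all__ = [
    "ThresholdResult",
    "SampleCall",
    "PlateCallResult",
    "plate_threshold",
    "call_sample",
    "call_plate",
]


@dataclass(frozen=True)
class ThresholdResult:
    """A per-plate threshold with its provenance.

    Invariant: ``threshold_rfu == pooled_mean + sd_multiplier * pooled_sd``
    exactly (the pooled SD uses the n-1 denominator, so the quantity is
    reproducible bit for bit).
    """

    plate_id: str
    threshold_rfu: float
    n_baseline_reads: int
    sd_multiplier: float
    n_wells_pooled: int
    pooled_mean: float
    pooled_sd: float


@dataclass(frozen=True)
class SampleCall:
    """Positive/negative call for one sample x dilution replicate group."""

    sample_id: str
    dilution_exponent: int
    n_replicates: int
    n_positive_wells: int
    call: str  # "positive" | "negative"
    spontaneous_flag: bool

    @property
    def is_positive(self) -> bool:
        return self.call == "positive"


@dataclass
class PlateCallResult:
    """Threshold, per-well metrics, and per-group calls for one plate."""

    plate_id: str
    threshold: ThresholdResult
    metrics: dict[str, WellMetrics]
    calls: list[SampleCall] = field(default_factory=list)


def plate_threshold(plate: PlateRun, config: RuleConfig | None = None) -> ThresholdResult:
    """Compute the plate's ThT positivity threshold.

    Pools the first ``config.n_baseline_reads`` readings of every
    non-excluded well (controls included unless
    ``include_controls_in_threshold`` is off) and returns
    mean + ``sd_multiplier`` x sample SD of that pooled set.
    """
    config = config or RuleConfig()
    if len(plate.time_grid) < config.n_baseline_reads:
        raise ValidationError(
            f"plate {plate.plate_id}: grid has {len(plate.time_grid)} reads, "
            f"fewer than the {config.n_baseline_reads} baseline reads required"
        )
    wells = plate.active_wells()
    if not config.include_controls_in_threshold:
        wells = [w for w in wells if not plate.well_meta[w.well_id].is_control]
    if len(wells) < 2:
        raise ValidationError(
            f"plate {plate.plate_id}: need >= 2 wells to estimate a threshold, "
            f"got {len(wells)}"
        )
    pooled = np.concatenate(
        [w.fluorescence[: config.n_baseline_reads] for w in wells]
    )
    mean = float(pooled.mean())
    sd = float(pooled.std(ddof=1))
    return ThresholdResult(
        plate_id=plate.plate_id,
        threshold_rfu=mean + config.sd_multiplier * sd,
        n_baseline_reads=config.n_baseline_reads,
        sd_multiplier=config.sd_multiplier,
        n_wells_pooled=len(wells),
        pooled_mean=mean,
        pooled_sd=sd,
    )


def call_sample(
    sample_id: str,
    dilution_exponent: int,
    well_metrics: Sequence[WellMetrics],
    config: RuleConfig | None = None,
) -> SampleCall:
    """Call one sample x dilution group from its replicate wells' metrics.

    Positive iff at least ``min_positive_replicates`` wells crossed the
    threshold; a group with exactly one crossing well is negative with
    ``spontaneous_flag`` set.
    """
    config = config or RuleConfig()
    if not well_metrics:
        raise ValidationError(
            f"{sample_id} @ 10^{dilution_exponent}: empty replicate group"
        )
    n = len(well_metrics)
    if n < config.min_positive_replicates:
        raise ValidationError(
            f"{sample_id} @ 10^{dilution_exponent}: {n} replicate(s) cannot "
            f"satisfy the >= {config.min_positive_replicates}-replicate rule"
        )
    n_positive = sum(m.crossed for m in well_metrics)
    return SampleCall(
        sample_id=sample_id,
        dilution_exponent=int(dilution_exponent),
        n_replicates=n,
        n_positive_wells=n_positive,
        call="positive" if n_positive >= config.min_positive_replicates else "negative",
        spontaneous_flag=(n_positive == 1),
    )


def call_plate(plate: PlateRun, config: RuleConfig | None = None) -> PlateCallResult:
    """Threshold a plate and call every sample x dilution group on it.

    Metrics are computed against the plate's own threshold over the plate's
    analysis window; excluded wells contribute to nothing.  Deterministic:
    re-calling the same plate gives identical output.
    """
    config = config or RuleConfig()
    thr = plate_threshold(plate, config)
    metrics: dict[str, WellMetrics] = {}
    calls: list[SampleCall] = []
    for (sample_id, exponent), well_ids in plate.iter_groups():
        group_metrics = []
        for wid in well_ids:
            m = compute_metrics(
                plate.wells[wid],
                plate.time_grid,
                threshold=thr.threshold_rfu,
                window_h=plate.analysis_window_h,
                saturation_rfu=plate.saturation_rfu,
            )
            metrics[wid] = m
            group_metrics.append(m)
        calls.append(call_sample(sample_id, exponent, group_metrics, config))
    return PlateCallResult(plate_id=plate.plate_id, threshold=thr,
                           metrics=metrics, calls=calls)
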