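"""Core data model for RT-QuIC plate runs.

An RT-QuIC (real-time quaking-induced conversion) run is a plate-reader time
course: every well holds a seeded amyloid-conversion reaction whose thioflavin
T (ThT) fluorescence, in relative fluorescence units (RFU), is read on a shared
time grid (nominally hourly over >= 40 h).  A samplesheet maps each well to a
tissue sample, its serial dilution, and its replicate index.  Everything
downstream — per-well kinetics, the per-plate positivity threshold, replicate
calling, endpoint titration — consumes only the :class:`PlateRun` built here
plus a :class:`RuleConfig`; no analysis code touches files directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "ValidationError",
    "TimeGrid",
    "WellRecord",
    "SampleMeta",
    "WellMeta",
    "PlateRun",
    "RuleConfig",
    "DEFAULT_SATURATION_RFU",
    "DEFAULT_ANALYSIS_WINDOW_H",
]

#: Ceiling of the plate reader's dynamic range; readings clip here.
DEFAULT_SATURATION_RFU = 260_000.0

#: Length of the reaction window over which kinetics are evaluated (hours).
DEFAULT_ANALYSIS_WINDOW_H = 40.0

#: Minimum number of reads a grid must carry: the threshold uses the first
#: five baseline reads and at least one post-baseline read must exist.
MIN_GRID_READS = 6

GENOTYPES = ("transgenic", "non_carrier")
TISSUES = ("brain", "colon")


class ValidationError(ValueError):
    """A structural problem in plate data or configuration."""


def _as_float_array(values: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional, got shape {arr.shape}")
    return arr


@dataclass(frozen=True)
class TimeGrid:
    """Shared read schedule for every well on a plate.

    Times are in hours from reaction start.  The nominal schedule is one read
    per hour, but irregular spacing is representable; the only requirements
    are strict monotonicity and enough reads to support baseline thresholding.
    """

    times_h: np.ndarray

    def __post_init__(self) -> None:
        arr = _as_float_array(self.times_h, "times_h")
        if len(arr) < MIN_GRID_READS:
            raise ValidationError(
                f"time grid needs >= {MIN_GRID_READS} reads "
                f"(baseline window plus at least one later read), got {len(arr)}"
            )
        if not np.all(np.isfinite(arr)):
            raise ValidationError("time grid contains non-finite values")
        if arr[0] < 0:
            raise ValidationError(f"first read time must be >= 0 h, got {arr[0]}")
        if not np.all(np.diff(arr) > 0):
            raise ValidationError("time grid must be strictly increasing")
        object.__setattr__(self, "times_h", arr)

    def __len__(self) -> int:
        return len(self.times_h)

    @property
    def max_h(self) -> float:
        return float(self.times_h[-1])

    @classmethod
    def hourly(cls, run_length_h: float = DEFAULT_ANALYSIS_WINDOW_H,
               interval_h: float = 1.0) -> "TimeGrid":
        """Grid with a read at t=0 and then every ``interval_h`` hours."""
        n = int(math.floor(run_length_h / interval_h + 1e-9)) + 1
        return cls(np.arange(n, dtype=float) * interval_h)


@dataclass(frozen=True)
class WellRecord:
    """One well's fluorescence trace, aligned to the plate's TimeGrid."""

    well_id: str
    fluorescence: np.ndarray
    excluded: bool = False

    def __post_init__(self) -> None:
        arr = _as_float_array(self.fluorescence, f"fluorescence[{self.well_id}]")
        if not self.excluded:
            if not np.all(np.isfinite(arr)):
                raise ValidationError(
                    f"well {self.well_id}: missing/non-finite readings in a "
                    "non-excluded well"
                )
            if np.any(arr < 0):
                raise ValidationError(f"well {self.well_id}: negative RFU reading")
        object.__setattr__(self, "fluorescence", arr)


@dataclass(frozen=True)
class SampleMeta:
    """Sample-level metadata (one tissue specimen from one subject).

    ``genotype`` and ``tissue`` are controlled vocabularies with an explicit
    escape: any other string is accepted and passed through untouched.
    ``homogenate_percent`` is descriptive only (the study used 10% w/v brain
    and 5% w/v colon homogenates); dilutions are always expressed relative to
    tissue, not to the homogenate.
    """

    sample_id: str
    subject_id: str
    age_months: int | None = None
    genotype: str = "transgenic"
    tissue: str = "brain"
    homogenate_percent: float | None = None

    @property
    def is_non_carrier(self) -> bool:
        return self.genotype == "non_carrier"


@dataclass(frozen=True)
class WellMeta:
    """Mapping of one well to (sample, dilution, replicate).

    ``dilution_exponent`` is the integer e in the tissue-relative dilution
    10^e (so -3 means a 10^-3 dilution of tissue; -2 is a 1% homogenate).
    Dilutions are stored as integer exponents only, never floats.
    """

    well_id: str
    sample_id: str
    dilution_exponent: int
    replicate_index: int
    is_control: bool = False

    def __post_init__(self) -> None:
        if not isinstance(self.dilution_exponent, (int, np.integer)):
            raise ValidationError(
                f"well {self.well_id}: dilution_exponent must be an integer "
                f"(10^e convention), got {self.dilution_exponent!r}"
            )
        if self.dilution_exponent > 0:
            raise ValidationError(
                f"well {self.well_id}: dilution_exponent must be <= 0, "
                f"got {self.dilution_exponent}"
            )
        if self.replicate_index < 1:
            raise ValidationError(
                f"well {self.well_id}: replicate_index must be >= 1"
            )

    @property
    def group_key(self) -> tuple[str, int]:
        return (self.sample_id, int(self.dilution_exponent))


@dataclass
class PlateRun:
    """A validated plate run: time grid, traces, and well/sample metadata."""

    plate_id: str
    time_grid: TimeGrid
    wells: dict[str, WellRecord]
    well_meta: dict[str, WellMeta]
    sample_meta: dict[str, SampleMeta] = field(default_factory=dict)
    saturation_rfu: float = DEFAULT_SATURATION_RFU
    analysis_window_h: float = DEFAULT_ANALYSIS_WINDOW_H
    truncated: bool = field(init=False, default=False)

    def __post_init__(self) -> None:
        if self.saturation_rfu <= 0:
            raise ValidationError("saturation_rfu must be positive")
        if self.analysis_window_h <= 0:
            raise ValidationError("analysis_window_h must be positive")
        missing_meta = sorted(set(self.wells) - set(self.well_meta))
        if missing_meta:
            raise ValidationError(
                "wells present in curves but absent from samplesheet: "
                + ", ".join(missing_meta)
            )
        orphan_meta = sorted(set(self.well_meta) - set(self.wells))
        if orphan_meta:
            raise ValidationError(
                "samplesheet wells with no fluorescence data: "
                + ", ".join(orphan_meta)
            )
        n = len(self.time_grid)
        seen_groups: dict[tuple[str, int, int], str] = {}
        for wid, rec in self.wells.items():
            if rec.well_id != wid:
                raise ValidationError(f"well record keyed {wid} carries id {rec.well_id}")
            if len(rec.fluorescence) != n:
                raise ValidationError(
                    f"well {wid}: {len(rec.fluorescence)} readings but the "
                    f"plate grid has {n} times"
                )
            if not rec.excluded and np.any(rec.fluorescence > self.saturation_rfu):
                raise ValidationError(
                    f"well {wid}: reading above saturation "
                    f"({self.saturation_rfu:g} RFU)"
                )
            meta = self.well_meta[wid]
            key = (meta.sample_id, int(meta.dilution_exponent), meta.replicate_index)
            if key in seen_groups:
                raise ValidationError(
                    f"duplicate (sample, dilution, replicate) {key}: wells "
                    f"{seen_groups[key]} and {wid}"
                )
            seen_groups[key] = wid
            if self.sample_meta and meta.sample_id not in self.sample_meta:
                raise ValidationError(
                    f"well {wid}: sample {meta.sample_id!r} has no sample metadata"
                )
        # A window longer than the run is allowed but flagged, so reports can
        # say the 40-h window was not fully observed.
        self.truncated = self.analysis_window_h > self.time_grid.max_h + 1e-9

    # -- convenience accessors -------------------------------------------------

    def active_wells(self) -> list[WellRecord]:
        """Non-excluded wells in well-id order."""
        return [self.wells[w] for w in sorted(self.wells) if not self.wells[w].excluded]

    def iter_groups(self) -> Iterator[tuple[tuple[str, int], list[str]]]:
        """Yield ((sample_id, dilution_exponent), well_ids) for non-excluded
        wells, sorted by sample then by dilution from least to most dilute."""
        groups: dict[tuple[str, int], list[str]] = {}
        for wid in sorted(self.wells):
            if self.wells[wid].excluded:
                continue
            groups.setdefault(self.well_meta[wid].group_key, []).append(wid)
        for key in sorted(groups, key=lambda k: (k[0], -k[1])):
            yield key, groups[key]


@dataclass(frozen=True)
class RuleConfig:
    """Analysis rule parameters with the study's defaults.

    * the per-plate threshold is the mean of the first ``n_baseline_reads``
      readings pooled over wells, plus ``sd_multiplier`` pooled sample SDs;
    * a sample x dilution group is positive when at least
      ``min_positive_replicates`` of its wells cross that threshold
      (2 of 4 quadruplicates by default);
    * ``lag_convention`` fixes how lag is read off the grid; the only
      supported value takes the first read at or above threshold, with no
      interpolation between hourly reads.
    """

    n_baseline_reads: int = 5
    sd_multiplier: float = 10.0
    min_positive_replicates: int = 2
    expected_replicates: int = 4
    include_controls_in_threshold: bool = True
    lag_convention: str = "first_at_or_above"

    def __post_init__(self) -> None:
        if self.n_baseline_reads < 2:
            raise ValidationError("n_baseline_reads must be >= 2")
        if self.sd_multiplier <= 0:
            raise ValidationError("sd_multiplier must be positive")
        if not (1 <= self.min_positive_replicates <= self.expected_replicates):
            raise ValidationError(
                "need 1 <= min_positive_replicates <= expected_replicates, got "
                f"{self.min_positive_replicates} / {self.expected_replicates}"
            )
        if self.lag_convention != "first_at_or_above":
            raise ValidationError(
                f"unsupported lag_convention {self.lag_convention!r}; "
                "only 'first_at_or_above' is implemented"
            )

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, object]) -> "RuleConfig":
        known = {f for f in cls.__dataclass_fields__}  # type: ignore[attr-defined]
        unknown = sorted(set(mapping) - known)
        if unknown:
            raise ValidationError(f"unknown rule-config fields: {', '.join(unknown)}")
        return cls(**mapping)  # type: ignore[arg-type]
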