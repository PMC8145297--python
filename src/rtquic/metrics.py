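"""Per-well kinetic curve metrics.

For each well the assay reads three things off the raw trace: the starting
fluorescence (RFU_initial), the maximum over the 40-h analysis window
(RFU_max), and their ratio RFU_max/RFU_initial; plus whether and when the
trace crossed the plate's positivity threshold.  Lag is the first measured
timepoint at or above threshold — no interpolation between reads, because the
hourly schedule is the assay's native resolution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model import TimeGrid, ValidationError, WellRecord

__all__ = ["WellMetrics", "compute_metrics"]


@dataclass(frozen=True)
class WellMetrics:
    """Kinetics of a single well against a given threshold and window.

    ``lag_h`` is defined iff ``crossed``.  ``rfu_ratio`` is NaN and
    ``ratio_undefined`` is set when the starting read is exactly zero (a
    degenerate trace, not an exception).  Because the window always includes
    t0, ``rfu_max >= rfu_initial`` and hence ``rfu_ratio >= 1`` whenever the
    ratio is defined.
    """

    well_id: str
    rfu_initial: float
    rfu_max: float
    rfu_ratio: float
    crossed: bool
    lag_h: float | None
    saturated: bool
    ratio_undefined: bool = False


def compute_metrics(
    well: WellRecord,
    grid: TimeGrid,
    threshold: float,
    window_h: float,
    saturation_rfu: float | None = None,
) -> WellMetrics:
    """Compute :class:`WellMetrics` for one well.

    Parameters
    ----------
    well : WellRecord
        Non-excluded well trace aligned to ``grid``.
    grid : TimeGrid
        The plate's read schedule.
    threshold : float
        Positivity threshold in RFU; a reading counts as crossing when it is
        at or above this value ("at or above" keeps ties deterministic).
    window_h : float
        Analysis window in hours; reads at times <= ``window_h`` (t0 always
        included) contribute to RFU_max, crossing, and lag.
    saturation_rfu : float, optional
        Instrument ceiling; when given, ``saturated`` flags any in-window
        reading equal to it.  Saturated reads are evidence of positivity and
        are never dropped.
    """
    if well.excluded:
        raise ValidationError(f"well {well.well_id} is excluded from analysis")
    if threshold <= 0:
        raise ValidationError("threshold must be positive")
    if window_h <= 0:
        raise ValidationError("window_h must be positive")
    if len(well.fluorescence) != len(grid):
        raise ValidationError(
            f"well {well.well_id}: trace length {len(well.fluorescence)} does "
            f"not match grid length {len(grid)}"
        )

    times = grid.times_h
    in_window = times <= window_h + 1e-9
    in_window[0] = True  # window always includes the starting read
    trace = well.fluorescence[in_window]
    wtimes = times[in_window]

    rfu_initial = float(well.fluorescence[0])
    rfu_max = float(trace.max())
    if rfu_initial == 0.0:
        rfu_ratio = math.nan
        ratio_undefined = True
    else:
        rfu_ratio = rfu_max / rfu_initial
        ratio_undefined = False

    above = trace >= threshold
    crossed = bool(above.any())
    lag_h = float(wtimes[int(np.argmax(above))]) if crossed else None
    saturated = bool(
        saturation_rfu is not None and np.any(trace >= saturation_rfu)
    )
    return WellMetrics(
        well_id=well.well_id,
        rfu_initial=rfu_initial,
        rfu_max=rfu_max,
        rfu_ratio=rfu_ratio,
        crossed=crossed,
        lag_h=lag_h,
        saturated=saturated,
        ratio_undefined=ratio_undefined,
    )
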