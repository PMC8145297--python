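import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from rtquic.model import PlateRun, SampleMeta, TimeGrid, WellMeta, WellRecord

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


def build_plate(
    traces: dict[str, list[float]],
    times=None,
    plate_id: str = "toy",
    replicates_per_sample: int = 1,
    **plate_kwargs,
) -> PlateRun:
    """Assemble a minimal valid PlateRun: one sample per well by default."""
    first = next(iter(traces.values()))
    if times is None:
        times = np.arange(len(first), dtype=float)
    grid = TimeGrid(np.asarray(times, dtype=float))
    wells = {
        wid: WellRecord(well_id=wid, fluorescence=np.asarray(vals, dtype=float))
        for wid, vals in traces.items()
    }
    meta = {}
    sample_meta = {}
    for i, wid in enumerate(sorted(traces)):
        sid = f"s{i // replicates_per_sample}"
        meta[wid] = WellMeta(
            well_id=wid,
            sample_id=sid,
            dilution_exponent=-3,
            replicate_index=i % replicates_per_sample + 1,
        )
        sample_meta.setdefault(sid, SampleMeta(sample_id=sid, subject_id=sid))
    return PlateRun(
        plate_id=plate_id,
        time_grid=grid,
        wells=wells,
        well_meta=meta,
        sample_meta=sample_meta,
        **plate_kwargs,
    )


@pytest.fixture
def plate_factory():
    return build_plate
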