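"""Readers and writers for the pipeline's tabular formats.

The canonical curve format is a long-format CSV with columns
``plate_id, well_id, time_h, rfu`` — unambiguous even for irregular read
grids.  A wide dialect (one column per well) is accepted as a convenience.
The samplesheet maps wells to samples:
``well_id, sample_id, subject_id, age_months, genotype, tissue,
dilution_exponent, replicate_index, is_control`` (plus an optional
``plate_id`` column when one sheet covers several plates).  Proprietary
plate-reader exports are out of scope; users convert to CSV first.

All downstream analysis consumes the validated :class:`~rtquic.model.PlateRun`
built here; nothing else reads files.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .calling import PlateCallResult, SampleCall
from .model import (
    DEFAULT_ANALYSIS_WINDOW_H,
    DEFAULT_SATURATION_RFU,
    PlateRun,
    RuleConfig,
    SampleMeta,
    TimeGrid,
    ValidationError,
    WellMeta,
    WellRecord,
)
from .titration import TitrationResult, format_endpoint, parse_endpoint

__all__ = [
    "read_plate",
    "read_plates",
    "read_plate_wide",
    "curves_frame",
    "write_plate",
    "write_calls",
    "read_calls",
    "write_titrations",
    "read_titrations",
    "load_rule_config",
    "samplesheet_frame",
    "sample_meta_from_sheet",
    "sample_calls_from_frame",
]

CURVE_COLUMNS = ("plate_id", "well_id", "time_h", "rfu")
SHEET_COLUMNS = (
    "well_id", "sample_id", "subject_id", "age_months", "genotype",
    "tissue", "dilution_exponent", "replicate_index", "is_control",
)


def _require_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{what} is missing columns: {', '.join(missing)}")


def _parse_bool(value: object) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    s = str(value).strip().lower()
    if s in ("true", "1", "yes"):
        return True
    if s in ("false", "0", "no", ""):
        return False
    raise ValidationError(f"cannot parse boolean value {value!r}")


def _meta_from_sheet(sheet: pd.DataFrame) -> tuple[dict[str, WellMeta], dict[str, SampleMeta]]:
    well_meta: dict[str, WellMeta] = {}
    sample_meta: dict[str, SampleMeta] = {}
    for row in sheet.itertuples():
        wid = str(row.well_id)
        if wid in well_meta:
            raise ValidationError(f"duplicate samplesheet entry for well {wid}")
        well_meta[wid] = WellMeta(
            well_id=wid,
            sample_id=str(row.sample_id),
            dilution_exponent=int(row.dilution_exponent),
            replicate_index=int(row.replicate_index),
            is_control=_parse_bool(row.is_control),
        )
        age = row.age_months
        age_months = None if pd.isna(age) else int(age)
        hp = getattr(row, "homogenate_percent", None)
        homogenate = None if hp is None or pd.isna(hp) else float(hp)
        meta = SampleMeta(
            sample_id=str(row.sample_id),
            subject_id=str(row.subject_id),
            age_months=age_months,
            genotype=str(row.genotype),
            tissue=str(row.tissue),
            homogenate_percent=homogenate,
        )
        previous = sample_meta.get(meta.sample_id)
        if previous is not None and previous != meta:
            raise ValidationError(
                f"inconsistent sample metadata for {meta.sample_id!r}"
            )
        sample_meta[meta.sample_id] = meta
    return well_meta, sample_meta


def sample_meta_from_sheet(sheet: pd.DataFrame) -> dict[str, SampleMeta]:
    """Sample-level metadata from a samplesheet, ignoring well layout.

    Unlike the per-plate parser this tolerates the same well ids recurring
    across plates (a multi-plate sheet); sample metadata must still be
    self-consistent.
    """
    metas: dict[str, SampleMeta] = {}
    for row in sheet.itertuples():
        age = row.age_months
        hp = getattr(row, "homogenate_percent", None)
        meta = SampleMeta(
            sample_id=str(row.sample_id),
            subject_id=str(row.subject_id),
            age_months=None if pd.isna(age) else int(age),
            genotype=str(row.genotype),
            tissue=str(row.tissue),
            homogenate_percent=None if hp is None or pd.isna(hp) else float(hp),
        )
        previous = metas.get(meta.sample_id)
        if previous is not None and previous != meta:
            raise ValidationError(f"inconsistent sample metadata for {meta.sample_id!r}")
        metas[meta.sample_id] = meta
    return metas


def _build_plate(
    plate_id: str,
    curves: pd.DataFrame,
    sheet: pd.DataFrame,
    saturation_rfu: float,
    analysis_window_h: float,
    clip_on_read: bool,
) -> PlateRun:
    dup = curves.duplicated(subset=["well_id", "time_h"])
    if dup.any():
        pairs = curves.loc[dup, ["well_id", "time_h"]].drop_duplicates()
        listed = "; ".join(f"{r.well_id}@{r.time_h}h" for r in pairs.itertuples())
        raise ValidationError(f"plate {plate_id}: duplicate (well, time) readings: {listed}")

    grid_times = np.array(sorted(curves["time_h"].unique()), dtype=float)
    ragged = []
    for wid, grp in curves.groupby("well_id", sort=True):
        times = np.sort(grp["time_h"].to_numpy(dtype=float))
        if len(times) != len(grid_times) or not np.allclose(times, grid_times):
            ragged.append(str(wid))
    if ragged:
        raise ValidationError(
            f"plate {plate_id}: ragged time grid; wells not matching the "
            f"common schedule: {', '.join(ragged)}"
        )
    grid = TimeGrid(grid_times)

    wells: dict[str, WellRecord] = {}
    for wid, grp in curves.groupby("well_id", sort=True):
        ordered = grp.sort_values("time_h")
        rfu = ordered["rfu"].to_numpy(dtype=float)
        if np.any(rfu > saturation_rfu):
            if clip_on_read:
                rfu = np.clip(rfu, None, saturation_rfu)
            else:
                raise ValidationError(
                    f"plate {plate_id}: well {wid} has readings above "
                    f"saturation ({saturation_rfu:g} RFU); pass clip_on_read "
                    "to clip"
                )
        wells[str(wid)] = WellRecord(well_id=str(wid), fluorescence=rfu)

    well_meta, sample_meta = _meta_from_sheet(sheet)
    return PlateRun(
        plate_id=plate_id,
        time_grid=grid,
        wells=wells,
        well_meta={w: m for w, m in well_meta.items() if w in wells},
        sample_meta=sample_meta,
        saturation_rfu=saturation_rfu,
        analysis_window_h=analysis_window_h,
    )


def read_plates(
    curves_path: str | Path,
    samplesheet_path: str | Path,
    saturation_rfu: float = DEFAULT_SATURATION_RFU,
    analysis_window_h: float = DEFAULT_ANALYSIS_WINDOW_H,
    clip_on_read: bool = False,
) -> list[PlateRun]:
    """Read a long-format curves CSV (possibly several plates) plus a
    samplesheet into validated :class:`PlateRun` objects."""
    curves = pd.read_csv(curves_path, float_precision="round_trip")
    _require_columns(curves, CURVE_COLUMNS, "curves table")
    sheet = pd.read_csv(samplesheet_path)
    _require_columns(sheet, SHEET_COLUMNS, "samplesheet")
    plates = []
    for plate_id, plate_curves in curves.groupby("plate_id", sort=True):
        plate_sheet = sheet
        if "plate_id" in sheet.columns:
            plate_sheet = sheet[sheet["plate_id"] == plate_id]
        covered = set(plate_sheet["well_id"].astype(str))
        present = set(plate_curves["well_id"].astype(str))
        missing = sorted(present - covered)
        if missing:
            raise ValidationError(
                f"plate {plate_id}: samplesheet is missing wells: "
                + ", ".join(missing)
            )
        plates.append(
            _build_plate(
                str(plate_id), plate_curves, plate_sheet,
                saturation_rfu, analysis_window_h, clip_on_read,
            )
        )
    if not plates:
        raise ValidationError("curves table contains no readings")
    return plates


def read_plate(
    curves_path: str | Path,
    samplesheet_path: str | Path,
    **kwargs,
) -> PlateRun:
    """Like :func:`read_plates` but expects exactly one plate."""
    plates = read_plates(curves_path, samplesheet_path, **kwargs)
    if len(plates) != 1:
        raise ValidationError(
            f"expected a single plate, found {len(plates)}: "
            + ", ".join(p.plate_id for p in plates)
        )
    return plates[0]


def read_plate_wide(
    curves_path: str | Path,
    samplesheet_path: str | Path,
    plate_id: str = "plate1",
    **kwargs,
) -> PlateRun:
    """Convenience dialect: one ``time_h`` column plus one column per well."""
    wide = pd.read_csv(curves_path)
    if "time_h" not in wide.columns:
        raise ValidationError("wide curves table needs a time_h column")
    long = wide.melt(id_vars=["time_h"], var_name="well_id", value_name="rfu")
    long.insert(0, "plate_id", plate_id)
    import io as _io

    buffer = _io.StringIO()
    long.to_csv(buffer, index=False)
    buffer.seek(0)
    return read_plate(buffer, samplesheet_path, **kwargs)


def samplesheet_frame(plate: PlateRun) -> pd.DataFrame:
    """Samplesheet DataFrame for a plate (inverse of the samplesheet reader)."""
    rows = []
    for wid in sorted(plate.well_meta):
        m = plate.well_meta[wid]
        s = plate.sample_meta.get(m.sample_id)
        rows.append(
            {
                "plate_id": plate.plate_id,
                "well_id": wid,
                "sample_id": m.sample_id,
                "subject_id": s.subject_id if s else m.sample_id,
                "age_months": s.age_months if s else None,
                "genotype": s.genotype if s else "transgenic",
                "tissue": s.tissue if s else "",
                "homogenate_percent": s.homogenate_percent if s else None,
                "dilution_exponent": m.dilution_exponent,
                "replicate_index": m.replicate_index,
                "is_control": m.is_control,
            }
        )
    return pd.DataFrame(rows)


def curves_frame(plate: PlateRun) -> pd.DataFrame:
    """Long-format curves DataFrame (plate_id, well_id, time_h, rfu)."""
    rows = []
    for wid in sorted(plate.wells):
        rec = plate.wells[wid]
        for t, v in zip(plate.time_grid.times_h, rec.fluorescence):
            rows.append((plate.plate_id, wid, t, v))
    return pd.DataFrame(rows, columns=list(CURVE_COLUMNS))


def write_plate(
    plate: PlateRun,
    curves_path: str | Path,
    samplesheet_path: str | Path | None = None,
) -> None:
    """Write a plate as long-format curves CSV (+ samplesheet).

    Floats are serialized with 17 significant digits and read back with
    round-trip parsing, so ``read_plate(write_plate(p))`` reproduces every
    numeric field bit-exactly.
    """
    curves_frame(plate).to_csv(curves_path, index=False, float_format="%.17g")
    if samplesheet_path is not None:
        samplesheet_frame(plate).to_csv(samplesheet_path, index=False)


# ---------------------------------------------------------------------------
# Calls and titration serialization
# ---------------------------------------------------------------------------


def write_calls(results: PlateCallResult | Iterable[PlateCallResult],
                path: str | Path) -> None:
    """Serialize call results: one row per well (metrics) and one row per
    sample x dilution (the call), distinguished by ``record_type``."""
    if isinstance(results, PlateCallResult):
        results = [results]
    results = list(results)
    if not results:
        raise ValidationError("no call results to write")
    rows = []
    for res in results:
        for wid in sorted(res.metrics):
            m = res.metrics[wid]
            rows.append(
                {
                    "record_type": "well",
                    "plate_id": res.plate_id,
                    "well_id": wid,
                    "sample_id": "",
                    "dilution_exponent": "",
                    "rfu_initial": m.rfu_initial,
                    "rfu_max": m.rfu_max,
                    "rfu_ratio": m.rfu_ratio,
                    "crossed": m.crossed,
                    "lag_h": "" if m.lag_h is None else m.lag_h,
                    "saturated": m.saturated,
                    "ratio_undefined": m.ratio_undefined,
                    "threshold_rfu": res.threshold.threshold_rfu,
                    "n_replicates": "",
                    "n_positive_wells": "",
                    "call": "",
                    "spontaneous_flag": "",
                }
            )
        for call in res.calls:
            rows.append(
                {
                    "record_type": "sample",
                    "plate_id": res.plate_id,
                    "well_id": "",
                    "sample_id": call.sample_id,
                    "dilution_exponent": call.dilution_exponent,
                    "rfu_initial": "",
                    "rfu_max": "",
                    "rfu_ratio": "",
                    "crossed": "",
                    "lag_h": "",
                    "saturated": "",
                    "ratio_undefined": "",
                    "threshold_rfu": res.threshold.threshold_rfu,
                    "n_replicates": call.n_replicates,
                    "n_positive_wells": call.n_positive_wells,
                    "call": call.call,
                    "spontaneous_flag": call.spontaneous_flag,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_calls(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read back a calls CSV into (well metric rows, sample call rows)."""
    df = pd.read_csv(path)
    _require_columns(df, ("record_type",), "calls table")
    well_cols = [
        "plate_id", "well_id", "rfu_initial", "rfu_max", "rfu_ratio",
        "crossed", "lag_h", "saturated", "ratio_undefined", "threshold_rfu",
    ]
    sample_cols = [
        "plate_id", "sample_id", "dilution_exponent", "n_replicates",
        "n_positive_wells", "call", "spontaneous_flag", "threshold_rfu",
    ]
    wells = df[df["record_type"] == "well"][well_cols].reset_index(drop=True)
    samples = df[df["record_type"] == "sample"][sample_cols].reset_index(drop=True)
    if len(samples):
        samples = samples.astype(
            {"dilution_exponent": int, "n_replicates": int, "n_positive_wells": int}
        )
    return wells, samples


def sample_calls_from_frame(samples: pd.DataFrame) -> list[SampleCall]:
    """Reconstruct :class:`SampleCall` objects from a read-back calls table."""
    calls = []
    for row in samples.itertuples():
        calls.append(
            SampleCall(
                sample_id=str(row.sample_id),
                dilution_exponent=int(row.dilution_exponent),
                n_replicates=int(row.n_replicates),
                n_positive_wells=int(row.n_positive_wells),
                call=str(row.call),
                spontaneous_flag=_parse_bool(row.spontaneous_flag),
            )
        )
    return calls


def write_titrations(
    titrations: Mapping[str, TitrationResult],
    path: str | Path,
) -> None:
    """One row per sample; an undetectable endpoint is the literal ``ND``,
    never an empty cell."""
    if not titrations:
        raise ValidationError("no titration results to write")
    rows = []
    for sid in sorted(titrations):
        t = titrations[sid]
        tested = sorted(t.calls_by_exponent, reverse=True)
        rows.append(
            {
                "sample_id": sid,
                "endpoint": format_endpoint(t.endpoint_exponent),
                "tested_exponents": " ".join(str(e) for e in tested),
                "calls": " ".join(t.calls_by_exponent[e] for e in tested),
                "monotone": t.monotone,
                "inhibited_low_dilution_flag": t.inhibited_low_dilution_flag,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_titrations(path: str | Path) -> dict[str, TitrationResult]:
    df = pd.read_csv(path)
    _require_columns(
        df, ("sample_id", "endpoint", "tested_exponents", "calls"), "titration table"
    )
    out: dict[str, TitrationResult] = {}
    for row in df.itertuples():
        exponents = [int(e) for e in str(row.tested_exponents).split()]
        calls = str(row.calls).split()
        if len(calls) != len(exponents):
            raise ValidationError(f"sample {row.sample_id}: calls/exponents mismatch")
        result = TitrationResult(
            sample_id=str(row.sample_id),
            calls_by_exponent=dict(zip(exponents, calls)),
            endpoint_exponent=parse_endpoint(str(row.endpoint)),
            monotone=_parse_bool(row.monotone),
            inhibited_low_dilution_flag=_parse_bool(row.inhibited_low_dilution_flag),
        )
        out[result.sample_id] = result
    return out


def load_rule_config(path: str | Path) -> RuleConfig:
    """Load a :class:`RuleConfig` from YAML or JSON (by file suffix)."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValidationError(f"rule config {path} must be a mapping")
    return RuleConfig.from_mapping(data)
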