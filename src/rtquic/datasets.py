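"""Packaged endpoint-table fixtures for the study cohort.

``table1.csv`` transcribes the published endpoint table: twelve subjects
(three transgenic A53T alpha-synuclein carriers plus one non-carrier control
per age group at 3, 6 and 12 months), brain and colon, with the detectable
dilution per tissue or the literal ``ND`` (not detectable at the 10^-3
starting dilution).  ``month1_colon.csv`` carries the 1-month colon screen
(all flat) reported in the text but absent from the table itself.

Tested dilution ranges come from the figure legends where stated (brains and
colons titrated to 10^-5 at 3 and 6 months, 12-month brains to 10^-8,
controls seeded at 10^-3 only); where the text only says that further
dilutions were negative, the minimal reading — one step beyond the endpoint —
is recorded.  Each fixture row is expanded into a per-dilution call series
(positive from 10^-3 down to the endpoint, negative beyond, all negative for
ND), which is exact for monotone series like these.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .model import SampleMeta, ValidationError
from .titration import TitrationResult, endpoint_dilution, parse_endpoint

__all__ = [
    "load_table1",
    "load_month1_colon",
    "load_study_cohort",
]

_HOMOGENATE_PERCENT = {"brain": 10.0, "colon": 5.0}


def _read_fixture(name: str) -> pd.DataFrame:
    with resources.files("rtquic.data").joinpath(name).open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh)


def _expand(df: pd.DataFrame) -> tuple[dict[str, TitrationResult], dict[str, SampleMeta]]:
    titrations: dict[str, TitrationResult] = {}
    metas: dict[str, SampleMeta] = {}
    for row in df.itertuples():
        sample_id = f"{row.subject_id}-{row.tissue}"
        endpoint = parse_endpoint(str(row.endpoint))
        tested_to = int(row.tested_to)
        if endpoint is not None and endpoint < tested_to:
            raise ValidationError(
                f"{sample_id}: endpoint 10^{endpoint} beyond tested range "
                f"10^{tested_to}"
            )
        calls = {
            e: "positive" if endpoint is not None and e >= endpoint else "negative"
            for e in range(-3, tested_to - 1, -1)
        }
        titrations[sample_id] = endpoint_dilution(calls, sample_id=sample_id)
        metas[sample_id] = SampleMeta(
            sample_id=sample_id,
            subject_id=str(row.subject_id),
            age_months=int(row.age_months),
            genotype=str(row.genotype),
            tissue=str(row.tissue),
            homogenate_percent=_HOMOGENATE_PERCENT.get(str(row.tissue)),
        )
    return titrations, metas


def load_table1() -> tuple[dict[str, TitrationResult], dict[str, SampleMeta]]:
    """The published endpoint table (3/6/12-month cohort, both tissues)."""
    return _expand(_read_fixture("table1.csv"))


def load_month1_colon() -> tuple[dict[str, TitrationResult], dict[str, SampleMeta]]:
    """The 1-month colon screen (all samples flat / ND)."""
    return _expand(_read_fixture("month1_colon.csv"))


def load_study_cohort() -> tuple[dict[str, TitrationResult], dict[str, SampleMeta]]:
    """Endpoint table plus the 1-month colon calls, as one cohort."""
    t1, m1 = load_table1()
    t2, m2 = load_month1_colon()
    overlap = set(t1) & set(t2)
    if overlap:
        raise ValidationError(f"fixtures overlap on samples: {sorted(overlap)}")
    t1.update(t2)
    m1.update(m2)
    return t1, m1
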