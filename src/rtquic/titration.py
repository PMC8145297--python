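"""Endpoint-dilution titration and cohort summaries.

Seeding activity is semi-quantified by the endpoint dilution: the most dilute
tissue dilution at which a sample is still called positive by the replicate
rule.  A sample negative at every tested dilution is ND ("not detectable" at
the least dilute tested dilution, 10^-3 by convention).  Comparisons between
samples use only the total order

    ND < positive at 10^-3 < positive at 10^-4 < ...

never a numeric stand-in for ND.  Fold differences between two endpoints are
powers of ten of the exponent gap — the only quantitation the endpoint design
supports.  Non-monotone dilution series (a negative between positives, which
the 10^-3 inhibition phenomenon can produce) are kept and flagged rather than
truncated at the first negative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .calling import SampleCall
from .model import SampleMeta, ValidationError

__all__ = [
    "ND",
    "TitrationResult",
    "FoldResult",
    "CohortSummary",
    "endpoint_dilution",
    "fold_difference",
    "titrate_calls",
    "summarize_cohort",
    "seeding_rank",
    "format_endpoint",
    "parse_endpoint",
]

#: Sentinel spelled in serialized output for "not detectable".
ND = "ND"

#: Least dilute dilution conventionally tested (10^-3 of tissue).
BASE_EXPONENT = -3


def seeding_rank(endpoint_exponent: int | None) -> int:
    """Rank of an endpoint in the seeding-activity total order.

    ND (``None``) ranks below any positive endpoint; a more negative exponent
    (more dilute endpoint) ranks higher.  Only usable for ordering — ND is
    never treated as a number.
    """
    if endpoint_exponent is None:
        return 0
    return -int(endpoint_exponent)


def format_endpoint(endpoint_exponent: int | None) -> str:
    """Serialize an endpoint as the literal ``"ND"`` or ``"1e-5"`` style."""
    if endpoint_exponent is None:
        return ND
    return f"1e{int(endpoint_exponent)}"


def parse_endpoint(text: str) -> int | None:
    """Inverse of :func:`format_endpoint`; also accepts a bare exponent."""
    s = str(text).strip()
    if s.upper() == ND:
        return None
    if s.lower().startswith("1e"):
        s = s[2:]
    exponent = int(s)
    if exponent > 0:
        raise ValidationError(f"dilution exponent must be <= 0, got {exponent}")
    return exponent


@dataclass(frozen=True)
class TitrationResult:
    """Endpoint determination for one sample's dilution series.

    ``endpoint_exponent`` is the most dilute (most negative) exponent with a
    positive call, or ``None`` for ND.  ``monotone`` is False when the series
    is not positives-then-negatives in dilution order.
    ``inhibited_low_dilution_flag`` marks series negative at 10^-3 but
    positive at a more dilute exponent — the signature of reaction inhibitors
    that a further tenfold dilution removed.
    """

    sample_id: str
    calls_by_exponent: Mapping[int, str]
    endpoint_exponent: int | None
    monotone: bool
    inhibited_low_dilution_flag: bool

    @property
    def is_nd(self) -> bool:
        return self.endpoint_exponent is None


def endpoint_dilution(
    calls: Mapping[int, SampleCall | str],
    sample_id: str | None = None,
    require_exponent: int | None = BASE_EXPONENT,
) -> TitrationResult:
    """Determine the endpoint dilution from per-dilution calls.

    Parameters
    ----------
    calls : mapping of dilution exponent -> call
        Values may be :class:`SampleCall` objects or the strings
        ``"positive"``/``"negative"``.
    sample_id : str, optional
        Taken from the calls when they are :class:`SampleCall` objects.
    require_exponent : int or None
        Tested exponents must include this dilution (default 10^-3, the
        conventional least dilute start of a series); pass ``None`` to relax.
    """
    if not calls:
        raise ValidationError("empty call map")
    norm: dict[int, str] = {}
    for exponent, value in calls.items():
        e = int(exponent)
        if isinstance(value, SampleCall):
            if sample_id is None:
                sample_id = value.sample_id
            elif value.sample_id != sample_id:
                raise ValidationError(
                    f"calls mix samples {sample_id!r} and {value.sample_id!r}"
                )
            norm[e] = value.call
        else:
            call = str(value).lower()
            if call not in ("positive", "negative"):
                raise ValidationError(f"unrecognized call {value!r} at 10^{e}")
            norm[e] = call
    if require_exponent is not None and require_exponent not in norm:
        raise ValidationError(
            f"tested dilutions {sorted(norm)} do not include 10^{require_exponent}"
        )
    exponents = sorted(norm, reverse=True)  # least dilute first
    positives = [e for e in exponents if norm[e] == "positive"]
    endpoint = min(positives) if positives else None
    flags = [norm[e] == "positive" for e in exponents]
    # monotone = positives form an uninterrupted prefix of the series
    n_pos = sum(flags)
    monotone = all(flags[:n_pos]) and not any(flags[n_pos:])
    inhibited = (
        max(exponents) in norm
        and norm[max(exponents)] == "negative"
        and any(norm[e] == "positive" for e in exponents if e < max(exponents))
    )
    return TitrationResult(
        sample_id=sample_id or "",
        calls_by_exponent=dict(norm),
        endpoint_exponent=endpoint,
        monotone=monotone,
        inhibited_low_dilution_flag=inhibited,
    )


def titrate_calls(
    calls: Iterable[SampleCall],
    require_exponent: int | None = BASE_EXPONENT,
) -> dict[str, TitrationResult]:
    """Group :class:`SampleCall` records by sample and titrate each series."""
    by_sample: dict[str, dict[int, SampleCall]] = {}
    for call in calls:
        series = by_sample.setdefault(call.sample_id, {})
        if call.dilution_exponent in series:
            raise ValidationError(
                f"duplicate call for {call.sample_id} @ 10^{call.dilution_exponent}"
            )
        series[call.dilution_exponent] = call
    return {
        sid: endpoint_dilution(series, sample_id=sid, require_exponent=require_exponent)
        for sid, series in sorted(by_sample.items())
    }


@dataclass(frozen=True)
class FoldResult:
    """Fold difference in seeding level between two titrated samples.

    ``fold`` is the factor by which sample a's seeding level exceeds sample
    b's (> 1 when a's endpoint is the more dilute).  Undefined — never a
    number — when either endpoint is ND.
    """

    fold: float | None
    log10_fold: int | None
    defined: bool


def fold_difference(a: TitrationResult, b: TitrationResult) -> FoldResult:
    """Endpoint-based fold difference, 10^(e_b - e_a).

    A brain endpoint of 10^-8 against a colon endpoint of 10^-5 gives
    fold = 10^3: the brain's seeding level is a thousandfold higher.
    """
    if a.is_nd or b.is_nd:
        return FoldResult(fold=None, log10_fold=None, defined=False)
    k = int(b.endpoint_exponent) - int(a.endpoint_exponent)
    return FoldResult(fold=math.pow(10.0, k), log10_fold=k, defined=True)


@dataclass
class CohortSummary:
    """Cohort-level summary shaped like an endpoint table.

    ``records`` has one row per subject x tissue (columns: subject_id,
    age_months, genotype, tissue, endpoint_exponent, endpoint, inhibited_flag,
    non_monotone_flag).  Derived statistics cover only transgenic (carrier)
    subjects; controls are audited separately.
    """

    records: pd.DataFrame
    positive_counts: pd.DataFrame
    earliest_positive_age: dict[str, int | None]
    most_dilute_endpoint: dict[str, int | None]
    tissue_comparison: pd.DataFrame
    control_failures: list[str]

    @property
    def contamination_warning(self) -> bool:
        """True when any non-carrier control sample was not ND."""
        return bool(self.control_failures)


def summarize_cohort(
    titrations: Mapping[str, TitrationResult],
    sample_meta: Mapping[str, SampleMeta],
) -> CohortSummary:
    """Summarize a cohort of titrated samples into an endpoint table.

    Emits one record per subject x tissue plus: per-age x tissue positive
    counts among carriers, the earliest age at which each tissue is positive
    in any carrier, the most dilute endpoint per tissue, and a per-subject
    comparison of which tissue carries the more dilute endpoint (ND ranks
    below any positive endpoint).  Any non-ND non-carrier control raises the
    contamination warning.  Order of input records never matters.
    """
    missing = sorted(set(titrations) - set(sample_meta))
    if missing:
        raise ValidationError("titrated samples without metadata: " + ", ".join(missing))
    rows = []
    seen: dict[tuple[str, str, int | None], int | None] = {}
    for sid in sorted(titrations):
        t = titrations[sid]
        m = sample_meta[sid]
        key = (m.subject_id, m.tissue, m.age_months)
        if key in seen:
            if seen[key] != t.endpoint_exponent:
                raise ValidationError(
                    f"conflicting duplicate records for subject {m.subject_id} "
                    f"{m.tissue} at {m.age_months} months"
                )
            continue
        seen[key] = t.endpoint_exponent
        rows.append(
            {
                "subject_id": m.subject_id,
                "age_months": m.age_months,
                "genotype": m.genotype,
                "tissue": m.tissue,
                "endpoint_exponent": t.endpoint_exponent,
                "endpoint": format_endpoint(t.endpoint_exponent),
                "inhibited_flag": t.inhibited_low_dilution_flag,
                "non_monotone_flag": not t.monotone,
            }
        )
    records = pd.DataFrame(rows).sort_values(
        ["age_months", "subject_id", "tissue"], kind="stable"
    ).reset_index(drop=True)

    carriers = records[records["genotype"] != "non_carrier"]
    counts = (
        carriers.assign(positive=carriers["endpoint_exponent"].notna())
        .groupby(["age_months", "tissue"], dropna=False)["positive"]
        .agg(n_positive="sum", n_total="count")
        .reset_index()
    )
    counts["n_positive"] = counts["n_positive"].astype(int)

    earliest: dict[str, int | None] = {}
    most_dilute: dict[str, int | None] = {}
    for tissue, grp in carriers.groupby("tissue"):
        pos = grp[grp["endpoint_exponent"].notna()]
        ages = pos["age_months"].dropna()
        earliest[str(tissue)] = int(ages.min()) if len(ages) else None
        most_dilute[str(tissue)] = (
            int(pos["endpoint_exponent"].min()) if len(pos) else None
        )

    comparison_rows = []
    for (subject, age), grp in carriers.groupby(["subject_id", "age_months"]):
        if grp["tissue"].nunique() < 2:
            continue
        ranked = {
            row.tissue: seeding_rank(
                None if pd.isna(row.endpoint_exponent) else int(row.endpoint_exponent)
            )
            for row in grp.itertuples()
        }
        best = max(ranked.values())
        leaders = [t for t, r in ranked.items() if r == best]
        comparison_rows.append(
            {
                "subject_id": subject,
                "age_months": age,
                "more_dilute_tissue": leaders[0] if len(leaders) == 1 else "equal",
            }
        )
    comparison = pd.DataFrame(
        comparison_rows, columns=["subject_id", "age_months", "more_dilute_tissue"]
    )

    control_failures = sorted(
        sid
        for sid in titrations
        if sample_meta[sid].is_non_carrier and not titrations[sid].is_nd
    )
    return CohortSummary(
        records=records,
        positive_counts=counts,
        earliest_positive_age=earliest,
        most_dilute_endpoint=most_dilute,
        tissue_comparison=comparison,
        control_failures=control_failures,
    )
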