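"""Cohort-level summaries of potentially pathogenic SV carriers.

Carrier tables are plain pandas DataFrames with one row per
(patient, SV) and at minimum the columns ``patient_id``, ``ancestry``,
``final_class`` (and ``isup_gg`` for aggressiveness summaries).
Fractions use distinct-patient semantics: a patient carrying several
qualifying SVs counts once.  Percentages are rounded half-up to one
decimal, with the underlying counts reported alongside so the rounding
is auditable.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd


@dataclass
class PatientRecord:
    patient_id: str
    ancestry: str
    age: Optional[float] = None
    psa: Optional[float] = None
    isup_gg: Optional[int] = None

    def __post_init__(self) -> None:
        if self.isup_gg is not None and not 1 <= self.isup_gg <= 5:
            raise ValueError(f"{self.patient_id}: ISUP GG {self.isup_gg} out of range")


@dataclass
class Fraction:
    """A count over a denominator with its half-up-rounded percentage."""

    count: int
    denominator: int
    percent: float

    def __iter__(self):
        return iter((self.count, self.denominator, self.percent))


def round_half_up(value: float, decimals: int = 1) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def _fraction(count: int, denominator: int) -> Fraction:
    if denominator <= 0:
        raise ValueError("empty cohort")
    return Fraction(count, denominator, round_half_up(100.0 * count / denominator))


def _cohort_size(
    patients: Union[Sequence[PatientRecord], Mapping[str, int]], ancestry: str
) -> int:
    if isinstance(patients, Mapping):
        return int(patients[ancestry])
    return sum(1 for p in patients if p.ancestry == ancestry)


def carrier_fraction(
    carriers: pd.DataFrame,
    patients: Union[Sequence[PatientRecord], Mapping[str, int]],
    ancestry: str,
    classes: Iterable[str],
) -> Fraction:
    """Fraction of an ancestry's patients carrying >= 1 SV of the classes.

    ``patients`` is either a list of :class:`PatientRecord` or a mapping
    of ancestry label to cohort size.
    """
    classes = set(classes)
    mask = (carriers["ancestry"] == ancestry) & carriers["final_class"].isin(classes)
    count = carriers.loc[mask, "patient_id"].nunique()
    return _fraction(count, _cohort_size(patients, ancestry))


UNKNOWN_POLICIES = ("exclude", "count_aggressive", "count_nonaggressive")


def aggressive_fraction(
    carriers: pd.DataFrame,
    classes: Iterable[str],
    gg_threshold: int = 3,
    unknown_policy: str = "count_aggressive",
) -> Fraction:
    """Fraction of distinct carrier patients with aggressive disease.

    Aggressive (high-risk) disease is ISUP group grade >= ``gg_threshold``.
    Patients of unknown grade are handled per ``unknown_policy``:
    excluded from the denominator, counted as aggressive, or counted as
    non-aggressive.
    """
    if unknown_policy not in UNKNOWN_POLICIES:
        raise ValueError(f"unknown_policy must be one of {UNKNOWN_POLICIES}")
    classes = set(classes)
    sub = carriers[carriers["final_class"].isin(classes)]
    # one grade per patient; several rows for one patient agree or are NaN
    grades = sub.groupby("patient_id")["isup_gg"].max()
    known = grades.dropna()
    aggressive = int((known >= gg_threshold).sum())
    denominator = len(known)
    n_unknown = len(grades) - len(known)
    if unknown_policy == "count_aggressive":
        aggressive += n_unknown
        denominator += n_unknown
    elif unknown_policy == "count_nonaggressive":
        denominator += n_unknown
    return _fraction(aggressive, denominator)


def mean_vaf(carriers: pd.DataFrame) -> float:
    """Mean variant allele fraction over all carrier rows, as a percent
    rounded half-up to one decimal (heterozygous germline inheritance
    predicts about 50%)."""
    return round_half_up(100.0 * float(carriers["vaf"].mean()))


def summarize_tables(
    calls: pd.DataFrame,
    frequencies: pd.DataFrame,
    carriers: pd.DataFrame,
    funnel: Mapping[str, int],
    outdir: str,
) -> dict[str, str]:
    """Render deterministic, sorted summary TSVs.

    Writes ``table1.tsv`` (one row per final candidate SV with its
    frequencies), ``table2.tsv`` (one row per carrier patient/SV) and
    ``funnel.tsv`` (cascade stage counts).  Returns the paths written.
    """
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {}

    table1 = calls.merge(frequencies, on="sv_id", how="left")
    table1 = table1.sort_values(["final_class", "sv_id"], kind="mergesort")
    paths["table1"] = os.path.join(outdir, "table1.tsv")
    table1.to_csv(paths["table1"], sep="\t", index=False)

    table2 = carriers.sort_values(["final_class", "patient_id", "sv_id"], kind="mergesort")
    paths["table2"] = os.path.join(outdir, "table2.tsv")
    table2.to_csv(paths["table2"], sep="\t", index=False)

    funnel_df = pd.DataFrame(
        [{"stage": k, "count": v} for k, v in funnel.items()]
    )
    paths["funnel"] = os.path.join(outdir, "funnel.tsv")
    funnel_df.to_csv(paths["funnel"], sep="\t", index=False)
    return paths
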