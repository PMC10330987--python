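"""Phenotype record editing: outliers, completeness, connectedness, CGs.

The editing rules mirror standard beef-cattle evaluation practice: records
beyond ±k standard deviations from the database mean are dropped, records
missing required covariates are dropped, animals with no pedigree link to
the genotyped set are dropped (their evaluations could not differ between
pedigree-only and single-step analyses), contemporary groups (CG) are built
as herd × birth-year × birth-season, and CGs with fewer than two records or
zero within-group variance are removed.  Filters are applied in that order
and the :class:`QcReport` keeps the per-rule accounting.

Records travel as a pandas DataFrame with columns ``animal, value, herd,
birth_date, dam_age, sex`` plus ``mgmt`` and ``age`` for post-weaning traits,
and gain a ``cg`` column once contemporary groups are assigned.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError
from .pedigree import PedigreeTable

#: Julian-window season boundaries: [80, 171] spring, [172, 264] summer,
#: [265, 354] autumn, [355, 366] ∪ [1, 79] winter.
SEASON_WINDOWS = (
    (80, 171, "spring"),
    (172, 264, "summer"),
    (265, 354, "autumn"),
)


@dataclass
class QcReport:
    """Counts of records removed per rule, in application order."""

    n_input: int = 0
    steps: list[tuple[str, int]] = field(default_factory=list)

    def add(self, rule: str, n_removed: int) -> None:
        self.steps.append((rule, int(n_removed)))

    @property
    def n_removed(self) -> int:
        return sum(n for _, n in self.steps)

    @property
    def n_surviving(self) -> int:
        return self.n_input - self.n_removed

    def removed(self, rule: str) -> int:
        return dict(self.steps).get(rule, 0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps, columns=["rule", "n_removed"])


# ---------------------------------------------------------------------- #
# individual rules
# ---------------------------------------------------------------------- #
def filter_outliers(
    records: pd.DataFrame, k: float = 3.0
) -> tuple[pd.DataFrame, QcReport]:
    """Drop records with |value − mean| > k·SD.

    Mean and sample SD are computed once on the full input set (single
    pass, no re-iteration); with SD = 0 all equal records are kept.
    """
    if len(records) < 2:
        raise DataError("outlier filter needs at least two records")
    values = records["value"].to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise DataError("non-finite phenotype values")
    mean = values.mean()
    sd = values.std(ddof=1)
    keep = np.abs(values - mean) <= k * sd
    report = QcReport(n_input=len(records))
    report.add("outlier", int((~keep).sum()))
    return records.loc[keep].reset_index(drop=True), report


def filter_incomplete(
    records: pd.DataFrame, required: tuple[str, ...] = ("herd", "dam_age")
) -> tuple[pd.DataFrame, QcReport]:
    """Drop records missing any required field, counted per field."""
    report = QcReport(n_input=len(records))
    keep = np.ones(len(records), dtype=bool)
    for col in required:
        if col not in records.columns:
            missing = np.ones(len(records), dtype=bool)
        else:
            missing = records[col].isna().to_numpy()
        newly = missing & keep
        report.add(f"missing_{col}", int(newly.sum()))
        keep &= ~missing
    return records.loc[keep].reset_index(drop=True), report


def filter_unconnected(
    records: pd.DataFrame, pedigree: PedigreeTable, genotyped_ids
) -> tuple[pd.DataFrame, QcReport]:
    """Drop records of animals with no pedigree relationship to any
    genotyped animal.

    "Related" means sharing a connected component of the undirected
    pedigree graph with a genotyped animal — exactly the condition for a
    nonzero entry of A, decided without forming A.  Animals absent from the
    pedigree are a record-level error, counted separately and dropped.
    """
    report = QcReport(n_input=len(records))
    in_ped = records["animal"].astype(np.int64).isin(pedigree.ids).to_numpy()
    report.add("not_in_pedigree", int((~in_ped).sum()))
    related = set(int(a) for a in pedigree.related_to(genotyped_ids))
    connected = records["animal"].astype(np.int64).isin(related).to_numpy()
    report.add("unconnected", int((in_ped & ~connected).sum()))
    keep = in_ped & connected
    return records.loc[keep].reset_index(drop=True), report


def assign_season(day_of_year: int) -> str:
    """Season of a Julian day in 1..366, by the fixed calendar windows."""
    day = int(day_of_year)
    if day < 1 or day > 366:
        raise ValueError(f"day of year {day} outside 1..366")
    for lo, hi, name in SEASON_WINDOWS:
        if lo <= day <= hi:
            return name
    return "winter"


def build_contemporary_groups(
    records: pd.DataFrame,
) -> tuple[pd.DataFrame, QcReport]:
    """Label each record with its herd ⊕ birth-year ⊕ birth-season CG.

    Records with missing herd or birth date cannot be grouped; they are
    counted as record-level errors and dropped.
    """
    report = QcReport(n_input=len(records))
    herd_ok = records["herd"].notna().to_numpy()
    date = pd.to_datetime(records["birth_date"], errors="coerce")
    date_ok = date.notna().to_numpy()
    keep = herd_ok & date_ok
    report.add("missing_herd_or_date", int((~keep).sum()))
    out = records.loc[keep].reset_index(drop=True).copy()
    date = date[keep].reset_index(drop=True)
    seasons = [assign_season(d) for d in date.dt.dayofyear]
    out["cg"] = [
        f"{h}_{y}_{s}"
        for h, y, s in zip(out["herd"], date.dt.year, seasons)
    ]
    return out, report


def filter_small_or_constant_cg(
    records: pd.DataFrame,
) -> tuple[pd.DataFrame, QcReport]:
    """Drop records in CGs with < 2 records or zero phenotype variance."""
    if "cg" not in records.columns:
        raise DataError("contemporary groups not assigned; run build_contemporary_groups")
    report = QcReport(n_input=len(records))
    sizes = records.groupby("cg")["value"].transform("size").to_numpy()
    spread = (
        records.groupby("cg")["value"].transform(lambda v: v.max() - v.min()).to_numpy()
    )
    small = sizes < 2
    constant = ~small & (spread == 0)
    report.add("cg_too_small", int(small.sum()))
    report.add("cg_zero_variance", int(constant.sum()))
    keep = ~small & ~constant
    return records.loc[keep].reset_index(drop=True), report


# ---------------------------------------------------------------------- #
# composed pipeline
# ---------------------------------------------------------------------- #
def run_phenotype_qc(
    records: pd.DataFrame,
    pedigree: PedigreeTable,
    genotyped_ids,
    sd_multiplier: float = 3.0,
    required: tuple[str, ...] = ("herd", "dam_age"),
) -> tuple[pd.DataFrame, QcReport]:
    """Apply every editing rule in the canonical order.

    Order: outliers → completeness → connectedness → CG construction →
    small/constant-CG removal.  The composition is order-dependent (the
    outlier mean/SD see the raw data; CG sizes are counted after the other
    filters), and the returned report lists the rules in exactly the order
    applied.
    """
    report = QcReport(n_input=len(records))
    out, r = filter_outliers(records, k=sd_multiplier)
    report.steps.extend(r.steps)
    out, r = filter_incomplete(out, required=required)
    report.steps.extend(r.steps)
    out, r = filter_unconnected(out, pedigree, genotyped_ids)
    report.steps.extend(r.steps)
    out, r = build_contemporary_groups(out)
    report.steps.extend(r.steps)
    out, r = filter_small_or_constant_cg(out)
    report.steps.extend(r.steps)
    return out, report
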