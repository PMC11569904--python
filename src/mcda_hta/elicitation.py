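"""100-point allocation survey data: reading, validation, per-sample summaries.

Weights are elicited by point allocation: each respondent distributes 100
points among the domains, 100 points among the criteria within each domain,
and 100 points among the subcriteria within each criterion. Every sibling
group is therefore a composition on the 100-point simplex.

The on-disk format is long-form UTF-8 CSV with a header row and columns
``respondent_id,sample_id,group_id,node_id,points`` — one row per
(respondent, node); ``group_id`` is the parent whose children are being
weighted (:data:`~mcda_hta.tree.ROOT_GROUP` for the domain-level question).
Rows violating the budget or the tree are rejected, not silently fixed; an
optional proportional repair rescales near-miss rows to an exact 100.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .rounding import round_preserving_sum
from .tree import ROOT_GROUP, CriteriaTree

REQUIRED_COLUMNS = ["respondent_id", "sample_id", "group_id", "node_id", "points"]

#: Conventional sample identifiers for the two stakeholder groups.
PROFESSIONALS = "professionals"
GENERAL_POPULATION = "general_population"

SUM_TOL = 1e-9


class AllocationFormatError(ValueError):
    """Raised when an allocation file is structurally unreadable."""


@dataclass
class AllocationRecord:
    """One respondent's 100-point split over one sibling group.

    ``points`` maps each child of ``group_id`` to a non-negative number of
    points; a valid record covers exactly the group's children and sums to
    100.
    """

    respondent_id: str
    sample_id: str
    group_id: str
    points: dict[str, float]

    def total(self) -> float:
        return float(sum(self.points.values()))


@dataclass
class AllocationSet:
    """Validated allocation records tied to a criteria tree."""

    tree: CriteriaTree
    records: list[AllocationRecord] = field(default_factory=list)

    @property
    def samples(self) -> set[str]:
        return {r.sample_id for r in self.records}

    def for_sample(self, sample_id: str) -> list[AllocationRecord]:
        return [r for r in self.records if r.sample_id == sample_id]

    def add(self, record: AllocationRecord) -> None:
        """Append after validation; rejects duplicates and invariant breaches."""
        problems = validate_allocation(record, self.tree)
        if problems:
            raise ValueError(f"invalid allocation record: {problems}")
        if any(
            r.respondent_id == record.respondent_id and r.group_id == record.group_id
            and r.sample_id == record.sample_id
            for r in self.records
        ):
            raise ValueError(
                f"duplicate record for respondent {record.respondent_id!r}, "
                f"group {record.group_id!r}"
            )
        self.records.append(record)

    def to_frame(self) -> pd.DataFrame:
        """Long-form DataFrame with the canonical CSV columns."""
        rows = [
            (r.respondent_id, r.sample_id, r.group_id, nid, pts)
            for r in self.records
            for nid, pts in r.points.items()
        ]
        return pd.DataFrame(rows, columns=REQUIRED_COLUMNS)

    def points_matrix(self, sample_id: str, group_id: str) -> pd.DataFrame:
        """Respondent × child-node matrix of points for one group (NaN = unanswered)."""
        children = self.tree.children(group_id)
        recs = [r for r in self.for_sample(sample_id) if r.group_id == group_id]
        data = {r.respondent_id: [r.points[c] for c in children] for r in recs}
        return pd.DataFrame.from_dict(data, orient="index", columns=children)


@dataclass
class SampleSummary:
    """Per-node descriptive statistics for one sample.

    ``table`` is indexed by node_id with columns ``group_id, n, mean, sd,
    median``; SD uses the n−1 denominator (NaN when n < 2).
    """

    sample_id: str
    table: pd.DataFrame

    def means(self, group_id: str) -> pd.Series:
        sub = self.table[self.table["group_id"] == group_id]
        return sub["mean"]


def validate_allocation(record: AllocationRecord, tree: CriteriaTree) -> list[str]:
    """All invariant violations of ``record`` against ``tree`` (empty = valid)."""
    problems: list[str] = []
    if record.group_id != ROOT_GROUP and record.group_id not in tree.index:
        return [f"unknown-group: {record.group_id}"]
    children = tree.children(record.group_id)
    if not children:
        return [f"not-a-group: {record.group_id} has no children to weight"]
    child_set = set(children)
    for nid in record.points:
        if nid not in child_set:
            problems.append(f"unknown-node: {nid}")
    for nid in children:
        if nid not in record.points:
            problems.append(f"missing-sibling: {nid}")
    negatives = [nid for nid, p in record.points.items() if p < 0]
    if negatives:
        problems.append("negative-points: " + ", ".join(sorted(negatives)))
    if not any(p.startswith(("unknown-node", "missing-sibling", "negative-points")) for p in problems):
        if not math.isclose(record.total(), 100.0, abs_tol=SUM_TOL):
            problems.append(f"sum-not-100: total={record.total():g}")
    return problems


def _repair_proportional(points: dict[str, float]) -> Optional[dict[str, float]]:
    """Rescale a positive-total allocation to exactly 100 integer points."""
    total = sum(points.values())
    if total <= 0 or any(p < 0 for p in points.values()):
        return None
    nodes = list(points)
    scaled = np.array([points[n] for n in nodes], dtype=float) * (100.0 / total)
    ints = round_preserving_sum(scaled, 100)
    return {n: float(v) for n, v in zip(nodes, ints)}


def read_allocations(
    path: str | Path,
    tree: CriteriaTree,
    repair: Optional[str] = None,
) -> tuple[AllocationSet, pd.DataFrame]:
    """Read the long-form allocation CSV.

    Parameters
    ----------
    path : path
        CSV with columns ``respondent_id,sample_id,group_id,node_id,points``.
    tree : CriteriaTree
        Hierarchy the allocations refer to.
    repair : {None, "proportional"}
        With ``"proportional"``, records whose points are non-negative but
        sum ≠ 100 are rescaled to 100 and re-rounded by the largest-remainder
        method instead of being rejected; repaired records are flagged in the
        rejection report with reason ``repaired``.

    Returns
    -------
    (AllocationSet, DataFrame)
        The set of valid records, and a rejection report with columns
        ``respondent_id, sample_id, group_id, reason``.
    """
    if repair not in (None, "proportional"):
        raise ValueError(f"unknown repair mode {repair!r}")
    path = Path(path)
    try:
        frame = pd.read_csv(path, dtype={"respondent_id": str, "sample_id": str,
                                         "group_id": str, "node_id": str})
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise AllocationFormatError(f"{path}: cannot read allocation CSV: {exc}") from exc
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise AllocationFormatError(f"{path}: missing required column(s): {', '.join(missing)}")
    frame["points"] = pd.to_numeric(frame["points"], errors="coerce")

    allocs = AllocationSet(tree=tree)
    rejected: list[tuple[str, str, str, str]] = []
    seen: set[tuple[str, str, str]] = set()
    for (resp, samp, group), block in frame.groupby(
        ["respondent_id", "sample_id", "group_id"], sort=False
    ):
        key = (resp, samp, group)
        if block["points"].isna().any():
            rejected.append((*key, "non-numeric-points"))
            continue
        if block["node_id"].duplicated().any():
            rejected.append((*key, "duplicate-node-row"))
            continue
        record = AllocationRecord(
            respondent_id=resp,
            sample_id=samp,
            group_id=group,
            points={nid: float(p) for nid, p in zip(block["node_id"], block["points"])},
        )
        problems = validate_allocation(record, tree)
        if problems:
            fixable = all(p.startswith("sum-not-100") for p in problems)
            if repair == "proportional" and fixable:
                fixed = _repair_proportional(record.points)
                if fixed is not None:
                    record.points = fixed
                    rejected.append((*key, "repaired"))
                    problems = []
            if problems:
                rejected.append((*key, "; ".join(problems)))
                continue
        if key in seen:
            rejected.append((*key, "duplicate-record"))
            continue
        seen.add(key)
        allocs.records.append(record)
    report = pd.DataFrame(rejected, columns=["respondent_id", "sample_id", "group_id", "reason"])
    return allocs, report


def write_allocations(allocs: AllocationSet, path: str | Path) -> None:
    """Write the canonical long-form CSV (round-trips bit-for-bit on points)."""
    allocs.to_frame().to_csv(path, index=False)


def summarize_sample(allocs: AllocationSet, sample_id: str) -> SampleSummary:
    """Per-node n / mean / SD (n−1 denominator) / median for one sample.

    n is counted per sibling group: a respondent who skipped a group simply
    does not contribute to that group's nodes.
    """
    records = allocs.for_sample(sample_id)
    if not records:
        raise ValueError(f"no-records-for-sample: {sample_id!r}")
    rows = []
    by_group: dict[str, list[AllocationRecord]] = {}
    for r in records:
        by_group.setdefault(r.group_id, []).append(r)
    # iterate groups in tree order for a deterministic table
    for group_id in allocs.tree.sibling_groups():
        recs = by_group.get(group_id)
        if not recs:
            continue
        for nid in allocs.tree.children(group_id):
            vals = np.array([r.points[nid] for r in recs], dtype=float)
            rows.append(
                {
                    "node_id": nid,
                    "group_id": group_id,
                    "n": len(vals),
                    "mean": float(vals.mean()),
                    "sd": float(vals.std(ddof=1)) if len(vals) > 1 else float("nan"),
                    "median": float(np.median(vals)),
                }
            )
    table = pd.DataFrame(rows).set_index("node_id")
    return SampleSummary(sample_id=sample_id, table=table)
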