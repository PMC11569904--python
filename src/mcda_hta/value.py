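"""Additive multi-attribute value function over the criteria hierarchy.

The composite value of a technology is the nested weighted sum

    V = Σ_i ŵ_i · Σ_j ŵ_ij · Σ_k ŵ_ijk · s_ijk

where i, j, k index domains, criteria, and subcriteria, ŵ are the
sibling-normalized weights (each level sums to one within its group), and
s are the technology's scores at the leaves. For a criterion without
subcriteria the k-sum collapses and the criterion's own score enters
directly. Because every sibling group's normalized weights sum to one, the
product of weights along each leaf path — the *effective leaf weight* —
sums to one over all leaves, so V lives on the same scale as the scores.

Scores are elicited at leaves only; a domain's or criterion's "score" is by
construction the weighted average of its descendants, which avoids double
counting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .weights import WeightTable


@dataclass
class ScoreSheet:
    """Leaf-level scores for one technology on a declared scale.

    ``scale`` is the closed score range (default [0, 1]); every leaf of the
    tree must receive exactly one score inside it.
    """

    technology_id: str
    scores: dict[str, float]
    scale: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        lo, hi = self.scale
        if not lo < hi:
            raise ValueError(f"scale must satisfy low < high, got {self.scale}")


@dataclass
class ValueResult:
    """Composite value of one technology plus its per-domain decomposition."""

    technology_id: str
    value: float
    scale: tuple[float, float]
    domain_contributions: dict[str, float]
    effective_weights: dict[str, float]
    rank: int | None = None
    tied: bool = False


def effective_leaf_weights(weights: WeightTable) -> dict[str, float]:
    """Product of normalized sibling weights along each leaf's path.

    A subcriterion's effective weight is ŵ_domain·ŵ_criterion·ŵ_subcriterion;
    a subcriterion-less criterion contributes ŵ_domain·ŵ_criterion (implicit
    subcriterion weight of one). The values sum to one over all leaves.
    """
    tree = weights.tree
    out: dict[str, float] = {}
    for did in tree.domains:
        wd = weights.normalized(did)
        for cid in tree.index[did].children:
            wc = weights.normalized(cid)
            subs = tree.index[cid].children
            if subs:
                for sid in subs:
                    out[sid] = wd * wc * weights.normalized(sid)
            else:
                out[cid] = wd * wc
    return out


def _check_sheet(weights: WeightTable, sheet: ScoreSheet) -> None:
    leaves = weights.tree.leaves()
    missing = [leaf for leaf in leaves if leaf not in sheet.scores]
    if missing:
        raise ValueError(
            f"score sheet {sheet.technology_id!r} misses leaf score(s): {missing}"
        )
    lo, hi = sheet.scale
    bad = {k: v for k, v in sheet.scores.items() if k in set(leaves) and not lo <= v <= hi}
    if bad:
        raise ValueError(
            f"score sheet {sheet.technology_id!r} has out-of-scale score(s) "
            f"for scale [{lo}, {hi}]: {bad}"
        )


def aggregate_value(weights: WeightTable, sheet: ScoreSheet) -> ValueResult:
    """Composite value V of one technology and its per-domain contributions.

    Raises if the sheet misses a leaf or a score falls outside its declared
    scale. Domain contributions are the weighted partial sums over each
    domain's leaves; they add up to V exactly.
    """
    _check_sheet(weights, sheet)
    eff = effective_leaf_weights(weights)
    tree = weights.tree
    contributions: dict[str, float] = {}
    for did in tree.domains:
        total = 0.0
        for cid in tree.index[did].children:
            subs = tree.index[cid].children
            for leaf in subs or [cid]:
                total += eff[leaf] * sheet.scores[leaf]
        contributions[did] = total
    value = float(sum(contributions.values()))
    return ValueResult(
        technology_id=sheet.technology_id,
        value=value,
        scale=sheet.scale,
        domain_contributions=contributions,
        effective_weights=eff,
    )


def rank_technologies(results: Sequence[ValueResult]) -> list[ValueResult]:
    """Competition-rank results by descending composite value.

    Ties share a rank (1, 2, 2, 4, ...) and are flagged. All results must be
    on the same score scale. Returns the results sorted by rank; the input
    objects are annotated in place.
    """
    if not results:
        raise ValueError("need at least one result to rank")
    scales = {r.scale for r in results}
    if len(scales) > 1:
        raise ValueError(f"cannot rank technologies on mixed scales: {sorted(scales)}")
    ordered = sorted(results, key=lambda r: -r.value)
    for pos, res in enumerate(ordered):
        if pos > 0 and res.value == ordered[pos - 1].value:
            res.rank = ordered[pos - 1].rank
            res.tied = ordered[pos - 1].tied = True
        else:
            res.rank = pos + 1
            res.tied = False
    return ordered


def results_frame(results: Sequence[ValueResult]) -> pd.DataFrame:
    """Ranking table: one row per technology with V, rank, domain contributions."""
    rows = []
    for r in results:
        row: dict = {"technology_id": r.technology_id, "value": r.value,
                     "rank": r.rank, "tied": r.tied}
        row.update({f"contrib_{d}": v for d, v in r.domain_contributions.items()})
        rows.append(row)
    return pd.DataFrame(rows).set_index("technology_id")
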