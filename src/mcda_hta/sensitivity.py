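"""Sensitivity of composite values and rankings to weight uncertainty.

Two complementary analyses:

* **One-way (deterministic).** Sweep one domain's or criterion's percent
  weight over a grid while rescaling its siblings proportionally so the
  100-point budget is preserved, and recompute every technology's composite
  value. Because the value function is linear in each normalized weight,
  the resulting curves are piecewise linear (indeed globally linear in the
  varied percent) and ranking crossovers can be located exactly.

* **Probabilistic.** Propagate sampling uncertainty in the elicited weights
  by a stratified bootstrap: resample respondents with replacement within
  each sample, rebuild the pooled weights (unrounded — integer rounding is
  a presentation step and its noise would swamp small groups), recompute
  values and ranks, and report rank-acceptability fractions plus percentile
  intervals. For users without respondent-level microdata, a Dirichlet
  approximation with moment-matched concentrations stands in for the
  bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .elicitation import AllocationSet, SampleSummary
from .tree import ROOT_GROUP, CriteriaTree
from .value import ScoreSheet, aggregate_value, effective_leaf_weights
from .weights import WeightTable, _assemble_table, pool_means

__all__ = [
    "SensitivityCurve",
    "RankAcceptability",
    "one_way_weight_sensitivity",
    "probabilistic_sensitivity",
    "dirichlet_params_from_summary",
]


@dataclass
class SensitivityCurve:
    """Composite values along a one-way weight sweep.

    ``values`` is a DataFrame indexed by technology with one column per grid
    point (percent weight of the varied node). ``crossovers`` lists the
    percents at which the top-ranked technology changes, located exactly by
    linear interpolation. ``baseline`` is the varied node's percent in the
    unperturbed weight table.
    """

    node_id: str
    grid: np.ndarray
    values: pd.DataFrame
    baseline: float
    crossovers: list[float]


def _shifted_weight_table(weights: WeightTable, node_id: str, percent: float) -> WeightTable:
    """Weight table with ``node_id`` at ``percent`` and siblings rescaled."""
    tree = weights.tree
    node = tree.index[node_id]
    group = node.parent_id if node.parent_id is not None else ROOT_GROUP
    siblings = tree.children(group)
    base = np.array([weights.normalized(s) * 100.0 for s in siblings])
    idx = siblings.index(node_id)
    others = base.sum() - base[idx]
    if percent < 100.0 and others <= 0:
        raise ValueError(
            f"cannot rescale siblings of {node_id!r}: remaining weight is zero"
        )
    new = base * ((100.0 - percent) / others if others > 0 else 0.0)
    new[idx] = percent
    table = weights.table.copy()
    mask = table["group_id"] == group
    table.loc[mask, "normalized"] = [new[siblings.index(n)] / 100.0
                                     for n in table.index[mask]]
    return WeightTable(
        tree=tree, table=table, lambda_=weights.lambda_,
        sample_a=weights.sample_a, sample_b=weights.sample_b,
        rounding=weights.rounding, normalize_on=weights.normalize_on,
    )


def one_way_weight_sensitivity(
    weights: WeightTable,
    sheets: Sequence[ScoreSheet],
    node_id: str,
    grid: Sequence[float],
) -> SensitivityCurve:
    """Sweep one node's percent weight; siblings keep their relative shares.

    ``node_id`` must be a domain or a criterion; grid percents must lie in
    [0, 100]. At the baseline percent the recomputed values equal the
    unperturbed :func:`~mcda_hta.value.aggregate_value` output exactly.
    """
    level = weights.tree.index[node_id].level
    if level == "subcriterion":
        raise ValueError("one-way sweeps apply to domains or criteria, not subcriteria")
    grid_arr = np.asarray(sorted(grid), dtype=float)
    if grid_arr.size == 0 or (grid_arr < 0).any() or (grid_arr > 100).any():
        raise ValueError("grid percents must be a non-empty subset of [0, 100]")
    baseline = weights.normalized(node_id) * 100.0
    techs = [s.technology_id for s in sheets]
    vals = np.empty((len(sheets), grid_arr.size))
    for j, g in enumerate(grid_arr):
        if np.isclose(g, baseline):
            wt = weights
        else:
            wt = _shifted_weight_table(weights, node_id, float(g))
        for i, sheet in enumerate(sheets):
            vals[i, j] = aggregate_value(wt, sheet).value
    values = pd.DataFrame(vals, index=pd.Index(techs, name="technology_id"),
                          columns=grid_arr)
    crossovers: list[float] = []
    if len(sheets) > 1:
        top = values.to_numpy().argmax(axis=0)
        for j in range(1, grid_arr.size):
            if top[j] != top[j - 1]:
                a, b = top[j - 1], top[j]
                d0 = vals[a, j - 1] - vals[b, j - 1]
                d1 = vals[a, j] - vals[b, j]
                g0, g1 = grid_arr[j - 1], grid_arr[j]
                crossovers.append(float(g0 + (g1 - g0) * d0 / (d0 - d1))
                                  if d0 != d1 else float(g0))
    return SensitivityCurve(node_id=node_id, grid=grid_arr, values=values,
                            baseline=float(baseline), crossovers=crossovers)


@dataclass
class RankAcceptability:
    """Monte-Carlo rank distribution under weight uncertainty.

    ``rank_fractions``: technology × rank table of the fraction of draws in
    which each technology attained each (competition) rank; rows sum to one,
    and columns sum to one whenever no draw produced an exact value tie.
    ``value_stats``: per technology mean V and 2.5/97.5 percentile V over
    draws. ``n_ties`` counts draws containing at least one exact tie.
    """

    n_draws: int
    seed: int
    rank_fractions: pd.DataFrame
    value_stats: pd.DataFrame
    n_ties: int = 0


def dirichlet_params_from_summary(
    summary: SampleSummary, tree: CriteriaTree
) -> dict[str, np.ndarray]:
    """Moment-matched Dirichlet alphas for the sampling distribution of each
    group's *mean* weight vector.

    For a Dirichlet with mean m and concentration c, Var = m(1−m)/(c+1).
    Matching the standard error of the mean (sd²/n per node) gives, per
    group, c = avg_i[m_i(1−m_i)·n/sd_i²] − 1 and alpha = c·m. Zero-variance
    groups fall back to a near-degenerate concentration.
    """
    params: dict[str, np.ndarray] = {}
    for gid in tree.sibling_groups():
        children = tree.children(gid)
        if not all(c in summary.table.index for c in children):
            continue
        sub = summary.table.loc[children]
        m = sub["mean"].to_numpy() / 100.0
        se2 = (sub["sd"].to_numpy() / 100.0) ** 2 / sub["n"].to_numpy()
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = m * (1.0 - m) / se2
        ratio = ratio[np.isfinite(ratio) & (ratio > 0)]
        c = float(ratio.mean() - 1.0) if ratio.size else 1e6
        c = max(c, 1.0)
        params[gid] = np.clip(c * m, 1e-8, None)
    return params


def _sample_matrices(
    allocs: AllocationSet, sample_id: str
) -> tuple[list[str], dict[str, tuple[np.ndarray, np.ndarray]]]:
    """Per-group (respondent × child) point matrices for fast bootstrap."""
    tree = allocs.tree
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    respondents: list[str] = []
    seen: set[str] = set()
    for r in allocs.for_sample(sample_id):
        if r.respondent_id not in seen:
            seen.add(r.respondent_id)
            respondents.append(r.respondent_id)
    pos = {rid: i for i, rid in enumerate(respondents)}
    for gid in tree.sibling_groups():
        children = tree.children(gid)
        mat = np.full((len(respondents), len(children)), np.nan)
        for r in allocs.for_sample(sample_id):
            if r.group_id == gid:
                mat[pos[r.respondent_id]] = [r.points[c] for c in children]
        answered = ~np.isnan(mat[:, 0])
        out[gid] = (mat[answered], np.asarray(children, dtype=object))
    return respondents, out


def _values_from_group_means(
    tree: CriteriaTree, group_means: dict[str, np.ndarray], sheets: Sequence[ScoreSheet]
) -> np.ndarray:
    """Composite values from unrounded per-group mean percents (one draw)."""
    pooled = pd.Series(
        {c: float(v) for gid, vec in group_means.items()
         for c, v in zip(tree.children(gid), vec)}
    )
    table, _ = _assemble_table(tree, pooled, "largest-remainder", "pooled")
    wt = WeightTable(tree=tree, table=table, normalize_on="pooled")
    eff = effective_leaf_weights(wt)
    leaves = tree.leaves()
    w = np.array([eff[leaf] for leaf in leaves])
    s = np.array([[sheet.scores[leaf] for leaf in leaves] for sheet in sheets])
    return s @ w


def probabilistic_sensitivity(
    sheets: Sequence[ScoreSheet],
    n_draws: int,
    seed: int,
    allocs: Optional[AllocationSet] = None,
    dirichlet_params: Optional[dict[str, dict[str, np.ndarray]]] = None,
    tree: Optional[CriteriaTree] = None,
    lambda_: float = 0.5,
    sample_order: Optional[Sequence[str]] = None,
) -> RankAcceptability:
    """Rank acceptability under weight uncertainty.

    Exactly one of ``allocs`` (respondent microdata → stratified bootstrap)
    or ``dirichlet_params`` (sample_id → group_id → alpha vector, with
    ``tree``; → independent Dirichlet draws per group) must be given. Each
    draw rebuilds pooled group means with coefficient ``lambda_`` applied to
    the first sample, skips integer rounding, recomputes every technology's
    value, and competition-ranks them. Deterministic given ``seed``.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be ≥1")
    if (allocs is None) == (dirichlet_params is None):
        raise ValueError("provide exactly one of allocs or dirichlet_params")
    if not sheets:
        raise ValueError("need at least one score sheet")
    rng = np.random.default_rng(seed)

    if allocs is not None:
        tree = allocs.tree
        if sample_order is None:
            seen: list[str] = []
            for r in allocs.records:
                if r.sample_id not in seen:
                    seen.append(r.sample_id)
            sample_order = seen
        if len(sample_order) != 2:
            raise ValueError("stratified bootstrap needs exactly two samples")
        mats = {}
        for sid in sample_order:
            _, groups = _sample_matrices(allocs, sid)
            for gid, (mat, _children) in groups.items():
                if mat.shape[0] < 2:
                    raise ValueError(
                        f"sample {sid!r} has <2 respondents for group {gid!r}"
                    )
            mats[sid] = groups
    else:
        if tree is None:
            raise ValueError("tree is required with dirichlet_params")
        if sample_order is None:
            sample_order = list(dirichlet_params)
        if len(sample_order) != 2:
            raise ValueError("Dirichlet sensitivity needs exactly two samples")

    techs = [s.technology_id for s in sheets]
    n_tech = len(techs)
    lam = {sample_order[0]: lambda_, sample_order[1]: 1.0 - lambda_}
    rank_counts = np.zeros((n_tech, n_tech))
    draws = np.empty((n_draws, n_tech))
    n_ties = 0
    group_ids = tree.sibling_groups()
    for d in range(n_draws):
        group_means: dict[str, np.ndarray] = {}
        for gid in group_ids:
            total = None
            for sid in sample_order:
                if allocs is not None:
                    mat, _children = mats[sid][gid]
                    idx = rng.integers(0, mat.shape[0], size=mat.shape[0])
                    mean_vec = mat[idx].mean(axis=0)
                else:
                    alpha = dirichlet_params[sid].get(gid)
                    if alpha is None:
                        raise ValueError(f"no Dirichlet alphas for sample {sid!r}, group {gid!r}")
                    mean_vec = 100.0 * rng.dirichlet(alpha)
                contrib = lam[sid] * mean_vec
                total = contrib if total is None else total + contrib
            group_means[gid] = total
        vals = _values_from_group_means(tree, group_means, sheets)
        draws[d] = vals
        order = np.argsort(-vals, kind="stable")
        ranks = np.empty(n_tech, dtype=int)
        tie = False
        for pos_, t in enumerate(order):
            if pos_ > 0 and vals[t] == vals[order[pos_ - 1]]:
                ranks[t] = ranks[order[pos_ - 1]]
                tie = True
            else:
                ranks[t] = pos_ + 1
        n_ties += tie
        for t in range(n_tech):
            rank_counts[t, ranks[t] - 1] += 1
    rank_fractions = pd.DataFrame(
        rank_counts / n_draws,
        index=pd.Index(techs, name="technology_id"),
        columns=pd.Index(range(1, n_tech + 1), name="rank"),
    )
    value_stats = pd.DataFrame(
        {
            "mean": draws.mean(axis=0),
            "p2.5": np.percentile(draws, 2.5, axis=0),
            "p97.5": np.percentile(draws, 97.5, axis=0),
        },
        index=pd.Index(techs, name="technology_id"),
    )
    return RankAcceptability(
        n_draws=n_draws, seed=seed, rank_fractions=rank_fractions,
        value_stats=value_stats, n_ties=n_ties,
    )
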