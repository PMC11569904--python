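"""Weight synthesis: two-sample comparison, pooling, rounding, normalization.

The elicited weights come from two stakeholder samples of very different
size and dispersion (a small expert panel and a large population survey).
Pooling their raw responses would drown the experts, so the final weight of
each node is an equal-weighted average of the two *sample means* (pooling
coefficient λ = 0.5 by default), rounded per sibling group to integers that
sum to exactly 100, and finally normalized to fractions summing to one —
the form the additive value function consumes.

Per-node differences between the samples are tested with Welch's
unequal-variance t-test and the Mann–Whitney–Wilcoxon rank-sum test
(two-sided, normal approximation with tie correction).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .elicitation import AllocationSet, SampleSummary, summarize_sample
from .rounding import naive_round, round_preserving_sum
from .tree import ROOT_GROUP, CriteriaTree

#: default two-sided significance threshold used when flagging comparisons
ALPHA = 0.05


@dataclass
class ComparisonResult:
    """Two-sample comparison of the points allocated to one node.

    ``mean_diff`` is sample A − sample B in points. ``degenerate`` marks the
    zero-variance corner (both samples constant and equal) where the t
    statistic is undefined and p is reported as 1.
    """

    node_id: str
    sample_a: str
    sample_b: str
    n_a: int
    n_b: int
    mean_diff: float
    t_stat: float
    t_pvalue: float
    t_df: float
    u_stat: float
    u_pvalue: float
    degenerate: bool = False

    @property
    def significant(self) -> bool:
        return self.t_pvalue < ALPHA


def _node_values(allocs: AllocationSet, sample_id: str, node_id: str) -> np.ndarray:
    parent = allocs.tree.index[node_id].parent_id
    group = parent if parent is not None else ROOT_GROUP
    vals = [r.points[node_id] for r in allocs.for_sample(sample_id) if r.group_id == group]
    return np.asarray(vals, dtype=float)


def compare_samples(
    allocs: AllocationSet, node_id: str, sample_a: str, sample_b: str
) -> ComparisonResult:
    """Welch t and Mann–Whitney–Wilcoxon tests on one node, two-sided.

    Requires ≥2 respondents per sample for the node's group. When both
    samples are constant: equal constants give p = 1 with a degeneracy flag;
    different constants give p = 0 (an infinite t).
    """
    a = _node_values(allocs, sample_a, node_id)
    b = _node_values(allocs, sample_b, node_id)
    if len(a) < 2 or len(b) < 2:
        raise ValueError(
            f"need ≥2 respondents per sample for node {node_id!r} "
            f"(got {len(a)} and {len(b)})"
        )
    mean_diff = float(a.mean() - b.mean())
    degenerate = False
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        degenerate = True
        if mean_diff == 0.0:
            t_stat, t_p, df = float("nan"), 1.0, float("nan")
        else:
            t_stat = float("inf") if mean_diff > 0 else float("-inf")
            t_p, df = 0.0, float("nan")
    else:
        t_res = stats.ttest_ind(a, b, equal_var=False)
        t_stat, t_p = float(t_res.statistic), float(t_res.pvalue)
        df = float(t_res.df)
    if np.unique(np.concatenate([a, b])).size == 1:
        u_stat = float(len(a) * len(b) / 2.0)
        u_p = 1.0
        degenerate = True
    else:
        u_res = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=False
        )
        u_stat, u_p = float(u_res.statistic), float(u_res.pvalue)
    return ComparisonResult(
        node_id=node_id, sample_a=sample_a, sample_b=sample_b,
        n_a=len(a), n_b=len(b), mean_diff=mean_diff,
        t_stat=t_stat, t_pvalue=t_p, t_df=df,
        u_stat=u_stat, u_pvalue=u_p, degenerate=degenerate,
    )


def compare_all_nodes(
    allocs: AllocationSet, sample_a: str, sample_b: str,
    holm: bool = False,
) -> pd.DataFrame:
    """`compare_samples` over every node answered in both samples.

    With ``holm=True`` a Holm step-down adjustment is added per test family
    (raw p-values remain in the table); off by default.
    """
    rows = []
    for node_id in allocs.tree.iter_ids():
        try:
            res = compare_samples(allocs, node_id, sample_a, sample_b)
        except ValueError:
            continue
        rows.append(vars(res))
    table = pd.DataFrame(rows).set_index("node_id")
    if holm and len(table):
        for col in ("t_pvalue", "u_pvalue"):
            p = table[col].to_numpy()
            order = np.argsort(p)
            adj = np.empty_like(p)
            running = 0.0
            m = len(p)
            for rank, idx in enumerate(order):
                running = max(running, (m - rank) * p[idx])
                adj[idx] = min(1.0, running)
            table[col.replace("pvalue", "pvalue_holm")] = adj
    return table


def pool_means(
    summary_a: SampleSummary, summary_b: SampleSummary, lambda_: float = 0.5
) -> pd.Series:
    """Convex combination of the two samples' per-node mean weights.

    pooled = λ·mean_a + (1−λ)·mean_b. With λ = 0.5 this is the equal-weighted
    average of the two sample means, which deliberately gives the small
    expert sample the same voice as the large population sample. Sibling
    sums of 100 are preserved by linearity.
    """
    if not 0.0 <= lambda_ <= 1.0:
        raise ValueError(f"lambda must be in [0, 1], got {lambda_}")
    nodes_a, nodes_b = set(summary_a.table.index), set(summary_b.table.index)
    if nodes_a != nodes_b:
        diff = sorted(nodes_a.symmetric_difference(nodes_b))
        raise ValueError(f"summaries cover different node sets; difference: {diff}")
    mean_b = summary_b.table["mean"].reindex(summary_a.table.index)
    pooled = lambda_ * summary_a.table["mean"] + (1.0 - lambda_) * mean_b
    pooled.name = "pooled"
    return pooled


@dataclass
class WeightTable:
    """Final weights per node, at every stage of synthesis.

    ``table`` is indexed by node_id, document order, with columns
    ``label, level, group_id, mean_a, sd_a, n_a, mean_b, sd_b, n_b, pooled,
    rounded, normalized`` (single-sample columns are NaN when built from
    integer weights directly). ``normalized`` fractions sum to one within
    each sibling group.
    """

    tree: CriteriaTree
    table: pd.DataFrame
    lambda_: float = 0.5
    sample_a: Optional[str] = None
    sample_b: Optional[str] = None
    rounding: str = "largest-remainder"
    normalize_on: str = "rounded"
    broken_sum_groups: tuple[str, ...] = ()

    def normalized(self, node_id: str) -> float:
        return float(self.table.loc[node_id, "normalized"])

    def rounded(self, node_id: str) -> int:
        return int(self.table.loc[node_id, "rounded"])

    def group_frame(self, group_id: str) -> pd.DataFrame:
        return self.table[self.table["group_id"] == group_id]


def _normalize_groups(table: pd.DataFrame, column: str) -> pd.Series:
    out = pd.Series(np.nan, index=table.index, dtype=float)
    for gid, block in table.groupby("group_id", sort=False):
        total = block[column].sum()
        if total <= 0:
            raise ValueError(f"group {gid!r}: cannot normalize, {column} sums to {total}")
        out.loc[block.index] = block[column] / total
    return out


def _assemble_table(
    tree: CriteriaTree,
    pooled: pd.Series,
    rounding: str,
    normalize_on: str,
) -> tuple[pd.DataFrame, list[str]]:
    rows = []
    for gid in tree.sibling_groups():
        children = tree.children(gid)
        if not all(c in pooled.index for c in children):
            continue
        vals = pooled.reindex(children).to_numpy(dtype=float)
        if rounding == "largest-remainder":
            ints = round_preserving_sum(vals, 100)
        elif rounding == "naive":
            ints = naive_round(vals)
        else:
            raise ValueError(f"unknown rounding policy {rounding!r}")
        for c, v, w in zip(children, vals, ints):
            node = tree.index[c]
            rows.append(
                {"node_id": c, "label": node.label, "level": node.level,
                 "group_id": gid, "pooled": float(v), "rounded": int(w)}
            )
    table = pd.DataFrame(rows).set_index("node_id")
    broken = [
        gid for gid, block in table.groupby("group_id", sort=False)
        if int(block["rounded"].sum()) != 100
    ]
    base = "rounded" if normalize_on == "rounded" else "pooled"
    if normalize_on not in ("rounded", "pooled"):
        raise ValueError(f"unknown normalization base {normalize_on!r}")
    table["normalized"] = _normalize_groups(table, base)
    return table, broken


def build_weight_table(
    allocs: AllocationSet,
    lambda_: float = 0.5,
    sample_order: Optional[Sequence[str]] = None,
    rounding: str = "largest-remainder",
    normalize_on: str = "rounded",
) -> WeightTable:
    """Full synthesis: summarize each sample → pool → round → normalize.

    Parameters
    ----------
    allocs : AllocationSet
        Must contain exactly two samples (or pass ``sample_order`` to pick
        two). λ applies to the first sample of the pair.
    lambda_ : float
        Pooling coefficient in [0, 1]; 0.5 = equal-weighted average.
    rounding : {"largest-remainder", "naive"}
        Largest-remainder guarantees each sibling group's integers sum to
        exactly 100; naive nearest-integer may break the sum, in which case
        the offending groups are recorded in ``broken_sum_groups``.
    normalize_on : {"rounded", "pooled"}
        Basis for the normalized fractions (default: the rounded integers,
        i.e. ŵ = W/100 in full groups).
    """
    if sample_order is None:
        seen: list[str] = []
        for r in allocs.records:
            if r.sample_id not in seen:
                seen.append(r.sample_id)
        sample_order = seen
    if len(sample_order) != 2:
        raise ValueError(
            f"weight synthesis needs exactly two samples, got {list(sample_order)}"
        )
    sa, sb = sample_order
    summary_a = summarize_sample(allocs, sa)
    summary_b = summarize_sample(allocs, sb)
    pooled = pool_means(summary_a, summary_b, lambda_)
    table, broken = _assemble_table(allocs.tree, pooled, rounding, normalize_on)
    for summ, suffix in ((summary_a, "a"), (summary_b, "b")):
        table[f"mean_{suffix}"] = summ.table["mean"].reindex(table.index)
        table[f"sd_{suffix}"] = summ.table["sd"].reindex(table.index)
        table[f"n_{suffix}"] = summ.table["n"].reindex(table.index)
    return WeightTable(
        tree=allocs.tree, table=table, lambda_=lambda_,
        sample_a=sa, sample_b=sb, rounding=rounding,
        normalize_on=normalize_on, broken_sum_groups=tuple(broken),
    )


def weight_table_from_integers(
    tree: CriteriaTree, weights: dict[str, float], normalize_on: str = "rounded"
) -> WeightTable:
    """Build a WeightTable from published per-node percent weights.

    For users who already have a final weight table (integer percents per
    sibling group) and want to skip elicitation entirely. ``weights`` maps
    every child of every sibling group to its percent. Groups whose printed
    percents do not sum to 100 (independent per-item rounding in the source)
    are rescaled to 100 and recorded in ``broken_sum_groups``.
    """
    missing = [
        c for gid in tree.sibling_groups() for c in tree.children(gid)
        if c not in weights
    ]
    if missing:
        raise ValueError(f"missing weights for node(s): {missing}")
    pooled = pd.Series({k: float(v) for k, v in weights.items()})
    repaired: list[str] = []
    for gid in tree.sibling_groups():
        children = tree.children(gid)
        total = pooled.loc[children].sum()
        if total <= 0:
            raise ValueError(f"group {gid!r}: weights sum to {total}")
        if abs(total - 100.0) > 1e-6:
            repaired.append(gid)
            pooled.loc[children] = pooled.loc[children] * (100.0 / total)
    table, _ = _assemble_table(tree, pooled, "largest-remainder", normalize_on)
    return WeightTable(tree=tree, table=table, broken_sum_groups=tuple(repaired),
                       normalize_on=normalize_on)
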