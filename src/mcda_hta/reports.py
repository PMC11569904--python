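"""Distribution reports for elicited weights: histograms and box summaries.

Point-allocation responses cluster on multiples of five and differ sharply
in spread between stakeholder samples, so the default report bins points in
width-5 bins over [0, 100] (the last bin closed) and adds the median and
quartiles per node × sample.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .elicitation import AllocationSet

DEFAULT_BIN_WIDTH = 5


def distribution_report(
    allocs: AllocationSet,
    level: str,
    bin_width: int = DEFAULT_BIN_WIDTH,
) -> pd.DataFrame:
    """Histogram counts and quartiles per node × sample at one tree level.

    Returns a DataFrame with one row per (sample_id, node_id) and columns
    ``n, median, q1, q3`` plus one ``bin_<lo>_<hi>`` count column per bin.
    Bin edges are ``0, bin_width, ..., 100`` with the final bin closed, so
    each node's bin counts sum to the sample's n for that node's group.
    """
    if not allocs.records:
        raise ValueError("no allocation records to report on")
    if 100 % bin_width:
        raise ValueError("bin_width must divide 100")
    edges = np.arange(0, 100 + bin_width, bin_width)
    nodes = allocs.tree.nodes_at_level(level)
    rows = []
    for sample_id in sorted(allocs.samples):
        for nid in nodes:
            parent = allocs.tree.index[nid].parent_id
            group = parent if parent is not None else "root"
            vals = np.array(
                [r.points[nid] for r in allocs.for_sample(sample_id)
                 if r.group_id == group],
                dtype=float,
            )
            if vals.size == 0:
                continue
            counts, _ = np.histogram(vals, bins=edges)
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            row = {"sample_id": sample_id, "node_id": nid,
                   "label": allocs.tree.index[nid].label,
                   "n": int(vals.size), "median": float(med),
                   "q1": float(q1), "q3": float(q3)}
            row.update({f"bin_{lo}_{lo + bin_width}": int(c)
                        for lo, c in zip(edges[:-1], counts)})
            rows.append(row)
    return pd.DataFrame(rows)


def plot_histograms(
    allocs: AllocationSet, level: str, path: str, bin_width: int = DEFAULT_BIN_WIDTH
) -> Optional[str]:
    """Write a per-node histogram grid (one line per sample) to ``path``.

    Requires matplotlib; returns the path written, or None if matplotlib is
    not installed (the CSV report carries the same information).
    """
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except ImportError:
        return None
    nodes = allocs.tree.nodes_at_level(level)
    samples = sorted(allocs.samples)
    edges = np.arange(0, 100 + bin_width, bin_width)
    ncols = min(3, len(nodes))
    nrows = -(-len(nodes) // ncols)
    fig, axes = plt.subplots(nrows, ncols, figsize=(4 * ncols, 3 * nrows),
                             squeeze=False)
    for ax, nid in zip(axes.flat, nodes):
        parent = allocs.tree.index[nid].parent_id
        group = parent if parent is not None else "root"
        for sample_id in samples:
            vals = [r.points[nid] for r in allocs.for_sample(sample_id)
                    if r.group_id == group]
            ax.hist(vals, bins=edges, density=True, alpha=0.5, label=sample_id)
        ax.set_title(allocs.tree.index[nid].label, fontsize=9)
        ax.set_xlabel("points")
    for ax in axes.flat[len(nodes):]:
        ax.axis("off")
    axes.flat[0].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
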