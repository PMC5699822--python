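"""Quality control of gene trees and posterior tree samples.

Covers mean bootstrap support and quantile-based locus filtering,
substitution-saturation diagnosis (p-distance vs patristic-distance
regression with a lower Tukey fence on the slopes), MCMC burn-in
removal, split frequencies and the average standard deviation of split
frequencies (ASDSF) convergence diagnostic, and maximum clade
credibility topology (MCCT) selection from a posterior sample.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
from scipy import stats

from .likelihood import p_distance_matrix  # re-exported: same statistic feeds QC

logger = logging.getLogger(__name__)

__all__ = [
    "LocusQCRecord", "TreeSample", "SplitFrequencyTable",
    "read_tree", "read_tree_sample", "leaf_labels", "nontrivial_splits",
    "mean_support", "filter_low_support_loci", "p_distance_matrix",
    "patristic_matrix", "saturation_regression", "flag_saturated_loci",
    "apply_burnin", "split_frequencies", "asdsf", "mcct",
]


@dataclass
class LocusQCRecord:
    locus_id: str
    mean_support: float = float("nan")
    sat_slope: float = float("nan")
    sat_intercept: float = float("nan")
    sat_r2: float = float("nan")
    dropped_low_support: bool = False
    dropped_saturated: bool = False

    @property
    def kept(self) -> bool:
        return not (self.dropped_low_support or self.dropped_saturated)


@dataclass
class TreeSample:
    """Ordered posterior sample of trees from one MCMC run."""

    trees: list[dendropy.Tree]
    sample_interval: int = 1
    burnin_fraction: float = 0.25

    def __len__(self) -> int:
        return len(self.trees)


def read_tree(path_or_newick: str | Path) -> dendropy.Tree:
    text = str(path_or_newick)
    if "(" in text and not Path(text).exists():
        return dendropy.Tree.get(data=text, schema="newick")
    return dendropy.Tree.get(path=text, schema="newick")


def read_tree_sample(path: str | Path, **kwargs) -> TreeSample:
    """Read a ``.t``-style tree-list file: one newick per line, optionally
    prefixed ``tree NAME = [&U]``."""
    trees = []
    ns = dendropy.TaxonNamespace()
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if "(" not in line:
            continue
        newick = line[line.index("(") :]
        trees.append(
            dendropy.Tree.get(data=newick, schema="newick", taxon_namespace=ns)
        )
    return TreeSample(trees, **kwargs)


def leaf_labels(tree: dendropy.Tree) -> frozenset[str]:
    return frozenset(
        (leaf.taxon.label if leaf.taxon else leaf.label)
        for leaf in tree.leaf_node_iter()
    )


def _node_label(node: dendropy.Node) -> str | None:
    return node.taxon.label if node.taxon else node.label


def _clade_leafsets(tree: dendropy.Tree) -> dict[int, frozenset[str]]:
    """Leaf-label set under every node, keyed by id(node)."""
    out: dict[int, frozenset[str]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            out[id(node)] = frozenset([_node_label(node)])
        else:
            out[id(node)] = frozenset().union(
                *(out[id(c)] for c in node.child_nodes())
            )
    return out


def nontrivial_splits(tree: dendropy.Tree) -> frozenset[frozenset[str]]:
    """Non-trivial unrooted bipartitions, each keyed by the side NOT
    containing the lexicographically first taxon."""
    leaves = leaf_labels(tree)
    anchor = min(leaves)
    clades = _clade_leafsets(tree)
    splits = set()
    for node in tree.preorder_internal_node_iter():
        side = clades[id(node)]
        if anchor in side:
            side = leaves - side
        if 2 <= len(side) <= len(leaves) - 2:
            splits.add(side)
    return frozenset(splits)


# ---------------------------------------------------------------------------
# support filtering

def _internal_supports(tree: dendropy.Tree) -> list[float]:
    leaves = leaf_labels(tree)
    clades = _clade_leafsets(tree)
    supports = []
    for node in tree.preorder_internal_node_iter():
        side = clades[id(node)]
        if not (2 <= len(side) <= len(leaves) - 2):
            continue  # trivial split (root edge or cherry complement)
        label = node.label
        if label is None:
            continue
        try:
            supports.append(float(label))
        except ValueError:
            continue
    return supports


def mean_support(tree: dendropy.Tree) -> float:
    """Mean internal-edge support, normalized to the [0, 100] scale.

    Supports on [0, 1] (posterior probabilities) are auto-detected and
    scaled by 100.
    """
    supports = _internal_supports(tree)
    if not supports:
        raise ValueError("tree carries no internal-edge support values")
    values = np.asarray(supports, dtype=float)
    if values.max() <= 1.0:
        values = values * 100.0
    return float(values.mean())


def filter_low_support_loci(
    records: Sequence[LocusQCRecord], q: float = 0.10
) -> list[LocusQCRecord]:
    """Flag loci whose mean support falls strictly below the q-quantile
    (linear interpolation, type-7 convention) of all mean supports."""
    if len(records) < 2:
        raise ValueError("need >= 2 records")
    means = np.array([r.mean_support for r in records], dtype=float)
    cutoff = float(np.quantile(means, q))
    for record in records:
        record.dropped_low_support = bool(record.mean_support < cutoff)
    return list(records)


# ---------------------------------------------------------------------------
# saturation

def patristic_matrix(
    tree: dendropy.Tree, taxa: Sequence[str] | None = None
) -> np.ndarray:
    """Leaf-to-leaf path-length (sum of branch length) matrix."""
    order = list(taxa) if taxa is not None else sorted(leaf_labels(tree))
    index = {t: i for i, t in enumerate(order)}
    n = len(order)
    # accumulate distances from each node down to its leaves
    dist = np.zeros((n, n))
    below: dict[int, list[tuple[int, float]]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[id(node)] = [(index[_node_label(node)], 0.0)]
            continue
        groups = []
        for child in node.child_nodes():
            if child.edge.length is None:
                raise ValueError("missing branch length on tree")
            groups.append(
                [(i, d + child.edge.length) for i, d in below[id(child)]]
            )
        for gi in range(len(groups)):
            for gj in range(gi + 1, len(groups)):
                for i, di in groups[gi]:
                    for j, dj in groups[gj]:
                        dist[i, j] = dist[j, i] = di + dj
        below[id(node)] = [pair for group in groups for pair in group]
    return dist


def saturation_regression(
    p: np.ndarray, patristic: np.ndarray
) -> tuple[float, float, float]:
    """OLS of p-distance on patristic distance over upper-triangle pairs.

    A saturated locus shows p-distances plateauing while tree distances
    keep growing, i.e. a depressed slope.  Returns (slope, intercept, r2);
    pairs with missing p-distance are excluded.
    """
    iu = np.triu_indices_from(p, k=1)
    x = np.asarray(patristic)[iu].astype(float)
    y = np.asarray(p)[iu].astype(float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need >= 3 complete pairs for the saturation regression")
    if np.ptp(x) == 0:
        return 0.0, float(y.mean()), 0.0
    fit = stats.linregress(x, y)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue**2)


def flag_saturated_loci(
    records: Sequence[LocusQCRecord],
    method: str = "tukey",
    multiplier: float = 1.5,
) -> list[LocusQCRecord]:
    """Flag loci whose saturation slope falls below the lower Tukey fence
    Q1 - multiplier*IQR of the slope distribution."""
    if method != "tukey":
        raise ValueError(f"unknown saturation outlier method: {method}")
    slopes = np.array([r.sat_slope for r in records], dtype=float)
    if len(slopes) < 4 or np.isnan(slopes).any():
        raise ValueError("need >= 4 records with saturation slopes")
    q1, q3 = np.percentile(slopes, [25, 75])
    fence = q1 - multiplier * (q3 - q1)
    for record in records:
        record.dropped_saturated = bool(record.sat_slope < fence)
    return list(records)


# ---------------------------------------------------------------------------
# posterior samples

def apply_burnin(sample: TreeSample) -> TreeSample:
    """Drop the first floor(burnin_fraction * N) trees of the run."""
    if not (0 <= sample.burnin_fraction < 1):
        raise ValueError("burnin_fraction must be in [0, 1)")
    n_drop = math.floor(sample.burnin_fraction * len(sample.trees))
    kept = sample.trees[n_drop:]
    if not kept:
        raise ValueError("burn-in removed every sampled tree")
    return TreeSample(kept, sample.sample_interval, 0.0)


@dataclass
class SplitFrequencyTable:
    """Per-run frequency of every observed non-trivial split."""

    frequencies: dict[frozenset[str], np.ndarray]
    n_runs: int


def split_frequencies(samples: Sequence[TreeSample]) -> SplitFrequencyTable:
    """Per-run split frequencies over post-burn-in samples.

    Splits never seen in a run get frequency 0 there; all runs must share
    one leaf set.
    """
    if not samples:
        raise ValueError("no tree samples given")
    leafsets = {leaf_labels(s.trees[0]) for s in samples}
    if len(leafsets) != 1:
        raise ValueError("tree samples have mismatched leaf sets")
    counts: dict[frozenset[str], np.ndarray] = {}
    for run_idx, sample in enumerate(samples):
        for tree in sample.trees:
            if leaf_labels(tree) != next(iter(leafsets)):
                raise ValueError("tree samples have mismatched leaf sets")
            for split in nontrivial_splits(tree):
                if split not in counts:
                    counts[split] = np.zeros(len(samples))
                counts[split][run_idx] += 1
    freqs = {
        split: row / np.array([len(s.trees) for s in samples], dtype=float)
        for split, row in counts.items()
    }
    return SplitFrequencyTable(freqs, len(samples))


def asdsf(table: SplitFrequencyTable, min_freq: float = 0.10) -> float:
    """Average (over qualifying splits) of the sample standard deviation
    (n_runs - 1 denominator) of per-run split frequencies.

    Splits qualify when their frequency reaches ``min_freq`` in at least
    one run — the convention of the MCMC tool this diagnostic mirrors.
    """
    if table.n_runs < 2:
        raise ValueError("ASDSF needs >= 2 runs")
    sds = [
        float(np.std(row, ddof=1))
        for row in table.frequencies.values()
        if row.max() >= min_freq
    ]
    if not sds:
        raise ValueError(f"no split reaches the {min_freq} inclusion threshold")
    return float(np.mean(sds))


def mcct(sample: TreeSample) -> dendropy.Tree:
    """Maximum clade credibility topology from a posterior sample.

    Candidates are the sampled trees themselves; each is scored by the sum
    of log clade frequencies (clades of the rooted representation,
    frequencies over the full sample), ties broken by first occurrence.
    Internal nodes of the returned (cloned) tree are annotated with their
    clade posterior frequency.
    """
    if not sample.trees:
        raise ValueError("empty tree sample")
    n = len(sample.trees)
    clade_counts: dict[frozenset[str], int] = {}
    per_tree_clades = []
    for tree in sample.trees:
        clades = [
            c for c in _clade_leafsets(tree).values() if len(c) >= 2
        ]
        per_tree_clades.append(clades)
        for clade in set(clades):
            clade_counts[clade] = clade_counts.get(clade, 0) + 1
    best_idx, best_score = 0, -math.inf
    for idx, clades in enumerate(per_tree_clades):
        score = sum(math.log(clade_counts[c] / n) for c in set(clades))
        if score > best_score:
            best_idx, best_score = idx, score
    winner = sample.trees[best_idx].clone(depth=1)
    clades = _clade_leafsets(winner)
    for node in winner.preorder_internal_node_iter():
        freq = clade_counts.get(clades[id(node)], 0) / n
        node.label = f"{freq:.4f}"
        node.annotations["posterior"] = freq
    return winner


def write_qc_report(records: Sequence[LocusQCRecord], out_path: str | Path) -> None:
    out = Path(out_path)
    out.parent.mkdir(parents=True, exist_ok=True)
    with open(out, "w") as fh:
        fh.write(
            "locus_id\tmean_support\tsat_slope\tsat_intercept\tsat_r2\t"
            "dropped_low_support\tdropped_saturated\n"
        )
        for r in sorted(records, key=lambda r: r.locus_id):
            fh.write(
                f"{r.locus_id}\t{r.mean_support:.6g}\t{r.sat_slope:.6g}\t"
                f"{r.sat_intercept:.6g}\t{r.sat_r2:.6g}\t"
                f"{int(r.dropped_low_support)}\t{int(r.dropped_saturated)}\n"
            )
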