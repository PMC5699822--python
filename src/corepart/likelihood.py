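"""GTR+Gamma likelihood engine on a fixed guide tree.

Implements Felsenstein's pruning algorithm with discrete-gamma rate
variation (category means of equal-probability slices of
Gamma(alpha, alpha)), neighbor-joining guide trees from Jukes-Cantor
distances, and maximum-likelihood fitting of subset models by bounded
coordinate ascent.  Branch lengths live on the guide tree and are shared
by all subsets of a locus; subsets differ only in their substitution
parameters and a relative rate multiplier.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from .alignments import LocusAlignment

logger = logging.getLogger(__name__)

# state coding: A=0 C=1 G=2 T=3, anything else = 4 (missing)
_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i

#: exchangeability order (i, j) for the 6 relative rates
RATE_PAIRS = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]

RATE_BOUNDS = (1e-6, 100.0)
ALPHA_BOUNDS = (0.02, 100.0)
MULTIPLIER_BOUNDS = (1e-3, 100.0)
FREQ_WEIGHT_BOUNDS = (1e-3, 1e3)
BRLEN_BOUNDS = (1e-8, 10.0)


def encode_alignment(aln: LocusAlignment) -> np.ndarray:
    """(n_taxa, length) int8 array; 0-3 = ACGT, 4 = missing/ambiguous."""
    raw = np.frombuffer("".join(aln.seqs).encode(), dtype=np.uint8)
    return _CODE[raw].reshape(aln.n_taxa, aln.length)


@dataclass
class GTRGammaModel:
    """General time-reversible model with discrete-gamma rate variation.

    ``rates`` are the six exchangeabilities in the order
    AC, AG, AT, CG, CT, GT with GT fixed to 1 as the reference;
    ``rate_multiplier`` rescales the guide tree's branch lengths for the
    subset this model is attached to.
    """

    rates: np.ndarray = field(default_factory=lambda: np.ones(6))
    freqs: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    alpha: float = 1.0
    n_categories: int = 4
    rate_multiplier: float = 1.0

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.rates.shape != (6,) or (self.rates < 0).any():
            raise ValueError("need 6 non-negative exchangeabilities")
        if self.freqs.shape != (4,) or (self.freqs < 0).any():
            raise ValueError("need 4 non-negative base frequencies")
        if abs(self.freqs.sum() - 1.0) > 1e-8:
            raise ValueError("base frequencies must sum to 1")
        if self.alpha <= 0:
            raise ValueError("gamma shape alpha must be > 0")
        if self.rate_multiplier <= 0:
            raise ValueError("rate multiplier must be > 0")

    @property
    def n_free_params(self) -> int:
        # 5 exchangeabilities (GT == 1) + 3 frequencies + alpha
        return 9

    def q_matrix(self) -> np.ndarray:
        """Rate matrix normalized to one expected substitution per unit time."""
        q = np.zeros((4, 4))
        for rate, (i, j) in zip(self.rates, RATE_PAIRS):
            q[i, j] = rate * self.freqs[j]
            q[j, i] = rate * self.freqs[i]
        np.fill_diagonal(q, -q.sum(axis=1))
        mu = -(self.freqs * np.diag(q)).sum()
        return q / mu


def discrete_gamma_rates(alpha: float, n_categories: int) -> np.ndarray:
    """Mean rate of each equal-probability slice of Gamma(alpha, alpha).

    The category means integrate to exactly 1, so the expected rate over
    categories is 1 for every alpha.
    """
    if n_categories == 1:
        return np.ones(1)
    edges = gamma_dist.ppf(np.arange(1, n_categories) / n_categories, a=alpha, scale=1 / alpha)
    cdf1 = np.concatenate(([0.0], gammainc(alpha + 1, alpha * edges), [1.0]))
    return n_categories * np.diff(cdf1)


class PruningTree:
    """Flattened postorder view of a dendropy tree for fast pruning.

    Leaves are matched to alignment rows by taxon label; the (arbitrary)
    dendropy seed node serves as root, which is inconsequential for a
    reversible model.
    """

    def __init__(self, tree: dendropy.Tree, taxa: list[str]):
        taxon_row = {t: i for i, t in enumerate(taxa)}
        nodes = list(tree.postorder_node_iter())
        self.n_nodes = len(nodes)
        index = {id(n): i for i, n in enumerate(nodes)}
        self.children: list[list[int]] = [[] for _ in nodes]
        self.edge_lengths = np.zeros(self.n_nodes)
        self.leaf_row = np.full(self.n_nodes, -1, dtype=int)
        for i, node in enumerate(nodes):
            for child in node.child_nodes():
                self.children[i].append(index[id(child)])
            self.edge_lengths[i] = node.edge.length or 0.0
            if node.is_leaf():
                label = node.taxon.label if node.taxon else node.label
                if label not in taxon_row:
                    raise ValueError(f"tree leaf {label!r} not in alignment")
                self.leaf_row[i] = taxon_row[label]
        self.root = self.n_nodes - 1

    @property
    def n_branches(self) -> int:
        return self.n_nodes - 1


def compress_patterns(data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unique site columns and their multiplicities."""
    cols, weights = np.unique(data.T, axis=0, return_counts=True)
    return cols.T, weights.astype(float)


def _transition_matrices(model: GTRGammaModel, scaled_lengths: np.ndarray) -> np.ndarray:
    """P(t) for every (category, branch) via symmetric eigendecomposition."""
    q = model.q_matrix()
    pi_sqrt = np.sqrt(model.freqs)
    sym = q * pi_sqrt[:, None] / pi_sqrt[None, :]
    eigval, eigvec = np.linalg.eigh((sym + sym.T) / 2)
    left = eigvec / pi_sqrt[:, None]
    right = eigvec * pi_sqrt[:, None]
    # scaled_lengths: (ncat, nbranch); result (ncat, nbranch, 4, 4)
    expo = np.exp(eigval[None, None, :] * scaled_lengths[:, :, None])
    return np.einsum("ik,cbk,jk->cbij", left, expo, right)


def gtr_gamma_loglik(
    aln: LocusAlignment | np.ndarray,
    tree: dendropy.Tree | PruningTree,
    model: GTRGammaModel,
    taxa: list[str] | None = None,
    pattern_cache: tuple[np.ndarray, np.ndarray] | None = None,
) -> float:
    """Log-likelihood of an alignment (or encoded array) on a fixed tree.

    Missing states contribute all-ones tip partials; identical site
    patterns are compressed and weighted; branch lengths are scaled by
    ``model.rate_multiplier`` and the discrete-gamma category rates.
    """
    model.validate()
    if isinstance(aln, LocusAlignment):
        data = encode_alignment(aln)
        taxa = aln.taxa
    else:
        data = aln
        if taxa is None and not isinstance(tree, PruningTree):
            raise ValueError("taxa required with an encoded array")
    ptree = tree if isinstance(tree, PruningTree) else PruningTree(tree, list(taxa))
    patterns, weights = pattern_cache if pattern_cache is not None else compress_patterns(data)
    return _loglik_inner(patterns, weights, ptree, model)


class LikelihoodKernel:
    """Reusable pruning workspace for one (pattern set, tree) pair.

    Tip partials and the postorder schedule are computed once; each
    ``loglik`` call only rebuilds the transition matrices and runs the
    pruning recursion, which makes repeated evaluation during model
    fitting cheap.
    """

    def __init__(self, patterns: np.ndarray, weights: np.ndarray, ptree: PruningTree):
        self.patterns = patterns
        self.weights = weights
        self.ptree = ptree
        tip_partial = np.vstack([np.eye(4), np.ones(4)])
        self.tip = {
            node: tip_partial[patterns[ptree.leaf_row[node]]]
            for node in range(ptree.n_nodes)
            if not ptree.children[node]
        }

    def loglik(self, model: GTRGammaModel) -> float:
        ptree = self.ptree
        ncat = model.n_categories
        cat_rates = discrete_gamma_rates(model.alpha, ncat)
        scaled = cat_rates[:, None] * (model.rate_multiplier * ptree.edge_lengths[None, :])
        # pmats transposed once so pruning is a plain batched matmul
        pmats_t = _transition_matrices(model, scaled).transpose(0, 1, 3, 2)
        partials: list = [None] * ptree.n_nodes
        for node in range(ptree.n_nodes):
            kids = ptree.children[node]
            if not kids:
                partials[node] = self.tip[node]
                continue
            acc = None
            for child in kids:
                down = np.matmul(partials[child], pmats_t[:, child])
                acc = down if acc is None else acc * down
            partials[node] = acc
        site_like = (partials[ptree.root] @ model.freqs).mean(axis=0)
        if (site_like <= 0).any():
            return -np.inf
        return float(self.weights @ np.log(site_like))


def _loglik_inner(
    patterns: np.ndarray, weights: np.ndarray, ptree: PruningTree, model: GTRGammaModel
) -> float:
    return LikelihoodKernel(patterns, weights, ptree).loglik(model)


# ---------------------------------------------------------------------------
# distances and the NJ guide tree

JC_MAX_DISTANCE = 5.0


def p_distance_matrix(aln: LocusAlignment) -> np.ndarray:
    """Uncorrected pairwise mismatch proportions over unambiguous sites.

    Pairs with zero overlapping sites get NaN with a warning.
    """
    if aln.n_taxa < 2:
        raise ValueError("need >= 2 taxa")
    data = encode_alignment(aln)
    valid = data < 4
    n = aln.n_taxa
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            overlap = int(both.sum())
            if overlap == 0:
                logger.warning(
                    "no overlapping sites between %s and %s in locus %s",
                    aln.taxa[i], aln.taxa[j], aln.locus_id,
                )
                dist[i, j] = dist[j, i] = np.nan
                continue
            mism = int((data[i, both] != data[j, both]).sum())
            dist[i, j] = dist[j, i] = mism / overlap
    return dist


def jc_correct(p: float) -> float:
    """Jukes-Cantor distance; saturated pairs are capped at JC_MAX_DISTANCE."""
    if p >= 0.75:
        return JC_MAX_DISTANCE
    return min(-0.75 * math.log1p(-4.0 * p / 3.0), JC_MAX_DISTANCE)


def nj_guide_tree(aln: LocusAlignment) -> dendropy.Tree:
    """Neighbor-joining guide tree from JC-corrected pairwise distances.

    Negative NJ branch lengths are clamped to zero.  A taxon pair with no
    overlapping data has no defined distance and raises.
    """
    from skbio import DistanceMatrix
    from skbio.tree import nj

    if aln.n_taxa < 3:
        raise ValueError("need >= 3 taxa for a guide tree")
    pmat = p_distance_matrix(aln)
    if np.isnan(pmat).any():
        raise ValueError(f"locus {aln.locus_id}: taxon pair with no overlapping sites")
    dmat = np.vectorize(jc_correct)(pmat)
    np.fill_diagonal(dmat, 0.0)
    skb = nj(DistanceMatrix(dmat, ids=aln.taxa))
    tree = dendropy.Tree.get(data=str(skb), schema="newick")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            edge.length = 0.0
        if edge.length is None and edge.head_node is not tree.seed_node:
            edge.length = 0.0
    return tree


def optimize_branch_lengths(
    tree: dendropy.Tree,
    aln: LocusAlignment,
    model: GTRGammaModel | None = None,
    sweeps: int = 2,
    tol: float = 1e-4,
) -> float:
    """One-off coordinate-ascent refinement of guide-tree branch lengths
    under a (default) GTR+Gamma model, done once per locus before subset
    fitting.  Returns the final log-likelihood."""
    model = model or GTRGammaModel()
    data = encode_alignment(aln)
    patterns, weights = compress_patterns(data)
    ptree = PruningTree(tree, aln.taxa)
    edges = [i for i in range(ptree.n_nodes) if i != ptree.root]
    kernel = LikelihoodKernel(patterns, weights, ptree)
    best = kernel.loglik(model)
    for _ in range(sweeps):
        previous = best
        for e in edges:
            def nll(x: float, e: int = e) -> float:
                ptree.edge_lengths[e] = x
                return -kernel.loglik(model)

            res = minimize_scalar(
                nll, bounds=BRLEN_BOUNDS, method="bounded", options={"xatol": 1e-5}
            )
            if -res.fun >= best:
                best = -res.fun
                ptree.edge_lengths[e] = res.x
            else:
                nll(ptree.edge_lengths[e])  # restore
        if best - previous < tol:
            break
    # copy optimized lengths back onto the dendropy tree
    for i, node in enumerate(tree.postorder_node_iter()):
        if i != ptree.root:
            node.edge.length = float(ptree.edge_lengths[i])
    return best


# ---------------------------------------------------------------------------
# subset model fitting

@dataclass
class SubsetFit:
    """ML fit of one model subset (a union of charsets) on the guide tree."""

    member_charsets: list[str]
    n_sites: int
    model: GTRGammaModel
    lnL: float
    k: int
    converged: bool = True


@dataclass
class FitOptions:
    max_sweeps: int = 200
    tol: float = 1e-6
    scalar_xatol: float = 1e-3
    fit_multiplier: bool = True
    n_categories: int = 4


def fit_subset_model(
    aln_subset: LocusAlignment | np.ndarray,
    tree: dendropy.Tree | PruningTree,
    opts: FitOptions | None = None,
    taxa: list[str] | None = None,
    member_charsets: list[str] | None = None,
) -> SubsetFit:
    """Maximize the GTR+Gamma log-likelihood over exchangeabilities, base
    frequencies, alpha and the subset rate multiplier by coordinate ascent
    with bounded scalar line searches (parameters searched in log space).

    Guide-tree branch lengths are held fixed.  The returned lnL never falls
    below the likelihood at the default initial parameters.
    """
    opts = opts or FitOptions()
    if isinstance(aln_subset, LocusAlignment):
        data = encode_alignment(aln_subset)
        taxa = aln_subset.taxa
    else:
        data = aln_subset
    ptree = tree if isinstance(tree, PruningTree) else PruningTree(tree, list(taxa))
    patterns, weights = compress_patterns(data)
    n_sites = int(weights.sum())

    # parameter vector: 5 log-exchangeabilities, 3 log freq weights (T ref),
    # log alpha, log multiplier
    state = {
        "rates": np.ones(6),
        "weights": np.ones(4),
        "alpha": 1.0,
        "multiplier": 1.0,
    }

    def current_model() -> GTRGammaModel:
        freqs = state["weights"] / state["weights"].sum()
        return GTRGammaModel(
            rates=state["rates"].copy(),
            freqs=freqs,
            alpha=state["alpha"],
            n_categories=opts.n_categories,
            rate_multiplier=state["multiplier"],
        )

    kernel = LikelihoodKernel(patterns, weights, ptree)

    def lnl() -> float:
        return kernel.loglik(current_model())

    best = lnl()
    converged = False
    coords: list[tuple[str, int, tuple[float, float]]] = (
        [("rates", i, RATE_BOUNDS) for i in range(5)]
        + [("weights", i, FREQ_WEIGHT_BOUNDS) for i in range(3)]
        + [("alpha", -1, ALPHA_BOUNDS)]
        + ([("multiplier", -1, MULTIPLIER_BOUNDS)] if opts.fit_multiplier else [])
    )

    def get(kind: str, idx: int) -> float:
        return state[kind][idx] if idx >= 0 else state[kind]

    def put(kind: str, idx: int, value: float) -> None:
        if idx >= 0:
            state[kind][idx] = value
        else:
            state[kind] = value

    stale = {i: 0 for i in range(len(coords))}
    for sweep in range(opts.max_sweeps):
        previous = best
        xatol = 0.05 if sweep < 2 else opts.scalar_xatol
        for ci, (kind, idx, (lo, hi)) in enumerate(coords):
            if stale[ci] >= 2:  # coordinate stopped contributing
                continue
            saved = get(kind, idx)

            def nll(logx: float) -> float:
                put(kind, idx, math.exp(logx))
                return -lnl()

            res = minimize_scalar(
                nll,
                bounds=(math.log(lo), math.log(hi)),
                method="bounded",
                options={"xatol": xatol},
            )
            if -res.fun > best:
                gain = -res.fun - best
                best = -res.fun
                put(kind, idx, math.exp(res.x))
            else:
                gain = 0.0
                put(kind, idx, saved)
            stale[ci] = stale[ci] + 1 if gain < opts.tol else 0
        if best - previous < opts.tol:
            converged = True
            break
    if not converged:
        logger.warning("subset fit did not converge after %d sweeps", opts.max_sweeps)

    model = current_model()
    return SubsetFit(
        member_charsets=list(member_charsets or []),
        n_sites=n_sites,
        model=model,
        lnL=best,
        k=model.n_free_params,
        converged=converged,
    )
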