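"""AICc-based selection of the best grouping of a locus's charsets.

Every charset starts in its own model subset; a greedy search repeatedly
merges the pair of subsets that most decreases the scheme AICc, stopping
when no merge improves it.  An exhaustive search over all set-partitions
(feasible up to six charsets) serves as the reference optimum.

Scheme bookkeeping: branch lengths of the shared guide tree are counted
once (2T-3 parameters); each subset contributes 9 substitution-model
parameters; the subset rate multipliers satisfy a mean-rate-one
constraint across the locus, so S subsets contribute S-1 free
multipliers.  The AICc sample size is the number of sites of the locus.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import dendropy

from .alignments import LocusAlignment
from .likelihood import FitOptions, PruningTree, SubsetFit, encode_alignment, fit_subset_model
from .partition import CharSet

logger = logging.getLogger(__name__)


def aicc(lnL: float, K: int, n: int, aic_fallback: bool = False) -> float:
    """Small-sample corrected AIC: 2K - 2 lnL + 2K(K+1)/(n - K - 1).

    When ``n <= K + 1`` the correction term is undefined; by default this
    is an error, with ``aic_fallback`` the plain AIC is returned with a
    warning.
    """
    if n - K - 1 <= 0:
        if not aic_fallback:
            raise ValueError(f"AICc undefined: n={n} <= K+1={K + 1}")
        logger.warning("AICc undefined for n=%d, K=%d; falling back to AIC", n, K)
        return 2 * K - 2 * lnL
    return 2 * K - 2 * lnL + 2 * K * (K + 1) / (n - K - 1)


@dataclass
class PartitionScheme:
    """A set-partition of a locus's charsets with its AICc score."""

    subsets: list[SubsetFit]
    total_lnL: float
    total_K: int
    aicc: float
    n_sites: int

    @property
    def n_subsets(self) -> int:
        return len(self.subsets)

    def subset_names(self) -> list[tuple[str, ...]]:
        return [tuple(s.member_charsets) for s in self.subsets]


@dataclass
class SchemeSearchContext:
    """Shared state for one locus: encoded data, guide tree, fit cache."""

    aln: LocusAlignment
    charsets: list[CharSet]
    tree: dendropy.Tree
    opts: FitOptions = field(default_factory=FitOptions)
    aic_fallback: bool = False

    def __post_init__(self) -> None:
        self._data = encode_alignment(self.aln)
        self._ptree = PruningTree(self.tree, self.aln.taxa)
        self._by_name = {cs.name: cs for cs in self.charsets}
        self._cache: dict[frozenset[str], SubsetFit] = {}

    @property
    def n_taxa(self) -> int:
        return self.aln.n_taxa

    @property
    def n_sites(self) -> int:
        return self.aln.length

    def fit(self, members: frozenset[str]) -> SubsetFit:
        if members not in self._cache:
            sites = sorted(
                i for name in members for cs in [self._by_name[name]] for i in cs.sites
            )
            fit = fit_subset_model(
                self._data[:, sites],
                self._ptree,
                self.opts,
                member_charsets=sorted(members),
            )
            self._cache[members] = fit
        return self._cache[members]

    def score(self, grouping: Sequence[frozenset[str]]) -> PartitionScheme:
        """Fit (with caching) and AICc-score one set-partition of charsets."""
        fits = [self.fit(g) for g in sorted(grouping, key=lambda g: sorted(g))]
        total_lnL = sum(f.lnL for f in fits)
        S = len(fits)
        total_K = (2 * self.n_taxa - 3) + sum(f.k for f in fits) + (S - 1)
        value = aicc(total_lnL, total_K, self.n_sites, self.aic_fallback)
        return PartitionScheme(fits, total_lnL, total_K, value, self.n_sites)


def greedy_scheme_search(
    charsets: Sequence[CharSet],
    aln: LocusAlignment,
    tree: dendropy.Tree,
    opts: FitOptions | None = None,
    context: SchemeSearchContext | None = None,
) -> PartitionScheme:
    """Greedy AICc scheme search in the style of PartitionFinder.

    Starts from the fully split scheme and accepts, per round, the subset
    merge that most decreases the scheme AICc; ties break on the
    lexicographically first merged-name pair.  Fit failures skip the
    offending merge with a warning.
    """
    if not charsets:
        raise ValueError("need at least one charset")
    ctx = context or SchemeSearchContext(aln, list(charsets), tree, opts or FitOptions())
    groups = [frozenset([cs.name]) for cs in charsets]
    best = ctx.score(groups)
    while len(groups) > 1:
        candidates = []
        for a, b in itertools.combinations(sorted(groups, key=sorted), 2):
            merged = [g for g in groups if g not in (a, b)] + [a | b]
            try:
                scheme = ctx.score(merged)
            except Exception as exc:  # propagate-as-skip per contract
                logger.warning("merge %s+%s failed: %s", sorted(a), sorted(b), exc)
                continue
            candidates.append((scheme.aicc, sorted(a | b), merged, scheme))
        if not candidates:
            break
        candidates.sort(key=lambda c: (c[0], c[1]))
        top_aicc, _, top_groups, top_scheme = candidates[0]
        if top_aicc < best.aicc:
            groups, best = top_groups, top_scheme
        else:
            break
    return best


def _set_partitions(items: list[str]) -> Iterator[list[frozenset[str]]]:
    """All set-partitions of ``items`` (Bell(n) of them)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for partial in _set_partitions(rest):
        for i in range(len(partial)):
            yield partial[:i] + [partial[i] | {first}] + partial[i + 1 :]
        yield partial + [frozenset([first])]


def exhaustive_scheme_search(
    charsets: Sequence[CharSet],
    aln: LocusAlignment,
    tree: dendropy.Tree,
    opts: FitOptions | None = None,
    context: SchemeSearchContext | None = None,
) -> PartitionScheme:
    """Score every set-partition of the charsets and return the AICc
    optimum (reference oracle; limited to six charsets, Bell(6) = 203)."""
    if not charsets:
        raise ValueError("need at least one charset")
    if len(charsets) > 6:
        raise ValueError("exhaustive search limited to <= 6 charsets")
    ctx = context or SchemeSearchContext(aln, list(charsets), tree, opts or FitOptions())
    best: PartitionScheme | None = None
    for grouping in _set_partitions([cs.name for cs in charsets]):
        scheme = ctx.score(grouping)
        if best is None or scheme.aicc < best.aicc:
            best = scheme
    return best


def write_scheme_report(
    schemes: dict[str, PartitionScheme], out_path: str | Path
) -> None:
    """Per-locus best-scheme table as TSV."""
    out = Path(out_path)
    out.parent.mkdir(parents=True, exist_ok=True)
    with open(out, "w") as fh:
        fh.write("locus_id\tn_subsets\tsubsets\tlnL\tK\taicc\n")
        for locus_id in sorted(schemes):
            s = schemes[locus_id]
            members = ";".join("+".join(m) for m in s.subset_names())
            fh.write(
                f"{locus_id}\t{s.n_subsets}\t{members}\t"
                f"{s.total_lnL:.6g}\t{s.total_K}\t{s.aicc:.6g}\n"
            )
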