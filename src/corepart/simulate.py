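"""Synthetic UCE data generators.

Emulates the study conditions the pipeline is built for: ~33-taxon loci
of 231-802 sites whose per-site rate is lowest in a central 160 bp core
and rises outward through the flanks, museum-age-dependent locus dropout
and flank truncation, posterior tree samples with controllable
between-run disagreement, and multi-study capture-decay tables.  Every
generator is a pure function of (configuration, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
from scipy.special import expit

from .alignments import LocusAlignment
from .capture import SpecimenRecord
from .likelihood import GTRGammaModel, discrete_gamma_rates
from .partition import CoreSpec, build_charsets
from .treedist import UnrootedTree, spr_neighbors
from .treeqc import TreeSample

#: Default outward-rising rate profile: the conserved core evolves at a
#: fifth of the average rate, the outermost flank half again faster.
DEFAULT_RATE_PROFILE = {
    "core": 0.2, "flank1": 0.46, "flank2": 0.72,
    "flank3": 0.98, "flank4": 1.24, "flank5": 1.5,
}


@dataclass
class MuseumModel:
    """Logit-linear retention of loci with specimen age: a locus survives
    in a specimen with probability expit(intercept + slope*age); surviving
    museum sequences lose a flank fraction growing with age."""

    dropout_intercept: float = 4.0
    dropout_slope: float = -0.06
    truncation_rate: float = 0.004


@dataclass
class CaptureStudyModel:
    intercept: float
    slope: float
    noise_sd: float
    max_loci: int = 600


@dataclass
class SimConfig:
    seed: int = 0
    n_taxa: int = 33
    n_loci: int = 100
    locus_length_range: tuple[int, int] = (231, 802)
    core_length: int = 160
    n_flank_bins: int = 5
    flank_rate_profile: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_RATE_PROFILE)
    )
    model: GTRGammaModel = field(default_factory=GTRGammaModel)
    tree_height: float = 0.15
    museum_model: MuseumModel = field(default_factory=MuseumModel)
    posterior_perturbation: float = 0.1

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.flank_rate_profile.values()):
            raise ValueError("rate profile must be non-negative")


@dataclass
class SimTruth:
    """Ground truth emitted alongside each simulated dataset."""

    tree_newick: str
    charset_rates: dict[str, float]
    locus_length: int
    branch_scale: float
    alpha: float


def simulate_tree(
    n_taxa: int,
    seed: int,
    tree_height: float = 0.15,
    model: str = "yule",
) -> dendropy.Tree:
    """Random Yule (pure-birth) topology, ultrametric, scaled so the root
    is ``tree_height`` expected substitutions per site from the tips."""
    if n_taxa < 3:
        raise ValueError("need >= 3 taxa")
    if model != "yule":
        raise ValueError(f"unknown tree model: {model}")
    rng = np.random.default_rng(seed)
    next_id = [0]

    def fresh() -> dict:
        next_id[0] += 1
        return {"children": [], "start": 0.0, "end": None}

    root = fresh()
    active = []
    for _ in range(2):
        child = fresh()
        root["children"].append(child)
        active.append(child)
    t = 0.0
    while len(active) < n_taxa:
        t += rng.exponential(1.0 / len(active))
        idx = rng.integers(len(active))
        node = active.pop(idx)
        node["end"] = t
        for _ in range(2):
            child = fresh()
            child["start"] = t
            node["children"].append(child)
            active.append(child)
    t += rng.exponential(1.0 / len(active))
    for node in active:
        node["end"] = t
    scale = tree_height / t if t > 0 else 1.0
    labels = iter(f"t{i + 1}" for i in range(n_taxa))

    def render(node) -> str:
        length = (node["end"] - node["start"]) * scale
        if not node["children"]:
            return f"{next(labels)}:{length:.10f}"
        inner = ",".join(render(c) for c in node["children"])
        return f"({inner}):{length:.10f}"

    newick = "(" + ",".join(render(c) for c in root["children"]) + ");"
    return dendropy.Tree.get(data=newick, schema="newick")


def _transition(q_eig, length: float) -> np.ndarray:
    left, eigval, right = q_eig
    return left @ np.diag(np.exp(eigval * length)) @ right


def simulate_locus(
    tree: dendropy.Tree,
    cfg: SimConfig,
    branch_scale: float = 1.0,
    seed: int = 0,
    locus_id: str = "locus",
) -> tuple[LocusAlignment, SimTruth]:
    """Evolve one UCE-like locus down the tree under GTR+Gamma.

    The locus length is drawn uniformly from the configured range, the
    columns are split into core/flank charsets, and each site evolves at
    rate (charset multiplier) x (gamma category rate) x ``branch_scale``.
    """
    rng = np.random.default_rng(seed)
    model = cfg.model
    model.validate()
    lo, hi = cfg.locus_length_range
    length = int(rng.integers(lo, hi + 1))
    spec = CoreSpec(cfg.core_length, cfg.n_flank_bins)
    charsets = build_charsets(length, spec)
    site_mult = np.empty(length)
    for cs in charsets:
        if cs.name not in cfg.flank_rate_profile:
            raise ValueError(f"no rate multiplier for charset {cs.name}")
        site_mult[cs.sites] = cfg.flank_rate_profile[cs.name]
    cat_rates = discrete_gamma_rates(model.alpha, model.n_categories)
    site_rate = site_mult * cat_rates[rng.integers(model.n_categories, size=length)]
    site_rate *= branch_scale * model.rate_multiplier

    q = model.q_matrix()
    pi_sqrt = np.sqrt(model.freqs)
    sym = q * pi_sqrt[:, None] / pi_sqrt[None, :]
    eigval, eigvec = np.linalg.eigh((sym + sym.T) / 2)
    q_eig = (eigvec / pi_sqrt[:, None], eigval, (eigvec * pi_sqrt[:, None]).T)

    # distinct per-site rates are few (charsets x categories): group them
    classes, class_idx = np.unique(site_rate, return_inverse=True)
    states: dict[int, np.ndarray] = {}
    root_states = rng.choice(4, size=length, p=model.freqs)
    taxa, rows = [], []
    stack = [(tree.seed_node, root_states)]
    while stack:
        node, state = stack.pop()
        for child in node.child_nodes():
            bl = child.edge.length or 0.0
            child_state = np.empty(length, dtype=int)
            for ci, rate in enumerate(classes):
                pmat = _transition(q_eig, bl * rate)
                np.clip(pmat, 0.0, None, out=pmat)
                pmat /= pmat.sum(axis=1, keepdims=True)
                cum = np.cumsum(pmat, axis=1)
                mask = class_idx == ci
                u = rng.random(int(mask.sum()))
                parent = state[mask]
                child_state[mask] = (u[:, None] > cum[parent]).sum(axis=1)
            if child.is_leaf():
                taxa.append(child.taxon.label if child.taxon else child.label)
                rows.append("".join("ACGT"[s] for s in child_state))
            else:
                stack.append((child, child_state))
    aln = LocusAlignment(locus_id, taxa, rows)
    truth = SimTruth(
        tree_newick=tree.as_string(schema="newick").strip(),
        charset_rates={cs.name: cfg.flank_rate_profile[cs.name] for cs in charsets},
        locus_length=length,
        branch_scale=branch_scale,
        alpha=model.alpha,
    )
    return aln, truth


def degrade_museum_specimens(
    alns: Sequence[LocusAlignment],
    specimen_ages: Mapping[str, tuple[float, str]],
    cfg: SimConfig,
    seed: int = 0,
) -> tuple[list[LocusAlignment], list[SpecimenRecord]]:
    """Museum degradation: per specimen x locus, the sequence is retained
    with probability expit(a + b*age); surviving sequences of aged
    specimens lose a fraction ``min(0.9, truncation_rate*age)`` of their
    columns from each end (flanks decay first).  Returns degraded copies
    of the alignments plus realized per-specimen locus counts."""
    rng = np.random.default_rng(seed)
    mm = cfg.museum_model
    counts = {s: 0 for s in specimen_ages}
    degraded = []
    for aln in alns:
        taxa, rows = [], []
        for taxon, seq in zip(aln.taxa, aln.seqs):
            age, _preservation = specimen_ages.get(taxon, (0.0, "ethanol"))
            keep_p = expit(mm.dropout_intercept + mm.dropout_slope * age)
            if rng.random() > keep_p:
                continue
            if age > 0 and mm.truncation_rate > 0:
                cut = int(min(0.9, mm.truncation_rate * age) / 2 * len(seq))
                if cut:
                    seq = "-" * cut + seq[cut:-cut] + "-" * cut
            taxa.append(taxon)
            rows.append(seq)
            if taxon in counts:
                counts[taxon] += 1
        if taxa:
            degraded.append(LocusAlignment(aln.locus_id, taxa, rows))
    records = [
        SpecimenRecord(taxon, age, preservation, counts[taxon], "simulated")
        for taxon, (age, preservation) in specimen_ages.items()
    ]
    return degraded, records


def simulate_posterior_sample(
    true_tree: dendropy.Tree,
    n_samples: int,
    perturbation: float,
    seed: int = 0,
) -> TreeSample:
    """Pseudo-posterior sample: each tree is the true topology modified by
    Poisson(perturbation) random SPR moves."""
    if perturbation < 0:
        raise ValueError("perturbation must be >= 0")
    rng = np.random.default_rng(seed)
    base = UnrootedTree.from_dendropy(true_tree)
    ns = dendropy.TaxonNamespace()
    trees = []
    for _ in range(n_samples):
        current = base.copy()
        for _ in range(rng.poisson(perturbation)):
            neighbors = spr_neighbors(current)
            current = neighbors[rng.integers(len(neighbors))]
        trees.append(
            dendropy.Tree.get(
                data=current.to_newick(), schema="newick", taxon_namespace=ns
            )
        )
    return TreeSample(trees, burnin_fraction=0.0)


def simulate_capture_table(
    study_models: Mapping[str, CaptureStudyModel],
    n_per_study: int,
    seed: int = 0,
    ages: Sequence[float] | None = None,
    age_range: tuple[float, float] = (0.0, 60.0),
) -> list[SpecimenRecord]:
    """Multi-study capture-decay table: logit capture fraction is linear
    in age with Gaussian noise, mapped back to locus counts through each
    study's maximum."""
    rng = np.random.default_rng(seed)
    records = []
    for study in sorted(study_models):
        sm_ = study_models[study]
        if ages is not None:
            draw = np.resize(np.asarray(ages, dtype=float), n_per_study)
        else:
            draw = rng.uniform(*age_range, size=n_per_study)
        logits = sm_.intercept + sm_.slope * draw + rng.normal(0, sm_.noise_sd, n_per_study)
        fractions = expit(logits)
        for i, (age, frac) in enumerate(zip(draw, fractions)):
            records.append(
                SpecimenRecord(
                    f"{study}_{i + 1}",
                    float(age),
                    "pinned" if age > 1 else "ethanol",
                    int(round(frac * sm_.max_loci)),
                    study,
                )
            )
    return records


def write_truth(truths: Mapping[str, SimTruth], out_path: str | Path) -> None:
    out = Path(out_path)
    out.parent.mkdir(parents=True, exist_ok=True)
    out.write_text(
        json.dumps({k: asdict(v) for k, v in sorted(truths.items())}, indent=1)
    )
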