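"""Per-locus UCE alignment handling.

Reads one FASTA file per locus, removes all-missing columns, counts
parsimony-informative sites, applies taxon-completeness filtering and
writes concatenated supermatrices with partition definitions for the
downstream inference tools.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: Symbols treated as missing data for column cleanup and distance/likelihood
#: computations.  Other IUPAC ambiguity codes are treated as missing states
#: but never trigger column removal.
MISSING = frozenset("-N?")
NUCLEOTIDES = frozenset("ACGT")


class RaggedAlignmentError(ValueError):
    """Rows of one locus alignment differ in length."""


class DuplicateTaxonError(ValueError):
    """A taxon label occurs more than once within one locus."""


@dataclass
class LocusAlignment:
    """One aligned UCE locus: taxa in input order, equal-length sequence rows.

    Sequences are stored upper-cased over the alphabet ``{A,C,G,T,-,N,?}``
    plus IUPAC ambiguity codes (which count as missing data downstream).
    """

    locus_id: str
    taxa: list[str]
    seqs: list[str]

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.seqs):
            raise ValueError(f"{self.locus_id}: {len(self.taxa)} labels for {len(self.seqs)} rows")
        if len(set(self.taxa)) != len(self.taxa):
            raise DuplicateTaxonError(f"duplicate taxon label in locus {self.locus_id}")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) > 1:
            raise RaggedAlignmentError(
                f"locus {self.locus_id}: unequal row lengths {sorted(lengths)}"
            )
        if self.seqs and len(self.seqs[0]) < 1:
            raise ValueError(f"locus {self.locus_id}: zero-length alignment")
        self.seqs = [s.upper() for s in self.seqs]

    @property
    def length(self) -> int:
        return len(self.seqs[0]) if self.seqs else 0

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def to_array(self) -> np.ndarray:
        """Alignment as a (n_taxa, length) array of single characters."""
        return np.frombuffer("".join(self.seqs).encode(), dtype="S1").reshape(
            self.n_taxa, self.length
        ).astype("U1")

    def columns(self, sites: Sequence[int]) -> "LocusAlignment":
        """Sub-alignment restricted to the given 0-based columns (order kept)."""
        arr = self.to_array()[:, list(sites)]
        return LocusAlignment(
            self.locus_id, list(self.taxa), ["".join(row) for row in arr]
        )


@dataclass
class LocusSummary:
    locus_id: str
    length: int
    n_taxa: int
    pis: int
    completeness: float


@dataclass
class MatrixFilterConfig:
    """Completeness filter: keep loci with at least ``ceil(min_completeness*T)``
    of the ``T`` study taxa (the rounding rule is documented, not mandated by
    convention; ``floor`` can be compared by passing an adjusted fraction)."""

    taxon_set: list[str]
    min_completeness: float = 0.70
    min_taxa_for_alignment: int = 3

    def __post_init__(self) -> None:
        if not self.taxon_set:
            raise ValueError("taxon_set must not be empty")
        if not (0 < self.min_completeness <= 1):
            raise ValueError("min_completeness must be in (0, 1]")

    @property
    def min_taxa(self) -> int:
        return math.ceil(self.min_completeness * len(self.taxon_set))


def read_locus_alignments(directory_path: str | Path, pattern: str = "*.fasta") -> list[LocusAlignment]:
    """Read one FASTA file per locus from a directory.

    The locus id is the filename stem; sequences are upper-cased.  Files
    matching ``*.fa``/``*.fna`` are picked up as well.
    """
    directory = Path(directory_path)
    paths = sorted(
        p for p in directory.iterdir()
        if p.suffix.lower() in {".fasta", ".fa", ".fna"}
    ) if directory.is_dir() else []
    if directory.is_dir() and not paths:
        logger.warning("no FASTA files found in %s", directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"not a directory: {directory}")
    alignments = []
    for path in paths:
        taxa, seqs = [], []
        for record in SeqIO.parse(str(path), "fasta"):
            taxa.append(record.id)
            seqs.append(str(record.seq))
        try:
            alignments.append(LocusAlignment(path.stem, taxa, seqs))
        except (RaggedAlignmentError, DuplicateTaxonError) as exc:
            raise type(exc)(f"{exc} (file {path})") from exc
    return alignments


def drop_empty_columns(aln: LocusAlignment) -> LocusAlignment:
    """Remove columns in which every taxon has ``-``, ``N`` or ``?``.

    Column order is otherwise preserved; an alignment that would become
    empty raises, since such a locus carries no data at all.
    """
    arr = aln.to_array()
    missing = np.isin(arr, list(MISSING))
    keep = ~missing.all(axis=0)
    if not keep.any():
        raise ValueError(f"locus {aln.locus_id}: all columns missing after cleanup")
    if keep.all():
        return aln
    kept = arr[:, keep]
    return LocusAlignment(aln.locus_id, list(aln.taxa), ["".join(r) for r in kept])


def count_informative_sites(aln: LocusAlignment) -> int:
    """Parsimony-informative sites: columns where >= 2 distinct unambiguous
    nucleotides each occur in >= 2 taxa.  Gaps, N, ? and IUPAC ambiguity
    codes are not states."""
    arr = aln.to_array()
    count = 0
    for j in range(aln.length):
        col = arr[:, j]
        states, freqs = np.unique(col[np.isin(col, list(NUCLEOTIDES))], return_counts=True)
        if (freqs >= 2).sum() >= 2:
            count += 1
    return count


def filter_by_completeness(
    alns: Iterable[LocusAlignment], cfg: MatrixFilterConfig
) -> list[LocusAlignment]:
    """Keep loci whose taxon count meets the completeness threshold."""
    threshold = cfg.min_taxa
    return [a for a in alns if a.n_taxa >= threshold]


@dataclass
class LociAggregate:
    mean_length: float
    mean_pis: float
    slope: float
    intercept: float
    r_squared: float
    slope_se: float


def summarize_loci(
    alns: Sequence[LocusAlignment], taxon_set: Sequence[str] | None = None
) -> tuple[list[LocusSummary], LociAggregate]:
    """Per-locus length/taxa/PIS summaries plus the PIS-on-length OLS fit.

    The aggregate regression (ordinary least squares with intercept)
    quantifies how strongly locus length predicts the number of
    parsimony-informative sites.
    """
    if not alns:
        raise ValueError("summarize_loci requires at least one locus")
    total = len(taxon_set) if taxon_set else max(a.n_taxa for a in alns)
    summaries = [
        LocusSummary(a.locus_id, a.length, a.n_taxa, count_informative_sites(a), a.n_taxa / total)
        for a in alns
    ]
    x = np.array([s.length for s in summaries], dtype=float)
    y = np.array([s.pis for s in summaries], dtype=float)
    if len(alns) >= 2 and np.ptp(x) > 0:
        slope, intercept = np.polyfit(x, y, 1)
        resid = y - (slope * x + intercept)
        ss_res = float(resid @ resid)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 if ss_tot == 0 else 1 - ss_res / ss_tot
        dof = len(x) - 2
        se = (
            math.sqrt(ss_res / dof / ((x - x.mean()) ** 2).sum()) if dof > 0 else float("nan")
        )
    else:
        slope, intercept, r2, se = 0.0, float(y.mean()), 0.0, float("nan")
    agg = LociAggregate(float(x.mean()), float(y.mean()), float(slope), float(intercept), r2, se)
    return summaries, agg


_SANITIZE = re.compile(r"[^A-Za-z0-9_.]")


def write_concatenated_matrix(
    alns: Sequence[LocusAlignment],
    out_prefix: str | Path,
    fmt: str = "fasta",
) -> dict[str, tuple[int, int]]:
    """Concatenate loci (sorted by locus id) into one supermatrix.

    Taxa absent from a locus are padded with ``?``.  Writes
    ``<prefix>.fasta`` (or ``.phy``), a RAxML-style ``<prefix>.partitions``
    file and a NEXUS sets block ``<prefix>.charsets.nex``, all with 1-based
    inclusive coordinates.  Returns the locus -> (start, end) coordinate map
    (1-based inclusive).
    """
    if not alns:
        raise ValueError("no loci to concatenate")
    ordered = sorted(alns, key=lambda a: a.locus_id)
    taxa = sorted({t for a in ordered for t in a.taxa})
    sanitized = {t: _SANITIZE.sub("_", t) for t in taxa}
    if len(set(sanitized.values())) != len(taxa):
        raise ValueError("taxon label collision after sanitization")

    coords: dict[str, tuple[int, int]] = {}
    rows = {t: [] for t in taxa}
    pos = 0
    for a in ordered:
        seq_by_taxon = dict(zip(a.taxa, a.seqs))
        for t in taxa:
            rows[t].append(seq_by_taxon.get(t, "?" * a.length))
        coords[a.locus_id] = (pos + 1, pos + a.length)
        pos += a.length

    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "fasta":
        with open(f"{prefix}.fasta", "w") as fh:
            for t in taxa:
                fh.write(f">{sanitized[t]}\n{''.join(rows[t])}\n")
    elif fmt == "phylip":
        with open(f"{prefix}.phy", "w") as fh:
            fh.write(f"{len(taxa)} {pos}\n")
            for t in taxa:
                fh.write(f"{sanitized[t]}  {''.join(rows[t])}\n")
    else:
        raise ValueError(f"unknown matrix format: {fmt}")

    with open(f"{prefix}.partitions", "w") as fh:
        for locus, (start, end) in coords.items():
            fh.write(f"DNA, {locus} = {start}-{end}\n")
    with open(f"{prefix}.charsets.nex", "w") as fh:
        fh.write("#NEXUS\nbegin sets;\n")
        for locus, (start, end) in coords.items():
            fh.write(f"    charset {locus} = {start}-{end};\n")
        fh.write("end;\n")
    return coords


def read_concatenated_matrix(
    fasta_path: str | Path, coords: dict[str, tuple[int, int]]
) -> list[LocusAlignment]:
    """Split a concatenated FASTA matrix back into per-locus alignments
    using 1-based inclusive charset coordinates (round-trip helper)."""
    taxa, seqs = [], []
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        taxa.append(record.id)
        seqs.append(str(record.seq).upper())
    loci = []
    for locus_id in sorted(coords):
        start, end = coords[locus_id]
        block_t, block_s = [], []
        for t, s in zip(taxa, seqs):
            segment = s[start - 1 : end]
            if set(segment) <= {"?"}:
                continue  # padding row: taxon absent from this locus
            block_t.append(t)
            block_s.append(segment)
        loci.append(LocusAlignment(locus_id, block_t, block_s))
    return loci
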