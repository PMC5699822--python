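"""Core/flank character-set construction for UCE loci.

A captured UCE locus has a conserved central core (the bait region,
160 bp by default) and increasingly variable flanks.  Each flank is cut
into five contiguous bins; bin *k* of the left flank is pooled with bin
*k* of the right flank into character set ``flank_k`` (k = 1 adjacent to
the core, increasing outward), giving up to six character sets per locus
for downstream model selection.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .alignments import LocusAlignment


@dataclass(frozen=True)
class CoreSpec:
    core_length: int = 160
    n_flank_bins: int = 5

    def __post_init__(self) -> None:
        if self.core_length < 1 or self.n_flank_bins < 1:
            raise ValueError("core_length and n_flank_bins must be >= 1")


@dataclass
class CharSet:
    """Named set of alignment columns, stored as 0-based half-open ranges."""

    name: str
    ranges: list[tuple[int, int]]

    @property
    def sites(self) -> list[int]:
        return [i for start, stop in self.ranges for i in range(start, stop)]

    @property
    def n_sites(self) -> int:
        return sum(stop - start for start, stop in self.ranges)


def locate_core(length: int, spec: CoreSpec = CoreSpec()) -> tuple[int, int, bool]:
    """Centre the core window on the locus.

    Returns ``(start, stop, core_only)`` with a 0-based half-open interval.
    The left offset is ``floor((L - core) / 2)`` so that when ``L - core``
    is odd the extra column falls to the right flank.  Loci shorter than
    the core cannot be split and are flagged ``core_only``.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if length < spec.core_length:
        return 0, length, True
    start = (length - spec.core_length) // 2
    return start, start + spec.core_length, False


def _flank_bin_widths(flank_len: int, n_bins: int) -> list[int]:
    """Widths inner (core-adjacent) -> outer.  The remainder r = F mod n is
    given one extra site to each of the r outermost bins, keeping the bins
    nearest the core homogeneous in rate."""
    q, r = divmod(flank_len, n_bins)
    return [q + (1 if k > n_bins - r else 0) for k in range(1, n_bins + 1)]


def build_charsets(aln_or_length: LocusAlignment | int, spec: CoreSpec = CoreSpec()) -> list[CharSet]:
    """Build the core charset plus mirrored flank bins for one locus.

    Empty charsets are dropped; a locus shorter than the core yields the
    single ``core`` charset.  The returned charsets are disjoint and cover
    every column of the locus.
    """
    length = aln_or_length.length if isinstance(aln_or_length, LocusAlignment) else aln_or_length
    start, stop, core_only = locate_core(length, spec)
    charsets = [CharSet("core", [(start, stop)])]
    if core_only:
        return charsets
    left_widths = _flank_bin_widths(start, spec.n_flank_bins)
    right_widths = _flank_bin_widths(length - stop, spec.n_flank_bins)
    # left flank: bins run outward towards column 0; right flank: outward
    # towards the last column.
    left_edge, right_edge = start, stop
    for k in range(1, spec.n_flank_bins + 1):
        ranges = []
        lw, rw = left_widths[k - 1], right_widths[k - 1]
        if lw:
            ranges.append((left_edge - lw, left_edge))
            left_edge -= lw
        if rw:
            ranges.append((right_edge, right_edge + rw))
            right_edge += rw
        if ranges:
            charsets.append(CharSet(f"flank{k}", sorted(ranges)))
    return charsets


def write_charset_definitions(
    schemes: dict[str, Sequence[CharSet]], out_path: str | Path, style: str = "nexus"
) -> None:
    """Write per-locus charsets as a NEXUS sets block or a
    PartitionFinder-style block, 1-based inclusive coordinates.

    Charsets of one locus must be disjoint; multi-range charsets are
    written as space-separated ranges in the deterministic order
    core, flank1 ... flankN.
    """
    lines = []
    for locus_id in sorted(schemes):
        charsets = list(schemes[locus_id])
        seen: set[int] = set()
        for cs in charsets:
            sites = set(cs.sites)
            if seen & sites:
                raise ValueError(f"overlapping charsets in locus {locus_id}")
            seen |= sites
        for cs in charsets:
            spans = " ".join(f"{a + 1}-{b}" for a, b in cs.ranges)
            if style == "nexus":
                lines.append(f"    charset {locus_id}_{cs.name} = {spans};")
            else:
                lines.append(f"{locus_id}_{cs.name} = {spans};")
    out = Path(out_path)
    out.parent.mkdir(parents=True, exist_ok=True)
    with open(out, "w") as fh:
        if style == "nexus":
            fh.write("#NEXUS\nbegin sets;\n")
            fh.write("\n".join(lines) + "\n")
            fh.write("end;\n")
        else:
            fh.write("## ALIGNMENT ##\n[data_blocks]\n")
            fh.write("\n".join(lines) + "\n")


def parse_charset_definitions(path: str | Path) -> dict[str, list[CharSet]]:
    """Inverse of :func:`write_charset_definitions` (NEXUS style)."""
    schemes: dict[str, list[CharSet]] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line.lower().startswith("charset"):
            continue
        name_part, _, spans_part = line[len("charset"):].strip().partition("=")
        full_name = name_part.strip()
        locus_id, _, cs_name = full_name.rpartition("_")
        ranges = []
        for span in spans_part.strip().rstrip(";").split():
            a, _, b = span.partition("-")
            ranges.append((int(a) - 1, int(b)))
        schemes.setdefault(locus_id, []).append(CharSet(cs_name, ranges))
    return schemes
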