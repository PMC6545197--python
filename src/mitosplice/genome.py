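"""Circular-genome model, annotation containers and genome-level analyses.

Hexacoral mitochondrial genomes are small covalently closed circles on which
every conventional gene sits on the same strand.  All coordinates in this
package are 0-based, half-open and modular: a feature with ``end <= start``
wraps through the origin.  GFF3 conversion to 1-based inclusive coordinates
happens only in :mod:`mitosplice.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "CircularGenome",
    "Feature",
    "OrfHit",
    "CoordinateError",
    "InputError",
    "revcomp",
    "compute_igrs",
    "find_antisense_orfs",
    "gtg_start_fraction",
    "find_direct_repeats",
    "STOP_CODONS",
]

VALID_BASES = frozenset("ACGTN")
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

FEATURE_TYPES = frozenset(
    {"CDS", "rRNA", "tRNA", "exon", "intron", "ORF", "aORF", "IGR", "repeat"}
)


class CoordinateError(ValueError):
    """A position falls outside ``[0, genome length)``."""


class InputError(ValueError):
    """Invalid input to an analysis operation."""


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class CircularGenome:
    """A circular nucleotide sequence with modular coordinate arithmetic.

    Parameters
    ----------
    name:
        Identifier used as the GFF3/FASTA sequence id.
    sequence:
        Upper-case nucleotide string over ``{A, C, G, T, N}``.
    """

    name: str
    sequence: str
    topology: str = "circular"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise InputError("genome sequence must be non-empty")
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise InputError(
                f"genome contains invalid characters {sorted(bad)}; "
                "only A, C, G, T, N are accepted"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def _check(self, *positions: int) -> None:
        for p in positions:
            if not 0 <= p < self.length:
                raise CoordinateError(
                    f"position {p} out of range for genome of length {self.length}"
                )

    def base(self, pos: int) -> str:
        """Nucleotide at ``pos`` (modular)."""
        return self.sequence[pos % self.length]

    def subsequence(self, start: int, end: int) -> str:
        """Downstream walk from ``start`` to ``end``.

        If ``end <= start`` the walk wraps through the origin; in particular
        ``start == end`` returns the full genome rotation starting at
        ``start``.
        """
        self._check(start, end)
        if end > start:
            return self.sequence[start:end]
        return self.sequence[start:] + self.sequence[:end]

    def circular_distance(self, a: int, b: int) -> int:
        """Number of nucleotides walked downstream from ``a`` to ``b``."""
        self._check(a, b)
        return (b - a) % self.length


@dataclass(frozen=True)
class Feature:
    """An annotated span on a circular genome.

    ``end <= start`` means the feature wraps through the origin.  Strand "-"
    is permitted only for aORF-type features: every conventional mitochondrial
    gene in these genomes is encoded on the forward strand.
    """

    id: str
    ftype: str
    start: int
    end: int
    strand: str = "+"
    attributes: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise InputError(f"feature {self.id}: strand must be '+' or '-'")
        if self.strand == "-" and self.ftype != "aORF":
            raise InputError(
                f"feature {self.id}: strand '-' is only permitted for aORF features"
            )

    @property
    def wraps(self) -> bool:
        return self.end <= self.start

    def length(self, genome_length: int) -> int:
        n = (self.end - self.start) % genome_length
        if n == 0:
            raise InputError(f"feature {self.id} has zero length")
        return n

    def positions(self, genome_length: int) -> range:
        """Absolute (unwrapped) positions; take mod genome_length to index."""
        return range(self.start, self.start + self.length(genome_length))


@dataclass(frozen=True)
class OrfHit:
    """An open reading frame found on either strand of a region."""

    start: int
    end: int
    strand: str
    start_codon: str
    aa_length: int


def compute_igrs(
    genome: CircularGenome,
    features: Sequence[Feature],
    exclude_types: Iterable[str] = ("aORF",),
    label_prefix: str = "IGR",
) -> list[Feature]:
    """Intergenic regions: maximal circular gaps between annotated spans.

    Features of the types in ``exclude_types`` (by default the antisense ORF,
    which overlaps intergenic space on the opposite strand) are ignored.  The
    remaining spans must be non-overlapping.  Gaps of length zero are omitted
    and labels run ``IGR-1..IGR-n`` starting from the gap that follows the
    feature with the smallest start coordinate.
    """
    excluded = set(exclude_types)
    spans = [f for f in features if f.ftype not in excluded]
    if not spans:
        raise InputError("compute_igrs requires at least one feature")
    L = genome.length
    occupied = bytearray(L)
    for f in spans:
        for p in f.positions(L):
            p %= L
            if occupied[p]:
                raise InputError(
                    f"features overlap at position {p} (feature {f.id}); "
                    "pass a non-overlapping gene-level selection"
                )
            occupied[p] = 1
    spans = sorted(spans, key=lambda f: f.start)
    igrs: list[Feature] = []
    n = 0
    for i, f in enumerate(spans):
        nxt = spans[(i + 1) % len(spans)]
        gap_start = (f.start + f.length(L)) % L
        gap_len = (nxt.start - gap_start) % L
        if len(spans) == 1:
            gap_len = (f.start - gap_start) % L
        if gap_len == 0:
            continue
        n += 1
        igrs.append(
            Feature(
                id=f"{label_prefix}-{n}",
                ftype="IGR",
                start=gap_start,
                end=(gap_start + gap_len) % L,
                strand="+",
                attributes={"after": f.id},
            )
        )
    return igrs


def _orf_scan(rc: str, starts: frozenset[str], min_aa: int) -> list[tuple[int, int, str, int]]:
    """Scan one strand (given 5'->3') for start->stop ORFs in all 3 frames.

    Returns (offset, end_offset, start_codon, aa_length) tuples where offsets
    index into ``rc``.  Per in-frame stop codon, the longest ORF (earliest
    qualifying start after the previous stop) is reported.
    """
    hits = []
    n = len(rc)
    for frame in range(3):
        start_idx: int | None = None
        codon_start: str | None = None
        for i in range(frame, n - 2, 3):
            codon = rc[i : i + 3]
            if codon in STOP_CODONS:
                if start_idx is not None:
                    aa = (i - start_idx) // 3
                    if aa >= min_aa:
                        hits.append((start_idx, i + 3, codon_start, aa))
                start_idx = None
                codon_start = None
            elif start_idx is None and codon in starts:
                start_idx = i
                codon_start = codon
    return hits


def find_antisense_orfs(
    genome: CircularGenome,
    region: Feature,
    starts: Iterable[str] = ("ATG", "GTG"),
    min_aa: int = 1,
) -> list[OrfHit]:
    """ORFs on the reverse complement of ``region``, all three frames.

    Hits require a start codon from ``starts`` and at least ``min_aa`` codons
    before an in-frame stop; coordinates are reported on the genome's forward
    coordinate system with strand "-".  Sorted by amino-acid length,
    descending.
    """
    starts = frozenset(starts)
    if not starts <= {"ATG", "GTG"}:
        raise InputError("start codons must be a subset of {ATG, GTG}")
    if min_aa < 1:
        raise InputError("min_aa must be >= 1")
    L = genome.length
    region_len = region.length(L)
    if region_len < 3 * (min_aa + 1):  # smallest hit: start + (min_aa-1) codons + stop
        return []
    seq = genome.subsequence(region.start, region.end)
    rc = revcomp(seq)
    out = []
    for off, end_off, codon, aa in _orf_scan(rc, starts, min_aa):
        # rc index i corresponds to forward position region.start + region_len-1-i
        fwd_start = (region.start + region_len - end_off) % L
        fwd_end = (region.start + region_len - off) % L
        out.append(
            OrfHit(start=fwd_start, end=fwd_end, strand="-", start_codon=codon, aa_length=aa)
        )
    out.sort(key=lambda h: (-h.aa_length, h.start))
    return out


def first_codon(genome: CircularGenome, feature: Feature) -> str:
    """Strand-aware initiation codon of a coding feature."""
    L = genome.length
    if feature.length(L) < 3:
        raise InputError(f"feature {feature.id} shorter than one codon")
    if feature.strand == "+":
        return genome.subsequence(feature.start, (feature.start + 3) % L)
    return revcomp(genome.subsequence((feature.end - 3) % L, feature.end))


def gtg_start_fraction(genome: CircularGenome, cds: Sequence[Feature]) -> float:
    """Fraction of coding features whose initiation codon is GTG.

    Corallimorpharian mtDNA uses GTG initiation in a substantial minority of
    reading frames (tRNA-fMet reads both ATG and GTG).
    """
    if not cds:
        raise InputError("gtg_start_fraction requires at least one CDS")
    n_gtg = sum(1 for f in cds if first_codon(genome, f) == "GTG")
    return n_gtg / len(cds)


def find_direct_repeats(seq: str, min_len: int = 8) -> list[tuple[int, int, int]]:
    """Maximal exact repeated substring pairs of length >= ``min_len``.

    A pair (pos1, pos2, length), pos1 < pos2, is *maximal* when the match can
    be extended neither left nor right.  Pairs are sorted by length
    descending, then position, and greedily filtered so that reported pairs
    do not overlap previously reported ones.
    """
    if min_len < 8:
        raise InputError("min_len must be >= 8")
    n = len(seq)
    if n < 2 * min_len - (min_len - 1):  # n < min_len + 1: cannot repeat
        return []
    # seed-and-extend on exact min_len-mers
    seeds: dict[str, list[int]] = {}
    for i in range(n - min_len + 1):
        seeds.setdefault(seq[i : i + min_len], []).append(i)
    maximal: set[tuple[int, int, int]] = set()
    for positions in seeds.values():
        if len(positions) < 2:
            continue
        for ai in range(len(positions)):
            for bi in range(ai + 1, len(positions)):
                i, j = positions[ai], positions[bi]
                # extend left
                while i > 0 and seq[i - 1] == seq[j - 1]:
                    i -= 1
                    j -= 1
                # extend right
                length = min_len + (positions[ai] - i)
                while j + length < n and seq[i + length] == seq[j + length]:
                    length += 1
                if length >= min_len:
                    maximal.add((i, j, length))
    ordered = sorted(maximal, key=lambda t: (-t[2], t[0], t[1]))
    chosen: list[tuple[int, int, int]] = []
    occupied: set[int] = set()
    for i, j, length in ordered:
        span = set(range(i, i + length)) | set(range(j, j + length))
        if span & occupied:
            continue
        chosen.append((i, j, length))
        occupied |= span
    return chosen
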