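"""Junction-library construction and read classification.

Replaces manual counting of junction-spanning reads: every diagnostic
junction contributes a 2k-nt context (k nt either side), and a read is
assigned to a junction when its best ungapped alignment (either orientation,
every offset) crosses the junction midpoint with at least ``min_overlap`` nt
on both sides at a mismatch rate no higher than ``max_mismatch_rate``.  Ties
across different junctions are reported AMBIGUOUS, never broken arbitrarily.

Alignment is ungapped and substitution-only.  Batch classification uses an
exact-seed prefilter: any read with a valid candidate alignment is guaranteed
to share an exact w-mer with some context (w chosen from the worst-case
error spacing), so reads without shared w-mers are UNASSIGNED without
scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .genome import CircularGenome, Feature, InputError, revcomp
from .splice import IntronModel, Junction, JunctionCategory

__all__ = [
    "JunctionLibrary",
    "ReadAssignment",
    "ClassificationCounts",
    "build_junction_library",
    "classify_read",
    "classify_reads",
    "FeatureAssigner",
    "assign_read_to_features",
    "count_by_category",
    "detect_backsplice_support",
    "BacksplicEvidence",
]

ASSIGNED = "ASSIGNED"
UNASSIGNED = "UNASSIGNED"
AMBIGUOUS = "AMBIGUOUS"

_CODE = np.full(256, 9, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
_RC_CODE = np.full(256, 9, dtype=np.uint8)
for _i, _b in enumerate(b"TGCA"):
    _RC_CODE[_b] = _i


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _encode_rc(seq: str) -> np.ndarray:
    return _RC_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)][::-1]


@dataclass(frozen=True)
class LibraryEntry:
    junction_id: str
    context: str
    k: int
    categories: tuple[tuple[str, str, int | None], ...]  # (category, intron_id, donor)


@dataclass(frozen=True)
class JunctionLibrary:
    entries: tuple[LibraryEntry, ...]
    k: int

    def __len__(self) -> int:
        return len(self.entries)


def junction_id(j: Junction) -> str:
    jid = f"{j.intron_id}|{j.category}"
    if j.donor_offset is not None:
        jid += f"@{j.donor_offset}"
    return jid


def build_junction_library(junctions: Sequence[Junction], k: int) -> JunctionLibrary:
    """Index junction contexts; duplicate contexts collapse into one entry.

    A collapsed entry carries every source category and will classify reads
    as AMBIGUOUS (the context cannot discriminate its sources).
    """
    by_context: dict[str, list[Junction]] = {}
    order: list[str] = []
    for j in junctions:
        if len(j.left_flank) != k or len(j.right_flank) != k:
            raise InputError(
                f"junction {junction_id(j)} flanks are not length k={k}"
            )
        ctx = j.context
        if ctx not in by_context:
            order.append(ctx)
        by_context.setdefault(ctx, []).append(j)
    entries = []
    for ctx in order:
        group = by_context[ctx]
        jid = "+".join(junction_id(j) for j in group)
        cats = tuple((j.category, j.intron_id, j.donor_offset) for j in group)
        entries.append(LibraryEntry(junction_id=jid, context=ctx, k=k, categories=cats))
    return JunctionLibrary(entries=tuple(entries), k=k)


@dataclass(frozen=True)
class ReadAssignment:
    read_id: str
    outcome: str
    junction_id: str | None = None
    feature_id: str | None = None
    categories: tuple[tuple[str, str, int | None], ...] = ()
    mismatches: int | None = None
    left_overlap: int | None = None
    right_overlap: int | None = None
    strand: str | None = None


def _context_matrix(lib: JunctionLibrary) -> np.ndarray:
    return np.stack([_encode(e.context) for e in lib.entries])


def _score_orientation(
    read_codes: np.ndarray, ctx_mat: np.ndarray, k: int, m: int, rate: float
) -> list[tuple[int, tuple[int, int, int, int]]]:
    """Best valid ungapped placement per context for one oriented read.

    Returns (entry index, (mismatches, span, left_overlap, right_overlap))
    for every context with a valid candidate.  Offsets o place read index 0
    at context position o; validity requires >= m aligned nt on both sides
    of the context midpoint k at a mismatch rate <= ``rate``.
    """
    r = read_codes.size
    two_k = ctx_mat.shape[1]
    o_min, o_max = k + m - r, k - m
    if o_min > o_max:
        return []
    # pad the read with sentinel 9 so every offset is a full 2k window
    padded = np.full(r + 2 * two_k, 9, dtype=np.uint8)
    padded[two_k : two_k + r] = read_codes
    # window for offset o starts at padded index two_k - o
    starts = np.arange(two_k - o_max, two_k - o_min + 1)
    windows = np.lib.stride_tricks.sliding_window_view(padded, two_k)[starts]
    mm_total = (windows[None, :, :] != ctx_mat[:, None, :]).sum(axis=2)
    offsets = two_k - starts
    a = np.maximum(0, offsets)
    b = np.minimum(two_k, offsets + r)
    span = b - a
    mm = mm_total - (two_k - span)  # sentinel positions always mismatch
    valid = mm <= rate * span
    out = []
    for e_i in np.nonzero(valid.any(axis=1))[0]:
        mm_e = mm[e_i]
        v = valid[e_i]
        mm_masked = np.where(v, mm_e, np.iinfo(np.int64).max)
        order = np.lexsort((-span, mm_masked))
        i = order[0]
        o = int(offsets[i])
        left = k - max(0, o)
        right = min(two_k, o + r) - k
        out.append((int(e_i), (int(mm_e[i]), int(span[i]), left, right)))
    return out


def classify_read(
    seq: str,
    lib: JunctionLibrary,
    min_overlap: int = 10,
    max_mismatch_rate: float = 0.04,
    read_id: str = "",
    _ctx_mat: np.ndarray | None = None,
) -> ReadAssignment:
    """Classify one read against the junction library (both orientations)."""
    m = min_overlap
    if m < 6:
        raise InputError("min_overlap must be >= 6")
    if not 0 <= max_mismatch_rate < 0.2:
        raise InputError("max_mismatch_rate must be in [0, 0.2)")
    if len(seq) < 2 * m or not lib.entries:
        return ReadAssignment(read_id=read_id, outcome=UNASSIGNED)
    ctx_mat = _context_matrix(lib) if _ctx_mat is None else _ctx_mat
    best_key: tuple[int, int] | None = None
    best_hits: list[tuple[LibraryEntry, str, tuple[int, int, int, int]]] = []
    for strand, codes in (("+", _encode(seq)), ("-", _encode_rc(seq))):
        for e_i, hit in _score_orientation(codes, ctx_mat, lib.k, m, max_mismatch_rate):
            key = (hit[0], -hit[1])
            if best_key is None or key < best_key:
                best_key = key
                best_hits = [(lib.entries[e_i], strand, hit)]
            elif key == best_key:
                best_hits.append((lib.entries[e_i], strand, hit))
    if best_key is None:
        return ReadAssignment(read_id=read_id, outcome=UNASSIGNED)
    entries = {e.junction_id for e, _, _ in best_hits}
    entry, strand, (mm, span, left, right) = best_hits[0]
    if len(entries) > 1 or len(entry.categories) > 1:
        cats = tuple(c for e, _, _ in best_hits for c in e.categories)
        return ReadAssignment(read_id=read_id, outcome=AMBIGUOUS, categories=cats,
                              mismatches=mm, left_overlap=left, right_overlap=right)
    return ReadAssignment(
        read_id=read_id, outcome=ASSIGNED, junction_id=entry.junction_id,
        categories=entry.categories, mismatches=mm,
        left_overlap=left, right_overlap=right, strand=strand,
    )


def _seed_length(k: int, m: int, rate: float) -> int:
    """Longest w such that every valid candidate alignment contains an exact
    w-mer shared with the context (worst-case spacing of allowed mismatches)."""
    best = 2 * k
    for s in range(2 * m, 2 * k + 1):
        e = int(rate * s)
        run = -(-(s - e) // (e + 1))  # ceil
        best = min(best, run)
    return max(best, 6)


def _kmer_hashes(codes: np.ndarray, w: int) -> np.ndarray:
    """Base-5 positional hashes of all w-mers (windows containing non-ACGT
    never collide with pure-ACGT seeds because the encoding is injective)."""
    n = codes.size - w + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    h = np.zeros(n, dtype=np.int64)
    for j in range(w):
        h = h * 5 + codes[j : j + n]
    return h


def classify_reads(
    reads: Iterable[tuple[str, str]],
    lib: JunctionLibrary,
    min_overlap: int = 10,
    max_mismatch_rate: float = 0.04,
) -> list[ReadAssignment]:
    """Classify many reads; exact-seed prefilter, then full scoring.

    Equivalent to calling :func:`classify_read` on every read (property
    tested), but reads sharing no exact seed word with any context are
    dismissed without alignment.
    """
    reads = list(reads)
    m = min_overlap
    if not lib.entries:
        return [ReadAssignment(read_id=rid, outcome=UNASSIGNED) for rid, _ in reads]
    w = _seed_length(lib.k, m, max_mismatch_rate)
    seed_set: set[int] = set()
    for entry in lib.entries:
        for s in (entry.context, revcomp(entry.context)):
            seed_set.update(_kmer_hashes(_encode(s), w).tolist())
    seeds = np.fromiter(seed_set, dtype=np.int64)
    seeds.sort()

    # one padded code matrix for the whole batch; pad windows hash to junk
    # values that at worst create false-positive candidates (then scored)
    n = len(reads)
    if n == 0:
        return []
    maxlen = max(len(seq) for _, seq in reads)
    mat = np.full((n, max(maxlen, w)), 9, dtype=np.uint8)
    for i, (_, seq) in enumerate(reads):
        mat[i, : len(seq)] = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    n_win = mat.shape[1] - w + 1
    h = mat[:, :n_win].astype(np.int64)
    for j in range(1, w):
        h *= 5
        h += mat[:, j : j + n_win]
    pos = np.searchsorted(seeds, h)
    np.clip(pos, 0, seeds.size - 1, out=pos)
    is_candidate = (seeds[pos] == h).any(axis=1)

    ctx_mat = _context_matrix(lib)
    out: list[ReadAssignment] = []
    for i, (rid, seq) in enumerate(reads):
        if is_candidate[i] or (len(seq) < w and len(seq) >= 2 * m):
            out.append(classify_read(seq, lib, m, max_mismatch_rate, read_id=rid,
                                     _ctx_mat=ctx_mat))
        else:
            out.append(ReadAssignment(read_id=rid, outcome=UNASSIGNED))
    return out


class FeatureAssigner:
    """Place reads on the circular genome and assign them to features.

    Ungapped, wrap-aware, both strands; a read is assigned to the feature
    covering the majority of its placement.  Used for abundance tables only.
    """

    def __init__(
        self,
        genome: CircularGenome,
        features: Sequence[Feature],
        min_match: int = 20,
        max_mismatch_rate: float = 0.04,
        seed_len: int = 16,
    ):
        if min_match < 20:
            raise InputError("min_match must be >= 20")
        self.genome = genome
        self.features = list(features)
        self.min_match = min_match
        self.max_mismatch_rate = max_mismatch_rate
        self.seed_len = seed_len
        doubled = genome.sequence * 2
        self._doubled = _encode(doubled)
        self._index: dict[str, list[int]] = {}
        L = genome.length
        for i in range(L):
            self._index.setdefault(doubled[i : i + seed_len], []).append(i)

    def _place(self, codes: np.ndarray, seq: str) -> tuple[int, int] | None:
        """Best (start, mismatches) of a full-read ungapped placement."""
        L = self.genome.length
        r = codes.size
        if r < self.min_match or r > L:
            return None
        best: tuple[int, int] | None = None
        tried: set[int] = set()
        w = self.seed_len
        for off in range(0, min(r - w + 1, 8 * w), w):
            for p in self._index.get(seq[off : off + w], ()):
                start = (p - off) % L
                if start in tried:
                    continue
                tried.add(start)
                mm = int(np.count_nonzero(self._doubled[start : start + r] != codes))
                if mm <= self.max_mismatch_rate * r:
                    if best is None or mm < best[1]:
                        best = (start, mm)
        return best

    def assign(self, seq: str, read_id: str = "") -> ReadAssignment:
        L = self.genome.length
        placements: list[tuple[int, int, str]] = []
        for strand, codes, s in (
            ("+", _encode(seq), seq),
            ("-", _encode_rc(seq), revcomp(seq)),
        ):
            hit = self._place(codes, s)
            if hit is not None:
                placements.append((hit[0], hit[1], strand))
        if not placements:
            return ReadAssignment(read_id=read_id, outcome=UNASSIGNED)
        placements.sort(key=lambda t: t[1])
        start, mm, strand = placements[0]
        r = len(seq)
        overlaps: list[tuple[int, str]] = []
        for f in self.features:
            flen = f.length(L)
            # overlap of [start, start+r) with [f.start, f.start+flen) mod L;
            # the feature interval can intersect the read in up to two arms
            d = (f.start - start) % L
            ov = max(0, min(r, d + flen) - d) if d < r else 0
            ov += max(0, min(r, d + flen - L))
            if ov > 0:
                overlaps.append((ov, f.id))
        if not overlaps:
            return ReadAssignment(read_id=read_id, outcome=UNASSIGNED,
                                  mismatches=mm, strand=strand)
        overlaps.sort(key=lambda t: (-t[0], t[1]))
        if len(overlaps) > 1 and overlaps[0][0] == overlaps[1][0]:
            return ReadAssignment(read_id=read_id, outcome=AMBIGUOUS,
                                  mismatches=mm, strand=strand)
        return ReadAssignment(read_id=read_id, outcome=ASSIGNED,
                              feature_id=overlaps[0][1], mismatches=mm, strand=strand)


def assign_read_to_features(
    seq: str,
    genome: CircularGenome,
    features: Sequence[Feature],
    min_match: int = 20,
    max_mismatch_rate: float = 0.04,
    read_id: str = "",
) -> ReadAssignment:
    """One-off convenience wrapper around :class:`FeatureAssigner`."""
    return FeatureAssigner(genome, features, min_match, max_mismatch_rate).assign(
        seq, read_id=read_id
    )


@dataclass
class ClassificationCounts:
    """Read-count bookkeeping; conserves the number of input reads."""

    junction_counts: dict[tuple[str, str], int] = field(default_factory=dict)
    feature_counts: dict[str, int] = field(default_factory=dict)
    ambiguous: int = 0
    unassigned: int = 0
    total: int = 0

    def conserved(self) -> bool:
        return (
            sum(self.junction_counts.values())
            + sum(self.feature_counts.values())
            + self.ambiguous
            + self.unassigned
            == self.total
        )

    def junction_count(self, intron_id: str, category: str) -> int:
        return self.junction_counts.get((intron_id, category), 0)


def count_by_category(assignments: Iterable[ReadAssignment]) -> ClassificationCounts:
    counts = ClassificationCounts()
    for a in assignments:
        counts.total += 1
        if a.outcome == AMBIGUOUS:
            counts.ambiguous += 1
        elif a.outcome == UNASSIGNED:
            counts.unassigned += 1
        elif a.feature_id is not None:
            counts.feature_counts[a.feature_id] = counts.feature_counts.get(a.feature_id, 0) + 1
        else:
            category, intron_id, _ = a.categories[0]
            key = (intron_id, category)
            counts.junction_counts[key] = counts.junction_counts.get(key, 0) + 1
    return counts


@dataclass(frozen=True)
class BacksplicEvidence:
    seq_id: str
    has_ligation: bool
    has_permuted_contiguity: bool

    @property
    def supports(self) -> bool:
        return self.has_ligation and self.has_permuted_contiguity


def detect_backsplice_support(
    sequences: Iterable[tuple[str, str]],
    intron: IntronModel,
    genome: CircularGenome,
    k: int = 25,
    min_overlap: int = 10,
) -> tuple[int, list[BacksplicEvidence]]:
    """Count sequences carrying *both* back-splicing hallmarks.

    A sequence (read, amplicon or clone; pass circular molecules doubled)
    supports back-splicing only when it contains the exon-ligation junction
    AND the permuted genomic contiguity (exon 2 3' end running into the
    linker).  Either alone is insufficient: the ligation junction is equally
    produced by cis-splicing, and the permuted contiguity alone is present on
    the linear permuted precursor.
    """
    m = min_overlap
    L = genome.length
    sub = genome.subsequence
    lig = (sub((intron.five_ss - m) % L, intron.five_ss)
           + sub(intron.three_ss, (intron.three_ss + m) % L))
    perm = sub((intron.exon2_end - m) % L, (intron.exon2_end + m) % L)
    evidence = []
    n = 0
    for sid, seq in sequences:
        seq = seq.upper()
        both = seq + " " + revcomp(seq)
        e = BacksplicEvidence(sid, lig in both, perm in both)
        evidence.append(e)
        n += e.supports
    return n, evidence
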