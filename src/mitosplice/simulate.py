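"""Synthetic study generator: genome, RNA species pool, sequencing reads.

Emulates the salient architecture of a corallimorpharian mitochondrial
genome: a ~21 kb circle whose ND5-like gene is split by a giant group I
intron spanning >90% of the genome (so that exon 2 sits upstream-adjacent of
exon 1 across a short linker carrying a tRNA), with the intron's P8
insertion carrying the rRNA genes, a dozen protein-coding genes including a
COI-like gene interrupted by a small intron with an internal ORF, an
antisense ORF on the opposite strand, and intergenic regions one of which
holds a planted direct repeat.  The giant intron terminates in omega-A, the
small one in omega-G, mirroring the chemistry contrast that permits intron
circles only for the small intron.

Transcript abundances span three orders of magnitude with rRNA-like units
5-20x the typical mRNA.  Reads are single-end ~200 nt with substitution
errors (Ion-Torrent-like scale; homopolymer indels are not modelled).  Read
start positions are uniform over every position of the source molecule —
reads are truncated at the 3' end of linear molecules and wrap across the
closure of circular ones — so junction-spanning read counts are
proportional to molecule abundance regardless of molecule length.

All randomness flows from one root seed through per-stage child streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .genome import CircularGenome, Feature, InputError, revcomp
from .splice import (
    IntronModel,
    JunctionSite,
    RNASpecies,
    SpeciesClass,
    TranscriptModel,
    back_splice,
    build_conventional_precursor,
    build_permuted_precursor,
    circularize_intron,
    cis_splice,
)

__all__ = [
    "SimConfig",
    "ConfigError",
    "PoolEntry",
    "ReadTruth",
    "generate_genome",
    "generate_transcript_pool",
    "simulate_reads",
    "DEFAULT_EXPRESSION",
]


class ConfigError(ValueError):
    """Unsatisfiable or invalid simulation configuration."""


# Relative molar abundance per transcription unit.  rRNA units 5-20x the
# typical mRNA; full spread three orders of magnitude (LSU 20 vs ND6 0.02).
DEFAULT_EXPRESSION: dict[str, float] = {
    "SSU": 12.0,
    "LSU": 20.0,
    "ND1": 0.8,
    "ND2": 0.6,
    "CYTB": 1.5,
    "COII": 2.5,
    "COIII": 2.0,
    "ND3": 0.7,
    "ND4": 0.9,
    "ATP6": 0.5,
    "ND6": 0.02,
    "HEG": 0.1,
    "aORF": 0.3,
    "ND5": 1.0,
    "COI": 2.5,
}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic experiment."""

    seed: int = 1
    genome_length: int = 21000
    at_content: float = 0.62
    giant_omega: str = "A"
    small_omega: str = "G"
    giant_spliced_fraction: float = 0.30
    small_spliced_fraction: float = 0.98
    circ_fraction: float = 0.2
    circle_offsets: tuple[int, ...] = (0, 57)
    backsplice: bool = True
    tx_pad: int = 250
    expression: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_EXPRESSION))
    n_reads: int = 50_000
    read_length: int = 200
    substitution_rate: float = 0.01
    quality_char: str = "I"

    def __post_init__(self) -> None:
        if not 5000 <= self.genome_length <= 25000:
            raise ConfigError("genome_length must be in [5000, 25000]")
        for name in ("giant_spliced_fraction", "small_spliced_fraction", "circ_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")
        if not 0.0 <= self.substitution_rate < 0.5:
            raise ConfigError("substitution_rate must be in [0, 0.5)")
        if self.read_length < 30:
            raise ConfigError("read_length must be >= 30")
        if self.n_reads < 1:
            raise ConfigError("n_reads must be >= 1")
        if any(w <= 0 for w in self.expression.values()):
            raise ConfigError("expression weights must be positive")


# Fixed gene plan (coordinates for the 21 kb default; the trailing intergenic
# region absorbs any extra length).  Columns: id, ftype, start, end, strand,
# start codon to stamp (CDS/ORF only), {attributes}.
_MIN_GENOME = 19700

_PLAN = [
    ("ND5_E2",  "exon", 0,     450,   "+", None),
    ("trnW",    "tRNA", 500,   570,   "+", None),
    ("ND5_E1",  "exon", 700,   1417,  "+", "GTG"),
    ("SSU",     "rRNA", 2000,  3500,  "+", None),
    ("LSU",     "rRNA", 3700,  6000,  "+", None),
    ("ND1",     "CDS",  6200,  7150,  "+", "ATG"),
    ("COI_E1",  "exon", 7400,  8284,  "+", "ATG"),
    ("HEG",     "ORF",  8500,  9300,  "+", "ATG"),
    ("COI_E2",  "exon", 9484,  10150, "+", None),
    ("ND2",     "CDS",  10400, 11600, "+", "GTG"),
    ("trnM",    "tRNA", 11700, 11770, "+", None),
    ("CYTB",    "CDS",  11900, 13000, "+", "ATG"),
    ("COII",    "CDS",  13200, 13900, "+", "ATG"),
    ("COIII",   "CDS",  14700, 15450, "+", "GTG"),
    ("ND3",     "CDS",  15650, 16000, "+", "ATG"),
    ("ND4",     "CDS",  16800, 18100, "+", "GTG"),
    ("ATP6",    "CDS",  18300, 18900, "+", "ATG"),
    ("ND6",     "CDS",  19100, 19600, "+", "GTG"),
]

_AORF_SPAN = (14100, 14478)  # strand "-", inside the gap after COII (125 aa)
_REPEAT_UNIT_LEN = 90
_REPEAT_POSITIONS = (16100, 16450)  # inside the gap after ND3

_GIANT_5SS, _GIANT_3SS = 1417, 0          # intron wraps through the origin
_SMALL_5SS, _SMALL_3SS = 8284, 9484       # inside COI, insertion at 884


def _stamp(seq: bytearray, pos: int, text: str) -> None:
    seq[pos : pos + len(text)] = text.encode()


def _random_codons(rng: np.random.Generator, n: int) -> str:
    """n random sense (non-stop) codons."""
    bases = "ACGT"
    codons = []
    while len(codons) < n:
        c = "".join(rng.choice(list(bases), size=3))
        if c not in {"TAA", "TAG", "TGA"}:
            codons.append(c)
    return "".join(codons)


def generate_genome(
    config: SimConfig,
) -> tuple[CircularGenome, list[Feature], list[IntronModel]]:
    """Deterministic synthetic genome, annotation and intron models.

    The exon-ligation flanks of the giant intron are the experimentally
    determined ones (exon 1 ends AGGGT, exon 2 starts CCAACT in DNA space);
    exon 2 ends with a stop codon and exon 1 starts with GTG, so the
    back-splicing circular intermediate carries stop codon, start codon and
    ligation site in one continuous sequence.
    """
    L = config.genome_length
    if L < _MIN_GENOME:
        raise ConfigError(
            f"gene plan does not fit in {L} nt (needs >= {_MIN_GENOME})"
        )
    ss = np.random.SeedSequence(config.seed)
    rng_genome, _, _ = [np.random.default_rng(c) for c in ss.spawn(3)]

    p_at = config.at_content / 2
    p_gc = (1 - config.at_content) / 2
    seq = bytearray(
        rng_genome.choice(
            np.frombuffer(b"ACGT", dtype=np.uint8),
            size=L,
            p=[p_at, p_gc, p_gc, p_at],
        ).tobytes()
    )

    features: list[Feature] = []
    # HEG sits inside the small intron and the COI exons are covered by the
    # COI gene-level locus below; none of the three is an intergenic unit.
    not_igr_unit = {"HEG", "COI_E1", "COI_E2"}
    for fid, ftype, start, end, strand, start_codon in _PLAN:
        attrs = {"gene": fid.split("_")[0]}
        if fid not in not_igr_unit:
            attrs["igr_unit"] = "1"
        features.append(Feature(id=fid, ftype=ftype, start=start, end=end,
                                strand=strand, attributes=attrs))
        if start_codon is not None:
            _stamp(seq, start, start_codon)
        if ftype in {"CDS", "ORF"}:
            _stamp(seq, end - 3, "TAA")
    # COI gene-level locus (exon1 + intron + exon2) for gap computation and
    # start-codon statistics; overlaps its parts by construction
    features.append(Feature(id="COI", ftype="CDS", start=7400, end=10150, strand="+",
                            attributes={"gene": "COI", "igr_unit": "1"}))
    _stamp(seq, 10147, "TAA")  # COI terminal stop (end of exon 2)

    # splice-relevant stamps (giant intron, experimentally printed flanks)
    _stamp(seq, 0, "CCAACT")            # exon 2 5' start
    _stamp(seq, 447, "TAA")             # exon 2 terminal stop codon
    _stamp(seq, 1412, "AGGGT")          # exon 1 3' terminus
    seq[L - 1] = ord(config.giant_omega)   # omega of the giant intron
    seq[_SMALL_3SS - 1] = ord(config.small_omega)  # omega of the small intron

    # antisense ORF: ATG + 124 sense codons + TAA on the minus strand, with an
    # in-frame stop immediately 5' of it (in minus-strand reading) so the ORF
    # scan starts exactly at the planted ATG
    a_start, a_end = _AORF_SPAN
    aorf_cds = "ATG" + _random_codons(rng_genome, (a_end - a_start) // 3 - 2) + "TAA"
    _stamp(seq, a_start, revcomp(aorf_cds))
    _stamp(seq, a_end, revcomp("TAA"))
    features.append(Feature(id="aORF", ftype="aORF", start=a_start, end=a_end,
                            strand="-", attributes={"gene": "aORF"}))

    # planted direct repeat (two exact copies) in the gap after ND3
    unit = "".join(
        rng_genome.choice(list("ACGT"), size=_REPEAT_UNIT_LEN,
                          p=[p_at, p_gc, p_gc, p_at])
    )
    for pos in _REPEAT_POSITIONS:
        _stamp(seq, pos, unit)

    genome = CircularGenome(name=f"synthetic_mt_{config.seed}", sequence=seq.decode())

    embedded = [fid for fid, _ftype, start, _end, *_ in _PLAN
                if start >= _GIANT_5SS] + ["COI", "aORF"]
    giant = IntronModel(
        id="ND5-717",
        five_ss=_GIANT_5SS,
        three_ss=_GIANT_3SS,
        exon1_start=700,
        exon2_end=450,
        host_gene="ND5",
        insertion_pos=717,
        omega=config.giant_omega,
        p8_span=(1600, L - 200),
        embedded_ids=tuple(embedded),
    )
    small = IntronModel(
        id="COI-884",
        five_ss=_SMALL_5SS,
        three_ss=_SMALL_3SS,
        exon1_start=7400,
        exon2_end=10150,
        host_gene="COI",
        insertion_pos=884,
        omega=config.small_omega,
        embedded_ids=("HEG",),
    )
    features.append(Feature(id="ND5-717", ftype="intron", start=_GIANT_5SS,
                            end=_GIANT_3SS, strand="+", attributes={"gene": "ND5"}))
    features.append(Feature(id="COI-884", ftype="intron", start=_SMALL_5SS,
                            end=_SMALL_3SS, strand="+", attributes={"gene": "COI"}))
    return genome, features, [giant, small]


@dataclass(frozen=True)
class PoolEntry:
    species: RNASpecies
    weight: float
    unit: str


def _plain_transcript(genome: CircularGenome, f: Feature, cls: str) -> RNASpecies:
    seq = genome.subsequence(f.start, f.end)
    strand = f.strand
    if strand == "-":
        seq = revcomp(seq)
    tx = TranscriptModel(segments=((f.start, f.end),), sequence=seq, strand=strand)
    return RNASpecies(species_class=cls, transcript=tx)


def generate_transcript_pool(
    genome: CircularGenome,
    features: Sequence[Feature],
    introns: Sequence[IntronModel],
    config: SimConfig,
) -> list[PoolEntry]:
    """RNA species pool under the configured splicing parameters.

    The giant-intron unit is transcribed as the permuted precursor; the
    configured spliced fraction back-splices into the circular intermediate
    plus the two intron segments.  The small-intron unit is a conventional
    precursor; its spliced fraction yields ligated mRNA plus the linear
    intron, of which ``circ_fraction`` goes on to form intron circles at the
    configured donor offsets.  Embedded genes and the antisense ORF are
    emitted as plain transcripts.
    """
    giant = next(i for i in introns if i.id == "ND5-717")
    small = next(i for i in introns if i.id == "COI-884")
    expr = dict(config.expression)
    pool: list[PoolEntry] = []

    # giant-intron transcription unit (permuted, back-splicing)
    w = expr.pop("ND5")
    L = genome.length
    perm = build_permuted_precursor(
        genome, giant,
        tx_start=(giant.three_ss - config.tx_pad) % L,
        tx_end=(giant.five_ss + config.tx_pad) % L,
    )
    sf = config.giant_spliced_fraction
    if sf < 1:
        pool.append(PoolEntry(perm, w * (1 - sf), "ND5"))
    if sf > 0 and config.backsplice:
        circ, seg3, seg5 = back_splice(perm, giant, genome)
        pool.append(PoolEntry(circ, w * sf, "ND5"))
        pool.append(PoolEntry(seg3, w * sf, "ND5"))
        pool.append(PoolEntry(seg5, w * sf, "ND5"))

    # small-intron transcription unit (conventional cis-splicing)
    w = expr.pop("COI")
    conv = build_conventional_precursor(genome, small, pad=config.tx_pad)
    sf = config.small_spliced_fraction
    if sf < 1:
        pool.append(PoolEntry(conv, w * (1 - sf), "COI"))
    if sf > 0:
        mrna, intron_lin = cis_splice(conv, small, genome)
        pool.append(PoolEntry(mrna, w * sf, "COI"))
        lin_w = w * sf * (1 - config.circ_fraction)
        if lin_w > 0:
            pool.append(PoolEntry(intron_lin, lin_w, "COI"))
        if config.circ_fraction > 0 and config.circle_offsets:
            per = w * sf * config.circ_fraction / len(config.circle_offsets)
            for d in config.circle_offsets:
                circle = circularize_intron(intron_lin, small, genome, donor_offset=d)
                pool.append(PoolEntry(circle, per, "COI"))

    # plain transcripts for embedded genes and the antisense ORF
    by_id = {f.id: f for f in features}
    for unit, weight in expr.items():
        f = by_id.get(unit)
        if f is None:
            raise ConfigError(f"expression weight for unknown feature {unit!r}")
        pool.append(PoolEntry(_plain_transcript(genome, f, SpeciesClass.GENIC_OTHER),
                              weight, unit))
    return pool


@dataclass(frozen=True)
class ReadTruth:
    read_id: str
    unit: str
    species_class: str
    source_intron: str | None
    junction_category: str | None
    junction_intron: str | None
    n_errors: int
    error_positions: tuple[int, ...] = ()


_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)


def simulate_reads(
    pool: Sequence[PoolEntry],
    config: SimConfig,
    seed: int | None = None,
    min_overlap: int = 10,
) -> tuple[list[tuple[str, str, str]], list[ReadTruth]]:
    """Draw single-end reads with substitution errors and ground truth.

    Molecules are sampled proportionally to weight x length (fragment mass);
    start positions are uniform over every position of the molecule.  Truth
    records the source species and any junction whose midpoint the read
    spans with at least ``min_overlap`` nt on both sides.
    """
    if seed is None:
        ss = np.random.SeedSequence(config.seed).spawn(3)[2]
    else:
        ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    n, rl = config.n_reads, config.read_length
    m = min_overlap

    lengths = np.array([len(e.species) for e in pool], dtype=np.int64)
    mass = np.array([e.weight for e in pool]) * lengths
    probs = mass / mass.sum()
    mol_of_read = rng.choice(len(pool), size=n, p=probs)

    reads: list[tuple[str, str, str] | None] = [None] * n
    truths: list[ReadTruth | None] = [None] * n
    qual_full = config.quality_char * rl

    for mi, entry in enumerate(pool):
        idx = np.nonzero(mol_of_read == mi)[0]
        if idx.size == 0:
            continue
        sp = entry.species
        seq = sp.sequence
        ell = len(seq)
        circular = sp.transcript.topology == "circular"
        arr = np.frombuffer((seq + seq).encode(), dtype=np.uint8)
        starts = rng.integers(0, ell, size=idx.size)
        if circular:
            read_lens = np.full(idx.size, min(rl, ell), dtype=np.int64)
        else:
            read_lens = np.minimum(rl, ell - starts)
        max_len = int(read_lens.max())
        gather = starts[:, None] + np.arange(max_len)[None, :]
        mat = arr[np.minimum(gather, 2 * ell - 1)]
        valid = np.arange(max_len)[None, :] < read_lens[:, None]

        if config.substitution_rate > 0:
            err_mask = (rng.random(mat.shape) < config.substitution_rate) & valid
            codes = _CODE_LOOKUP[mat]
            err_mask &= codes < 4  # never substitute N
            shift = rng.integers(1, 4, size=mat.shape)
            new_codes = (codes + shift) % 4
            mat = np.where(err_mask, _DECODE[new_codes], mat)
        else:
            err_mask = np.zeros(mat.shape, dtype=bool)

        # junction coverage per read
        jcats: list[tuple[int, str, str]] = [
            (js.offset, js.category, js.intron_id) for js in sp.junctions
        ]
        jun_cat = np.full(idx.size, -1, dtype=np.int64)
        for j_i, (joff, _, _) in enumerate(jcats):
            if circular:
                rel = (joff - starts) % ell
                covered = (rel >= m) & (rel <= read_lens - m)
            else:
                covered = (starts + m <= joff) & (joff <= starts + read_lens - m)
            jun_cat[covered & (jun_cat == -1)] = j_i

        err_rows, err_cols = np.nonzero(err_mask)
        errors_by_row: dict[int, list[int]] = {}
        for r_i, c_i in zip(err_rows.tolist(), err_cols.tolist()):
            errors_by_row.setdefault(r_i, []).append(c_i)

        buf = mat.tobytes()
        width = mat.shape[1]
        lens_list = read_lens.tolist()
        for row, read_i in enumerate(idx.tolist()):
            ln = lens_list[row]
            base = row * width
            s = buf[base : base + ln].decode()
            rid = f"r{read_i:06d}"
            reads[read_i] = (rid, s, qual_full[:ln])
            errs = tuple(errors_by_row.get(row, ()))
            j = int(jun_cat[row])
            truths[read_i] = ReadTruth(
                read_id=rid,
                unit=entry.unit,
                species_class=sp.species_class,
                source_intron=sp.source_intron,
                junction_category=jcats[j][1] if j >= 0 else None,
                junction_intron=jcats[j][2] if j >= 0 else None,
                n_errors=len(errs),
                error_positions=errs,
            )
    return reads, truths  # type: ignore[return-value]


_CODE_LOOKUP = np.full(256, 9, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE_LOOKUP[_b] = _i
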