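"""Group I intron splicing state machine on a circular genome.

Models the two-transesterification chemistry of group I introns and the two
precursor architectures seen for corallimorpharian mitochondrial introns:

* a *conventional* precursor ``exon1 - intron - exon2`` removed by
  cis-splicing (exogenous guanosine attacks the 5' splice site, the freed
  exon 1 3'-OH attacks the 3' splice site, the exons ligate and the linear
  intron is released with the exo-G on its 5' end);

* a *permuted* precursor ``intron 3' part - exon2 - linker - exon1 -
  intron 5' part``, which arises naturally when the intron spans most of a
  circular genome so that exon 2 lies upstream-adjacent of exon 1.  The same
  two steps then ligate exon 1 to exon 2 across the transcript ends,
  producing a covalently closed circular exon-containing RNA (back-splicing)
  plus two released intron segments.

The excised linear intron may additionally circularize by joining its
terminal nucleotide (the omega residue, canonically G) to its own 5' end or
to an internal donor site (truncated circles).  An intron terminating in
omega-A cannot perform this ligation, although back-splicing — which uses
the 3' splice site, not intron circularization — is unaffected.

Sequences are stored in the DNA alphabet; conversion to RNA (T->U) is a
presentation concern (:func:`to_rna`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

from .genome import CircularGenome, CoordinateError, InputError

__all__ = [
    "IntronModel",
    "TranscriptModel",
    "RNASpecies",
    "Junction",
    "JunctionSite",
    "ValidationCheck",
    "ChemistryError",
    "SpeciesClass",
    "JunctionCategory",
    "to_rna",
    "validate_intron",
    "build_conventional_precursor",
    "build_permuted_precursor",
    "cis_splice",
    "back_splice",
    "circularize_intron",
    "enumerate_junctions",
]


class ChemistryError(RuntimeError):
    """A reaction chemically unavailable to the substrate (e.g. no omega-G)."""


def to_rna(seq: str) -> str:
    """Present a DNA-alphabet sequence as RNA."""
    return seq.replace("T", "U")


class SpeciesClass:
    """Names for the RNA species the splicing pathways evidence."""

    PRECURSOR_CONVENTIONAL = "PRECURSOR_CONVENTIONAL"
    PRECURSOR_PERMUTED = "PRECURSOR_PERMUTED"
    MRNA_LIGATED = "MRNA_LIGATED"
    INTRON_LINEAR = "INTRON_LINEAR"
    INTRON_CIRCLE_FULL = "INTRON_CIRCLE_FULL"
    INTRON_CIRCLE_TRUNCATED = "INTRON_CIRCLE_TRUNCATED"
    CIRC_INTERMEDIATE = "CIRC_INTERMEDIATE"
    INTRON_5P_SEGMENT = "INTRON_5P_SEGMENT"
    INTRON_3P_SEGMENT = "INTRON_3P_SEGMENT"
    GENIC_OTHER = "GENIC_OTHER"


class JunctionCategory:
    E1E2_LIGATION = "E1E2_LIGATION"
    UNSPLICED_5SS = "UNSPLICED_5SS"
    UNSPLICED_3SS = "UNSPLICED_3SS"
    INTRON_CIRCLE = "INTRON_CIRCLE"
    PERMUTED_GENOMIC = "PERMUTED_GENOMIC"


@dataclass(frozen=True)
class IntronModel:
    """One group I intron on a circular genome.

    ``five_ss`` is the genome position of the first intron nucleotide and
    ``three_ss`` the position immediately after the last one (the first
    nucleotide of exon 2).  Host exon extents are carried so junction and
    permuted-precursor construction can locate exon boundaries:
    exon 1 = ``[exon1_start, five_ss)``, exon 2 = ``[three_ss, exon2_end)``.
    ``omega`` is the expected terminal residue; the genome is authoritative
    (see :func:`validate_intron`).  Insertion-position naming such as
    "ND5-717" is metadata only.
    """

    id: str
    five_ss: int
    three_ss: int
    exon1_start: int
    exon2_end: int
    host_gene: str = ""
    insertion_pos: int | None = None
    omega: str | None = None
    exo_g: str = "G"
    p8_span: tuple[int, int] | None = None
    embedded_ids: tuple[str, ...] = ()

    def length(self, genome: CircularGenome) -> int:
        return genome.circular_distance(self.five_ss, self.three_ss)

    def exon1_length(self, genome: CircularGenome) -> int:
        return genome.circular_distance(self.exon1_start, self.five_ss)

    def exon2_length(self, genome: CircularGenome) -> int:
        return genome.circular_distance(self.three_ss, self.exon2_end)

    def genome_omega(self, genome: CircularGenome) -> str:
        return genome.base(self.three_ss - 1)


@dataclass(frozen=True)
class TranscriptModel:
    """Ordered genomic segments walked 5'->3' plus the concatenated sequence."""

    segments: tuple[tuple[int, int], ...]
    sequence: str
    topology: str = "linear"
    strand: str = "+"


@dataclass(frozen=True)
class JunctionSite:
    """Location of a diagnostic junction inside one RNA molecule.

    ``offset`` is the index of the first nucleotide 3' of the junction in the
    molecule's own coordinates (for a circular molecule, the closure junction
    sits at offset 0).
    """

    offset: int
    category: str
    intron_id: str
    donor_offset: int | None = None


@dataclass(frozen=True)
class RNASpecies:
    """A transcript-level molecule with provenance back to the genome."""

    species_class: str
    transcript: TranscriptModel
    extra_5p: str = ""
    source_intron: str | None = None
    junctions: tuple[JunctionSite, ...] = ()

    def __post_init__(self) -> None:
        if self.extra_5p and self.species_class not in {
            SpeciesClass.INTRON_LINEAR,
            SpeciesClass.INTRON_5P_SEGMENT,
        }:
            raise InputError(
                "non-encoded 5' nucleotides occur only on excised 5'-intron products"
            )

    @property
    def sequence(self) -> str:
        return self.extra_5p + self.transcript.sequence

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Junction:
    """Sequence context of one splicing/circularization event."""

    category: str
    left_flank: str
    right_flank: str
    intron_id: str
    donor_offset: int | None = None

    @property
    def context(self) -> str:
        return self.left_flank + self.right_flank


@dataclass(frozen=True)
class ValidationCheck:
    name: str
    status: str  # "pass" | "warn" | "fail"
    message: str


def _segments_transcript(
    genome: CircularGenome, segments: Sequence[tuple[int, int]], topology: str = "linear"
) -> TranscriptModel:
    seq = "".join(genome.subsequence(s, e) for s, e in segments)
    return TranscriptModel(segments=tuple(segments), sequence=seq, topology=topology)


def validate_intron(genome: CircularGenome, intron: IntronModel) -> list[ValidationCheck]:
    """Consistency report for an intron annotation (never raises).

    A terminal residue other than G is a warning, not a failure: such introns
    (the giant ND5 intron ends in omega-A) still splice — step 2 uses the 3'
    splice site — but cannot form intron circles.
    """
    checks: list[ValidationCheck] = []
    L = genome.length
    coords_ok = all(0 <= p < L for p in (intron.five_ss, intron.three_ss,
                                         intron.exon1_start, intron.exon2_end))
    if not coords_ok:
        checks.append(ValidationCheck("coordinates", "fail",
                                      f"coordinates out of range for genome length {L}"))
        return checks
    checks.append(ValidationCheck("coordinates", "pass", "all coordinates in range"))

    ilen = intron.length(genome)
    if ilen == 0:
        checks.append(ValidationCheck("intron-length", "fail", "zero-length intron"))
        return checks
    checks.append(ValidationCheck("intron-length", "pass", f"intron length {ilen} nt"))

    omega = intron.genome_omega(genome)
    if intron.omega is not None and intron.omega != omega:
        checks.append(ValidationCheck(
            "omega-annotation", "fail",
            f"annotated omega {intron.omega} but genome has {omega}"))
    else:
        checks.append(ValidationCheck("omega-annotation", "pass",
                                      f"terminal residue is {omega}"))
    if omega != "G":
        checks.append(ValidationCheck(
            "omega-chemistry", "warn",
            f"terminal residue is {omega}, not omega-G: exon ligation proceeds but "
            "intron circularization is unavailable"))
    else:
        checks.append(ValidationCheck("omega-chemistry", "pass", "terminal residue is omega-G"))

    for name, n in (("exon1", intron.exon1_length(genome)),
                    ("exon2", intron.exon2_length(genome))):
        if n == 0:
            checks.append(ValidationCheck(f"{name}-length", "fail", f"zero-length {name}"))
        else:
            checks.append(ValidationCheck(f"{name}-length", "pass", f"{name} length {n} nt"))

    n_embedded = len(intron.embedded_ids)
    checks.append(ValidationCheck("embedded-features", "pass",
                                  f"{n_embedded} embedded feature(s) recorded"))
    return checks


def build_conventional_precursor(
    genome: CircularGenome, intron: IntronModel, pad: int
) -> RNASpecies:
    """Linear precursor: ``pad`` nt of exon 1, the intron, ``pad`` nt of exon 2."""
    if pad <= 0:
        raise InputError("pad must be positive")
    L = genome.length
    ilen = intron.length(genome)
    if ilen == 0:
        raise InputError("zero-length intron")
    if pad > intron.exon1_length(genome) or pad > intron.exon2_length(genome):
        raise InputError(
            f"pad {pad} exceeds available exon length "
            f"(exon1 {intron.exon1_length(genome)}, exon2 {intron.exon2_length(genome)})"
        )
    segments = [
        ((intron.five_ss - pad) % L, intron.five_ss),
        (intron.five_ss, intron.three_ss),
        (intron.three_ss, (intron.three_ss + pad) % L),
    ]
    tx = _segments_transcript(genome, segments)
    return RNASpecies(
        species_class=SpeciesClass.PRECURSOR_CONVENTIONAL,
        transcript=tx,
        source_intron=intron.id,
        junctions=(
            JunctionSite(pad, JunctionCategory.UNSPLICED_5SS, intron.id),
            JunctionSite(pad + ilen, JunctionCategory.UNSPLICED_3SS, intron.id),
        ),
    )


def build_permuted_precursor(
    genome: CircularGenome,
    intron: IntronModel,
    tx_start: int | None = None,
    tx_end: int | None = None,
    default_margin: int = 75,
) -> RNASpecies:
    """Permuted precursor ``[intron 3' tail][exon2][linker][exon1][intron 5' head]``.

    ``tx_start`` must lie strictly inside the intron's 3' region (upstream of
    the 3' splice site) and ``tx_end`` strictly inside its 5' region; the
    5'->3' walk passes 3'SS, exon 2, linker, exon 1, then the 5'SS.  Defaults
    place the termini ``default_margin`` nt outside the splice sites.
    """
    L = genome.length
    ilen = intron.length(genome)
    if tx_start is None:
        tx_start = (intron.three_ss - default_margin) % L
    if tx_end is None:
        tx_end = (intron.five_ss + default_margin) % L

    d_start_in_intron = genome.circular_distance(intron.five_ss, tx_start)
    d_end_in_intron = genome.circular_distance(intron.five_ss, tx_end)
    if not 0 < d_start_in_intron < ilen:
        raise InputError("tx_start must lie strictly inside the intron")
    if not 0 < d_end_in_intron < ilen:
        raise InputError("tx_end must lie strictly inside the intron")
    d_3ss = genome.circular_distance(tx_start, intron.three_ss)
    d_5ss = genome.circular_distance(tx_start, intron.five_ss)
    d_end = genome.circular_distance(tx_start, tx_end)
    if not d_3ss < d_5ss < d_end:
        raise InputError(
            "walking 5'->3' from tx_start must pass the 3'SS, the exons, then the 5'SS "
            "before tx_end"
        )
    segments = [
        (tx_start, intron.three_ss),
        (intron.three_ss, intron.exon2_end),
        (intron.exon2_end, intron.exon1_start),
        (intron.exon1_start, intron.five_ss),
        (intron.five_ss, tx_end),
    ]
    segments = [(s, e) for s, e in segments if s != e]
    tx = _segments_transcript(genome, segments)
    e2len = intron.exon2_length(genome)
    return RNASpecies(
        species_class=SpeciesClass.PRECURSOR_PERMUTED,
        transcript=tx,
        source_intron=intron.id,
        junctions=(
            JunctionSite(d_3ss, JunctionCategory.UNSPLICED_3SS, intron.id),
            JunctionSite(d_3ss + e2len, JunctionCategory.PERMUTED_GENOMIC, intron.id),
            JunctionSite(d_5ss, JunctionCategory.UNSPLICED_5SS, intron.id),
        ),
    )


def cis_splice(
    precursor: RNASpecies, intron: IntronModel, genome: CircularGenome
) -> tuple[RNASpecies, RNASpecies]:
    """Two-step cis-splicing: ligated mRNA plus the released linear intron.

    Nucleotide conservation: ``len(precursor) == len(mRNA) + (len(intron
    product) - 1)`` — the released intron carries one non-encoded exo-G.
    """
    if precursor.species_class != SpeciesClass.PRECURSOR_CONVENTIONAL:
        raise InputError("cis_splice requires a conventional precursor")
    if precursor.source_intron != intron.id:
        raise InputError(f"precursor was built for intron {precursor.source_intron}")
    L = genome.length
    pad = (precursor.transcript.segments[0][1] - precursor.transcript.segments[0][0]) % L
    mrna_segments = [
        ((intron.five_ss - pad) % L, intron.five_ss),
        (intron.three_ss, (intron.three_ss + pad) % L),
    ]
    mrna = RNASpecies(
        species_class=SpeciesClass.MRNA_LIGATED,
        transcript=_segments_transcript(genome, mrna_segments),
        source_intron=intron.id,
        junctions=(JunctionSite(pad, JunctionCategory.E1E2_LIGATION, intron.id),),
    )
    intron_product = RNASpecies(
        species_class=SpeciesClass.INTRON_LINEAR,
        transcript=_segments_transcript(genome, [(intron.five_ss, intron.three_ss)]),
        extra_5p=intron.exo_g,
        source_intron=intron.id,
    )
    assert len(precursor) == len(mrna) + (len(intron_product) - 1)
    return mrna, intron_product


def back_splice(
    precursor: RNASpecies, intron: IntronModel, genome: CircularGenome
) -> tuple[RNASpecies, RNASpecies, RNASpecies]:
    """Back-splicing of a permuted precursor.

    The same two transesterifications, applied to the permuted arrangement,
    close exon 2 + linker + exon 1 into a circular RNA intermediate (the
    ligation junction joins the exon 1 3' end to the exon 2 5' start) and
    release two linear intron segments; the full-length intron is never
    produced as one molecule.  Conservation: ``len(precursor) == len(circ) +
    len(3' segment) + (len(5' segment) - 1)``.
    """
    if precursor.species_class != SpeciesClass.PRECURSOR_PERMUTED:
        raise InputError("back_splice requires a permuted precursor")
    if precursor.source_intron != intron.id:
        raise InputError(f"precursor was built for intron {precursor.source_intron}")
    tx_start = precursor.transcript.segments[0][0]
    tx_end = precursor.transcript.segments[-1][1]
    e2len = intron.exon2_length(genome)

    circ = RNASpecies(
        species_class=SpeciesClass.CIRC_INTERMEDIATE,
        transcript=_segments_transcript(
            genome, [(intron.three_ss, intron.five_ss)], topology="circular"
        ),
        source_intron=intron.id,
        junctions=(
            JunctionSite(0, JunctionCategory.E1E2_LIGATION, intron.id),
            JunctionSite(e2len, JunctionCategory.PERMUTED_GENOMIC, intron.id),
        ),
    )
    seg3 = RNASpecies(
        species_class=SpeciesClass.INTRON_3P_SEGMENT,
        transcript=_segments_transcript(genome, [(tx_start, intron.three_ss)]),
        source_intron=intron.id,
    )
    seg5 = RNASpecies(
        species_class=SpeciesClass.INTRON_5P_SEGMENT,
        transcript=_segments_transcript(genome, [(intron.five_ss, tx_end)]),
        extra_5p=intron.exo_g,
        source_intron=intron.id,
    )
    assert len(precursor) == len(circ) + len(seg3) + (len(seg5) - 1)
    return circ, seg3, seg5


def circularize_intron(
    intron_product: RNASpecies,
    intron: IntronModel,
    genome: CircularGenome,
    donor_offset: int = 0,
    force: bool = False,
) -> RNASpecies:
    """Join the intron 3' terminus (omega) to an internal donor site.

    ``donor_offset`` counts from the intron 5' end after removing the exo-G;
    offset 0 gives the full-length circle.  Requires a terminal omega-G
    unless ``force`` is set — an omega-A intron cannot ligate its 3' end.
    """
    if intron_product.species_class != SpeciesClass.INTRON_LINEAR:
        raise InputError("circularize_intron requires a linear excised intron")
    body = intron_product.transcript.sequence  # exo-G excluded by construction
    if donor_offset < 0 or donor_offset >= len(body):
        raise InputError(f"donor_offset {donor_offset} out of range for intron of "
                         f"length {len(body)}")
    if body[-1] != "G" and not force:
        raise ChemistryError(
            f"terminal residue is not omega-G (found {body[-1]}): "
            "intron circularization is chemically unavailable"
        )
    L = genome.length
    start = (intron.five_ss + donor_offset) % L
    cls = (SpeciesClass.INTRON_CIRCLE_FULL if donor_offset == 0
           else SpeciesClass.INTRON_CIRCLE_TRUNCATED)
    return RNASpecies(
        species_class=cls,
        transcript=_segments_transcript(genome, [(start, intron.three_ss)],
                                        topology="circular"),
        source_intron=intron.id,
        junctions=(
            JunctionSite(0, JunctionCategory.INTRON_CIRCLE, intron.id,
                         donor_offset=donor_offset),
        ),
    )


def enumerate_junctions(
    genome: CircularGenome,
    intron: IntronModel,
    k: int = 25,
    circle_offsets: Sequence[int] = (),
) -> list[Junction]:
    """All diagnostic junction contexts of one intron, with exact k-nt flanks.

    Emits the exon-ligation junction (identical for cis- and back-splicing),
    the two unspliced splice-site junctions, one intron-circle junction per
    donor offset, and the permuted-genomic contiguity (exon 2 3' end running
    into the downstream genomic linker).
    """
    if k < 6:
        raise InputError("flank length k must be >= 6")
    L = genome.length
    ilen = intron.length(genome)
    if min(intron.exon1_length(genome), intron.exon2_length(genome)) < k:
        raise InputError(f"exons must be at least k={k} nt")
    if ilen < k:
        raise InputError(f"intron must be at least k={k} nt")
    sub = genome.subsequence
    e1_tail = sub((intron.five_ss - k) % L, intron.five_ss)
    e2_head = sub(intron.three_ss, (intron.three_ss + k) % L)
    i_head = sub(intron.five_ss, (intron.five_ss + k) % L)
    i_tail = sub((intron.three_ss - k) % L, intron.three_ss)
    e2_tail = sub((intron.exon2_end - k) % L, intron.exon2_end)
    after_e2 = sub(intron.exon2_end, (intron.exon2_end + k) % L)

    out = [
        Junction(JunctionCategory.E1E2_LIGATION, e1_tail, e2_head, intron.id),
        Junction(JunctionCategory.UNSPLICED_5SS, e1_tail, i_head, intron.id),
        Junction(JunctionCategory.UNSPLICED_3SS, i_tail, e2_head, intron.id),
        Junction(JunctionCategory.PERMUTED_GENOMIC, e2_tail, after_e2, intron.id),
    ]
    for d in circle_offsets:
        if not 0 <= d < ilen - k:
            raise InputError(f"circle donor offset {d} out of range")
        donor = sub((intron.five_ss + d) % L, (intron.five_ss + d + k) % L)
        out.append(
            Junction(JunctionCategory.INTRON_CIRCLE, i_tail, donor, intron.id,
                     donor_offset=d)
        )
    return out
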