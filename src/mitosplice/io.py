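"""Standard-format I/O: FASTA, GFF3 (circular dialect), FASTQ, GenBank, TSV.

GFF3 has no native convention for features that span the origin of a circular
sequence.  This package writes such a feature as two lines sharing an ``ID``
attribute (the part ending at the last base and the part starting at base 1)
and re-joins them on read.  All other coordinates convert between the
internal 0-based half-open modular system and GFF3's 1-based inclusive one.
"""

from __future__ import annotations

import os
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome import CircularGenome, Feature, InputError

__all__ = [
    "ParseError",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "read_fastq",
    "write_fastq",
    "read_genbank",
    "write_species_fasta",
]


class ParseError(ValueError):
    """Malformed record; carries the 1-based line number where known."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


def read_fasta(path: str | os.PathLike) -> CircularGenome:
    """Read the first record of a FASTA file as a circular genome."""
    for rec in SeqIO.parse(str(path), "fasta"):
        return CircularGenome(name=rec.id, sequence=str(rec.seq).upper())
    raise ParseError(f"no FASTA records in {path}")


def write_fasta(genome: CircularGenome, path: str | os.PathLike) -> None:
    rec = SeqRecord(Seq(genome.sequence), id=genome.name, description="topology=circular")
    SeqIO.write([rec], str(path), "fasta")


def _format_attributes(feature: Feature) -> str:
    parts = [f"ID={feature.id}"]
    for key in sorted(feature.attributes):
        parts.append(f"{key}={feature.attributes[key]}")
    return ";".join(parts)


def write_gff3(
    genome: CircularGenome, features: Sequence[Feature], path: str | os.PathLike
) -> None:
    """Write features in the circular GFF3 dialect (see module docstring)."""
    L = genome.length
    lines = ["##gff-version 3", f"##sequence-region {genome.name} 1 {L}"]

    def row(start1: int, end1: int, f: Feature) -> str:
        return "\t".join(
            [
                genome.name,
                "mitosplice",
                f.ftype,
                str(start1),
                str(end1),
                ".",
                f.strand,
                ".",
                _format_attributes(f),
            ]
        )

    for f in sorted(features, key=lambda f: f.start):
        f.length(L)  # validates non-zero
        if not f.wraps:
            lines.append(row(f.start + 1, f.end, f))
        elif f.end == 0:
            lines.append(row(f.start + 1, L, f))
        else:
            lines.append(row(f.start + 1, L, f))
            lines.append(row(1, f.end, f))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_gff3(path: str | os.PathLike) -> list[Feature]:
    """Read the circular GFF3 dialect back into Feature objects."""
    seq_length: int | None = None
    raw: list[tuple[int, str, int, int, str, str, dict]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                if line.startswith("##sequence-region"):
                    try:
                        seq_length = int(line.split()[3])
                    except (IndexError, ValueError):
                        raise ParseError("malformed ##sequence-region", lineno)
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ParseError(f"expected 9 columns, got {len(cols)}", lineno)
            try:
                start1, end1 = int(cols[3]), int(cols[4])
            except ValueError:
                raise ParseError("start/end are not integers", lineno)
            if start1 < 1:
                raise ParseError(f"start {start1} < 1", lineno)
            if end1 < start1:
                raise ParseError(f"end {end1} < start {start1}", lineno)
            attrs: dict[str, str] = {}
            for item in cols[8].split(";"):
                if not item:
                    continue
                if "=" not in item:
                    raise ParseError(f"malformed attribute {item!r}", lineno)
                k, v = item.split("=", 1)
                attrs[k] = v
            if "ID" not in attrs:
                raise ParseError("attribute ID is required", lineno)
            raw.append((lineno, cols[2], start1, end1, cols[6], attrs.pop("ID"), attrs))

    by_id: dict[str, list[tuple[int, str, int, int, str, dict]]] = {}
    order: list[str] = []
    for lineno, ftype, start1, end1, strand, fid, attrs in raw:
        if fid not in by_id:
            order.append(fid)
        by_id.setdefault(fid, []).append((lineno, ftype, start1, end1, strand, attrs))

    features: list[Feature] = []
    for fid in order:
        parts = by_id[fid]
        if len(parts) == 1:
            lineno, ftype, start1, end1, strand, attrs = parts[0]
            end0 = end1 % seq_length if seq_length else end1
            features.append(
                Feature(id=fid, ftype=ftype, start=start1 - 1, end=end0, strand=strand,
                        attributes=attrs)
            )
        elif len(parts) == 2:
            if seq_length is None:
                raise ParseError(
                    f"feature {fid} split in two parts but no ##sequence-region header",
                    parts[0][0],
                )
            parts = sorted(parts, key=lambda p: p[2])
            (ln_a, ftype, s_a, e_a, strand, attrs), (ln_b, ftype_b, s_b, e_b, strand_b, _) = parts
            if s_a != 1 or e_b != seq_length or ftype != ftype_b or strand != strand_b:
                raise ParseError(
                    f"feature {fid}: two parts do not form an origin-spanning split", ln_b
                )
            features.append(
                Feature(id=fid, ftype=ftype, start=s_b - 1, end=e_a % seq_length,
                        strand=strand, attributes=attrs)
            )
        else:
            raise ParseError(f"feature {fid} appears {len(parts)} times", parts[0][0])
    return features


def read_fastq(path: str | os.PathLike) -> Iterator[tuple[str, str, str]]:
    """Yield (read id, sequence, quality string) from a FASTQ file."""
    with open(path) as fh:
        lineno = 0
        while True:
            header = fh.readline()
            if not header:
                return
            seq, plus, qual = fh.readline(), fh.readline(), fh.readline()
            lineno += 4
            if not qual:
                raise ParseError("truncated FASTQ record", lineno)
            if not header.startswith("@") or not plus.startswith("+"):
                raise ParseError("malformed FASTQ record", lineno - 3)
            yield header[1:].split()[0], seq.strip().upper(), qual.strip()


def write_fastq(records: Iterable[tuple[str, str, str]], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for rid, seq, qual in records:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def write_intron_config(introns, path: str | os.PathLike,
                        circle_offsets: dict[str, tuple[int, ...]] | None = None) -> None:
    """Write intron annotations as an INI file (one section per intron)."""
    import configparser

    cp = configparser.ConfigParser()
    for intron in introns:
        sec = f"intron:{intron.id}"
        cp[sec] = {
            "five_ss": str(intron.five_ss),
            "three_ss": str(intron.three_ss),
            "exon1_start": str(intron.exon1_start),
            "exon2_end": str(intron.exon2_end),
            "host_gene": intron.host_gene,
            "omega": intron.omega or "",
        }
        if intron.insertion_pos is not None:
            cp[sec]["insertion_pos"] = str(intron.insertion_pos)
        offsets = (circle_offsets or {}).get(intron.id)
        if offsets:
            cp[sec]["circle_offsets"] = ",".join(str(d) for d in offsets)
    with open(path, "w") as fh:
        cp.write(fh)


def read_intron_config(path: str | os.PathLike):
    """Read intron annotations; returns (introns, circle_offsets by intron id)."""
    import configparser

    from .splice import IntronModel

    cp = configparser.ConfigParser()
    if not cp.read(str(path)):
        raise ParseError(f"cannot read intron config {path}")
    introns = []
    offsets: dict[str, tuple[int, ...]] = {}
    for section in cp.sections():
        if not section.startswith("intron:"):
            raise ParseError(f"unexpected section [{section}] in {path}")
        iid = section.split(":", 1)[1]
        sec = cp[section]
        try:
            intron = IntronModel(
                id=iid,
                five_ss=sec.getint("five_ss"),
                three_ss=sec.getint("three_ss"),
                exon1_start=sec.getint("exon1_start"),
                exon2_end=sec.getint("exon2_end"),
                host_gene=sec.get("host_gene", ""),
                insertion_pos=sec.getint("insertion_pos", fallback=None),
                omega=sec.get("omega", "") or None,
            )
        except ValueError as exc:
            raise ParseError(f"section [{section}]: {exc}") from exc
        introns.append(intron)
        raw = sec.get("circle_offsets", "").strip()
        if raw:
            offsets[iid] = tuple(int(x) for x in raw.split(","))
    return introns, offsets


_GENBANK_TYPES = {"CDS": "CDS", "rRNA": "rRNA", "tRNA": "tRNA", "intron": "intron"}


def read_genbank(path: str | os.PathLike) -> tuple[CircularGenome, list[Feature]]:
    """Convenience reader for a GenBank flat file (sequence + basic features)."""
    rec = next(SeqIO.parse(str(path), "genbank"))
    genome = CircularGenome(name=rec.id, sequence=str(rec.seq).upper())
    features: list[Feature] = []
    n = 0
    for feat in rec.features:
        ftype = _GENBANK_TYPES.get(feat.type)
        if ftype is None:
            continue
        n += 1
        name = feat.qualifiers.get("gene", feat.qualifiers.get("product", [f"feat{n}"]))[0]
        strand = "-" if feat.location.strand == -1 else "+"
        if strand == "-":
            ftype = "aORF"
        features.append(
            Feature(
                id=f"{name}.{n}",
                ftype=ftype,
                start=int(feat.location.start) % genome.length,
                end=int(feat.location.end) % genome.length,
                strand=strand,
            )
        )
    return genome, features


def write_species_fasta(pool, path: str | os.PathLike) -> None:
    """Write an RNA species pool as FASTA; species class in the description."""
    records = []
    for i, entry in enumerate(pool):
        species, weight = entry.species, entry.weight
        records.append(
            SeqRecord(
                Seq(species.sequence),
                id=f"{entry.unit}.{i}",
                description=(
                    f"class={species.species_class} topology={species.transcript.topology} "
                    f"weight={weight:g}"
                ),
            )
        )
    SeqIO.write(records, str(path), "fasta")
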