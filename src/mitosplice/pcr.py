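"""In-silico PCR on linear and circular templates.

The computational analogue of the discriminating RT-PCR experiments: a
*divergent* primer pair (both binding within one region, 3' ends pointing
away from each other) yields no product from a linear template but amplifies
around a circular one — the classic assay for circular RNA.  Convergent
pairs behave as ordinary PCR.  Primer 3' ends are anchored (the terminal
nucleotides must match exactly regardless of the mismatch allowance) because
the polymerase extends from the 3' end.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .genome import InputError, revcomp
from .splice import Junction

__all__ = [
    "Primer",
    "PrimerSite",
    "Amplicon",
    "find_primer_sites",
    "predict_amplicons",
]

_ANCHOR = 5  # 3'-terminal nucleotides that must match exactly


@dataclass(frozen=True)
class Primer:
    name: str
    sequence: str  # 5'->3'

    def __post_init__(self) -> None:
        if not 15 <= len(self.sequence) <= 35:
            raise InputError(f"primer {self.name}: length must be 15-35 nt")
        if set(self.sequence) - set("ACGT"):
            raise InputError(f"primer {self.name}: alphabet must be A/C/G/T")


@dataclass(frozen=True)
class PrimerSite:
    """Footprint start (leftmost template coordinate) and strand.

    Strand "+" means the primer sequence matches the template as written
    (extension rightward); strand "-" means the template matches the
    primer's reverse complement (extension leftward); the primer 5' end then
    sits at ``pos + len - 1``.
    """

    pos: int
    strand: str
    mismatches: int


def _match_at(template: str, probe: str, pos: int, max_mismatch: int,
              anchored_right: bool) -> int | None:
    """Mismatch count if probe matches at pos (3' anchor exact), else None."""
    n = len(probe)
    window = template[pos : pos + n]
    if len(window) < n:
        return None
    if anchored_right:
        if window[n - _ANCHOR :] != probe[n - _ANCHOR :]:
            return None
    else:
        if window[:_ANCHOR] != probe[:_ANCHOR]:
            return None
    mm = sum(a != b for a, b in zip(window, probe))
    return mm if mm <= max_mismatch else None


def find_primer_sites(
    sequence: str,
    primer: Primer,
    circular: bool = False,
    max_mismatch: int = 0,
) -> list[PrimerSite]:
    """All annealing sites of a primer on one template, both strands.

    Circular templates are searched on the doubled sequence and deduplicated
    modulo the template length, so origin-spanning sites are found once.
    """
    L = len(sequence)
    search = sequence * 2 if circular else sequence
    limit = L if circular else L - len(primer.sequence) + 1
    probe_fwd = primer.sequence
    probe_rev = revcomp(primer.sequence)
    sites: list[PrimerSite] = []
    if max_mismatch == 0:
        for probe, strand, anchored_right in ((probe_fwd, "+", True),
                                              (probe_rev, "-", False)):
            start = search.find(probe)
            while start != -1 and start < limit:
                sites.append(PrimerSite(pos=start % L, strand=strand, mismatches=0))
                start = search.find(probe, start + 1)
    else:
        for pos in range(max(0, limit)):
            mm = _match_at(search, probe_fwd, pos, max_mismatch, anchored_right=True)
            if mm is not None:
                sites.append(PrimerSite(pos=pos % L, strand="+", mismatches=mm))
            mm = _match_at(search, probe_rev, pos, max_mismatch, anchored_right=False)
            if mm is not None:
                sites.append(PrimerSite(pos=pos % L, strand="-", mismatches=mm))
    # dedup (possible when L < 2*len(primer) on circular templates)
    seen: set[tuple[int, str]] = set()
    unique = []
    for s in sites:
        key = (s.pos, s.strand)
        if key not in seen:
            seen.add(key)
            unique.append(s)
    return unique


@dataclass(frozen=True)
class Amplicon:
    sequence: str
    length: int
    fwd_site: PrimerSite
    rev_site: PrimerSite
    junctions_crossed: tuple[str, ...] = ()


def predict_amplicons(
    sequence: str,
    fwd: Primer,
    rev: Primer,
    circular: bool = False,
    max_len: int = 10000,
    max_mismatch: int = 0,
    junctions: Sequence[Junction] | None = None,
    junction_core: int = 10,
) -> list[Amplicon]:
    """Products of a primer pair on one template.

    Every (+ site of ``fwd``, - site of ``rev``) pair whose extension
    distance along the template is at most ``max_len`` yields one amplicon
    spanning from the forward primer 5' end to the reverse primer 5' end
    inclusive.  On a linear template a divergent pair has no downstream path
    and yields nothing; on a circular template the around-the-circle product
    is reported (shortest product per site pair only — no rolling-circle
    multimers).
    """
    if max_len <= max(len(fwd.sequence), len(rev.sequence)):
        raise InputError("max_len must exceed the primer lengths")
    L = len(sequence)
    lf, lr = len(fwd.sequence), len(rev.sequence)
    fwd_sites = [s for s in find_primer_sites(sequence, fwd, circular, max_mismatch)
                 if s.strand == "+"]
    rev_sites = [s for s in find_primer_sites(sequence, rev, circular, max_mismatch)
                 if s.strand == "-"]
    doubled = sequence * 2
    out: list[Amplicon] = []
    for fs in fwd_sites:
        for rs in rev_sites:
            rev5 = rs.pos + lr - 1  # template coordinate of rev primer 5' end
            if circular:
                amp_len = (rev5 - fs.pos) % L + 1
            else:
                if rs.pos < fs.pos + lf:  # no rightward path to the rev site
                    continue
                amp_len = rev5 - fs.pos + 1
            if amp_len < lf + lr or amp_len > max_len:
                continue
            if circular:
                amp_seq = (doubled * ((amp_len // L) + 1))[fs.pos : fs.pos + amp_len] \
                    if amp_len > 2 * L else doubled[fs.pos : fs.pos + amp_len]
            else:
                amp_seq = sequence[fs.pos : fs.pos + amp_len]
            crossed: list[str] = []
            if junctions:
                c = junction_core
                for j in junctions:
                    core = j.left_flank[-c:] + j.right_flank[:c]
                    if core in amp_seq or core in revcomp(amp_seq):
                        crossed.append(j.category)
            out.append(
                Amplicon(sequence=amp_seq, length=amp_len, fwd_site=fs,
                         rev_site=rs, junctions_crossed=tuple(dict.fromkeys(crossed)))
            )
    out.sort(key=lambda a: (a.length, a.fwd_site.pos))
    return out
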