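"""Model of an inversion locus: wild/inverted haplotypes and their breakpoint junctions.

The locus is a genomic segment carrying an invertible interval.  The wild
arrangement is called H1; the mutant arrangement H2 carries the interval in
reversed orientation and, mimicking non-homologous end joining, a small
deletion immediately upstream of the proximal breakpoint and a small
insertion at the distal breakpoint (defaults: "ACA" deleted, "GA" inserted).

Coordinates are 0-based and half-open throughout; the inverted interval on
H1 is ``[pb, db)``.  The deleted bases are the ``len(del_motif)`` bases of H1
immediately upstream of ``pb``; the insertion sits between the inverted
segment and the downstream flank on H2.

Four breakpoint junctions are derived from a haplotype pair and serve as
alignment targets for junction-spanning reads:

========  =========================================================
id        centred on
========  =========================================================
W_PB      the proximal breakpoint on H1 (wild)
W_DB      the distal breakpoint on H1 (wild)
M_PB      the proximal junction on H2 (mutant)
M_DB      the distal junction on H2 (mutant)
========  =========================================================
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "GenomeSegment",
    "InversionSpec",
    "HaplotypePair",
    "Junction",
    "JunctionSet",
    "MotifHit",
    "InvalidAlphabetError",
    "InvalidSpecError",
    "InvalidCdsError",
    "reverse_complement",
    "build_inverted_haplotype",
    "build_junction_set",
    "motif_scan",
    "cds_to_protein_length",
    "JUNCTION_IDS",
]

JUNCTION_IDS = ("W_PB", "W_DB", "M_PB", "M_DB")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_DNA_RE = re.compile(r"^[ACGT]*$")

#: IUPAC nucleotide codes and the bases each one matches.
IUPAC_CODES = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}


class InvalidAlphabetError(ValueError):
    """A sequence contains characters outside the expected alphabet."""


class InvalidSpecError(ValueError):
    """An inversion specification is internally inconsistent."""


class InvalidCdsError(ValueError):
    """A CDS length is not a valid codon multiple."""


def _check_dna(seq: str, what: str = "sequence") -> None:
    if not _DNA_RE.match(seq):
        bad = sorted(set(seq) - set("ACGT"))
        raise InvalidAlphabetError(f"{what} contains non-ACGT characters: {bad}")


@dataclass(frozen=True)
class GenomeSegment:
    """A named stretch of genomic DNA.

    ``origin_offset`` is the coordinate of ``seq[0]`` in an enclosing
    coordinate system (0-based), so slices of a chromosome keep track of
    where they came from.
    """

    id: str
    seq: str
    origin_offset: int = 0

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError("GenomeSegment.seq must be non-empty")
        _check_dna(self.seq, f"segment {self.id!r}")
        if self.origin_offset < 0:
            raise ValueError("origin_offset must be >= 0")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class InversionSpec:
    """Breakpoints of the inverted interval ``[pb, db)`` plus the indel signature."""

    pb: int
    db: int
    del_motif: str = "ACA"
    ins_motif: str = "GA"

    def __post_init__(self) -> None:
        _check_dna(self.del_motif, "del_motif")
        _check_dna(self.ins_motif, "ins_motif")
        if self.pb - len(self.del_motif) < 0:
            raise InvalidSpecError(
                f"pb={self.pb} leaves no room for the {len(self.del_motif)}-nt deletion"
            )
        if self.pb >= self.db:
            raise InvalidSpecError(f"pb={self.pb} must be < db={self.db}")


@dataclass(frozen=True)
class HaplotypePair:
    """The wild (H1) and inverted (H2) haplotypes of one locus.

    ``pb2``/``db2`` are the H2 coordinates of the proximal and distal
    junctions: ``pb2 = pb - len(del_motif)`` and
    ``db2 = pb2 + (db - pb) + len(ins_motif)``.
    """

    h1: GenomeSegment
    h2: GenomeSegment
    spec: InversionSpec
    pb2: int = field(init=False)
    db2: int = field(init=False)

    def __post_init__(self) -> None:
        s = self.spec
        object.__setattr__(self, "pb2", s.pb - len(s.del_motif))
        object.__setattr__(self, "db2", self.pb2 + (s.db - s.pb) + len(s.ins_motif))
        expect = len(self.h1.seq) - len(s.del_motif) + len(s.ins_motif)
        if len(self.h2.seq) != expect:
            raise InvalidSpecError(
                f"H2 length {len(self.h2.seq)} inconsistent with H1 and indels ({expect})"
            )


@dataclass(frozen=True)
class Junction:
    """A short reference sequence centred on a breakpoint.

    ``center`` is the 0-based boundary index of the breakpoint within
    ``seq`` (a position *between* bases, so ``0 < center < len(seq)``).
    """

    id: str
    seq: str
    center: int
    flank: int

    def __post_init__(self) -> None:
        if self.id not in JUNCTION_IDS:
            raise ValueError(f"unknown junction id {self.id!r}")
        if not (0 < self.center < len(self.seq)):
            raise ValueError("junction center must lie strictly inside seq")
        if len(self.seq) > 2 * self.flank:
            raise ValueError("junction longer than 2*flank")


@dataclass(frozen=True)
class JunctionSet:
    """Exactly four junctions, one per id, all with the same nominal flank."""

    junctions: tuple[Junction, Junction, Junction, Junction]

    def __post_init__(self) -> None:
        ids = tuple(j.id for j in self.junctions)
        if sorted(ids) != sorted(JUNCTION_IDS):
            raise ValueError(f"junction ids must be exactly {JUNCTION_IDS}, got {ids}")
        if len({j.flank for j in self.junctions}) != 1:
            raise ValueError("all junctions must share one flank size")

    def __iter__(self):
        return iter(self.junctions)

    def __getitem__(self, junction_id: str) -> Junction:
        for j in self.junctions:
            if j.id == junction_id:
                return j
        raise KeyError(junction_id)

    @property
    def flank(self) -> int:
        return self.junctions[0].flank


@dataclass(frozen=True)
class MotifHit:
    motif: str
    pos: int
    strand: str  # '+' or '-'


def reverse_complement(seq: str) -> str:
    """Reverse complement of an A/C/G/T string (involution; '' -> '')."""
    _check_dna(seq)
    return seq.translate(_COMPLEMENT)[::-1]


def build_inverted_haplotype(h1: GenomeSegment, spec: InversionSpec) -> HaplotypePair:
    """Construct the mutant haplotype H2 from H1 and an inversion spec.

    H2 = H1 upstream flank (minus the deleted bases) + reverse complement of
    the inverted interval + the inserted bases + H1 downstream flank::

        h2 = h1[0 : pb-len(del)] + revcomp(h1[pb:db]) + ins + h1[db:]

    The bases at ``h1[pb-len(del) : pb]`` must equal ``del_motif`` — the
    deletion removes real reference bases.
    """
    seq = h1.seq
    if spec.db > len(seq):
        raise InvalidSpecError(f"db={spec.db} beyond end of H1 ({len(seq)})")
    p = spec.pb - len(spec.del_motif)
    found = seq[p : spec.pb]
    if found != spec.del_motif:
        raise InvalidSpecError(
            f"expected deleted bases {spec.del_motif!r} at H1[{p}:{spec.pb}], found {found!r}"
        )
    h2_seq = seq[:p] + reverse_complement(seq[spec.pb : spec.db]) + spec.ins_motif + seq[spec.db :]
    h2 = GenomeSegment(id=f"{h1.id}_H2", seq=h2_seq, origin_offset=h1.origin_offset)
    return HaplotypePair(h1=h1, h2=h2, spec=spec)


def _window(seq: str, center: int, flank: int) -> tuple[str, int]:
    """Clip a ±flank window around a boundary; returns (subseq, adjusted center)."""
    start = max(0, center - flank)
    end = min(len(seq), center + flank)
    return seq[start:end], center - start


def build_junction_set(pair: HaplotypePair, flank: int) -> JunctionSet:
    """Extract the four breakpoint junction references from a haplotype pair.

    Windows are clipped (never padded) at sequence ends; the stored center
    index shifts accordingly.
    """
    if flank < 1:
        raise ValueError("flank must be >= 1")
    spec = pair.spec
    pieces = (
        ("W_PB", pair.h1.seq, spec.pb),
        ("W_DB", pair.h1.seq, spec.db),
        ("M_PB", pair.h2.seq, pair.pb2),
        ("M_DB", pair.h2.seq, pair.db2),
    )
    junctions = []
    for jid, seq, c in pieces:
        sub, center = _window(seq, c, flank)
        junctions.append(Junction(id=jid, seq=sub, center=center, flank=flank))
    return JunctionSet(junctions=tuple(junctions))


def _iupac_regex(motif: str) -> re.Pattern:
    parts = []
    for ch in motif:
        try:
            parts.append(f"[{IUPAC_CODES[ch]}]")
        except KeyError:
            raise InvalidAlphabetError(f"invalid IUPAC code {ch!r} in motif {motif!r}") from None
    # lookahead so overlapping occurrences are all reported
    return re.compile(f"(?=({''.join(parts)}))")


def motif_scan(seq: str, motifs: list[str], both_strands: bool = False) -> list[MotifHit]:
    """Report every position where an IUPAC motif matches ``seq``.

    With ``both_strands`` the reverse complement is scanned too and hits are
    reported on the '-' strand with positions in ``seq`` coordinates (0-based
    start of the covered interval).  Hits are sorted by position then strand.
    """
    _check_dna(seq)
    hits: list[MotifHit] = []
    for motif in motifs:
        motif = motif.upper()
        pat = _iupac_regex(motif)
        for m in pat.finditer(seq):
            hits.append(MotifHit(motif=motif, pos=m.start(), strand="+"))
        if both_strands:
            rc = reverse_complement(seq)
            for m in pat.finditer(rc):
                pos = len(seq) - m.start() - len(motif)
                hits.append(MotifHit(motif=motif, pos=pos, strand="-"))
    hits.sort(key=lambda h: (h.pos, h.strand, h.motif))
    return hits


def cds_to_protein_length(cds_len_bp: int) -> int:
    """Protein length (residues) encoded by a CDS that includes its stop codon."""
    if cds_len_bp <= 3 or cds_len_bp % 3 != 0:
        raise InvalidCdsError(f"CDS length {cds_len_bp} is not a codon multiple > 3")
    return cds_len_bp // 3 - 1
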