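"""Diploid inversion genotyping and split-read breakpoint refinement.

Two independent genotyping routes are implemented, mirroring how the locus
was assayed in practice:

* **sequencing-based** — tally junction-spanning reads; an allele is deemed
  present only when *both* of its junctions (proximal and distal) have at
  least ``min_reads`` spanning reads.  Both alleles present -> H1H2, only
  wild -> H1H1, only inverted -> H2H2, neither -> no call.
* **PCR-based** — three primer pairs: P1 spans the wild proximal breakpoint
  (amplifies H1 only); P2 and P3 span the mutant proximal and distal
  junctions (amplify H2 only).  Band patterns map directly to genotypes.

Breakpoint refinement recovers the inversion boundaries on the wild
reference from long reads that switch orientation: the read is split at the
index maximising forward-strand matches of its prefix plus reverse-strand
matches of its suffix, within user-supplied search windows bracketing the
two candidate junctions.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .haplotype_model import GenomeSegment, HaplotypePair, JunctionSet, reverse_complement
from .read_alignment import UNINFORMATIVE, JunctionAligner, SupportLabel
from .synthetic_data import Accession, SimulatedRead

__all__ = [
    "JunctionSupport",
    "GenotypeCall",
    "PrimerPair",
    "PcrPattern",
    "PcrAssay",
    "ReadBreakpoint",
    "RefineResult",
    "tally_support",
    "call_genotype",
    "genotype_from_reads",
    "insilico_pcr",
    "pcr_genotype",
    "design_assay",
    "genotype_by_pcr",
    "refine_breakpoints",
]

NO_CALL = "no_call"


@dataclass(frozen=True)
class JunctionSupport:
    """Spanning-read counts per junction for one accession."""

    n_wpb: int = 0
    n_wdb: int = 0
    n_mpb: int = 0
    n_mdb: int = 0
    n_uninformative: int = 0

    def __post_init__(self) -> None:
        if min(self.n_wpb, self.n_wdb, self.n_mpb, self.n_mdb, self.n_uninformative) < 0:
            raise ValueError("counts must be non-negative")


@dataclass(frozen=True)
class GenotypeCall:
    accession_id: str
    genotype: str  # H1H1 / H1H2 / H2H2 / no_call
    support: JunctionSupport
    reason: str = ""


@dataclass(frozen=True)
class PrimerPair:
    """A PCR primer pair; ``rev`` is given 5'->3' on the opposite strand."""

    id: str
    fwd: str
    rev: str
    max_amplicon: int = 2000
    min_len: int = 15  # lowered only in toy tests

    def __post_init__(self) -> None:
        if min(len(self.fwd), len(self.rev)) < self.min_len:
            raise ValueError(f"primers of pair {self.id!r} shorter than {self.min_len}")


@dataclass(frozen=True)
class PcrPattern:
    p1: bool
    p2: bool
    p3: bool


@dataclass(frozen=True)
class PcrAssay:
    """The three primer pairs of the diagnostic assay."""

    p1: PrimerPair
    p2: PrimerPair
    p3: PrimerPair


def tally_support(labels: list[SupportLabel]) -> JunctionSupport:
    c = Counter(lab.label for lab in labels)
    return JunctionSupport(
        n_wpb=c["W_PB"], n_wdb=c["W_DB"], n_mpb=c["M_PB"], n_mdb=c["M_DB"],
        n_uninformative=c[UNINFORMATIVE],
    )


def call_genotype(support: JunctionSupport, min_reads: int = 3,
                  accession_id: str = "") -> GenotypeCall:
    """Decision rule: an allele is present iff both of its junctions are supported."""
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    h1 = support.n_wpb >= min_reads and support.n_wdb >= min_reads
    h2 = support.n_mpb >= min_reads and support.n_mdb >= min_reads
    if h1 and h2:
        g, reason = "H1H2", ""
    elif h1:
        g, reason = "H1H1", ""
    elif h2:
        g, reason = "H2H2", ""
    else:
        g, reason = NO_CALL, "insufficient junction support"
    return GenotypeCall(accession_id=accession_id, genotype=g, support=support, reason=reason)


def genotype_from_reads(
    reads,
    junctions: JunctionSet,
    k: int = 15,
    max_mismatch_frac: float = 0.1,
    min_overhang: int = 15,
    min_identity: float = 0.9,
    min_reads: int = 3,
    accession_id: str = "",
    aligner: JunctionAligner | None = None,
) -> GenotypeCall:
    """Sequencing-based genotyping of one accession from its reads.

    ``reads`` may be :class:`~flatpeach.synthetic_data.SimulatedRead`
    objects, (id, seq) tuples, or bare sequences; paired reads are
    classified independently (mate information is not used).
    """
    if aligner is None:
        aligner = JunctionAligner(junctions, k=k, max_mismatch_frac=max_mismatch_frac)
    labels = []
    for i, r in enumerate(reads):
        if isinstance(r, SimulatedRead):
            rid, seq = r.id, r.seq
        elif isinstance(r, tuple):
            rid, seq = r
        else:
            rid, seq = f"read_{i}", r
        labels.append(aligner.classify(seq, read_id=rid,
                                       min_overhang=min_overhang,
                                       min_identity=min_identity))
    return call_genotype(tally_support(labels), min_reads=min_reads,
                         accession_id=accession_id)


# -- in-silico PCR ---------------------------------------------------------


def _binding_sites(primer: str, template: str, max_mismatches: int,
                   three_prime_exact: int, three_prime_left: bool) -> list[int]:
    """Start positions where ``primer`` (written on the forward strand) binds.

    ``three_prime_left`` marks primers whose 3' end is the left end of the
    written sequence (the case for a reverse primer's forward-strand image).
    """
    n, m = len(template), len(primer)
    sites = []
    for i in range(n - m + 1):
        window = template[i : i + m]
        mm = sum(a != b for a, b in zip(window, primer))
        if mm > max_mismatches:
            continue
        tp = window[:three_prime_exact] if three_prime_left else window[-three_prime_exact:]
        pp = primer[:three_prime_exact] if three_prime_left else primer[-three_prime_exact:]
        if tp == pp:
            sites.append(i)
    return sites


def insilico_pcr(
    primers: PrimerPair,
    template: GenomeSegment | str,
    max_mismatches: int = 0,
    three_prime_exact: int = 3,
) -> tuple[bool, int | None]:
    """Predict whether a primer pair amplifies a template, and the product size.

    A product exists when the forward primer binds the forward strand and
    the reverse primer binds the opposite strand downstream of it (or the
    mirrored arrangement on the other template orientation), each with at
    most ``max_mismatches`` substitutions, an exact 3'-terminal
    ``three_prime_exact`` bases, and a product no longer than
    ``max_amplicon``.  Returns ``(present, shortest_product_length)``.
    """
    seq = template.seq if isinstance(template, GenomeSegment) else template
    best: int | None = None
    for fwd, rev in ((primers.fwd, primers.rev), (primers.rev, primers.fwd)):
        f_sites = _binding_sites(fwd, seq, max_mismatches, three_prime_exact, False)
        r_image = reverse_complement(rev)
        r_sites = _binding_sites(r_image, seq, max_mismatches, three_prime_exact, True)
        if not f_sites or not r_sites:
            continue
        r_ends = sorted(j + len(r_image) for j in r_sites)
        for i in f_sites:
            # shortest product whose reverse site lies at/after the forward site
            for end in r_ends:
                length = end - i
                if length >= max(len(fwd), len(r_image)) and end - len(r_image) >= i:
                    if length <= primers.max_amplicon and (best is None or length < best):
                        best = length
                    break
    return best is not None, best


def pcr_genotype(pattern: PcrPattern, accession_id: str = "") -> GenotypeCall:
    """Genotype from the three-band pattern (P1 = H1; P2 and P3 = H2)."""
    key = (pattern.p1, pattern.p2, pattern.p3)
    mapping = {
        (True, False, False): "H1H1",
        (True, True, True): "H1H2",
        (False, True, True): "H2H2",
    }
    g = mapping.get(key)
    if g is None:
        return GenotypeCall(accession_id=accession_id, genotype=NO_CALL,
                            support=JunctionSupport(), reason="inconsistent band pattern")
    return GenotypeCall(accession_id=accession_id, genotype=g, support=JunctionSupport())


def design_assay(pair: HaplotypePair, primer_len: int = 20, offset: int = 40,
                 max_amplicon: int = 500) -> PcrAssay:
    """Design the three diagnostic primer pairs from a haplotype pair.

    Each pair straddles one junction with primers ``offset`` bases away from
    it: P1 the wild proximal breakpoint on H1, P2 and P3 the mutant proximal
    and distal junctions on H2.  Amplification across a junction fails on
    the other haplotype because the inward-facing primer's binding site is
    carried away (or re-oriented) by the inversion.
    """
    h1, h2 = pair.h1.seq, pair.h2.seq
    pb, db = pair.spec.pb, pair.spec.db
    pb2, db2 = pair.pb2, pair.db2

    def cut(seq, end):  # primer ending just before coordinate `end`
        return seq[end - primer_len : end]

    def cut_rev(seq, start):  # reverse primer whose forward-strand image starts at `start`
        return reverse_complement(seq[start : start + primer_len])

    p1 = PrimerPair("P1", fwd=cut(h1, pb - offset), rev=cut_rev(h1, pb + offset),
                    max_amplicon=max_amplicon)
    p2 = PrimerPair("P2", fwd=cut(h2, pb2 - offset), rev=cut_rev(h2, pb2 + offset),
                    max_amplicon=max_amplicon)
    p3 = PrimerPair("P3", fwd=cut(h2, db2 - offset), rev=cut_rev(h2, db2 + offset),
                    max_amplicon=max_amplicon)
    return PcrAssay(p1=p1, p2=p2, p3=p3)


def genotype_by_pcr(acc: Accession, assay: PcrAssay,
                    max_mismatches: int = 0) -> tuple[GenotypeCall, PcrPattern]:
    """PCR-based genotyping: a band is present if either haplotype amplifies."""
    bands = []
    for primers in (assay.p1, assay.p2, assay.p3):
        present = any(
            insilico_pcr(primers, hap, max_mismatches=max_mismatches)[0]
            for hap in (acc.hapA, acc.hapB)
        )
        bands.append(present)
    pattern = PcrPattern(*bands)
    return pcr_genotype(pattern, accession_id=acc.id), pattern


# -- breakpoint refinement from split long reads ---------------------------


@dataclass(frozen=True)
class ReadBreakpoint:
    read_id: str
    u: int  # proximal-window coordinate (forward/reverse switch on H1)
    v: int  # distal-window coordinate
    score: int  # total matching bases across the two parts


@dataclass
class RefineResult:
    per_read: list[ReadBreakpoint] = field(default_factory=list)
    no_estimate: list[str] = field(default_factory=list)  # read ids
    consensus_u: int | None = None
    consensus_v: int | None = None


def _kmer_positions(seq: str, k: int) -> dict[str, list[int]]:
    d: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        d.setdefault(seq[i : i + k], []).append(i)
    return d


def _top_diagonals(seq: str, index: dict[str, list[int]], k: int, cap: int) -> list[int]:
    counts: Counter = Counter()
    for i in range(len(seq) - k + 1):
        entry = index.get(seq[i : i + k])
        if entry:
            for pos in entry:
                counts[pos - i] += 1
    return [d for d, _ in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:cap]]


def _mode(values: list[int]) -> int:
    c = Counter(values)
    return sorted(c.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]


def refine_breakpoints(
    long_reads,
    h1: GenomeSegment,
    search_window: tuple[tuple[int, int], tuple[int, int]],
    k: int = 13,
    min_part: int = 20,
    min_part_identity: float = 0.8,
    max_diagonals: int = 6,
) -> RefineResult:
    """Estimate inversion boundaries on H1 from orientation-switching long reads.

    For each read (in both orientations) the split index ``s`` maximising
    forward-strand matches of ``read[:s]`` plus reverse-strand matches of
    ``read[s:]`` is found over seeded diagonals, subject to: the forward
    part's junction-side end and the reverse part's junction-side boundary
    fall one in each search window, and each part has at least ``min_part``
    matching bases at ``min_part_identity`` or better.  Tie splits are
    left-aligned (lowest proximal coordinate).  The per-read estimate is
    ``(u, v)``: the proximal-window and distal-window H1 coordinates of the
    orientation switch.  The consensus is the per-coordinate majority.

    With the default deletion signature the proximal junction is only
    observable at ``pb - len(del_motif)``, so the expected consensus for a
    planted inversion is ``(pb - 3, db)``.
    """
    (w1_lo, w1_hi), (w2_lo, w2_hi) = search_window
    ref = h1.seq
    n_ref = len(ref)
    rc_ref = reverse_complement(ref)
    fwd_index = _kmer_positions(ref, k)
    rc_index = _kmer_positions(rc_ref, k)
    ref_arr = np.frombuffer(ref.encode(), dtype=np.uint8)
    rc_arr = np.frombuffer(rc_ref.encode(), dtype=np.uint8)

    result = RefineResult()
    for idx, r in enumerate(long_reads):
        if isinstance(r, SimulatedRead):
            rid, seq = r.id, r.seq
        elif isinstance(r, tuple):
            rid, seq = r
        else:
            rid, seq = f"read_{idx}", r
        best: tuple | None = None  # (-score, u, v)
        for oriented in (seq, reverse_complement(seq)):
            L = len(oriented)
            if L < k:
                continue
            read_arr = np.frombuffer(oriented.encode(), dtype=np.uint8)
            for df in _top_diagonals(oriented, fwd_index, k, max_diagonals):
                F = np.zeros(L, dtype=bool)
                j0, j1 = max(0, -df), min(L, n_ref - df)
                if j1 > j0:
                    F[j0:j1] = read_arr[j0:j1] == ref_arr[j0 + df : j1 + df]
                Pc = np.concatenate(([0], np.cumsum(F)))
                for dr in _top_diagonals(oriented, rc_index, k, max_diagonals):
                    R = np.zeros(L, dtype=bool)
                    i0, i1 = max(0, -dr), min(L, n_ref - dr)
                    if i1 > i0:
                        R[i0:i1] = read_arr[i0:i1] == rc_arr[i0 + dr : i1 + dr]
                    Rc = np.concatenate(([0], np.cumsum(R)))
                    s = np.arange(L + 1)
                    pre = Pc
                    suf = Rc[-1] - Rc
                    u_f = df + s  # forward part junction-side end (H1 coord)
                    v_r = n_ref - dr - s  # reverse part junction-side boundary (H1 coord)
                    with np.errstate(divide="ignore", invalid="ignore"):
                        pre_id = np.where(s > 0, pre / np.maximum(s, 1), 0.0)
                        suf_id = np.where(s < L, suf / np.maximum(L - s, 1), 0.0)
                    ok_parts = (
                        (pre >= min_part) & (suf >= min_part)
                        & (pre_id >= min_part_identity) & (suf_id >= min_part_identity)
                    )
                    case_a = ok_parts & (u_f >= w1_lo) & (u_f < w1_hi) \
                        & (v_r >= w2_lo) & (v_r < w2_hi)
                    case_b = ok_parts & (u_f >= w2_lo) & (u_f < w2_hi) \
                        & (v_r >= w1_lo) & (v_r < w1_hi)
                    total = pre + suf
                    for mask, u_arr, v_arr in (
                        (case_a, u_f, v_r),  # forward part sits at the proximal side
                        (case_b, v_r, u_f),  # mirrored read orientation
                    ):
                        if not mask.any():
                            continue
                        cand = np.flatnonzero(mask)
                        t = total[cand]
                        top = cand[t == t.max()]
                        # left-align: among equal scores take the lowest proximal coord
                        pick = top[np.argmin(u_arr[top])]
                        key = (-int(total[pick]), int(u_arr[pick]), int(v_arr[pick]))
                        if best is None or key < best:
                            best = key
        if best is None:
            result.no_estimate.append(rid)
        else:
            result.per_read.append(
                ReadBreakpoint(read_id=rid, u=best[1], v=best[2], score=-best[0])
            )
    if result.per_read:
        result.consensus_u = _mode([e.u for e in result.per_read])
        result.consensus_v = _mode([e.v for e in result.per_read])
    return result
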