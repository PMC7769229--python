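"""Ungapped seed-and-extend alignment of reads against breakpoint junctions.

Reads are aligned to the four junction references (W_PB, W_DB, M_PB, M_DB)
by exact k-mer seeding followed by greedy ungapped extension, and classified
as *spanning* support for one junction — evidence for the wild or inverted
haplotype — or as uninformative.  A hit spans its junction when the aligned
interval covers the breakpoint with at least ``min_overhang`` bases on both
sides at ``min_identity`` or better; ambiguous reads (ties across junctions)
are conservatively left uninformative, which prevents haplotype miscalls at
the shared flanks.

Alignment is ungapped on purpose: the inversion signature at junction scale
is substitution-free and the bundled read simulator emits no indels.  Real
indel-bearing reads would need a gapped aligner; that limitation is
documented rather than papered over.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .haplotype_model import JunctionSet, reverse_complement

__all__ = [
    "AlignmentHit",
    "SupportLabel",
    "JunctionAligner",
    "seed_and_extend",
    "classify_read",
    "classify_hits",
]

UNINFORMATIVE = "uninformative"


@dataclass(frozen=True)
class AlignmentHit:
    """An ungapped local alignment of a read against one junction reference.

    ``read_start``/``read_end`` are coordinates on the read in the aligned
    orientation (i.e. on the reverse complement of the read for '-' hits).
    """

    read_id: str
    junction_id: str
    ref_start: int
    ref_end: int
    read_start: int
    read_end: int
    strand: str
    matches: int
    mismatches: int

    @property
    def identity(self) -> float:
        return self.matches / (self.matches + self.mismatches)

    def __post_init__(self) -> None:
        if self.ref_end - self.ref_start != self.read_end - self.read_start:
            raise ValueError("ungapped hit must have equal ref and read spans")


@dataclass(frozen=True)
class SupportLabel:
    read_id: str
    label: str  # junction id or 'uninformative'
    left_overhang: int = 0
    right_overhang: int = 0


class JunctionAligner:
    """Reusable aligner holding a k-mer index over one junction set.

    Building the index once and reusing it across a read set is what makes
    whole-accession genotyping cheap; the module-level function
    :func:`seed_and_extend` constructs a throwaway instance.
    """

    def __init__(self, junctions: JunctionSet, k: int = 15, max_mismatch_frac: float = 0.1):
        if k < 8:
            raise ValueError("k must be >= 8")
        if not 0 <= max_mismatch_frac <= 1:
            raise ValueError("max_mismatch_frac must be in [0, 1]")
        self.junctions = junctions
        self.k = k
        self.max_mismatch_frac = max_mismatch_frac
        self._seqs = [j.seq for j in junctions]
        self._ids = [j.id for j in junctions]
        index: dict[str, list[tuple[int, int]]] = {}
        for jx, seq in enumerate(self._seqs):
            for pos in range(len(seq) - k + 1):
                index.setdefault(seq[pos : pos + k], []).append((jx, pos))
        self._index = index

    # -- alignment ---------------------------------------------------------

    def _extend(self, read: str, jx: int, diag: int, seed_pos: int) -> tuple[int, ...]:
        """Optimal ungapped extension from the leftmost seed on one diagonal.

        The hit is the best-scoring contiguous window containing the seed,
        with match +1 and mismatch -(1/max_mismatch_frac - 1): no extension
        segment whose local mismatch fraction exceeds ``max_mismatch_frac``
        is ever worth including, so isolated sequencing errors are crossed
        but low-identity tails (e.g. sequence beyond a breakpoint the read
        does not carry) are excluded.  Ties prefer the longer window, which
        maximises matches.  Returns (read_start, read_end, matches,
        mismatches).
        """
        ref = self._seqs[jx]
        lo = max(0, -diag)
        hi = min(len(read), len(ref) - diag)
        frac = self.max_mismatch_frac
        penalty = (1.0 / frac - 1.0) if frac > 0 else float("inf")

        left = seed_pos
        run = best = 0.0
        i = seed_pos - 1
        while i >= lo:
            run += 1.0 if read[i] == ref[i + diag] else -penalty
            if run >= best:
                best, left = run, i
            i -= 1

        right = seed_pos + self.k
        run = best = 0.0
        i = right
        while i < hi:
            run += 1.0 if read[i] == ref[i + diag] else -penalty
            if run >= best:
                best, right = run, i + 1
            i += 1

        mm = sum(read[i] != ref[i + diag] for i in range(left, right))
        return left, right, (right - left) - mm, mm

    def align(self, seq: str, read_id: str = "read") -> list[AlignmentHit]:
        """Best hit per junction over both strands (at most four hits)."""
        k = self.k
        if len(seq) < k:
            warnings.warn(f"read {read_id!r} shorter than k={k}; no alignment attempted")
            return []
        best: dict[int, AlignmentHit] = {}
        for strand, oriented in (("+", seq), ("-", reverse_complement(seq))):
            seen: dict[tuple[int, int], int] = {}
            n = len(oriented) - k + 1
            index = self._index
            for i in range(n):
                entry = index.get(oriented[i : i + k])
                if entry:
                    for jx, pos in entry:
                        key = (jx, pos - i)
                        if key not in seen:
                            seen[key] = i
            for (jx, diag), seed_pos in seen.items():
                left, right, matches, mm = self._extend(oriented, jx, diag, seed_pos)
                hit = AlignmentHit(
                    read_id=read_id, junction_id=self._ids[jx],
                    ref_start=left + diag, ref_end=right + diag,
                    read_start=left, read_end=right,
                    strand=strand, matches=matches, mismatches=mm,
                )
                cur = best.get(jx)
                if cur is None or _hit_order(hit) < _hit_order(cur):
                    best[jx] = hit
        return [best[jx] for jx in sorted(best)]

    def classify(
        self, seq: str, read_id: str = "read",
        min_overhang: int = 15, min_identity: float = 0.9,
    ) -> SupportLabel:
        return classify_read(self.align(seq, read_id), self.junctions,
                             min_overhang=min_overhang, min_identity=min_identity,
                             read_id=read_id)


def _hit_order(h: AlignmentHit) -> tuple:
    """Deterministic preference: more matches, then '+' strand, then leftmost."""
    return (-h.matches, h.strand, h.ref_start)


def seed_and_extend(
    seq: str,
    junctions: JunctionSet,
    k: int = 15,
    max_mismatch_frac: float = 0.1,
    read_id: str = "read",
) -> list[AlignmentHit]:
    """One-shot alignment of a single read; see :class:`JunctionAligner`."""
    return JunctionAligner(junctions, k=k, max_mismatch_frac=max_mismatch_frac).align(
        seq, read_id=read_id
    )


def classify_hits(
    hits: list[AlignmentHit],
    junctions: JunctionSet,
    min_overhang: int = 15,
    min_identity: float = 0.9,
) -> tuple[str, int, int]:
    """Core spanning rule; returns (label, left_overhang, right_overhang)."""
    spanning = []
    for h in hits:
        center = junctions[h.junction_id].center
        left = center - h.ref_start
        right = h.ref_end - center
        if left >= min_overhang and right >= min_overhang and h.identity >= min_identity:
            spanning.append((h, left, right))
    if not spanning:
        return UNINFORMATIVE, 0, 0
    best_matches = max(h.matches for h, _, _ in spanning)
    top = [(h, l, r) for h, l, r in spanning if h.matches == best_matches]
    if len({h.junction_id for h, _, _ in top}) > 1:
        # tie across junctions: ambiguous, e.g. palindromic or shared-flank reads
        return UNINFORMATIVE, 0, 0
    h, left, right = top[0]
    return h.junction_id, left, right


def classify_read(
    hits: list[AlignmentHit],
    junctions: JunctionSet,
    min_overhang: int = 15,
    min_identity: float = 0.9,
    read_id: str | None = None,
) -> SupportLabel:
    """Label one read's hits as support for a single junction, or uninformative.

    A hit *spans* its junction if the aligned reference interval covers
    ``[center - min_overhang, center + min_overhang)`` at identity
    ``>= min_identity``.  The unique spanning hit with the most matches
    wins; ties across junction ids yield ``uninformative``.
    """
    if read_id is None:
        read_id = hits[0].read_id if hits else "read"
    label, left, right = classify_hits(hits, junctions, min_overhang, min_identity)
    return SupportLabel(read_id=read_id, label=label,
                        left_overhang=left, right_overhang=right)
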