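"""Synthetic data generators emulating the study design of a flat-fruit inversion locus.

Everything downstream of this module (alignment, genotyping, association,
expression screening) is exercised on data produced here: a random reference
segment with a planted invertible interval, diploid accessions whose
phenotype is a deterministic function of inversion genotype (round = H1H1,
flat = H1H2, fruit-aborted = H2H2), paired-end and long reads with truth
labels, a biallelic SNP panel with group-specific alternative-allele
frequencies, and negative-binomial RNA-seq counts with one planted
activated gene.

All generators are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .haplotype_model import (
    GenomeSegment,
    HaplotypePair,
    InversionSpec,
    reverse_complement,
)

__all__ = [
    "Accession",
    "SimulatedRead",
    "SnpPanel",
    "ExpressionSim",
    "PHENOTYPE_BY_GENOTYPE",
    "GENOTYPES",
    "generate_reference",
    "plant_inversion_site",
    "make_accession",
    "simulate_cross",
    "simulate_short_reads",
    "simulate_long_reads",
    "simulate_snp_panel",
    "simulate_expression_counts",
    "classify_fruit_shape",
]

GENOTYPES = ("H1H1", "H1H2", "H2H2")

#: Complete dominance of flat plus homozygote fruit abortion, as observed in
#: all crosses and cultivar panels; no penetrance parameter.
PHENOTYPE_BY_GENOTYPE = {"H1H1": "round", "H1H2": "flat", "H2H2": "aborted"}

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_QUAL30 = "?"  # constant Phred-30 quality; classification ignores quality


@dataclass
class Accession:
    """A diploid individual: two haplotype sequences plus the phenotype implied by genotype."""

    id: str
    genotype: str
    hapA: GenomeSegment
    hapB: GenomeSegment
    phenotype: str = field(init=False)

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ValueError(f"unknown genotype {self.genotype!r}")
        self.phenotype = PHENOTYPE_BY_GENOTYPE[self.genotype]


@dataclass
class SimulatedRead:
    """A simulated read with ground-truth origin for validation."""

    id: str
    seq: str
    qual: str
    mate: int | None  # 1, 2 or None for single-end
    truth_hap: str  # 'A' or 'B'
    truth_pos: int
    truth_strand: str  # '+' or '-'

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.qual):
            raise ValueError("seq and qual lengths differ")


@dataclass
class SnpPanel:
    """Biallelic SNP dosages (0/1/2 alternative-allele copies) for two phenotype groups."""

    positions: np.ndarray  # (n_snps,)
    genotypes: np.ndarray  # (n_accessions, n_snps) int dosages
    group: list[str]  # per-accession 'flat' or 'round'

    def __post_init__(self) -> None:
        if self.genotypes.shape[0] != len(self.group):
            raise ValueError("genotype rows must match group labels")
        if self.genotypes.shape[1] != len(self.positions):
            raise ValueError("genotype columns must match positions")
        if not np.isin(self.genotypes, (0, 1, 2)).all():
            raise ValueError("dosages must be in {0,1,2}")


@dataclass
class ExpressionSim:
    """Simulated RNA-seq counts with one planted differentially expressed gene."""

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray  # (n_genes, n_samples) non-negative ints
    gene_lengths: np.ndarray  # bp, >= 1
    group: list[str]  # per-sample 'FP' or 'RP'
    planted_gene: str
    planted_log2fc: float


def generate_reference(length: int, gc: float = 0.42, seed: int = 0) -> GenomeSegment:
    """An i.i.d. random reference segment with the requested GC fraction."""
    if length < 100:
        raise ValueError(f"reference length {length} too short (need >= 100)")
    if not 0 < gc < 1:
        raise ValueError("gc must be in (0, 1)")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq = rng.choice(_BASES, size=length, p=p).tobytes().decode()
    return GenomeSegment(id=f"ref_{length}bp", seq=seq)


def plant_inversion_site(
    segment: GenomeSegment,
    pb: int,
    db: int,
    del_motif: str = "ACA",
    ins_motif: str = "GA",
) -> tuple[GenomeSegment, InversionSpec]:
    """Overwrite the bases upstream of ``pb`` with the deletion motif.

    After planting, :func:`~flatpeach.haplotype_model.build_inverted_haplotype`
    is guaranteed to find the deleted bases where it expects them.

    Planting also breaks any microhomology across the proximal junction, so
    that the planted breakpoints are the *unique* (canonical) representation
    of the inversion: an inversion whose junction carries k bases of
    microhomology is only localisable to a k-bp interval, and exact
    truth-vs-estimate comparison would otherwise be ill-defined.  At most
    two reference bases adjacent to the junction are substituted, chosen
    deterministically.
    """
    if not (len(del_motif) <= pb < db <= len(segment.seq)):
        raise ValueError(f"breakpoints (pb={pb}, db={db}) out of range for planting")
    p = pb - len(del_motif)
    seq = list(segment.seq[:p] + del_motif + segment.seq[pb:])
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    # representations (u, v) and (u-1, v+1) of the junction coincide iff
    # seq[u-1] == complement(seq[v]); break both one-step equivalences at
    # the planted boundaries (u, v) = (p, db).
    if p >= 1 and db < len(seq) and seq[p - 1] == comp[seq[db]]:
        seq[p - 1] = next(b for b in "ACGT" if b != comp[seq[db]])
    if db - 1 > p and seq[p] == comp[seq[db - 1]]:
        seq[db - 1] = next(b for b in "ACGT" if b != comp[seq[p]])
    planted = GenomeSegment(id=segment.id, seq="".join(seq),
                            origin_offset=segment.origin_offset)
    return planted, InversionSpec(pb=pb, db=db, del_motif=del_motif, ins_motif=ins_motif)


def make_accession(acc_id: str, genotype: str, pair: HaplotypePair) -> Accession:
    """Instantiate a diploid accession with haplotype sequences matching its genotype."""
    alleles = (genotype[:2], genotype[2:])
    haps = []
    for which, allele in zip("AB", alleles):
        src = pair.h1 if allele == "H1" else pair.h2
        haps.append(GenomeSegment(id=f"{acc_id}_{which}_{allele}", seq=src.seq,
                                  origin_offset=src.origin_offset))
    return Accession(id=acc_id, genotype=genotype, hapA=haps[0], hapB=haps[1])


def simulate_cross(
    parent1: str,
    parent2: str,
    n: int,
    seed: int = 0,
    pair: HaplotypePair | None = None,
    id_prefix: str = "F1",
) -> list[Accession] | list[tuple[str, str, str]]:
    """F1 progeny of a cross: one uniformly random allele from each parent.

    With ``pair`` given, full :class:`Accession` objects (carrying haplotype
    sequences) are returned; otherwise light ``(id, genotype, phenotype)``
    tuples, which is all the segregation statistics need.
    """
    for g in (parent1, parent2):
        if g not in GENOTYPES:
            raise ValueError(f"unknown parent genotype {g!r}")
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    a1 = rng.integers(0, 2, size=n)
    a2 = rng.integers(0, 2, size=n)
    p1 = (parent1[:2], parent1[2:])
    p2 = (parent2[:2], parent2[2:])
    out = []
    for i in range(n):
        alleles = sorted((p1[a1[i]], p2[a2[i]]))
        genotype = "".join(alleles)
        acc_id = f"{id_prefix}_{i:04d}"
        if pair is not None:
            out.append(make_accession(acc_id, genotype, pair))
        else:
            out.append((acc_id, genotype, PHENOTYPE_BY_GENOTYPE[genotype]))
    return out


def _apply_errors(seq_arr: np.ndarray, err_rate: float, rng: np.random.Generator) -> np.ndarray:
    """I.i.d. substitution errors; each error picks one of the 3 other bases."""
    if err_rate <= 0:
        return seq_arr
    mask = rng.random(seq_arr.shape) < err_rate
    n_err = int(mask.sum())
    if n_err:
        shift = rng.integers(1, 4, size=n_err)
        base_idx = np.searchsorted(_BASES, seq_arr[mask])
        seq_arr = seq_arr.copy()
        seq_arr[mask] = _BASES[(base_idx + shift) % 4]
    return seq_arr


def _to_arr(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def simulate_short_reads(
    acc: Accession,
    coverage: float,
    read_len: int = 150,
    insert_mean: int = 400,
    insert_sd: float = 40.0,
    err_rate: float = 0.005,
    seed: int = 0,
) -> list[tuple[SimulatedRead, SimulatedRead]]:
    """Paired-end reads from uniformly sampled fragments of a random haplotype.

    The number of pairs is ``round(coverage * (len(hapA)+len(hapB)) /
    (2 * 2 * read_len))``; mate 1 is the fragment 5' end on the forward
    strand, mate 2 the reverse complement of its 3' end.
    """
    if read_len < 30:
        raise ValueError("read_len must be >= 30")
    if insert_mean < 2 * read_len:
        raise ValueError("insert_mean must be >= 2*read_len")
    if not 0 <= err_rate < 0.1:
        raise ValueError("err_rate must be in [0, 0.1)")
    haps = (acc.hapA, acc.hapB)
    min_hap = min(len(h.seq) for h in haps)
    if insert_mean > min_hap:
        raise ValueError("insert_mean longer than haplotype")
    total = len(acc.hapA.seq) + len(acc.hapB.seq)
    n_pairs = int(round(coverage * total / (2 * 2 * read_len)))
    rng = np.random.default_rng(seed)
    hap_arrs = [_to_arr(h.seq) for h in haps]
    hap_choice = rng.integers(0, 2, size=n_pairs)
    inserts = np.rint(rng.normal(insert_mean, insert_sd, size=n_pairs)).astype(int)
    qual = _QUAL30 * read_len
    pairs = []
    for i in range(n_pairs):
        h = int(hap_choice[i])
        arr = hap_arrs[h]
        ins = int(np.clip(inserts[i], 2 * read_len, len(arr)))
        start = int(rng.integers(0, len(arr) - ins + 1))
        frag = arr[start : start + ins]
        r1 = _apply_errors(frag[:read_len], err_rate, rng)
        r2 = _to_arr(reverse_complement(frag[-read_len:].tobytes().decode()))
        r2 = _apply_errors(r2, err_rate, rng)
        hap_label = "AB"[h]
        rid = f"{acc.id}_p{i:06d}"
        pairs.append((
            SimulatedRead(id=rid, seq=r1.tobytes().decode(), qual=qual, mate=1,
                          truth_hap=hap_label, truth_pos=start, truth_strand="+"),
            SimulatedRead(id=rid, seq=r2.tobytes().decode(), qual=qual, mate=2,
                          truth_hap=hap_label, truth_pos=start + ins - read_len,
                          truth_strand="-"),
        ))
    return pairs


def simulate_long_reads(
    acc: Accession,
    coverage: float,
    len_mean: int = 6000,
    len_sd: float = 1500.0,
    err_rate: float = 0.01,
    seed: int = 0,
) -> list[SimulatedRead]:
    """Single-end long reads with normal lengths truncated to [200, haplotype length].

    Reads from an H2 haplotype that cross a junction carry the
    forward/reverse orientation switch that breakpoint refinement exploits.
    """
    if len_mean < 200:
        raise ValueError("len_mean must be >= 200")
    total = len(acc.hapA.seq) + len(acc.hapB.seq)
    n_reads = int(round(coverage * total / len_mean))
    rng = np.random.default_rng(seed)
    haps = (acc.hapA, acc.hapB)
    hap_arrs = [_to_arr(h.seq) for h in haps]
    reads = []
    for i in range(n_reads):
        h = int(rng.integers(0, 2))
        arr = hap_arrs[h]
        length = int(np.clip(round(rng.normal(len_mean, len_sd)), 200, len(arr)))
        start = int(rng.integers(0, len(arr) - length + 1))
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        frag = arr[start : start + length]
        if strand == "-":
            frag = _to_arr(reverse_complement(frag.tobytes().decode()))
        frag = _apply_errors(frag, err_rate, rng)
        reads.append(SimulatedRead(
            id=f"{acc.id}_L{i:05d}", seq=frag.tobytes().decode(),
            qual=_QUAL30 * length, mate=None, truth_hap="AB"[h],
            truth_pos=start, truth_strand=strand,
        ))
    return reads


def simulate_snp_panel(
    n_flat: int,
    n_round: int,
    alt_freq_flat,
    alt_freq_round,
    seed: int = 0,
    positions=None,
) -> SnpPanel:
    """Dosages drawn binomial(2, group frequency) per accession per SNP."""
    f_flat = np.asarray(alt_freq_flat, dtype=float)
    f_round = np.asarray(alt_freq_round, dtype=float)
    if f_flat.shape != f_round.shape:
        raise ValueError("frequency vectors must have equal length")
    for f in (f_flat, f_round):
        if ((f < 0) | (f > 1)).any():
            raise ValueError("frequencies must be in [0, 1]")
    if n_flat < 1 or n_round < 1:
        raise ValueError("both groups must be non-empty")
    rng = np.random.default_rng(seed)
    g_flat = rng.binomial(2, f_flat, size=(n_flat, f_flat.size))
    g_round = rng.binomial(2, f_round, size=(n_round, f_round.size))
    if positions is None:
        positions = np.arange(f_flat.size) * 1000 + 1000
    return SnpPanel(
        positions=np.asarray(positions),
        genotypes=np.vstack([g_flat, g_round]),
        group=["flat"] * n_flat + ["round"] * n_round,
    )


def simulate_expression_counts(
    groups: list[str],
    n_genes: int,
    planted_log2fc: float,
    dispersion: float = 0.05,
    lib_size: int = 1_000_000,
    seed: int = 0,
) -> ExpressionSim:
    """Negative-binomial counts with log-normal base means and one planted gene.

    The planted gene's expected FP-group mean is ``2**planted_log2fc`` times
    its RP-group mean; all other genes share means across groups.  Counts use
    the NB2 parameterisation (variance = mu + dispersion * mu^2) with a
    common dispersion.  Gene lengths are uniform on [500, 5000] bp.
    """
    groups = list(groups)
    n_fp = groups.count("FP")
    n_rp = groups.count("RP")
    if n_fp + n_rp != len(groups):
        raise ValueError("groups must contain only 'FP' and 'RP'")
    if n_fp < 2 or n_rp < 2:
        raise ValueError("need at least 2 samples per group")
    if dispersion <= 0:
        raise ValueError("dispersion must be > 0")
    rng = np.random.default_rng(seed)
    base = rng.lognormal(mean=3.0, sigma=1.2, size=n_genes)
    base *= lib_size / base.sum()
    planted_idx = int(rng.integers(0, n_genes))
    mu = np.tile(base[:, None], (1, len(groups)))
    fp_cols = [i for i, g in enumerate(groups) if g == "FP"]
    mu[planted_idx, fp_cols] = base[planted_idx] * 2.0**planted_log2fc
    r = 1.0 / dispersion
    counts = rng.negative_binomial(r, r / (r + mu))
    gene_lengths = rng.integers(500, 5001, size=n_genes)
    gene_ids = [f"gene_{i:05d}" for i in range(n_genes)]
    sample_ids = []
    tally: dict[str, int] = {}
    for g in groups:
        tally[g] = tally.get(g, 0) + 1
        sample_ids.append(f"{g}{tally[g]}")
    return ExpressionSim(
        gene_ids=gene_ids, sample_ids=sample_ids, counts=counts,
        gene_lengths=gene_lengths, group=groups,
        planted_gene=gene_ids[planted_idx], planted_log2fc=planted_log2fc,
    )


def classify_fruit_shape(cheek_len: float, vertical_len: float) -> str:
    """Fruit-shape class from the cheek/vertical length ratio.

    flat if the ratio exceeds 1.5, round if below 1.2, otherwise
    unclassified (the gap between the two published thresholds).
    """
    if cheek_len <= 0 or vertical_len <= 0:
        raise ValueError("lengths must be positive")
    r = cheek_len / vertical_len
    if r > 1.5:
        return "flat"
    if r < 1.2:
        return "round"
    return "unclassified"
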