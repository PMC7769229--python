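"""End-to-end demonstration pipeline tying every analysis stage together.

``run_demo`` simulates the whole study at desk scale — locus, accession
panel, F1 cross, short and long reads, SNP panel and expression counts —
then genotypes every accession by both the sequencing and the PCR route,
runs co-segregation, Mendelian segregation, SNP association and the DEG
screen, writes all outputs as FASTA/FASTQ/TSV, and records a manifest with
the resolved configuration and per-file SHA-256 checksums.  A run is fully
determined by its configuration (including the seed): re-running with the
same configuration reproduces identical checksums.

The demo *checks* its own scientific invariants (perfect co-segregation,
100% cross-method concordance, Mendelian segregation, planted-signal
recovery) and raises :class:`PipelineError` if any fails, so a demo that
completes is itself an end-to-end validation.
"""

from __future__ import annotations

import hashlib
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .association_stats import cosegregation_check, segregation_chisq, snp_association
from .config import RunConfig
from .expression_analysis import CountMatrix, deg_screen, tpm_normalize
from .haplotype_model import build_inverted_haplotype, build_junction_set
from .inversion_genotyping import (
    design_assay,
    genotype_by_pcr,
    genotype_from_reads,
    refine_breakpoints,
)
from .io_utils import write_fastq, write_junctions, write_segments, write_tsv
from .read_alignment import JunctionAligner
from .synthetic_data import (
    GENOTYPES,
    generate_reference,
    make_accession,
    plant_inversion_site,
    simulate_cross,
    simulate_expression_counts,
    simulate_long_reads,
    simulate_short_reads,
    simulate_snp_panel,
)

__all__ = ["PipelineError", "RunManifest", "run_demo", "child_seed", "build_locus"]

log = logging.getLogger("flatpeach")


class PipelineError(RuntimeError):
    """A pipeline stage failed one of its scientific invariants."""


@dataclass
class RunManifest:
    config_text: str
    version: str
    checksums: dict[str, str] = field(default_factory=dict)

    def to_text(self) -> str:
        lines = [f"version: {self.version}", "config:"]
        lines += [f"  {line}" for line in self.config_text.strip().splitlines()]
        lines.append("checksums:")
        lines += [f"  {name}: {digest}" for name, digest in sorted(self.checksums.items())]
        return "\n".join(lines) + "\n"


def child_seed(base: int, tag: str) -> int:
    """A reproducible sub-seed (< 2^31) for one named source of randomness."""
    return zlib.crc32(f"{base}:{tag}".encode()) % (2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def build_locus(config: RunConfig):
    """Reference + planted inversion site -> (haplotype pair, junction set)."""
    ref = generate_reference(config.locus_length, gc=config.gc,
                             seed=child_seed(config.seed, "reference"))
    planted, spec = plant_inversion_site(ref, config.pb, config.db,
                                         del_motif=config.del_motif,
                                         ins_motif=config.ins_motif)
    pair = build_inverted_haplotype(planted, spec)
    junctions = build_junction_set(pair, flank=config.flank)
    return pair, junctions


def run_demo(config: RunConfig, outdir) -> RunManifest:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(name: str, writer) -> Path:
        path = outdir / name
        writer(path)
        written.append(path)
        return path

    # -- locus -------------------------------------------------------------
    log.info("stage locus: building haplotypes and junctions")
    pair, junctions = build_locus(config)
    emit("haplotypes.fasta", lambda p: write_segments(p, [pair.h1, pair.h2]))
    emit("junctions.fasta", lambda p: write_junctions(p, junctions))

    # -- accession panel and reads ------------------------------------------
    log.info("stage panel: %d accessions per genotype", config.n_per_genotype)
    accessions = [
        make_accession(f"acc_{g}_{i}", g, pair)
        for g in GENOTYPES
        for i in range(config.n_per_genotype)
    ]
    truth = pd.DataFrame(
        [(a.id, a.genotype, a.phenotype) for a in accessions],
        columns=["accession_id", "genotype", "phenotype"],
    )
    emit("accessions.tsv", lambda p: write_tsv(truth, p))

    aligner = JunctionAligner(junctions, k=config.k,
                              max_mismatch_frac=config.max_mismatch_frac)
    assay = design_assay(pair)
    calls, rows = [], []
    reads_dir = outdir / "reads"
    reads_dir.mkdir(exist_ok=True)
    for acc in accessions:
        pairs = simulate_short_reads(
            acc, coverage=config.coverage, read_len=config.read_len,
            insert_mean=config.insert_mean, insert_sd=config.insert_sd,
            err_rate=config.err_rate, seed=child_seed(config.seed, f"reads:{acc.id}"),
        )
        flat_reads = [r for pr in pairs for r in pr]
        path = reads_dir / f"{acc.id}.fastq"
        write_fastq(path, flat_reads)
        written.append(path)
        seq_call = genotype_from_reads(
            flat_reads, junctions, aligner=aligner, min_overhang=config.min_overhang,
            min_identity=config.min_identity, min_reads=config.min_reads,
            accession_id=acc.id,
        )
        pcr_call, pattern = genotype_by_pcr(acc, assay)
        calls.append(seq_call)
        s = seq_call.support
        rows.append((acc.id, s.n_wpb, s.n_wdb, s.n_mpb, s.n_mdb, s.n_uninformative,
                     seq_call.genotype, pcr_call.genotype,
                     int(pattern.p1), int(pattern.p2), int(pattern.p3)))
        if seq_call.genotype != acc.genotype:
            raise PipelineError(
                f"stage genotyping: {acc.id} called {seq_call.genotype}, truth {acc.genotype}"
            )
        if pcr_call.genotype != seq_call.genotype:
            raise PipelineError(f"stage genotyping: PCR/sequencing discordance for {acc.id}")
    genotype_df = pd.DataFrame(rows, columns=[
        "accession_id", "n_wpb", "n_wdb", "n_mpb", "n_mdb", "n_uninformative",
        "genotype_reads", "genotype_pcr", "p1", "p2", "p3",
    ])
    emit("genotypes.tsv", lambda p: write_tsv(genotype_df, p))

    report = cosegregation_check(calls, dict(zip(truth.accession_id, truth.phenotype)))
    if not report.perfect or report.no_calls:
        raise PipelineError(f"stage cosegregation: discordant={report.discordant} "
                            f"no_calls={report.no_calls}")

    # -- F1 cross segregation ------------------------------------------------
    log.info("stage cross: H1H2 x H1H2, n=%d", config.cross_n)
    progeny = simulate_cross("H1H2", "H1H2", config.cross_n,
                             seed=child_seed(config.seed, "cross"))
    counts = [sum(1 for _, g, _ in progeny if g == gt) for gt in GENOTYPES]
    seg = segregation_chisq(counts, (1, 2, 1))
    if seg.p <= 0.001:
        raise PipelineError(f"stage cross: segregation rejected 1:2:1 (p={seg.p:.2e})")
    if any(ph != "aborted" for _, g, ph in progeny if g == "H2H2"):
        raise PipelineError("stage cross: H2H2 progeny without aborted phenotype")
    seg_df = pd.DataFrame([{
        "n_H1H1": counts[0], "n_H1H2": counts[1], "n_H2H2": counts[2],
        "ratio": "1:2:1", "chi2": seg.chi2, "df": seg.df, "p": seg.p,
    }])
    emit("segregation.tsv", lambda p: write_tsv(seg_df, p))

    # -- breakpoint refinement ----------------------------------------------
    log.info("stage refine: long reads from an H2H2 accession")
    h2_acc = make_accession("acc_refine_H2H2", "H2H2", pair)
    long_reads = simulate_long_reads(
        h2_acc, coverage=config.long_coverage, len_mean=config.long_len_mean,
        len_sd=config.long_len_sd, err_rate=config.long_err_rate,
        seed=child_seed(config.seed, "longreads"),
    )
    emit("long_reads.fastq", lambda p: write_fastq(p, long_reads))
    w = config.refine_window_halfwidth
    spec = pair.spec
    refined = refine_breakpoints(
        long_reads, pair.h1,
        ((spec.pb - w, spec.pb + w), (spec.db - w, spec.db + w)),
        k=config.refine_k, min_part=config.refine_min_part,
    )
    expect = (spec.pb - len(spec.del_motif), spec.db)
    if (refined.consensus_u, refined.consensus_v) != expect:
        raise PipelineError(
            f"stage refine: consensus ({refined.consensus_u}, {refined.consensus_v}) "
            f"!= planted {expect}"
        )
    refine_df = pd.DataFrame(
        [(e.read_id, e.u, e.v, e.score) for e in refined.per_read]
        + [("consensus", refined.consensus_u, refined.consensus_v, len(refined.per_read))],
        columns=["read_id", "u", "v", "score"],
    )
    emit("breakpoints.tsv", lambda p: write_tsv(refine_df, p))

    # -- SNP association -----------------------------------------------------
    log.info("stage snps: %d SNPs, %d+%d accessions", config.n_snps,
             config.n_flat, config.n_round)
    freq_flat = [config.planted_alt_flat] + [config.null_alt_freq] * (config.n_snps - 1)
    freq_round = [config.planted_alt_round] + [config.null_alt_freq] * (config.n_snps - 1)
    panel = simulate_snp_panel(config.n_flat, config.n_round, freq_flat, freq_round,
                               seed=child_seed(config.seed, "snps"))
    dosage_df = pd.DataFrame(
        panel.genotypes, columns=[f"pos_{p}" for p in panel.positions],
    )
    dosage_df.insert(0, "accession_id", [f"snp_acc_{i:03d}" for i in range(len(panel.group))])
    dosage_df.insert(1, "group", panel.group)
    emit("snp_dosages.tsv", lambda p: write_tsv(dosage_df, p))
    assoc = snp_association(panel)
    assoc_df = pd.DataFrame(
        [(r.position, r.alt_freq_flat, r.alt_freq_round, r.p, r.q, r.monomorphic)
         for r in assoc],
        columns=["position", "alt_freq_flat", "alt_freq_round", "p", "q", "monomorphic"],
    )
    emit("snp_association.tsv", lambda p: write_tsv(assoc_df, p))
    min_q = min(r.q for r in assoc)
    if assoc[0].q > min_q:
        raise PipelineError("stage snps: planted SNP does not attain the minimum q")

    # -- expression screen ---------------------------------------------------
    log.info("stage expression: %d genes, planted log2FC %.1f",
             config.n_genes, config.planted_log2fc)
    sim = simulate_expression_counts(
        ["FP", "FP", "FP", "RP", "RP", "RP"], n_genes=config.n_genes,
        planted_log2fc=config.planted_log2fc, dispersion=config.dispersion,
        lib_size=config.lib_size, seed=child_seed(config.seed, "expression"),
    )
    cm = CountMatrix(gene_ids=sim.gene_ids, sample_ids=sim.sample_ids,
                     counts=sim.counts, gene_lengths=sim.gene_lengths)
    counts_df = pd.DataFrame(sim.counts, columns=sim.sample_ids)
    counts_df.insert(0, "gene_id", sim.gene_ids)
    counts_df["length"] = sim.gene_lengths
    emit("expression_counts.tsv", lambda p: write_tsv(counts_df, p))
    tpm = tpm_normalize(cm)
    tpm_df = pd.DataFrame(tpm.values.round(3), columns=tpm.sample_ids)
    tpm_df.insert(0, "gene_id", tpm.gene_ids)
    emit("expression_tpm.tsv", lambda p: write_tsv(tpm_df, p))
    degs = deg_screen(cm, sim.group, lfc_threshold=config.lfc_threshold,
                      fdr_threshold=config.fdr_threshold, pseudocount=config.pseudocount)
    deg_df = pd.DataFrame(
        [(r.gene_id, round(r.log2fc, 4), r.p, r.q, r.direction, r.passes) for r in degs],
        columns=["gene_id", "log2fc", "p", "q", "direction", "passes"],
    )
    emit("deg.tsv", lambda p: write_tsv(deg_df, p))
    # largest |log2FC| + fold threshold is the screen's robust deliverable at
    # n=3+3; p-value ranking is power-limited at this design size
    top_fc = max(degs, key=lambda r: abs(r.log2fc))
    if top_fc.gene_id != sim.planted_gene or abs(top_fc.log2fc) <= config.lfc_threshold:
        raise PipelineError(
            f"stage expression: planted gene {sim.planted_gene} not recovered "
            f"(largest |log2FC| gene {top_fc.gene_id}, log2fc {top_fc.log2fc:.2f})"
        )

    # -- manifest ------------------------------------------------------------
    manifest = RunManifest(
        config_text=config.to_text(), version=__version__,
        checksums={str(p.relative_to(outdir)): _sha256(p) for p in written},
    )
    (outdir / "manifest.txt").write_text(manifest.to_text())
    log.info("demo complete: %d files, manifest written", len(written))
    return manifest
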