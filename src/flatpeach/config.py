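"""Run configuration: one flat key/value file shared by all pipeline stages.

The defaults define a desk-scale study: a 30-kb locus carrying a 10-kb
inversion (scaled down from the megabase-scale event the design mimics),
paired-end reads at modest coverage, a 63-SNP panel with one
group-differentiated SNP, and a 1000-gene expression experiment with one
planted activated gene.  CLI flags override file values; the resolved
configuration is echoed into every run manifest so outputs are reproducible
from the manifest alone.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    seed: int = 7

    # locus geometry
    locus_length: int = 30_000
    pb: int = 10_000
    db: int = 20_000
    del_motif: str = "ACA"
    ins_motif: str = "GA"
    gc: float = 0.42
    flank: int = 300

    # short-read simulation
    coverage: float = 30.0
    read_len: int = 150
    insert_mean: int = 400
    insert_sd: float = 40.0
    err_rate: float = 0.005

    # long-read simulation
    long_coverage: float = 15.0
    long_len_mean: int = 6000
    long_len_sd: float = 1500.0
    long_err_rate: float = 0.01

    # alignment / genotyping thresholds
    k: int = 15
    min_overhang: int = 15
    min_identity: float = 0.9
    max_mismatch_frac: float = 0.1
    min_reads: int = 3

    # breakpoint refinement
    refine_k: int = 13
    refine_min_part: int = 20
    refine_window_halfwidth: int = 500

    # panel / cross sizes
    n_per_genotype: int = 3
    cross_n: int = 400

    # SNP panel
    n_snps: int = 63
    n_flat: int = 30
    n_round: int = 30
    planted_alt_flat: float = 0.9
    planted_alt_round: float = 0.1
    null_alt_freq: float = 0.5

    # expression screen
    n_genes: int = 500
    planted_log2fc: float = 5.0
    dispersion: float = 0.05
    lib_size: int = 1_000_000
    lfc_threshold: float = 2.0
    fdr_threshold: float = 0.1
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if not 0 <= self.pb - len(self.del_motif) < self.pb < self.db <= self.locus_length:
            raise ValueError("locus breakpoints out of range")
        if not (0 < self.min_identity <= 1 and 0 <= self.max_mismatch_frac <= 1):
            raise ValueError("identity/mismatch thresholds out of range")
        if self.min_reads < 1 or self.k < 8 or self.min_overhang < 1:
            raise ValueError("genotyping thresholds out of documented range")

    # -- serialisation -----------------------------------------------------

    def to_text(self) -> str:
        lines = [f"{f.name}: {getattr(self, f.name)}" for f in dataclasses.fields(self)]
        return "\n".join(lines) + "\n"

    @classmethod
    def from_file(cls, path, **overrides) -> "RunConfig":
        """Parse a flat ``key: value`` file; keyword overrides win."""
        values: dict = {}
        types = {f.name: f.type for f in dataclasses.fields(cls)}
        casts = {"int": int, "float": float, "str": str}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if ":" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key: value', got {raw!r}")
            key, val = (part.strip() for part in line.split(":", 1))
            if key not in types:
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
            values[key] = casts[types[key]](val)
        values.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**values)

    def replace(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **{k: v for k, v in kwargs.items() if v is not None})
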