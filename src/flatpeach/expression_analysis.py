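"""TPM normalisation, differential-expression screening and qPCR quantification.

The expression screen that nominated the candidate gene is reproduced on
count matrices: counts are length-normalised to transcripts per million
(TPM), per-gene log2 fold changes (flat-fruit FP group over round-fruit RP
group) are computed on group-mean TPM with a pseudocount, and genes pass
the screen when |log2FC| exceeds the fold threshold and the
Benjamini-Hochberg q-value of a Welch t-test on log2(TPM + pseudocount)
stays under the FDR threshold (defaults 2 and 0.1).

The Welch t-test is a deliberately simple stand-in for a count-model fit:
the screen's contract here is recovery of planted effects in synthetic
data, not reproduction of a specific published gene list.

qPCR relative expression uses the standard 2^-ddCt formula.
"""

from __future__ import annotations

from dataclasses import dataclass
from warnings import warn

import numpy as np
from scipy import stats

from .association_stats import bh_adjust

__all__ = [
    "CountMatrix",
    "TpmMatrix",
    "DegRecord",
    "QpcrMeasurement",
    "tpm_normalize",
    "log2_fold_change",
    "deg_screen",
    "delta_delta_ct",
]


@dataclass
class CountMatrix:
    """Genes x samples integer counts plus per-gene transcript lengths (bp)."""

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    gene_lengths: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.gene_lengths = np.asarray(self.gene_lengths)
        n_g, n_s = self.counts.shape
        if n_g != len(self.gene_ids) or n_s != len(self.sample_ids):
            raise ValueError("counts shape inconsistent with gene/sample ids")
        if len(self.gene_lengths) != n_g:
            raise ValueError("gene_lengths inconsistent with gene_ids")
        if (self.gene_lengths < 1).any():
            raise ValueError("gene lengths must be >= 1")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")


@dataclass
class TpmMatrix:
    """Same shape as the count matrix; each non-degenerate column sums to 1e6."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray


@dataclass(frozen=True)
class DegRecord:
    gene_id: str
    log2fc: float
    p: float
    q: float
    direction: str  # 'up' or 'down' (FP relative to RP)
    passes: bool


@dataclass(frozen=True)
class QpcrMeasurement:
    """Target and reference Ct values plus the calibrator sample's delta-Ct."""

    ct_target: float
    ct_reference: float
    calibrator_delta_ct: float

    def __post_init__(self) -> None:
        for v in (self.ct_target, self.ct_reference, self.calibrator_delta_ct):
            if not np.isfinite(v):
                raise ValueError("Ct values must be finite")


def tpm_normalize(m: CountMatrix) -> TpmMatrix:
    """Transcripts per million: length-normalised rates rescaled to 1e6 per sample."""
    rates = m.counts / m.gene_lengths[:, None]
    totals = rates.sum(axis=0)
    zero = totals == 0
    if zero.any():
        warn(f"sample(s) {[m.sample_ids[i] for i in np.flatnonzero(zero)]} have no counts; "
             "TPM column left at zero")
    safe = np.where(zero, 1.0, totals)
    tpm = rates / safe * 1e6
    tpm[:, zero] = 0.0
    return TpmMatrix(gene_ids=list(m.gene_ids), sample_ids=list(m.sample_ids), values=tpm)


def _group_masks(sample_ids, groups) -> tuple[np.ndarray, np.ndarray]:
    g = np.asarray(list(groups))
    fp = g == "FP"
    rp = g == "RP"
    if not fp.any() or not rp.any():
        raise ValueError("both FP and RP groups must be non-empty")
    if fp.sum() + rp.sum() != g.size:
        raise ValueError("groups must contain only 'FP' and 'RP'")
    return fp, rp


def log2_fold_change(tpm: TpmMatrix, groups, pseudocount: float = 1.0) -> np.ndarray:
    """Per-gene log2((mean FP TPM + pseudocount) / (mean RP TPM + pseudocount))."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    fp, rp = _group_masks(tpm.sample_ids, groups)
    mean_fp = tpm.values[:, fp].mean(axis=1)
    mean_rp = tpm.values[:, rp].mean(axis=1)
    return np.log2((mean_fp + pseudocount) / (mean_rp + pseudocount))


def deg_screen(
    m: CountMatrix,
    groups,
    lfc_threshold: float = 2.0,
    fdr_threshold: float = 0.1,
    pseudocount: float = 1.0,
) -> list[DegRecord]:
    """Differential-expression screen with a joint fold-change + FDR filter.

    TPM-normalises, computes per-gene log2 fold change on group means, tests
    group difference with a Welch t-test on log2(TPM + pseudocount)
    (degenerate zero-variance-equal-mean genes get p = 1), adjusts with
    Benjamini-Hochberg, and flags genes with ``|log2FC| > lfc_threshold``
    and ``q < fdr_threshold``.  Output is sorted by q then |log2FC| (desc).
    """
    fp, rp = _group_masks(m.sample_ids, groups)
    if fp.sum() < 2 or rp.sum() < 2:
        raise ValueError("need at least 2 samples per group")
    tpm = tpm_normalize(m)
    lfc = log2_fold_change(tpm, groups, pseudocount=pseudocount)
    logged = np.log2(tpm.values + pseudocount)
    with np.errstate(divide="ignore", invalid="ignore"):
        _, pvals = stats.ttest_ind(logged[:, fp], logged[:, rp], axis=1, equal_var=False)
    pvals = np.where(np.isnan(pvals), 1.0, pvals)
    qvals = bh_adjust(pvals)
    records = [
        DegRecord(
            gene_id=m.gene_ids[i],
            log2fc=float(lfc[i]),
            p=float(pvals[i]),
            q=float(qvals[i]),
            direction="up" if lfc[i] >= 0 else "down",
            passes=bool(abs(lfc[i]) > lfc_threshold and qvals[i] < fdr_threshold),
        )
        for i in range(len(m.gene_ids))
    ]
    records.sort(key=lambda r: (r.q, -abs(r.log2fc), r.gene_id))
    return records


def delta_delta_ct(q: QpcrMeasurement) -> float:
    """Relative expression 2^-ddCt against a reference gene and calibrator sample."""
    delta_ct = q.ct_target - q.ct_reference
    ddct = delta_ct - q.calibrator_delta_ct
    return float(2.0 ** (-ddct))
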