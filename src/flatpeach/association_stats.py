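"""Segregation and allele-frequency association statistics.

Three statistical layers support the genetics of the locus:

* **Co-segregation** — perfect correspondence of inversion genotype and
  phenotype (round = H1H1, flat = H1H2, fruit-aborted = H2H2) across a
  panel or pedigree.
* **Mendelian segregation** — chi-square goodness of fit of progeny
  genotype counts against the expected ratio (1:1 for a heterozygote x
  homozygote cross, 1:2:1 for heterozygote x heterozygote).
* **SNP association** — per-SNP 2x2 allele-count tables (flat vs round),
  two-sided Fisher exact p-values and Benjamini-Hochberg q-values.

The Fisher test sums hypergeometric probabilities of all tables sharing
the observed margins whose probability does not exceed the observed one
(with a 1e-7 relative tolerance for floating-point ties), the classic
two-sided convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .synthetic_data import SnpPanel

__all__ = [
    "ContingencyTable2x2",
    "SnpAssocResult",
    "SegregationResult",
    "CosegregationReport",
    "fisher_exact_two_sided",
    "bh_adjust",
    "snp_association",
    "segregation_chisq",
    "cosegregation_check",
]

_TIE_RTOL = 1e-7


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]]; rows are groups, columns allele/genotype classes."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("table must have at least one positive count")


@dataclass(frozen=True)
class SnpAssocResult:
    position: int
    alt_freq_flat: float
    alt_freq_round: float
    p: float
    q: float
    monomorphic: bool = False


@dataclass(frozen=True)
class SegregationResult:
    observed: tuple[int, ...]
    expected_ratio: tuple[float, ...]
    chi2: float
    df: int
    p: float


@dataclass
class CosegregationReport:
    perfect: bool
    discordant: list[str] = field(default_factory=list)
    no_calls: list[str] = field(default_factory=list)
    n_checked: int = 0


def fisher_exact_two_sided(t: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p-value for a 2x2 table.

    Conditions on both margins; the p-value is the total hypergeometric
    probability of tables at most as probable as the observed one.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    r1, c1, n = a + b, a + c, a + b + c + d
    lo = max(0, c1 - (c + d))
    hi = min(r1, c1)
    xs = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(xs, n, r1, c1)
    p_obs = pmf[xs == a][0]
    p = float(pmf[pmf <= p_obs * (1.0 + _TIE_RTOL)].sum())
    return min(p, 1.0)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in input order.

    q(i) = min over j >= i (in rank order) of p(j) * n / j, capped at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum(np.minimum.accumulate(ranked[::-1])[::-1], 1.0)
    out = np.empty(n)
    out[order] = q_sorted
    return out


def snp_association(panel: SnpPanel, genotype_based: bool = False) -> list[SnpAssocResult]:
    """Per-SNP flat-vs-round association with BH correction across the panel.

    By default the 2x2 table counts alleles (2 per accession), matching an
    allele-frequency comparison; ``genotype_based`` collapses dosages to
    carrier status instead (alt-carrying vs non-carrying accessions).
    """
    group = np.asarray(panel.group)
    flat = panel.genotypes[group == "flat"]
    rnd = panel.genotypes[group == "round"]
    if flat.shape[0] == 0 or rnd.shape[0] == 0:
        raise ValueError("both groups must be non-empty")
    results = []
    pvals = []
    for j, pos in enumerate(panel.positions):
        if genotype_based:
            fa, fr = int((flat[:, j] > 0).sum()), int((flat[:, j] == 0).sum())
            ra, rr = int((rnd[:, j] > 0).sum()), int((rnd[:, j] == 0).sum())
        else:
            fa = int(flat[:, j].sum())
            fr = 2 * flat.shape[0] - fa
            ra = int(rnd[:, j].sum())
            rr = 2 * rnd.shape[0] - ra
        mono = (fa + ra == 0) or (fr + rr == 0)
        p = 1.0 if mono else fisher_exact_two_sided(ContingencyTable2x2(fa, fr, ra, rr))
        pvals.append(p)
        results.append((int(pos), fa / (fa + fr), ra / (ra + rr), p, mono))
    qvals = bh_adjust(pvals)
    return [
        SnpAssocResult(position=pos, alt_freq_flat=ff, alt_freq_round=fr,
                       p=p, q=float(q), monomorphic=mono)
        for (pos, ff, fr, p, mono), q in zip(results, qvals)
    ]


def segregation_chisq(observed, expected_ratio) -> SegregationResult:
    """Chi-square goodness of fit of progeny counts against a Mendelian ratio."""
    obs = np.asarray(observed, dtype=float)
    ratio = np.asarray(expected_ratio, dtype=float)
    if obs.size != ratio.size or obs.size < 2:
        raise ValueError("observed and expected_ratio must have equal length >= 2")
    if obs.sum() <= 0:
        raise ValueError("total observed count must be positive")
    if (ratio <= 0).any():
        raise ValueError("expected ratio classes must be positive")
    expected = obs.sum() * ratio / ratio.sum()
    chi2, p = stats.chisquare(obs, f_exp=expected)
    return SegregationResult(
        observed=tuple(int(o) for o in obs),
        expected_ratio=tuple(float(r) for r in ratio),
        chi2=float(chi2), df=obs.size - 1, p=float(p),
    )


_EXPECTED_GENOTYPE = {"round": "H1H1", "flat": "H1H2", "aborted": "H2H2"}


def cosegregation_check(calls, phenotypes: dict[str, str]) -> CosegregationReport:
    """Check genotype calls against the genotype expected from each phenotype.

    ``calls`` are :class:`~flatpeach.inversion_genotyping.GenotypeCall`
    objects; no-calls are listed separately and not counted as discordant.
    """
    report = CosegregationReport(perfect=True)
    seen = set()
    for call in calls:
        if call.accession_id not in phenotypes:
            raise ValueError(f"no phenotype for accession {call.accession_id!r}")
        seen.add(call.accession_id)
        if call.genotype == "no_call":
            report.no_calls.append(call.accession_id)
            continue
        phen = phenotypes[call.accession_id]
        expected = _EXPECTED_GENOTYPE.get(phen)
        if expected is None:
            raise ValueError(f"unknown phenotype {phen!r}")
        report.n_checked += 1
        if call.genotype != expected:
            report.discordant.append(call.accession_id)
    missing = set(phenotypes) - seen
    if missing:
        raise ValueError(f"phenotypes with no genotype call: {sorted(missing)}")
    report.perfect = not report.discordant
    return report
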