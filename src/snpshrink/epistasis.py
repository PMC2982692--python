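"""Pairwise SNP-SNP interaction testing by logistic regression.

For a binary case/control trait and two SNPs coded as minor-allele dosages
(AA -> 0, Aa -> 1, aa -> 2), the interaction model is

    logit P(case) = b0 + b1*g1 + b2*g2 + b3*g1*g2

fitted by iteratively reweighted least squares.  The interaction term b3 is
reported as a log-odds ratio (OR_int = exp(b3)) with a 1-df Wald chi-square
statistic (b3/se)^2 and its asymptotic upper-tail P-value, matching the
allelic-model epistasis output of standard whole-genome toolkits.  Samples
with a missing dosage at either SNP are removed pairwise-complete.

The chi-square statistic and P-value are invariant to which allele is
counted by the dosage; only the sign of b3 (direction of OR_int) depends
on that choice.
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np
from scipy import stats

from .io import GenotypeMatrix

_DOSAGE = np.array([0.0, 1.0, 2.0, np.nan])  # AA, Aa, aa, missing

#: IRLS convergence tolerance on the log-likelihood
IRLS_TOL = 1e-8
IRLS_MAX_ITER = 50
#: |beta| beyond this flags (quasi-)complete separation
SEPARATION_BOUND = 15.0


def chi2_pvalue(statistic: float, df: int = 1) -> float:
    """Asymptotic upper-tail probability of a chi-square statistic."""
    if statistic < 0:
        raise ValueError("chi-square statistic must be nonnegative")
    return float(stats.chi2.sf(statistic, df=df))


def dosage(calls) -> np.ndarray:
    """Minor-allele dosage: AA -> 0, Aa -> 1, aa -> 2, missing -> NaN."""
    calls = np.asarray(calls)
    return _DOSAGE[calls.astype(int)]


@dataclasses.dataclass
class EpistasisResult:
    """One SNP pair's interaction fit (NaN fields when status != 'ok')."""

    snp1: str
    snp2: str
    n_used: int
    beta_int: float
    se_int: float
    or_int: float
    chi2: float
    p: float
    status: str = "ok"

    def as_row(self) -> dict:
        return dataclasses.asdict(self)


def _logistic_irls(X: np.ndarray, y: np.ndarray):
    """Newton/IRLS logistic fit; returns (beta, cov, status)."""
    n, q = X.shape
    beta = np.zeros(q)
    ll_old = -np.inf
    cov = None
    for _ in range(IRLS_MAX_ITER):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        # Fisher information X'WX; guard singular designs
        XtWX = X.T @ (X * w[:, None])
        try:
            step = np.linalg.solve(XtWX, X.T @ (y - mu))
        except np.linalg.LinAlgError:
            return beta, None, "singular"
        beta = beta + step
        if np.any(np.abs(beta) > SEPARATION_BOUND):
            return beta, None, "separation"
        ll = float(np.sum(y * eta - np.log1p(np.exp(eta))))
        if abs(ll - ll_old) < IRLS_TOL:
            try:
                cov = np.linalg.inv(XtWX)
            except np.linalg.LinAlgError:
                return beta, None, "singular"
            return beta, cov, "ok"
        ll_old = ll
    return beta, None, "no_convergence"


def interaction_test(y, g1, g2, snp1: str = "snp1",
                     snp2: str = "snp2") -> EpistasisResult:
    """Wald test of the g1 x g2 logistic interaction on a binary trait.

    ``y`` is 0/1 (control/case); ``g1``/``g2`` are dosages with NaN for
    missing, removed pairwise-complete.  Non-convergence, separation or a
    degenerate design yield a flagged result with NaN statistics.
    """
    y = np.asarray(y, dtype=float)
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    keep = ~(np.isnan(g1) | np.isnan(g2) | np.isnan(y))
    y, g1, g2 = y[keep], g1[keep], g2[keep]
    n_used = int(keep.sum())

    def failed(reason):
        return EpistasisResult(snp1, snp2, n_used, np.nan, np.nan, np.nan,
                               np.nan, np.nan, status=reason)

    if n_used == 0 or y.min() == y.max():
        return failed("one_class")
    inter = g1 * g2
    X = np.column_stack([np.ones_like(g1), g1, g2, inter])
    # constant columns (beyond the intercept) make beta3 unidentifiable
    if np.ptp(inter) == 0 or np.ptp(g1) == 0 or np.ptp(g2) == 0:
        return failed("constant_term")
    beta, cov, status = _logistic_irls(X, y)
    if status != "ok":
        return failed(status)
    b3 = float(beta[3])
    se = float(np.sqrt(cov[3, 3]))
    chi2 = (b3 / se) ** 2
    p = chi2_pvalue(chi2)
    return EpistasisResult(snp1, snp2, n_used, b3, se, float(np.exp(b3)),
                           float(chi2), p)


def _binary_response(g: GenotypeMatrix, case_label=None) -> np.ndarray:
    labels = g.classes()
    if len(labels) != 2:
        raise ValueError("epistasis testing needs exactly 2 classes")
    if case_label is None:
        case_label = "case" if "case" in labels else labels[1]
    return np.array([1.0 if l == case_label else 0.0 for l in g.labels])


def pairwise_scan(g: GenotypeMatrix, set_a, set_b, p_threshold: float = 0.01,
                  case_label=None) -> list[EpistasisResult]:
    """Test every unordered SNP pair (a, b), a in set_a, b in set_b, a != b.

    Pairs are deduplicated; results with p < ``p_threshold`` are returned
    sorted by ascending p (flagged results are excluded).
    """
    ids = g.snp_ids
    col = {sid: j for j, sid in enumerate(ids)}
    for sid in itertools.chain(set_a, set_b):
        if sid not in col:
            raise KeyError(f"SNP {sid} not in genotype matrix")
    y = _binary_response(g, case_label)
    dose = dosage(g.calls)
    pairs = {tuple(sorted((a, b), key=lambda s: col[s]))
             for a in set_a for b in set_b if a != b}
    results = []
    for s1, s2 in sorted(pairs, key=lambda t: (col[t[0]], col[t[1]])):
        r = interaction_test(y, dose[:, col[s1]], dose[:, col[s2]], s1, s2)
        if r.status == "ok" and r.p < p_threshold:
            results.append(r)
    results.sort(key=lambda r: r.p)
    return results


def write_epistasis_tsv(results, path, snp_chrom: dict | None = None,
                        n_tests: int | None = None) -> None:
    """Write results as CHR1 SNP1 CHR2 SNP2 N OR_INT STAT P (TSV).

    When ``n_tests`` is given, an informational Bonferroni-adjusted
    column P_BONF = min(1, P * n_tests) is appended; selection itself
    uses the raw P threshold.
    """
    snp_chrom = snp_chrom or {}
    with open(path, "w") as fh:
        header = "CHR1\tSNP1\tCHR2\tSNP2\tN\tOR_INT\tSTAT\tP"
        fh.write(header + ("\tP_BONF\n" if n_tests else "\n"))
        for r in results:
            row = (
                f"{snp_chrom.get(r.snp1, 'NA')}\t{r.snp1}\t"
                f"{snp_chrom.get(r.snp2, 'NA')}\t{r.snp2}\t{r.n_used}\t"
                f"{r.or_int:.6g}\t{r.chi2:.6g}\t{r.p:.6g}"
            )
            if n_tests:
                row += f"\t{min(1.0, r.p * n_tests):.6g}"
            fh.write(row + "\n")
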