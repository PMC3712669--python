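"""Per-SNP case-control association.

The workhorse is an additive-dosage logistic regression with covariate
adjustment and Wald two-sided p-values, matching the conventional GWAS
single-variant model. Two covariate-free screens are also provided: the
Cochran-Armitage trend test and a vectorized allelic-contingency scan
that yields a log odds ratio and standard error per SNP (and therefore
feeds the fixed-effect meta-analysis directly). The fast scans are used
for large simulation studies where per-SNP maximum-likelihood fits would
dominate the run time.
"""

from __future__ import annotations

import logging
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import StudyData
from .types import AssocResult

logger = logging.getLogger(__name__)

__all__ = [
    "logistic_association",
    "trend_test",
    "trend_scan",
    "allelic_scan",
    "logistic_scan",
    "assoc_table",
]

_P_FLOOR = 1e-300


def _design_matrix(
    dosage: np.ndarray, covariates: Optional[pd.DataFrame]
) -> np.ndarray:
    cols = [np.ones_like(dosage, dtype=float), dosage.astype(float)]
    if covariates is not None:
        for name in covariates.columns:
            col = covariates[name]
            if col.dtype.kind in "OUS" or isinstance(col.dtype, pd.CategoricalDtype):
                dummies = pd.get_dummies(col, drop_first=True, dtype=float)
                for d in dummies.columns:
                    cols.append(dummies[d].to_numpy())
            else:
                cols.append(col.to_numpy(dtype=float))
    X = np.column_stack(cols)
    # constant covariates (e.g. sex inside a single-gender stratum) carry
    # no information and break the fit; drop all but the intercept
    keep = [0, 1] + [
        j for j in range(2, X.shape[1]) if np.ptp(X[:, j]) > 0
    ]
    return X[:, keep]


def logistic_association(
    dosage: np.ndarray,
    status: np.ndarray,
    covariates: Optional[pd.DataFrame] = None,
    snp: str = "snp",
    effect_allele: str = "A1",
    other_allele: str = "A2",
) -> AssocResult:
    """Additive logistic regression of case status on one SNP's dosage.

    Returns the Wald summary for the dosage term. SNPs that cannot be fit
    (monomorphic genotype, complete separation, non-convergence) come back
    flagged with ``nan`` estimates and a ``note``; callers exclude flagged
    results from feature construction.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    dosage = np.asarray(dosage, dtype=float)
    status = np.asarray(status, dtype=float)
    n = dosage.size
    if status.sum() == 0 or status.sum() == n:
        raise ValueError("need at least one case and one control")

    def flagged(note: str) -> AssocResult:
        return AssocResult(snp, effect_allele, other_allele,
                           np.nan, np.nan, np.nan, n, note=note)

    if np.ptp(dosage) == 0:
        return flagged("monomorphic")

    X = _design_matrix(dosage, covariates)
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(status, X).fit(disp=0, method="newton", maxiter=100)
    except (PerfectSeparationError, np.linalg.LinAlgError):
        return flagged("separation")
    if not fit.mle_retvals.get("converged", False):
        return flagged("non-convergence")
    beta = float(fit.params[1])
    se = float(fit.bse[1])
    if not np.isfinite(se) or se <= 0 or se > 50:
        return flagged("separation")
    z = beta / se
    p = max(2.0 * stats.norm.sf(abs(z)), _P_FLOOR)
    return AssocResult(snp, effect_allele, other_allele, beta, se, p, n)


def trend_test(table: Sequence[Sequence[float]]) -> Tuple[float, float]:
    """Cochran-Armitage trend test on a 2x3 genotype table.

    ``table`` holds case counts in row 0 and control counts in row 1, by
    dosage class (0, 1, 2 copies). Returns the 1-df chi-square statistic
    and its p-value; dosage weights are (0, 1, 2), no continuity
    correction.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 3):
        raise ValueError("expected a 2x3 table")
    if t.sum() == 0 or t.sum(axis=1).min() == 0:
        raise ValueError("table has an empty margin")
    x = np.array([0.0, 1.0, 2.0])
    n_col = t.sum(axis=0)
    n = t.sum()
    r = t[0].sum()  # cases
    num = n * (x * t[0]).sum() - r * (x * n_col).sum()
    den = r * (n - r) * (n * (x**2 * n_col).sum() - (x * n_col).sum() ** 2)
    if den == 0:
        return 0.0, 1.0
    stat = float(n * num**2 / den)
    return stat, float(max(stats.chi2.sf(stat, df=1), _P_FLOOR))


def trend_scan(genotypes: np.ndarray, status: np.ndarray) -> pd.DataFrame:
    """Vectorized Cochran-Armitage trend scan over a genotype matrix.

    Monomorphic SNPs get ``nan`` statistics. Columns: STAT, P.
    """
    status = np.asarray(status, dtype=bool)
    g = genotypes
    counts = np.empty((2, 3, g.shape[1]))
    for dose in (0, 1, 2):
        is_d = g == dose
        counts[0, dose] = is_d[status].sum(axis=0)
        counts[1, dose] = is_d[~status].sum(axis=0)
    x = np.array([0.0, 1.0, 2.0])[:, None]
    n_col = counts.sum(axis=0)
    n = counts.sum(axis=(0, 1))
    r = counts[0].sum(axis=0)
    num = n * (x[:, 0][:, None] * counts[0]).sum(axis=0) - r * (x * n_col).sum(axis=0)
    den = r * (n - r) * (n * (x**2 * n_col).sum(axis=0) - (x * n_col).sum(axis=0) ** 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        stat = np.where(den > 0, n * num**2 / den, np.nan)
        p = stats.chi2.sf(stat, df=1)
    return pd.DataFrame({"STAT": stat, "P": p})


def allelic_scan(genotypes: np.ndarray, status: np.ndarray) -> pd.DataFrame:
    """Vectorized allelic 2x2 log odds ratio scan.

    Counts effect and other alleles in cases and controls, applies the
    Haldane-Anscombe 0.5 correction when any cell is empty, and returns
    BETA (log OR), SE and the two-sided normal p per SNP. Assumes
    Hardy-Weinberg dosages so allele counts are 2n per subject.
    Monomorphic SNPs are flagged with ``nan``.
    """
    status = np.asarray(status, dtype=bool)
    g = genotypes.astype(np.int64)
    a_case = g[status].sum(axis=0).astype(float)  # effect alleles in cases
    a_ctrl = g[~status].sum(axis=0).astype(float)
    b_case = 2.0 * status.sum() - a_case
    b_ctrl = 2.0 * (~status).sum() - a_ctrl
    cells = np.stack([a_case, b_case, a_ctrl, b_ctrl])
    mono = (a_case + a_ctrl == 0) | (b_case + b_ctrl == 0)
    needs_cc = (cells == 0).any(axis=0)
    cells = cells + 0.5 * needs_cc
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.log(cells[0] * cells[3] / (cells[1] * cells[2]))
        se = np.sqrt((1.0 / cells).sum(axis=0))
        p = 2.0 * stats.norm.sf(np.abs(beta / se))
    beta[mono] = np.nan
    se[mono] = np.nan
    p[mono] = np.nan
    return pd.DataFrame({"BETA": beta, "SE": se, "P": p})


def logistic_scan(
    study: StudyData,
    covariates: Optional[pd.DataFrame] = None,
    adjust: bool = True,
) -> pd.DataFrame:
    """Per-SNP covariate-adjusted logistic scan over a cohort.

    By default adjusts for age, study site and (in mixed strata) sex.
    Returns an association table (see :func:`assoc_table`); flagged SNPs
    carry ``nan`` and a count is logged.
    """
    if covariates is None and adjust:
        covariates = study.covariate_frame()
    results = []
    for j, snp in enumerate(study.snps):
        res = logistic_association(
            study.genotypes[:, j],
            study.status,
            covariates=covariates,
            snp=snp.id,
            effect_allele=snp.alt,
            other_allele=snp.ref,
        )
        results.append(res)
    n_flagged = sum(not r.ok for r in results)
    if n_flagged:
        logger.info("%s: %d SNP(s) flagged and excluded", study.name, n_flagged)
    return assoc_table(study, [(r.beta, r.se, r.p) for r in results],
                       notes=[r.note for r in results])


def assoc_table(
    study: StudyData,
    stats_triples: Sequence[Tuple[float, float, float]],
    notes: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Assemble a PLINK-.assoc-style summary table.

    Columns: SNP, CHR, BP, A1 (effect allele), A2, OR, SE (of the log
    odds ratio), P, N. Flagged SNPs keep their row with ``nan`` values.
    """
    beta = np.array([t[0] for t in stats_triples], dtype=float)
    se = np.array([t[1] for t in stats_triples], dtype=float)
    p = np.array([t[2] for t in stats_triples], dtype=float)
    df = pd.DataFrame(
        {
            "SNP": [s.id for s in study.snps],
            "CHR": [s.chrom for s in study.snps],
            "BP": [s.pos for s in study.snps],
            "A1": [s.alt for s in study.snps],
            "A2": [s.ref for s in study.snps],
            "OR": np.exp(beta),
            "SE": se,
            "P": p,
            "N": study.n_subjects,
        }
    )
    if notes is not None:
        df["NOTE"] = list(notes)
    return df


def scan_study(study: StudyData, method: str = "logistic") -> pd.DataFrame:
    """Run a whole-cohort association scan with the chosen method.

    ``logistic`` fits the covariate-adjusted model per SNP; ``allelic``
    is the fast contingency scan (no covariates, log OR + SE, suitable
    for meta-analysis); ``trend`` is the Cochran-Armitage screen
    (p-values only; OR column is nan).
    """
    if method == "logistic":
        return logistic_scan(study)
    if method == "allelic":
        res = allelic_scan(study.genotypes, study.status)
        return assoc_table(study, list(zip(res["BETA"], res["SE"], res["P"])))
    if method == "trend":
        res = trend_scan(study.genotypes, study.status)
        nan = np.full(len(res), np.nan)
        return assoc_table(study, list(zip(nan, nan, res["P"].to_numpy())))
    raise ValueError(f"unknown association method {method!r}")


__all__.append("scan_study")
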