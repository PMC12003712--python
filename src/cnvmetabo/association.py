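"""Dosage–metabolite association: reverse regression, signatures, corrections.

The association direction follows the multi-phenotype reverse-regression
idea: the CNV dosage (countAll, a continuous expectation in [0, 4]) is the
regression *outcome* and metabolites are predictors, so a joint model over
all phenotypes is a single fit. Univariate models test one metabolite at a
time; the multivariate "metabolomic signature" is the metabolite subset
surviving backward variable selection in the joint model. Covariates (sex and
LRR principal components) are always retained.

Multiple-testing correction uses the effective number of independent tests
from the eigenvalue variance of the metabolite correlation matrix
(Sidak–Nyholt): M_eff = 1 + (M − 1)(1 − Var(λ)/M), with the Sidak
exponentiation p_adj = 1 − (1 − p)^M_eff.

A nonparametric validation stratifies samples by countAll thresholds
(deletion < 1.75, duplication > 2.5) and compares phenotype distributions by
Mann–Whitney U.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy.stats import mannwhitneyu

from .cnv_hmm import cnv_allele_frequency
from .simulate import PhenotypePanel

__all__ = [
    "AssociationRecord",
    "SignatureRecord",
    "EffectiveTests",
    "GLOBAL_P_FILTER",
    "DEL_CUT",
    "DUP_CUT",
    "univariate_assoc",
    "multivariate_signature",
    "lrr_assoc",
    "effective_tests",
    "adjust_p",
    "stratified_validation",
]

GLOBAL_P_FILTER = 0.05
DEL_CUT = 1.75
DUP_CUT = 2.5


@dataclass(frozen=True)
class AssociationRecord:
    probe_id: str
    metabolite_name: str
    beta: float
    se: float
    p_raw: float
    p_adjusted: float
    n: int
    maf: float
    model: str  # "dosage" or "lrr"
    reportable: bool = False


@dataclass(frozen=True)
class SignatureRecord:
    probe_id: str
    selected_metabolites: tuple[str, ...]
    joint_p_raw: float
    joint_p_adjusted: float
    betas: dict[str, float] = field(default_factory=dict)
    n: int = 0
    maf: float = float("nan")
    model: str = "dosage"

    @property
    def reportable(self) -> bool:
        return bool(self.selected_metabolites) and self.joint_p_adjusted <= GLOBAL_P_FILTER


@dataclass(frozen=True)
class EffectiveTests:
    m: int
    var_lambda: float
    m_effective: float


def _design(covariates: np.ndarray | None, *columns: np.ndarray) -> np.ndarray:
    parts = [np.ones((len(columns[0]), 1))]
    parts.extend(c.reshape(len(c), -1) for c in columns)
    if covariates is not None and covariates.size:
        parts.append(covariates)
    return np.hstack(parts)


def _drop_collinear(X: np.ndarray, names: list[str], n_protected: int) -> tuple[np.ndarray, list[str]]:
    """Drop collinear trailing covariates (never the first n_protected columns)."""
    if np.linalg.matrix_rank(X) == X.shape[1]:
        return X, names
    keep = list(range(n_protected))
    for j in range(n_protected, X.shape[1]):
        trial = X[:, keep + [j]]
        if np.linalg.matrix_rank(trial) == len(keep) + 1:
            keep.append(j)
        else:
            warnings.warn(f"dropping collinear design column {names[j]}", stacklevel=3)
    return X[:, keep], [names[i] for i in keep]


def _ols(y: np.ndarray, X: np.ndarray):
    return sm.OLS(y, X).fit()


def effective_tests(corr: np.ndarray) -> EffectiveTests:
    """Effective number of independent tests from eigenvalue dispersion.

    Identity correlation gives Var(λ) = 0 hence M_eff = M; a rank-one
    all-ones correlation gives sample Var(λ) = M hence M_eff = 1.
    """
    corr = np.asarray(corr, dtype=float)
    m = corr.shape[0]
    if corr.shape != (m, m) or not np.allclose(corr, corr.T, atol=1e-8):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(corr), 1.0, atol=1e-6):
        raise ValueError("correlation matrix must have unit diagonal")
    lam = np.linalg.eigvalsh(corr)
    if lam.min() < -1e-6 * m:
        raise ValueError("correlation matrix is not positive semidefinite")
    var_lambda = float(np.var(lam, ddof=1)) if m > 1 else 0.0
    m_eff = 1.0 + (m - 1) * (1.0 - var_lambda / m)
    return EffectiveTests(m=m, var_lambda=var_lambda, m_effective=float(np.clip(m_eff, 1.0, m)))


def adjust_p(p_raw: float, m_effective: float) -> float:
    """Sidak-style adjustment 1 − (1 − p)^M_eff, numerically stable near 0."""
    if not 0 < p_raw <= 1:
        raise ValueError("p_raw must lie in (0, 1]")
    return float(min(1.0, -np.expm1(m_effective * np.log1p(-p_raw))))


def _assoc_core(
    outcome: np.ndarray,
    phenotypes: PhenotypePanel,
    covariates: np.ndarray | None,
    probe_id: str,
    model_tag: str,
    maf: float,
) -> list[AssociationRecord]:
    met = phenotypes.metabolites
    n, m = met.shape
    m_eff = effective_tests(np.corrcoef(met, rowvar=False)).m_effective if m > 1 else 1.0
    records = []
    for j in range(m):
        X = _design(covariates, met[:, j])
        names = ["const", phenotypes.metabolite_names[j]] + [
            f"cov{k}" for k in range(X.shape[1] - 2)
        ]
        X, names = _drop_collinear(X, names, n_protected=2)
        res = _ols(outcome, X)
        beta, se, p = res.params[1], res.bse[1], res.pvalues[1]
        p = float(np.clip(p, np.nextafter(0, 1), 1.0))
        p_adj = adjust_p(p, m_eff)
        records.append(
            AssociationRecord(
                probe_id=probe_id,
                metabolite_name=phenotypes.metabolite_names[j],
                beta=float(beta),
                se=float(se),
                p_raw=p,
                p_adjusted=p_adj,
                n=n,
                maf=maf,
                model=model_tag,
                reportable=p_adj <= GLOBAL_P_FILTER,
            )
        )
    return records


def univariate_assoc(
    dosage: np.ndarray,
    phenotypes: PhenotypePanel,
    covariates: np.ndarray | None = None,
    probe_id: str = "probe",
) -> list[AssociationRecord]:
    """Reverse regression dosage ~ metabolite + covariates, one metabolite at a time."""
    maf = cnv_allele_frequency(dosage)
    if covariates is None:
        covariates = phenotypes.covariates
    return _assoc_core(dosage, phenotypes, covariates, probe_id, "dosage", maf)


def lrr_assoc(
    lrr_column: np.ndarray,
    phenotypes: PhenotypePanel,
    covariates: np.ndarray | None = None,
    probe_id: str = "probe",
) -> list[AssociationRecord]:
    """Calling-free validation model: corrected LRR as the regression outcome."""
    if covariates is None:
        covariates = phenotypes.covariates
    return _assoc_core(lrr_column, phenotypes, covariates, probe_id, "lrr", float("nan"))


def multivariate_signature(
    dosage: np.ndarray,
    phenotypes: PhenotypePanel,
    covariates: np.ndarray | None = None,
    drop_alpha: float = 0.05,
    probe_id: str = "probe",
    model_tag: str = "dosage",
) -> SignatureRecord:
    """Backward variable selection on the joint reverse-regression model.

    Starting from dosage ~ all metabolites + covariates, refit and remove the
    largest-p metabolite while it exceeds ``drop_alpha`` (covariates are never
    candidates). The signature's joint p is the F-test of the final metabolite
    block against the covariate-only model; an empty final set yields p = 1.
    When n is too small for the full joint fit, metabolites are pre-screened
    to the top min(M, n // 10) by univariate p.
    """
    if covariates is None:
        covariates = phenotypes.covariates
    met = phenotypes.metabolites
    names = list(phenotypes.metabolite_names)
    n, m = met.shape
    n_cov = 0 if covariates is None else covariates.shape[1]
    m_eff = effective_tests(np.corrcoef(met, rowvar=False)).m_effective if m > 1 else 1.0
    maf = cnv_allele_frequency(dosage) if model_tag == "dosage" else float("nan")

    active = list(range(m))
    if n <= m + n_cov + 2:
        uni = _assoc_core(dosage, phenotypes, covariates, probe_id, model_tag, maf)
        order = np.argsort([r.p_raw for r in uni])
        keep = min(m, max(1, n // 10))
        active = sorted(int(i) for i in order[:keep])
        warnings.warn(
            f"n={n} too small for joint fit of {m} metabolites; pre-screened to {keep}",
            stacklevel=2,
        )

    while active:
        X = _design(covariates, met[:, active])
        # columns: const, metabolites..., covariates
        res = _ols(dosage, X)
        pvals = res.pvalues[1 : 1 + len(active)]
        worst = int(np.argmax(pvals))
        if pvals[worst] > drop_alpha:
            active.pop(worst)
        else:
            break

    if not active:
        return SignatureRecord(
            probe_id=probe_id,
            selected_metabolites=(),
            joint_p_raw=1.0,
            joint_p_adjusted=1.0,
            betas={},
            n=n,
            maf=maf,
            model=model_tag,
        )

    X_full = _design(covariates, met[:, active])
    res_full = _ols(dosage, X_full)
    X_null = _design(covariates, np.empty((n, 0)))
    res_null = _ols(dosage, X_null)
    f_test = res_full.compare_f_test(res_null)
    joint_p = float(np.clip(f_test[1], np.nextafter(0, 1), 1.0))
    betas = {names[i]: float(res_full.params[1 + k]) for k, i in enumerate(active)}
    return SignatureRecord(
        probe_id=probe_id,
        selected_metabolites=tuple(names[i] for i in active),
        joint_p_raw=joint_p,
        joint_p_adjusted=adjust_p(joint_p, m_eff),
        betas=betas,
        n=n,
        maf=maf,
        model=model_tag,
    )


def stratified_validation(
    count_all: np.ndarray,
    phenotype: np.ndarray,
    del_cut: float = DEL_CUT,
    dup_cut: float = DUP_CUT,
) -> dict:
    """Threshold countAll into deletion/neutral/duplication; Mann–Whitney tests.

    Returns the group labels and two-sided U-test p-values for deletion vs
    neutral and duplication vs neutral; a comparison with fewer than 2 samples
    in either group is skipped with an informative status.
    """
    c = np.asarray(count_all, dtype=float)
    labels = np.where(c < del_cut, "deletion", np.where(c > dup_cut, "duplication", "neutral"))
    out: dict = {"labels": labels}
    neutral = phenotype[labels == "neutral"]
    for group in ("deletion", "duplication"):
        vals = phenotype[labels == group]
        key = f"p_{group}_vs_neutral"
        if len(vals) < 2 or len(neutral) < 2:
            out[key] = None
            out[f"status_{group}"] = "skipped: fewer than 2 samples in a group"
            continue
        total = len(vals) + len(neutral)
        method = "exact" if (total < 25 and _no_ties(vals, neutral)) else "asymptotic"
        stat = mannwhitneyu(vals, neutral, alternative="two-sided", method=method)
        out[key] = float(stat.pvalue)
        out[f"status_{group}"] = "ok"
    return out


def _no_ties(a: np.ndarray, b: np.ndarray) -> bool:
    both = np.concatenate([a, b])
    return len(np.unique(both)) == len(both)
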