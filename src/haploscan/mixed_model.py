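"""REML variance components, mixed-model haplotype scan, GREML heritability.

Model
-----
The discovery-cohort model is

    y = X b + Z1 u + Z2 v + e,   u ~ N(0, G s2_u),  v ~ N(0, G_t s2_v),
                                 e ~ N(0, I s2_e)

with y the (standardized) general cognitive ability score, X the fixed
effects (intercept, haplotype dosage, sex, age, optional batch/centre),
G the leave-one-chromosome-out genomic relationship matrix and G_t its
close-relative thresholded counterpart.  Replication cohorts drop the
second random effect.  Variance components are estimated by average-
information REML with an expectation-maximisation warm-up; components are
constrained non-negative (pinned near zero at the boundary, re-entering
when their gradient turns positive).

The genome scan estimates the variance components once per chromosome
under the null (no haplotype term) and holds them fixed for every
haplotype on that chromosome; each haplotype's effect is then the
generalised-least-squares solution

    beta = d'Py / d'Pd,   se = (d'Pd)^{-1/2}

with P the projection V^{-1} - V^{-1}X(X'V^{-1}X)^{-1}X'V^{-1} under the
null V.  This is the usual mixed-linear-model association approximation;
an exact refit per haplotype is available behind a flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cho_factor, cho_solve

from .grm import GRM, GRMSet, threshold_grm
from .windows import HaplotypeAllele

_MIN_FRAC = 1e-6  # boundary pin, as a fraction of phenotypic variance


@dataclass
class REMLResult:
    """Variance component estimates with AI-matrix standard errors."""

    variance_components: np.ndarray  # one per GRM, residual last
    se: np.ndarray
    loglik: float
    converged: bool
    n_iter: int
    ai_covariance: np.ndarray

    @property
    def residual_variance(self) -> float:
        return float(self.variance_components[-1])

    def heritability(self) -> tuple[float, float]:
        """h2 = s2_g / total for the single-GRM model, with delta-method s.e."""
        if len(self.variance_components) != 2:
            raise ValueError("heritability() is defined for the one-GRM model")
        a, b = self.variance_components
        total = a + b
        h2 = a / total
        grad = np.array([b, -a]) / total**2
        var = float(grad @ self.ai_covariance @ grad)
        return float(h2), float(np.sqrt(max(var, 0.0)))


def _check_design(X: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] < X.shape[1]:
        X = X.T
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("fixed-effect design matrix is singular")
    return X


class _DirectKernel:
    """Per-iteration REML quantities for arbitrarily many GRMs (O(n^3))."""

    def __init__(self, y, X, kernels):
        self.y = y
        self.X = X
        self.kernels = kernels  # GRM matrices; identity appended implicitly
        self.n = len(y)

    def stats(self, theta):
        n = self.n
        V = theta[-1] * np.eye(n)
        for t, K in zip(theta[:-1], self.kernels):
            V += t * K
        c, low = cho_factor(V, lower=True)
        logdet_v = 2.0 * float(np.sum(np.log(np.diag(c))))
        vinv = cho_solve((c, low), np.eye(n))
        vinv_x = vinv @ self.X
        A = self.X.T @ vinv_x
        sign, logdet_a = np.linalg.slogdet(A)
        P = vinv - vinv_x @ np.linalg.solve(A, vinv_x.T)
        Py = P @ self.y
        loglik = -0.5 * (logdet_v + logdet_a + float(self.y @ Py))

        mats = self.kernels + [None]  # None = identity
        k = len(mats)
        tr_pk = np.empty(k)
        t_vecs = np.empty((n, k))
        for i, K in enumerate(mats):
            if K is None:
                tr_pk[i] = float(np.trace(P))
                t_vecs[:, i] = Py
            else:
                tr_pk[i] = float(np.sum(P * K))
                t_vecs[:, i] = K @ Py
        ypkpy = t_vecs.T @ Py
        ai = 0.5 * (t_vecs.T @ (P @ t_vecs))
        score = -0.5 * (tr_pk - ypkpy)
        return loglik, score, ai


class _EigenKernel:
    """Single-GRM REML via eigendecomposition (O(n^3) once, O(n p^2) per step)."""

    def __init__(self, y, X, grm_matrix):
        d, U = np.linalg.eigh(grm_matrix)
        self.d = np.maximum(d, 0.0)
        self.ystar = U.T @ y
        self.Xstar = U.T @ X

    def stats(self, theta):
        d, ys, Xs = self.d, self.ystar, self.Xstar
        v = theta[0] * d + theta[1]
        w = 1.0 / v
        wX = Xs * w[:, None]
        A = Xs.T @ wX
        sign, logdet_a = np.linalg.slogdet(A)
        Ainv = np.linalg.inv(A)
        Py = w * ys - wX @ (Ainv @ (wX.T @ ys))
        loglik = -0.5 * (float(np.sum(np.log(v))) + logdet_a + float(ys @ Py))

        kernels = [d, np.ones_like(d)]
        k = 2
        tr_pk = np.empty(k)
        t_vecs = np.empty((len(d), k))
        for i, kv in enumerate(kernels):
            tr_pk[i] = float(np.sum(w * kv)) - float(
                np.trace(Ainv @ ((wX.T * kv) @ wX))
            )
            t_vecs[:, i] = kv * Py
        ypkpy = t_vecs.T @ Py
        Pt = t_vecs * w[:, None] - wX @ (Ainv @ (wX.T @ t_vecs))
        ai = 0.5 * (t_vecs.T @ Pt)
        score = -0.5 * (tr_pk - ypkpy)
        return loglik, score, ai


def fit_reml(
    y,
    X,
    grms: list,
    tol: float = 1e-8,
    max_iter: int = 100,
    em_iters: int = 3,
) -> REMLResult:
    """Average-information REML for one or two (or more) GRMs plus residual.

    The first ``em_iters`` iterations use the (slower, monotone) EM update
    for stability, then AI steps with step-halving whenever the restricted
    log-likelihood would decrease.  Components are constrained to at least
    ``1e-6 x var(y)``; a pinned component re-enters whenever its gradient
    is positive because every update moves all components.
    """
    y = np.asarray(y, dtype=float)
    X = _check_design(X)
    mats = [np.asarray(g.matrix if isinstance(g, GRM) else g, dtype=float) for g in grms]
    if len(y) < X.shape[1] + 2:
        raise ValueError("not enough observations for REML")

    vp = float(np.var(y, ddof=1))
    floor = _MIN_FRAC * vp
    k = len(mats) + 1
    theta = np.full(k, vp / k)

    kernel = _EigenKernel(y, X, mats[0]) if len(mats) == 1 else _DirectKernel(y, X, mats)
    loglik, score, ai = kernel.stats(theta)
    converged = False
    it = 0
    n = len(y)
    for it in range(1, max_iter + 1):
        # active set: components pinned at the floor with negative gradient
        # are held fixed this iteration; they re-enter if the gradient
        # turns positive.
        free = (theta > floor * 1.001) | (score > 0)
        if not free.any():
            converged = True
            break
        delta = np.zeros(k)
        em_delta = theta**2 * (2.0 * score) / n  # EM: theta^2 (y'PKPy - trPK)/n
        if it <= em_iters:
            delta[free] = em_delta[free]
        else:
            # pseudoinverse: robust to an unidentifiable component (e.g. a
            # zero or duplicated GRM), which leaves AI rank-deficient
            delta[free] = np.linalg.pinv(
                ai[np.ix_(free, free)], rcond=1e-10
            ) @ score[free]
        step = 1.0
        accepted = False
        for _ in range(30):
            trial = np.maximum(theta + step * delta, floor)
            try:
                new_ll, new_score, new_ai = kernel.stats(trial)
            except np.linalg.LinAlgError:
                step *= 0.5
                continue
            if np.isfinite(new_ll) and (new_ll >= loglik - 1e-10 or it <= em_iters):
                accepted = True
                break
            step *= 0.5
        if not accepted:
            break  # no acceptable step: stop at current estimates
        change = abs(new_ll - loglik)
        theta, loglik, score, ai = trial, new_ll, new_score, new_ai
        if change < tol * (1.0 + abs(loglik)):
            converged = True
            break
    if not converged:
        warnings.warn("REML did not converge; returning last iterate", stacklevel=2)

    try:
        cov = np.linalg.inv(ai)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        cov = np.full((k, k), np.nan)
        se = np.full(k, np.nan)
    return REMLResult(
        variance_components=theta,
        se=se,
        loglik=float(loglik),
        converged=converged,
        n_iter=it,
        ai_covariance=cov,
    )


def null_projection(y, X, grms: list, theta) -> tuple[np.ndarray, np.ndarray]:
    """Explicit P matrix and P y under fixed variance components."""
    y = np.asarray(y, dtype=float)
    X = _check_design(X)
    n = len(y)
    V = theta[-1] * np.eye(n)
    for t, g in zip(theta[:-1], grms):
        V += t * np.asarray(g.matrix if isinstance(g, GRM) else g)
    c = cho_factor(V, lower=True)
    vinv = cho_solve(c, np.eye(n))
    vinv_x = vinv @ X
    A = X.T @ vinv_x
    P = vinv - vinv_x @ np.linalg.solve(A, vinv_x.T)
    return P, P @ y


def gls_association(P: np.ndarray, Py: np.ndarray, dosage: np.ndarray,
                    var_y: float) -> tuple[float, float, float, float]:
    """Single-haplotype GLS: beta, se, two-sided Wald P, variance explained."""
    d = np.asarray(dosage, dtype=float)
    dPd = float(d @ (P @ d))
    if d.var() == 0 or dPd <= 1e-10 * len(d):
        return np.nan, np.nan, np.nan, np.nan
    beta = float(d @ Py) / dPd
    se = 1.0 / np.sqrt(dPd)
    p = 2.0 * float(stats.norm.sf(abs(beta) / se))
    ve = beta**2 * float(np.var(d)) / var_y
    return beta, se, p, ve


def scan_haplotypes(
    y,
    covariates,
    haplotypes: list[HaplotypeAllele],
    grm_set: GRMSet,
    two_grm: bool = True,
    grm_cutoff: float = 0.05,
    cohort_label: str = "",
    refit_per_haplotype: bool = False,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> pd.DataFrame:
    """Mixed-model association scan over haplotype alleles.

    Variance components are fitted once per chromosome under the null
    (LOCO G, plus thresholded G_t when ``two_grm``) and reused for every
    haplotype on that chromosome.  Haplotypes whose dosage is constant or
    collinear with the covariates are flagged untestable (NaN estimates).
    """
    y = np.asarray(y, dtype=float)
    X = _check_design(covariates)
    var_y = float(np.var(y))
    by_chrom: dict = {}
    for hap in haplotypes:
        by_chrom.setdefault(hap.chrom, []).append(hap)

    rows = []
    for chrom, haps in by_chrom.items():
        g_loco = grm_set.loco(chrom)
        grms = [g_loco, threshold_grm(g_loco, grm_cutoff)] if two_grm else [g_loco]
        res = fit_reml(y, X, grms, tol=tol, max_iter=max_iter)
        P, Py = null_projection(y, X, grms, res.variance_components)
        dosage_mat = np.stack([h.dosage for h in haps]).astype(float)  # (H, n)
        PD = dosage_mat @ P  # row h = (P d_h)'  (P symmetric)
        num = PD @ y
        den = np.einsum("ij,ij->i", PD, dosage_mat)
        for idx, hap in enumerate(haps):
            d = dosage_mat[idx]
            if refit_per_haplotype and d.var() > 0:
                Xh = np.column_stack([X, d])
                try:
                    res_h = fit_reml(y, Xh, grms, tol=tol, max_iter=max_iter)
                    Ph, Pyh = null_projection(y, X, grms, res_h.variance_components)
                    beta, se, p, ve = gls_association(Ph, Pyh, d, var_y)
                except (ValueError, np.linalg.LinAlgError):
                    beta = se = p = ve = np.nan
            elif d.var() == 0 or den[idx] <= 1e-10 * len(d):
                beta = se = p = ve = np.nan
            else:
                beta = num[idx] / den[idx]
                se = 1.0 / np.sqrt(den[idx])
                p = 2.0 * float(stats.norm.sf(abs(beta) / se))
                ve = beta**2 * float(np.var(d)) / var_y
            rows.append(
                {
                    "hap_id": hap.hap_id,
                    "chr": chrom,
                    "bp_start": hap.window.bp_start,
                    "bp_end": hap.window.bp_end,
                    "allele_string": hap.allele_string,
                    "freq": hap.frequency,
                    "beta": beta,
                    "se": se,
                    "p": p,
                    "var_explained": ve,
                    "cohort": cohort_label,
                    "untestable": not np.isfinite(beta),
                }
            )
    return pd.DataFrame(rows)


def greml_h2(y, covariates, grm: GRM, tol: float = 1e-8,
             max_iter: int = 100) -> tuple[float, float, REMLResult]:
    """SNP heritability of ``y`` from a single GRM (GREML).

    Callers should pass an unrelated subset (relatedness pruned at 0.025)
    to avoid close-relative inflation; see
    :func:`haploscan.grm.unrelated_subset`.
    """
    res = fit_reml(np.asarray(y, float), covariates, [grm], tol=tol, max_iter=max_iter)
    h2, se = res.heritability()
    return h2, se, res


def lambda_gc(pvalues) -> float:
    """Genomic-control inflation: median observed chi2(1) over its null median."""
    p = np.asarray(pvalues, dtype=float)
    p = p[np.isfinite(p)]
    if len(p) < 100:
        raise ValueError("lambda_gc needs at least 100 P-values")
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / stats.chi2.isf(0.5, df=1))


# ---------------------------------------------------------------------------
# estimator-style wrappers


class VarianceComponentsREML:
    """Estimator-style wrapper around :func:`fit_reml`.

    After ``fit(X, y, grms=[...])`` exposes ``variance_components_``,
    ``se_``, ``loglik_``, ``converged_``.
    """

    def __init__(self, tol: float = 1e-8, max_iter: int = 100, em_iters: int = 3):
        self.tol = tol
        self.max_iter = max_iter
        self.em_iters = em_iters

    def get_params(self, deep=True):
        return {"tol": self.tol, "max_iter": self.max_iter, "em_iters": self.em_iters}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, X, y, grms: list):
        res = fit_reml(y, X, grms, tol=self.tol, max_iter=self.max_iter,
                       em_iters=self.em_iters)
        self.result_ = res
        self.variance_components_ = res.variance_components
        self.se_ = res.se
        self.loglik_ = res.loglik
        self.converged_ = res.converged
        return self


class GremlHeritability(VarianceComponentsREML):
    """GREML SNP-heritability estimator: ``fit`` sets ``h2_`` and ``h2_se_``."""

    def fit(self, X, y, grms: list):
        if len(grms) != 1:
            raise ValueError("GREML heritability uses exactly one GRM")
        super().fit(X, y, grms)
        self.h2_, self.h2_se_ = self.result_.heritability()
        return self


class HaplotypeScanner:
    """Configured genome scan; ``fit`` runs the scan and sets ``results_``."""

    def __init__(self, two_grm: bool = True, grm_cutoff: float = 0.05,
                 cohort_label: str = "", refit_per_haplotype: bool = False,
                 tol: float = 1e-8, max_iter: int = 100):
        self.two_grm = two_grm
        self.grm_cutoff = grm_cutoff
        self.cohort_label = cohort_label
        self.refit_per_haplotype = refit_per_haplotype
        self.tol = tol
        self.max_iter = max_iter

    def get_params(self, deep=True):
        return {
            "two_grm": self.two_grm, "grm_cutoff": self.grm_cutoff,
            "cohort_label": self.cohort_label,
            "refit_per_haplotype": self.refit_per_haplotype,
            "tol": self.tol, "max_iter": self.max_iter,
        }

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, y, covariates, haplotypes, grm_set: GRMSet):
        self.results_ = scan_haplotypes(
            y, covariates, haplotypes, grm_set,
            two_grm=self.two_grm, grm_cutoff=self.grm_cutoff,
            cohort_label=self.cohort_label,
            refit_per_haplotype=self.refit_per_haplotype,
            tol=self.tol, max_iter=self.max_iter,
        )
        return self
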