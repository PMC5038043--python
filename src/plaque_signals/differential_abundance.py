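"""Negative-binomial GLM differential abundance.

Per-taxon model: counts y_ij ~ NB(mu_ij, alpha_i) with variance
mu + alpha*mu^2 and log link,

    ln mu_ij = ln s_j + x_j' beta_i,

where s_j is a median-of-ratios size factor and x_j contains gingivitis
(BoP, continuous 0-6), periodontitis (binary) and adjustment terms
(study site, nutritional intervention arm, HIV status, sequencing run).
Coefficients are fit by iteratively reweighted least squares,
dispersion by profile maximum likelihood, inference by Wald tests with
Benjamini-Hochberg correction across taxa.

This is the NB-GLM core of the RNA-seq-style count model; no
empirical-Bayes dispersion shrinkage, outlier replacement or
independent filtering is applied — per-taxon MLE dispersion is used
throughout (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .io_core import CountMatrix, ValidationError

__all__ = [
    "DesignSpec",
    "GLMFailure",
    "size_factors",
    "build_design_matrix",
    "nb_loglik",
    "fit_nb_glm",
    "estimate_dispersion",
    "wald_bh",
    "run_differential_abundance",
]

DISPERSION_FLOOR = 1e-8


class GLMFailure(RuntimeError):
    """A per-taxon fit failed (separation, divergence, degenerate data)."""


@dataclass
class DesignSpec:
    """Model design: focal covariates plus adjustment terms."""

    continuous: tuple[str, ...] = ("bop",)
    binary: tuple[str, ...] = ("periodontitis",)
    categorical: tuple[str, ...] = ("site", "intervention", "seqrun")
    boolean: tuple[str, ...] = ("hiv",)
    intercept: bool = True

    def all_terms(self) -> tuple[str, ...]:
        return self.continuous + self.binary + self.categorical + self.boolean


def size_factors(counts: CountMatrix, pseudo_reference: bool = False) -> np.ndarray:
    """Median-of-ratios per-sample normalization factors.

    Reference taxa are those observed in every sample (no zero count);
    factor_j is the median over reference taxa of
    counts_ij / geometric-mean_i, rescaled so the factors' geometric
    mean is 1.  With ``pseudo_reference`` the geometric mean is taken
    over positive counts only, allowing tables with no all-positive
    taxon.
    """
    mat = counts.counts.astype(float)
    if pseudo_reference:
        with np.errstate(divide="ignore"):
            logs = np.where(mat > 0, np.log(mat), np.nan)
        log_geo = np.nanmean(logs, axis=1)
        usable = ~np.isnan(log_geo)
        ratios = np.where(mat > 0, mat / np.exp(log_geo)[:, None], np.nan)
        factors = np.nanmedian(ratios[usable], axis=0)
    else:
        reference = (mat > 0).all(axis=1)
        if not reference.any():
            raise ValidationError(
                "no taxon has positive counts in every sample; "
                "retry with pseudo_reference=True"
            )
        sub = mat[reference]
        geo = np.exp(np.log(sub).mean(axis=1))
        factors = np.median(sub / geo[:, None], axis=0)
    if np.any(~np.isfinite(factors)) or np.any(factors <= 0):
        raise ValidationError("non-positive size factor encountered")
    factors = factors / np.exp(np.log(factors).mean())
    return factors


def build_design_matrix(
    meta: pd.DataFrame, design: DesignSpec
) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Build a full-rank treatment-coded design matrix.

    Categorical terms use the lexicographically first observed level as
    reference.  Returns (matrix, column names, complete-case mask in
    the order of ``meta``); rows with any missing design covariate are
    excluded from the matrix.
    """
    cols: list[pd.Series] = []
    names: list[str] = []
    mask = np.ones(len(meta), dtype=bool)
    for term in design.all_terms():
        if term not in meta.columns:
            raise ValidationError(f"design term {term!r} missing from metadata")
        mask &= meta[term].notna().to_numpy()
    sub = meta.loc[mask]
    parts = []
    if design.intercept:
        parts.append(np.ones((len(sub), 1)))
        names.append("(intercept)")
    for term in design.continuous:
        parts.append(sub[term].to_numpy(dtype=float).reshape(-1, 1))
        names.append(term)
    for term in design.binary + design.boolean:
        parts.append(sub[term].to_numpy(dtype=float).reshape(-1, 1))
        names.append(term)
    for term in design.categorical:
        levels = sorted(set(sub[term].astype(str)))
        for level in levels[1:]:
            parts.append(
                (sub[term].astype(str) == level).to_numpy(dtype=float).reshape(-1, 1)
            )
            names.append(f"{term}[{level}]")
    X = np.hstack(parts) if parts else np.empty((len(sub), 0))
    if X.shape[1] and np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValidationError("design matrix is rank deficient")
    return X, names, mask


def nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: float) -> float:
    """Log likelihood of NB with variance mu + alpha*mu^2."""
    inv = 1.0 / alpha
    return float(
        np.sum(
            gammaln(y + inv)
            - gammaln(inv)
            - gammaln(y + 1.0)
            + y * np.log(alpha * mu / (1.0 + alpha * mu))
            - inv * np.log1p(alpha * mu)
        )
    )


def fit_nb_glm(
    taxon_counts: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    alpha: float,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit a log-link NB regression by IRLS.

    ``offset`` is the log size factor.  Returns (coefficients, standard
    errors from the Fisher information at the optimum).  Raises
    ``GLMFailure`` on divergence or non-finite iterates.
    """
    y = np.asarray(taxon_counts, dtype=float)
    n, k = X.shape
    if n <= k:
        raise GLMFailure("fewer observations than coefficients")
    # initialize from a least-squares fit to the shifted log counts
    z0 = np.log(y + 0.5) - offset
    beta, *_ = np.linalg.lstsq(X, z0, rcond=None)
    for _ in range(max_iter):
        eta = X @ beta + offset
        eta = np.clip(eta, -30.0, 30.0)
        mu = np.exp(eta)
        w = mu / (1.0 + alpha * mu)  # Fisher weights for log link
        z = (eta - offset) + (y - mu) / mu
        wx = X * w[:, None]
        try:
            beta_new = np.linalg.solve(X.T @ wx, wx.T @ z)
        except np.linalg.LinAlgError as exc:
            raise GLMFailure(f"singular weighted system: {exc}") from exc
        if not np.all(np.isfinite(beta_new)):
            raise GLMFailure("non-finite coefficients during IRLS")
        step = np.max(np.abs(beta_new - beta)) / max(1.0, np.max(np.abs(beta_new)))
        beta = beta_new
        if step < tol:
            break
    else:
        raise GLMFailure("IRLS did not converge within max_iter")
    mu = np.exp(np.clip(X @ beta + offset, -30.0, 30.0))
    w = mu / (1.0 + alpha * mu)
    info = X.T @ (X * w[:, None])
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError as exc:
        raise GLMFailure(f"singular Fisher information: {exc}") from exc
    se = np.sqrt(np.diag(cov))
    return beta, se


def _mom_dispersion(y: np.ndarray, mu: np.ndarray) -> float:
    """Method-of-moments fallback: solve var = mu + alpha mu^2."""
    num = np.sum((y - mu) ** 2 - mu)
    den = np.sum(mu**2)
    return max(num / den if den > 0 else DISPERSION_FLOOR, DISPERSION_FLOOR)


def estimate_dispersion(
    taxon_counts: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    alpha_max: float = 50.0,
) -> float:
    """Profile-likelihood MLE of the NB dispersion.

    Maximizes the NB log likelihood over alpha, refitting the GLM
    coefficients at each candidate (profiling); floored at 1e-8.  Falls
    back to a method-of-moments estimate if the profile optimization
    fails.
    """
    y = np.asarray(taxon_counts, dtype=float)
    n, k = X.shape
    if n - k < 2:
        raise ValidationError("need >= 2 residual degrees of freedom")

    def negloglik(log_alpha: float) -> float:
        a = float(np.exp(log_alpha))
        try:
            beta, _ = fit_nb_glm(y, X, offset, a)
        except GLMFailure:
            return np.inf
        mu = np.exp(np.clip(X @ beta + offset, -30.0, 30.0))
        return -nb_loglik(y, mu, a)

    try:
        res = minimize_scalar(
            negloglik,
            bounds=(np.log(DISPERSION_FLOOR), np.log(alpha_max)),
            method="bounded",
            options={"xatol": 1e-6},
        )
        if not np.isfinite(res.fun):
            raise GLMFailure("profile likelihood not finite")
        return max(float(np.exp(res.x)), DISPERSION_FLOOR)
    except GLMFailure:
        # Poisson fit for the fallback mean
        try:
            beta, _ = fit_nb_glm(y, X, offset, DISPERSION_FLOOR)
            mu = np.exp(np.clip(X @ beta + offset, -30.0, 30.0))
        except GLMFailure:
            mu = np.full_like(y, max(y.mean(), 1e-8))
        import warnings

        warnings.warn("dispersion MLE failed; using method-of-moments estimate")
        return _mom_dispersion(y, mu)


def wald_bh(results: pd.DataFrame, alpha_level: float = 0.05) -> pd.DataFrame:
    """Wald z tests with BH correction.

    ``results`` needs columns ``beta`` and ``se``; adds ``wald_z``,
    ``p``, ``q``, ``significant`` and a ``direction`` label
    (disease- vs health-associated by the sign of beta).
    """
    out = results.copy()
    out["wald_z"] = out["beta"] / out["se"]
    out["p"] = 2.0 * norm.sf(np.abs(out["wald_z"]))
    if len(out):
        _, qvals, _, _ = multipletests(out["p"].to_numpy(), method="fdr_bh")
        out["q"] = qvals
    else:
        out["q"] = []
    out["significant"] = out["q"] < alpha_level
    out["direction"] = np.where(
        out["beta"] > 0, "disease-associated", "health-associated"
    )
    return out


def run_differential_abundance(
    counts: CountMatrix,
    meta: pd.DataFrame,
    design: DesignSpec | None = None,
    fdr: float = 0.05,
    min_nonzero_samples: int = 5,
    pseudo_reference: bool = False,
) -> dict:
    """Fit the joint NB-GLM to every taxon; report per focal covariate.

    One model per taxon contains both focal covariates (BoP and
    periodontitis) and all adjustment terms; separate BH-corrected
    result tables are returned for the BoP and periodontitis
    coefficients, plus the intersection report (taxa associated with
    periodontitis but not with gingivitis, and vice versa) and the
    skipped-taxon log.
    """
    design = design or DesignSpec()
    X, names, mask = build_design_matrix(meta, design)
    kept_samples = [s for s, m in zip(meta["sample_id"].astype(str), mask) if m]
    sub_counts = counts.select_samples(kept_samples)
    factors = size_factors(sub_counts, pseudo_reference=pseudo_reference)
    offset = np.log(factors)

    focal = {}
    for term in design.continuous + design.binary:
        focal[term] = names.index(term)

    rows = {term: [] for term in focal}
    skipped: list[tuple[str, str]] = []
    base_means = (sub_counts.counts / factors[None, :]).mean(axis=1)
    for i, taxon in enumerate(sub_counts.taxon_ids):
        y = sub_counts.counts[i]
        if np.count_nonzero(y) < min_nonzero_samples:
            skipped.append((taxon, "too few nonzero counts"))
            continue
        try:
            alpha = estimate_dispersion(y, X, offset)
            beta, se = fit_nb_glm(y, X, offset, alpha)
        except (GLMFailure, ValidationError) as exc:
            skipped.append((taxon, str(exc)))
            continue
        for term, idx in focal.items():
            rows[term].append(
                {
                    "taxon_id": taxon,
                    "base_mean": base_means[i],
                    "beta": beta[idx],
                    "fold_change": float(np.exp(beta[idx])),
                    "se": se[idx],
                    "dispersion": alpha,
                }
            )

    tables = {}
    for term in focal:
        frame = pd.DataFrame(
            rows[term],
            columns=["taxon_id", "base_mean", "beta", "fold_change", "se", "dispersion"],
        )
        tables[term] = wald_bh(frame, alpha_level=fdr).set_index("taxon_id")

    bop_term = design.continuous[0] if design.continuous else None
    perio_term = design.binary[0] if design.binary else None
    intersection = {}
    if bop_term and perio_term:
        # disease-associated lists are directional: significantly MORE
        # abundant with the covariate (positive beta)
        bop_tab, perio_tab = tables[bop_term], tables[perio_term]
        bop_hits = set(bop_tab.index[bop_tab["significant"] & (bop_tab["beta"] > 0)])
        perio_hits = set(
            perio_tab.index[perio_tab["significant"] & (perio_tab["beta"] > 0)]
        )
        intersection = {
            "both": sorted(bop_hits & perio_hits),
            "periodontitis_only": sorted(perio_hits - bop_hits),
            "gingivitis_only": sorted(bop_hits - perio_hits),
        }
    return {
        "tables": tables,
        "intersection": intersection,
        "skipped": skipped,
        "n_samples_used": len(kept_samples),
        "size_factors": pd.Series(factors, index=kept_samples),
    }
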