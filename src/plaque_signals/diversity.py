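"""Rarefaction-based alpha diversity and covariate modeling.

Richness (observed taxa) and the Shannon index (nats) are averaged over
repeated rarefactions to a common depth (default 5,000 reads, 100
iterations), so samples of unequal library size are comparable.  The
resulting per-sample estimates are modeled against clinical covariates
by ordinary least squares with backward stepwise reduction by AIC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import CountMatrix, ValidationError

__all__ = [
    "InsufficientDepthError",
    "rarefy",
    "shannon_index",
    "alpha_diversity",
    "StepwiseModelResult",
    "backward_stepwise_lm",
]


class InsufficientDepthError(ValueError):
    """Sample has fewer reads than the requested rarefaction depth."""


def rarefy(
    sample_counts: np.ndarray,
    depth: int,
    mode: str = "without_replacement",
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Subsample one sample's counts to exactly ``depth`` reads.

    ``without_replacement`` is classical rarefaction (multivariate
    hypergeometric); ``with_replacement`` draws a multinomial from the
    sample's relative abundances.
    """
    if rng is None:
        rng = np.random.default_rng()
    counts = np.asarray(sample_counts)
    if (counts < 0).any():
        raise ValidationError("counts must be non-negative")
    counts = counts.astype(np.int64)
    if depth < 1:
        raise ValidationError("depth must be >= 1")
    total = int(counts.sum())
    if mode == "without_replacement":
        if total < depth:
            raise InsufficientDepthError(
                f"sample has {total} reads < depth {depth}"
            )
        if total == depth:
            return counts.copy()
        return rng.multivariate_hypergeometric(counts, depth)
    if mode == "with_replacement":
        if total == 0:
            raise InsufficientDepthError("sample has no reads")
        return rng.multinomial(depth, counts / total)
    raise ValueError(f"unknown rarefaction mode {mode!r}")


def shannon_index(counts: np.ndarray) -> float:
    """Shannon entropy in nats; zero-count taxa contribute 0."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-(p * np.log(p)).sum())


def alpha_diversity(
    counts: CountMatrix,
    depth: int = 5000,
    iterations: int = 100,
    mode: str = "without_replacement",
    seed: int = 0,
) -> tuple[pd.DataFrame, list[str]]:
    """Per-sample rarefied richness and Shannon index.

    Averages over ``iterations`` independent rarefactions.  Samples
    with fewer than ``depth`` reads are excluded (second return value)
    rather than estimated — the classical handling of shallow samples.
    """
    if iterations < 1:
        raise ValidationError("iterations must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    excluded: list[str] = []
    totals = counts.counts.sum(axis=0)
    for j, sample in enumerate(counts.sample_ids):
        if totals[j] < depth:
            excluded.append(sample)
            continue
        vec = counts.counts[:, j]
        rich = np.empty(iterations)
        shan = np.empty(iterations)
        for it in range(iterations):
            sub = rarefy(vec, depth, mode=mode, rng=rng)
            rich[it] = np.count_nonzero(sub)
            shan[it] = shannon_index(sub)
        rows.append(
            {
                "sample_id": sample,
                "richness": rich.mean(),
                "shannon": shan.mean(),
                "depth": depth,
                "iterations": iterations,
            }
        )
    return pd.DataFrame(rows), excluded


@dataclass
class StepwiseModelResult:
    retained_terms: list[str]
    coefficients: pd.DataFrame  # index: coefficient name; columns: coef, se
    aic_trace: list[tuple[str, float]]  # (dropped term or "<full>", AIC)

    @property
    def aic(self) -> float:
        return self.aic_trace[-1][1]


def _expand_terms(covariates: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """One design block per term; categoricals become treatment dummies."""
    blocks: dict[str, pd.DataFrame] = {}
    for name in covariates.columns:
        col = covariates[name]
        if isinstance(col.dtype, pd.CategoricalDtype) or col.dtype == object:
            dummies = pd.get_dummies(col.astype(str), prefix=name, drop_first=True)
            blocks[name] = dummies.astype(float)
        elif col.dtype == bool or str(col.dtype) == "boolean":
            blocks[name] = pd.DataFrame({name: col.astype(float)})
        else:
            blocks[name] = pd.DataFrame({name: col.astype(float)})
    return blocks


def _fit_ols(y: np.ndarray, blocks: dict[str, pd.DataFrame], terms: list[str]):
    n = len(y)
    columns = ["(intercept)"]
    parts = [np.ones((n, 1))]
    for term in terms:
        block = blocks[term]
        parts.append(block.to_numpy(dtype=float))
        columns.extend(block.columns)
    design = np.hstack(parts)
    k = design.shape[1]
    rank = np.linalg.matrix_rank(design)
    if rank < k:
        # identify aliased columns by pivoted QR
        _, r = np.linalg.qr(design)
        diag = np.abs(np.diag(r))
        aliased = [columns[i] for i in range(len(diag)) if diag[i] < 1e-8 * diag.max()]
        raise ValidationError(f"rank-deficient design; aliased terms: {aliased}")
    beta, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    rss = float(resid @ resid)
    aic = n * np.log(rss / n) + 2 * k
    sigma2 = rss / (n - k) if n > k else np.nan
    xtx_inv = np.linalg.inv(design.T @ design)
    se = np.sqrt(np.diag(xtx_inv) * sigma2)
    coef = pd.DataFrame({"coef": beta, "se": se}, index=columns)
    return aic, coef


def backward_stepwise_lm(
    response: np.ndarray | pd.Series, covariates: pd.DataFrame
) -> StepwiseModelResult:
    """Backward stepwise OLS reduction by AIC.

    Starts from the full model and repeatedly drops the single term
    whose removal lowers AIC the most, stopping when no removal lowers
    it.  AIC = n*ln(RSS/n) + 2k with k counting all coefficients
    including the intercept.  Categorical terms are dropped as whole
    blocks.  Ties are broken by dropping the term listed last.
    """
    y = np.asarray(response, dtype=float)
    if len(y) != len(covariates):
        raise ValidationError("response and covariates must align")
    if np.isnan(y).any() or covariates.isna().any().any():
        raise ValidationError("complete cases required; drop missing rows first")
    blocks = _expand_terms(covariates)
    terms = list(covariates.columns)
    n_params = 1 + sum(b.shape[1] for b in blocks.values())
    if len(y) <= n_params:
        raise ValidationError("need n > number of parameters")

    current_aic, coef = _fit_ols(y, blocks, terms)
    trace: list[tuple[str, float]] = [("<full>", current_aic)]
    while terms:
        best_term, best_aic, best_coef = None, current_aic, coef
        for term in terms:
            reduced = [t for t in terms if t != term]
            cand_aic, cand_coef = _fit_ols(y, blocks, reduced)
            # <= so that later-listed terms win ties
            if cand_aic < best_aic or (
                best_term is not None and cand_aic == best_aic
            ):
                best_term, best_aic, best_coef = term, cand_aic, cand_coef
        if best_term is None:
            break
        terms = [t for t in terms if t != best_term]
        current_aic, coef = best_aic, best_coef
        trace.append((best_term, current_aic))
    return StepwiseModelResult(terms, coef, trace)
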