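"""Ordination, grouped-abundance comparisons and cohort descriptives.

Bray-Curtis dissimilarities and principal-coordinates analysis give the
exploratory view of community composition; summed relative abundances
of a taxon set (e.g. the disease-associated taxa), rarefied once to a
fixed presentational depth, are compared across (BoP, periodontitis)
strata with Kruskal-Wallis tests; and the cohort descriptive table
reproduces the headline clinical statistics (gingivitis and
periodontitis prevalence, weighted mean age, Spearman correlation of
BoP with periodontitis).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import kruskal, spearmanr

from .diversity import InsufficientDepthError, rarefy
from .io_core import CountMatrix, ValidationError

__all__ = [
    "OrdinationResult",
    "bray_curtis",
    "pcoa",
    "group_summed_abundance",
    "kruskal_wallis",
    "cohort_summary",
]


@dataclass
class OrdinationResult:
    sample_ids: list[str]
    coordinates: np.ndarray  # samples x axes
    eigenvalues: np.ndarray  # positive eigenvalues, descending
    proportion_explained: np.ndarray
    n_negative_eigenvalues: int


def bray_curtis(counts: CountMatrix) -> np.ndarray:
    """Pairwise Bray-Curtis dissimilarity between samples,
    d(u,v) = 1 - 2 sum min(u,v) / (sum u + sum v)."""
    totals = counts.counts.sum(axis=0)
    zero = [s for s, t in zip(counts.sample_ids, totals) if t == 0]
    if zero:
        raise ValidationError(f"all-zero samples: {zero[:5]}")
    return squareform(pdist(counts.counts.T.astype(float), metric="braycurtis"))


def pcoa(dissim: np.ndarray, sample_ids: list[str] | None = None) -> OrdinationResult:
    """Classical scaling (principal coordinates) of a dissimilarity
    matrix; negative-eigenvalue axes are dropped and counted, with no
    Lingoes/Cailliez correction."""
    d = np.asarray(dissim, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n) or not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0):
        raise ValidationError("dissimilarity must be square symmetric with zero diagonal")
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = 1e-10 * max(abs(evals[0]), 1.0)
    positive = evals > tol
    n_negative = int((evals < -tol).sum())
    coords = evecs[:, positive] * np.sqrt(evals[positive])
    pos_evals = evals[positive]
    prop = pos_evals / pos_evals.sum() if pos_evals.size else pos_evals
    ids = sample_ids if sample_ids is not None else [str(i) for i in range(n)]
    return OrdinationResult(list(ids), coords, pos_evals, prop, n_negative)


def group_summed_abundance(
    counts: CountMatrix,
    taxon_set: list[str],
    meta: pd.DataFrame,
    rarefy_depth: int = 10000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-sample summed percentage abundance of a taxon set.

    Each sample is rarefied once (fixed seed; the output is
    presentational) to ``rarefy_depth``; shallower samples are
    excluded.  Returns sample_id, bop, periodontitis and the summed
    percentage.
    """
    if not taxon_set:
        raise ValidationError("taxon_set is empty")
    missing = set(taxon_set) - set(counts.taxon_ids)
    if missing:
        raise ValidationError(f"taxa not in table: {sorted(missing)[:5]}")
    rng = np.random.default_rng(seed)
    in_set = np.array([t in set(taxon_set) for t in counts.taxon_ids])
    meta_idx = meta.set_index(meta["sample_id"].astype(str))
    rows = []
    for j, sample in enumerate(counts.sample_ids):
        vec = counts.counts[:, j]
        try:
            sub = rarefy(vec, rarefy_depth, mode="without_replacement", rng=rng)
        except InsufficientDepthError:
            continue
        pct = 100.0 * sub[in_set].sum() / rarefy_depth
        row = {"sample_id": sample, "summed_pct": pct}
        if sample in meta_idx.index:
            row["bop"] = int(meta_idx.loc[sample, "bop"])
            row["periodontitis"] = bool(meta_idx.loc[sample, "periodontitis"])
        rows.append(row)
    return pd.DataFrame(rows)


def kruskal_wallis(groups: list[np.ndarray]) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and chi-squared p-value."""
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValidationError("need >= 2 non-empty groups")
    flat = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.all(flat == flat[0]):
        return 0.0, 1.0
    h, p = kruskal(*groups)
    return float(h), float(p)


def cohort_summary(meta: pd.DataFrame) -> dict:
    """Descriptive statistics of a cohort metadata table.

    Counts per (BoP, periodontitis) stratum, prevalence of gingivitis
    (BoP >= 1), periodontitis and disease-free status, mean age
    (weighted by record, i.e. stratum-size weighted when ages are
    stratum means), and the tie-corrected Spearman correlation between
    BoP and the periodontitis indicator (None when degenerate).
    """
    if len(meta) == 0:
        raise ValidationError("metadata is empty")
    bop = meta["bop"].to_numpy(dtype=int)
    perio = meta["periodontitis"].to_numpy(dtype=bool)
    n = len(meta)
    strata = (
        pd.DataFrame({"bop": bop, "periodontitis": perio})
        .value_counts()
        .rename("n")
        .reset_index()
        .sort_values(["bop", "periodontitis"])
        .reset_index(drop=True)
    )
    if np.ptp(bop) == 0 or perio.all() or not perio.any():
        rho = None
    else:
        rho = float(spearmanr(bop, perio.astype(int)).statistic)
    mean_age = (
        float(np.nanmean(meta["age"].to_numpy(dtype=float)))
        if "age" in meta.columns
        else None
    )
    return {
        "n": n,
        "strata": strata,
        "gingivitis_n": int((bop >= 1).sum()),
        "gingivitis_pct": 100.0 * (bop >= 1).mean(),
        "periodontitis_n": int(perio.sum()),
        "periodontitis_pct": 100.0 * perio.mean(),
        "disease_free_n": int(((bop == 0) & ~perio).sum()),
        "disease_free_pct": 100.0 * ((bop == 0) & ~perio).mean(),
        "mean_age": mean_age,
        "bop_perio_spearman": rho,
    }
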