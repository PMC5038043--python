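"""Synthetic-cohort generator with ground truth.

Emulates the statistical structure the downstream analysis assumes:

* per-sample metadata drawn from the reference cohort's printed
  (BoP, periodontitis) stratum marginals and within-stratum covariate
  distributions;
* library sizes lognormal, moment-matched to the cohort's printed
  mean +/- SD of reads per sample (13,565 +/- 6,833);
* counts negative-binomial around a log-linear mean,
  mu_ij = s_j * q_i * exp(beta_bop,i * bop_j + beta_perio,i * perio_j
  + confounder terms + latent module term), variance mu + alpha*mu^2 —
  exactly the model the differential-abundance stage fits, so effect
  recovery is well defined;
* optional latent cooccurrence modules: a per-sample standard-normal
  factor, scaled by a loading, added to the log mean of the module's
  taxa only in the module's active periodontitis stratum.  This induces
  stratum-specific cooccurrence detectable by a compositionally robust
  correlation estimator.

Everything is deterministic given (config, seed) and each generator
emits its ground truth (effect table, per-stratum basis correlation
matrix, module memberships) for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import reference_cohort as ref
from .io_core import (
    INTERVENTION_LEVELS,
    SEQRUN_LEVELS,
    SITE_LEVELS,
    CountMatrix,
    SequenceSet,
    ValidationError,
    validate_metadata,
)

__all__ = [
    "LatentModule",
    "GeneratorConfig",
    "SyntheticTruth",
    "sample_cohort_metadata",
    "generate_counts",
    "generate_cohort",
    "generate_compositional_counts",
    "generate_sequences",
]


@dataclass
class LatentModule:
    """A block of taxa co-regulated by one latent factor.

    ``active_periodontitis`` selects the stratum in which the factor is
    on: True (periodontitis samples only), False (non-periodontitis
    only) or None (all samples).
    """

    taxa: list[str]
    loading: float = 1.0
    active_periodontitis: bool | None = True


@dataclass
class GeneratorConfig:
    """Study-condition parameters of the synthetic cohort.

    Defaults reproduce the reference cohort: 962 samples, 664 taxa,
    BoP / periodontitis marginals from the printed stratum table and
    lognormal library sizes moment-matched to 13,565 +/- 6,833 reads.
    """

    n_samples: int = 962
    n_taxa: int = 664
    libsize_mean: float = ref.LIBSIZE_MEAN
    libsize_sd: float = ref.LIBSIZE_SD
    bop_weights: np.ndarray = field(default_factory=ref.bop_weights)
    perio_prob_by_bop: np.ndarray = field(default_factory=ref.perio_prob_by_bop)
    # per-taxon ln-fold effects; rows are taxon ids, columns beta_bop,
    # beta_perio and optionally beta_hiv (confounder adjustment tests)
    effect_table: pd.DataFrame | None = None
    dispersion: float | np.ndarray = 0.3
    module_spec: list[LatentModule] = field(default_factory=list)
    # lognormal spread of per-taxon base relative abundances
    base_log_sd: float = 2.0
    # per-taxon-per-sample lognormal noise on the log mean; with a
    # module loading lambda the induced latent log-scale correlation is
    # lambda^2 / (lambda^2 + sigma^2)
    taxon_log_noise_sd: float = 0.5

    def __post_init__(self) -> None:
        self.bop_weights = np.asarray(self.bop_weights, dtype=float)
        self.perio_prob_by_bop = np.asarray(self.perio_prob_by_bop, dtype=float)
        if self.bop_weights.shape != (7,) or (self.bop_weights < 0).any():
            raise ValidationError("bop_weights must be 7 non-negative weights")
        if self.bop_weights.sum() <= 0:
            raise ValidationError("bop_weights must sum to > 0")
        if self.perio_prob_by_bop.shape != (7,) or (
            (self.perio_prob_by_bop < 0) | (self.perio_prob_by_bop > 1)
        ).any():
            raise ValidationError("perio_prob_by_bop must be 7 probabilities")
        disp = np.asarray(self.dispersion, dtype=float)
        if (disp <= 0).any():
            raise ValidationError("dispersion must be > 0")

    def taxon_ids(self) -> list[str]:
        return [f"otu{i:04d}" for i in range(self.n_taxa)]

    def effects(self) -> pd.DataFrame:
        taxa = self.taxon_ids()
        table = pd.DataFrame(
            0.0, index=taxa, columns=["beta_bop", "beta_perio", "beta_hiv"]
        )
        if self.effect_table is not None:
            for col in self.effect_table.columns:
                table.loc[self.effect_table.index, col] = self.effect_table[col]
        return table

    def dispersions(self) -> np.ndarray:
        disp = np.asarray(self.dispersion, dtype=float)
        if disp.ndim == 0:
            return np.full(self.n_taxa, float(disp))
        if disp.shape != (self.n_taxa,):
            raise ValidationError("per-taxon dispersion must have length n_taxa")
        return disp


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside a generated cohort."""

    effect_table: pd.DataFrame
    # latent log-scale basis correlation matrix per periodontitis stratum
    basis_corr: dict[bool, np.ndarray]
    modules: list[LatentModule]
    taxon_ids: list[str]

    def module_membership(self) -> dict[str, int]:
        members: dict[str, int] = {}
        for m, module in enumerate(self.modules):
            for taxon in module.taxa:
                members[taxon] = m
        return members


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Moment-match a lognormal to a target arithmetic mean and SD."""
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


def sample_cohort_metadata(config: GeneratorConfig, seed: int) -> pd.DataFrame:
    """Draw per-sample metadata from the configured stratum marginals.

    BoP is categorical with ``bop_weights``; periodontitis is Bernoulli
    with probability ``perio_prob_by_bop[bop]``; the remaining
    covariates are drawn from the reference cohort's within-stratum
    empirical distributions (falling back to the closest stratum when a
    sampled (bop, perio) cell is absent from the printed table).
    """
    rng = np.random.default_rng(seed)
    n = config.n_samples
    if n == 0:
        empty = pd.DataFrame(
            columns=["sample_id", "bop", "periodontitis", "site", "intervention",
                     "hiv", "seqrun", "age", "bmi", "education", "ses",
                     "anemia", "malaria"]
        )
        return empty
    p_bop = config.bop_weights / config.bop_weights.sum()
    bop = rng.choice(7, size=n, p=p_bop)
    perio = rng.random(n) < config.perio_prob_by_bop[bop]

    strata = ref.STRATA.set_index(["bop", "periodontitis"])
    records = []
    for j in range(n):
        key = (int(bop[j]), bool(perio[j]))
        if key not in strata.index:  # e.g. (0, True): absent from the table
            key = (int(bop[j]), False)
        row = strata.loc[key]
        records.append(
            {
                "sample_id": f"s{j:04d}",
                "bop": int(bop[j]),
                "periodontitis": bool(perio[j]),
                "site": rng.choice(
                    SITE_LEVELS, p=np.asarray(row.site_n) / row.n
                ),
                "intervention": rng.choice(
                    INTERVENTION_LEVELS, p=np.asarray(row.intervention_n) / row.n
                ),
                "hiv": bool(rng.random() < row.hiv_n / row.n),
                "seqrun": rng.choice(
                    SEQRUN_LEVELS, p=np.asarray(row.seqrun_n) / row.n
                ),
                "age": float(rng.normal(row.age_mean, row.age_sd)),
                "bmi": float(rng.normal(row.bmi_mean, row.bmi_sd)),
                "education": float(rng.normal(row.education_mean, row.education_sd)),
                "ses": float(rng.normal(row.ses_mean, row.ses_sd)),
                "anemia": bool(rng.random() < row.anemia_n / row.n),
                "malaria": bool(rng.random() < row.malaria_n / row.n),
            }
        )
    return validate_metadata(pd.DataFrame.from_records(records))


def generate_counts(
    meta: pd.DataFrame, config: GeneratorConfig, seed: int
) -> tuple[CountMatrix, SyntheticTruth]:
    """Generate NB counts for an existing metadata table, with truth."""
    if len(meta) == 0:
        raise ValidationError("metadata is empty")
    rng = np.random.default_rng(seed)
    taxa = config.taxon_ids()
    n_taxa, n = config.n_taxa, len(meta)
    effects = config.effects()
    alpha = config.dispersions()

    # base relative abundances (lognormal, normalized)
    q = np.exp(rng.normal(0.0, config.base_log_sd, size=n_taxa))
    q /= q.sum()

    mu_ls, sd_ls = _lognormal_params(config.libsize_mean, config.libsize_sd)
    libsize = np.exp(rng.normal(mu_ls, sd_ls, size=n))

    bop = meta["bop"].to_numpy(dtype=float)
    perio = meta["periodontitis"].to_numpy(dtype=float)
    hiv = (
        meta["hiv"].to_numpy(dtype=float)
        if "hiv" in meta.columns
        else np.zeros(n)
    )

    log_m = (
        np.log(q)[:, None]
        + np.outer(effects["beta_bop"].to_numpy(), bop)
        + np.outer(effects["beta_perio"].to_numpy(), perio)
        + np.outer(effects["beta_hiv"].to_numpy(), hiv)
    )

    taxon_index = {t: i for i, t in enumerate(taxa)}
    perio_bool = meta["periodontitis"].to_numpy(dtype=bool)
    for module in config.module_spec:
        rows = [taxon_index[t] for t in module.taxa]
        z = rng.standard_normal(n)
        if module.active_periodontitis is None:
            active = np.ones(n, dtype=bool)
        else:
            active = perio_bool == module.active_periodontitis
        log_m[np.ix_(rows, np.nonzero(active)[0])] += (
            module.loading * z[active][None, :]
        )

    if config.taxon_log_noise_sd > 0:
        log_m += rng.normal(0.0, config.taxon_log_noise_sd, size=log_m.shape)

    # close each sample's relative intensities so the expected total
    # equals the drawn library size regardless of effects/noise
    m = np.exp(log_m)
    mu = libsize[None, :] * m / m.sum(axis=0, keepdims=True)
    # NB(mu, alpha) via gamma-Poisson mixture: var = mu + alpha mu^2
    shape = 1.0 / alpha[:, None]
    lam = rng.gamma(shape, alpha[:, None] * mu)
    counts = rng.poisson(lam)

    truth = SyntheticTruth(
        effect_table=effects,
        basis_corr=_truth_basis_corr(config),
        modules=list(config.module_spec),
        taxon_ids=taxa,
    )
    matrix = CountMatrix(taxa, list(meta["sample_id"].astype(str)), counts)
    return matrix, truth


def _truth_basis_corr(config: GeneratorConfig) -> dict[bool, np.ndarray]:
    taxa = config.taxon_ids()
    index = {t: i for i, t in enumerate(taxa)}
    sigma2 = config.taxon_log_noise_sd**2
    out: dict[bool, np.ndarray] = {}
    for stratum in (False, True):
        corr = np.eye(config.n_taxa)
        for module in config.module_spec:
            if module.active_periodontitis not in (None, stratum):
                continue
            lam2 = module.loading**2
            rho = lam2 / (lam2 + sigma2) if (lam2 + sigma2) > 0 else 0.0
            rows = [index[t] for t in module.taxa]
            for a in rows:
                for b in rows:
                    if a != b:
                        corr[a, b] = rho
        out[stratum] = corr
    return out


def generate_cohort(
    config: GeneratorConfig, seed: int
) -> tuple[CountMatrix, pd.DataFrame, SyntheticTruth]:
    """Metadata + counts in one call (independent substreams of ``seed``)."""
    ss = np.random.SeedSequence(seed)
    meta_seed, count_seed = (int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(2))
    meta = sample_cohort_metadata(config, meta_seed)
    counts, truth = generate_counts(meta, config, count_seed)
    return counts, meta, truth


def generate_compositional_counts(
    basis_corr: np.ndarray,
    n_samples: int,
    depth: int = 5000,
    log_sd: float = 1.0,
    seed: int = 0,
) -> CountMatrix:
    """Multinomial counts from lognormal basis abundances.

    Basis log-abundances are multivariate normal with the given
    correlation matrix (common log-SD), exponentiated, closed to
    relative abundances and read out as one multinomial draw of
    ``depth`` reads per sample.  This is the canonical test bed for a
    compositionally robust correlation estimator: the off-simplex
    (basis) correlations are known exactly.
    """
    basis_corr = np.asarray(basis_corr, dtype=float)
    d = basis_corr.shape[0]
    if basis_corr.shape != (d, d):
        raise ValidationError("basis_corr must be square")
    rng = np.random.default_rng(seed)
    cov = basis_corr * log_sd**2
    g = rng.multivariate_normal(np.zeros(d), cov, size=n_samples, method="cholesky")
    x = np.exp(g)
    frac = x / x.sum(axis=1, keepdims=True)
    counts = np.vstack([rng.multinomial(depth, f) for f in frac]).T
    taxa = [f"otu{i:04d}" for i in range(d)]
    samples = [f"s{j:04d}" for j in range(n_samples)]
    return CountMatrix(taxa, samples, counts)


def generate_sequences(
    reference: SequenceSet,
    identity_targets: Sequence[float],
    seed: int = 0,
) -> SequenceSet:
    """Mutate reference sequences to exact percent-identity targets.

    Output ``k`` is a copy of reference ``k mod len(reference)`` with
    exactly ``round((1 - t/100) * L)`` positions substituted to a
    different base, so its ungapped global identity to its source is
    exactly the target (up to the rounding of the substitution count).
    """
    if len(reference) == 0:
        raise ValidationError("reference set is empty")
    rng = np.random.default_rng(seed)
    bases = "ACGT"
    ids, seqs = [], []
    for k, target in enumerate(identity_targets):
        if not 0.0 <= target <= 100.0:
            raise ValidationError(f"identity target {target} outside [0, 100]")
        ref_id = reference.record_ids[k % len(reference)]
        seq = list(reference.sequences[k % len(reference)])
        n_sub = int(round((1.0 - target / 100.0) * len(seq)))
        positions = rng.choice(len(seq), size=n_sub, replace=False)
        for pos in positions:
            choices = [b for b in bases if b != seq[pos]]
            seq[pos] = choices[rng.integers(len(choices))]
        ids.append(f"query{k:04d}_{ref_id}")
        seqs.append("".join(seq))
    return SequenceSet(ids, seqs)
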