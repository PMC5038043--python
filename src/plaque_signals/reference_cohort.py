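"""Printed marginals of the reference cross-sectional cohort.

The analysis was designed around a cohort of 962 postpartum women
screened for periodontal disease: gingivitis graded as the number of
dental-arch sextants with bleeding on probing (BoP, 0-6) and
periodontitis as a binary classification.  The published demographic
table gives, for every (BoP, periodontitis) stratum, the stratum size
and the within-stratum demographics and technical covariates.  Those
printed values are data: they calibrate the synthetic-cohort generator
and let the cohort descriptive statistics be recomputed exactly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io_core import INTERVENTION_LEVELS, SEQRUN_LEVELS, SITE_LEVELS, validate_metadata

__all__ = [
    "STRATA",
    "bop_weights",
    "perio_prob_by_bop",
    "expand_reference_cohort",
    "LIBSIZE_MEAN",
    "LIBSIZE_SD",
]

# Library-size calibration: mean +/- SD of reads per sample.
LIBSIZE_MEAN = 13565.0
LIBSIZE_SD = 6833.0

_COLUMNS = [
    "bop", "periodontitis", "n", "age_mean", "age_sd", "hiv_n", "malaria_n",
    "bmi_mean", "bmi_sd", "education_mean", "education_sd", "anemia_n",
    "ses_mean", "ses_sd", "site_n", "intervention_n", "seqrun_n",
]

# One row per (BoP, periodontitis) stratum; count vectors are per-site
# (lungwena/malindi/namwera/mangochi), per-arm (IFA/MMN/LNS) and
# per-sequencing-run splits within the stratum.
_ROWS = [
    (0, False, 140, 23.4, 5.8, 27, 37, 22.7, 3.2, 5.6, 3.6, 36,  0.38, 1.22, (36, 37, 18, 49), (43, 53, 44), (47, 49, 41, 3)),
    (1, False,  72, 23.9, 5.9,  7, 16, 22.6, 3.4, 5.1, 3.8, 12,  0.19, 1.11, (25,  9, 17, 21), (32, 19, 21), (34, 26, 12, 0)),
    (1, True,   11, 31.6, 6.1,  1,  1, 22.7, 2.4, 4.4, 3.3,  3, -0.35, 0.62, ( 6,  2,  1,  2), ( 8,  0,  3), ( 3,  5,  3, 0)),
    (2, False,  95, 24.7, 6.2, 11, 22, 22.1, 2.6, 4.4, 3.6, 19,  0.10, 1.10, (39, 19, 13, 24), (38, 34, 23), (31, 41, 23, 0)),
    (2, True,   23, 27.5, 6.2,  5,  5, 21.7, 2.0, 2.7, 3.3,  4, -0.16, 0.91, (13,  1,  4,  5), ( 5, 11,  7), ( 9,  7,  7, 0)),
    (3, False, 111, 24.4, 5.4, 11, 32, 21.7, 2.3, 4.3, 3.3, 21, -0.12, 0.84, (41, 22, 22, 26), (40, 34, 37), (36, 34, 39, 2)),
    (3, True,   27, 26.5, 5.7,  4,  3, 22.2, 2.7, 3.6, 3.0,  6, -0.20, 0.91, (11,  6,  3,  7), (11,  4, 12), (11,  6, 10, 0)),
    (4, False,  72, 25.0, 6.4,  9, 16, 21.7, 2.2, 3.4, 3.0, 11, -0.16, 0.80, (28, 16, 10, 18), (16, 26, 30), (26, 28, 18, 0)),
    (4, True,   51, 26.9, 5.4,  8, 11, 21.8, 2.7, 3.3, 3.1,  7, -0.17, 0.81, (27,  3,  7, 14), (14, 19, 18), (23,  7, 21, 0)),
    (5, False,  63, 24.9, 5.2,  7, 12, 21.6, 2.4, 4.0, 3.6, 15, -0.16, 0.81, (22, 11,  9, 21), (22, 23, 18), (26, 13, 24, 0)),
    (5, True,   50, 26.6, 5.9,  5,  7, 21.8, 3.1, 2.4, 2.8,  5, -0.36, 0.61, (18, 11,  7, 14), (16, 15, 19), (21, 12, 17, 0)),
    (6, False, 102, 24.5, 5.5, 10, 18, 21.9, 2.3, 3.5, 3.0, 26, -0.20, 0.81, (36, 24, 16, 26), (33, 41, 28), (18, 46, 36, 2)),
    (6, True,  145, 28.3, 7.0, 30, 28, 22.1, 2.5, 2.9, 3.0, 32, -0.27, 0.74, (66, 28, 17, 34), (45, 48, 52), (59, 43, 41, 2)),
]

STRATA = pd.DataFrame(_ROWS, columns=_COLUMNS)


def bop_weights() -> np.ndarray:
    """Cohort counts per BoP level (length 7), usable as sampling weights."""
    return np.array(
        [STRATA.loc[STRATA.bop == b, "n"].sum() for b in range(7)], dtype=float
    )


def perio_prob_by_bop() -> np.ndarray:
    """Empirical P(periodontitis | BoP) per BoP level (length 7)."""
    probs = np.zeros(7)
    for b in range(7):
        sub = STRATA[STRATA.bop == b]
        probs[b] = sub.loc[sub.periodontitis, "n"].sum() / sub["n"].sum()
    return probs


def _spread_counts(total: int, split: tuple[int, ...], levels: tuple[str, ...]) -> list[str]:
    assert sum(split) == total, (total, split)
    out: list[str] = []
    for count, level in zip(split, levels):
        out.extend([level] * count)
    return out


def expand_reference_cohort() -> pd.DataFrame:
    """Expand the printed stratum table into one record per woman.

    Within each stratum, continuous covariates are set to the stratum
    mean and counted covariates (HIV, anemia, malaria, site, arm,
    sequencing run) are assigned exactly at their printed counts, so
    descriptive statistics of the expanded table reproduce the printed
    marginals exactly.
    """
    records: list[dict] = []
    idx = 0
    for row in STRATA.itertuples(index=False):
        sites = _spread_counts(row.n, row.site_n, SITE_LEVELS)
        arms = _spread_counts(row.n, row.intervention_n, INTERVENTION_LEVELS)
        runs = _spread_counts(row.n, row.seqrun_n, SEQRUN_LEVELS)
        for k in range(row.n):
            records.append(
                {
                    "sample_id": f"ref{idx:04d}",
                    "bop": row.bop,
                    "periodontitis": row.periodontitis,
                    "site": sites[k],
                    "intervention": arms[k],
                    "hiv": k < row.hiv_n,
                    "seqrun": runs[k],
                    "age": row.age_mean,
                    "bmi": row.bmi_mean,
                    "education": row.education_mean,
                    "ses": row.ses_mean,
                    "anemia": k < row.anemia_n,
                    "malaria": k < row.malaria_n,
                }
            )
            idx += 1
    return validate_metadata(pd.DataFrame.from_records(records))
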