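"""Test-retest reliability statistics for autoregulation indices.

Three tools compare the repeatability of indices measured over repeated
thigh-cuff manoeuvres:

* the unbiased coefficient of variation per subject,
  CoV = (1 + 1/(4n)) * sd/mean * 100%;
* the standard error of measurement, SEM = sqrt(within-subject mean square)
  from a one-way repeated-measures ANOVA, with missing repetitions handled
  by computing sums of squares and degrees of freedom on the available cells
  (df = N_obs - n_subjects);
* Bland-Altman bias and 95% limits of agreement between two indices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, UndefinedCovError

__all__ = [
    "ReliabilityTable",
    "unbiased_cov",
    "population_cov",
    "sem_repeated_measures",
    "bland_altman",
]


@dataclass
class ReliabilityTable:
    """Subjects x repetitions matrix of index values; NaN marks missing cells.

    Validation drops subjects with fewer than two recorded repetitions and
    requires at least two subjects overall.
    """

    values: np.ndarray
    subjects: list | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("values must be a 2-D subjects x repetitions array")
        keep = np.sum(~np.isnan(v), axis=1) >= 2
        if self.subjects is None:
            self.subjects = list(range(v.shape[0]))
        self.subjects = [s for s, k in zip(self.subjects, keep) if k]
        self.values = v[keep]
        if self.values.shape[0] < 2:
            raise InsufficientDataError(
                "need >= 2 subjects with >= 2 repetitions each"
            )

    @classmethod
    def from_tidy(
        cls,
        df: pd.DataFrame,
        subject: str = "subject",
        repetition: str = "repetition",
        value: str = "value",
    ) -> "ReliabilityTable":
        """Build from a tidy (subject, repetition, value) table."""
        wide = df.pivot(index=subject, columns=repetition, values=value)
        return cls(values=wide.to_numpy(), subjects=list(wide.index))


def unbiased_cov(values: np.ndarray) -> float:
    """Unbiased coefficient of variation of one subject's repetitions (%).

    (1 + 1/(4n)) * sample sd / mean * 100, computed on non-missing values.

    Raises
    ------
    InsufficientDataError
        If fewer than two values are available.
    UndefinedCovError
        If the mean is (near) zero.
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    n = x.size
    if n < 2:
        raise InsufficientDataError(f"CoV needs >= 2 repetitions, got {n}")
    mean = x.mean()
    sd = x.std(ddof=1)
    if abs(mean) < 1e-12 * max(sd, 1.0):
        raise UndefinedCovError("mean is zero; CoV undefined")
    return float((1.0 + 1.0 / (4.0 * n)) * sd / mean * 100.0)


def population_cov(table: ReliabilityTable) -> float:
    """Population mean CoV: average of the per-subject unbiased CoVs (%)."""
    return float(np.mean([unbiased_cov(row) for row in table.values]))


def sem_repeated_measures(table: ReliabilityTable) -> tuple[float, float]:
    """Standard error of measurement from one-way repeated-measures ANOVA.

    SEM = sqrt(SS_within / df_within) with SS_within the pooled squared
    deviation of each available cell from its subject mean and
    df_within = N_obs - n_subjects; also returned as a percentage of the
    grand mean. An all-identical table gives SEM = 0.
    """
    v = table.values
    n_obs = int(np.sum(~np.isnan(v)))
    n_subj = v.shape[0]
    df_within = n_obs - n_subj
    if df_within <= 0:
        raise InsufficientDataError("no within-subject degrees of freedom")
    subj_means = np.nanmean(v, axis=1, keepdims=True)
    ss_within = float(np.nansum((v - subj_means) ** 2))
    sem = float(np.sqrt(ss_within / df_within))
    grand = float(np.nanmean(v))
    pct = sem / abs(grand) * 100.0 if grand != 0 else float("nan")
    return sem, pct


def bland_altman(
    a: np.ndarray, b: np.ndarray
) -> tuple[float, tuple[float, float]]:
    """Bland-Altman agreement between two paired index sets.

    Returns ``(bias, (lower, upper))`` with bias the mean difference a - b
    and the 95% limits of agreement bias +/- 1.96 * sd(differences).

    Raises
    ------
    InsufficientDataError
        If fewer than three pairs are supplied.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be 1-D arrays of equal length")
    if a.size < 3:
        raise InsufficientDataError(f"Bland-Altman needs >= 3 pairs, got {a.size}")
    diff = a - b
    bias = float(diff.mean())
    half = 1.96 * float(diff.std(ddof=1))
    return bias, (bias - half, bias + half)
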