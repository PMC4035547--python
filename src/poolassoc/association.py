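"""Allele-effect estimation from pooled read counts, with attenuation correction.

The estimator is ordinary least squares of family phenotype on observed pool
allele frequency S1/S_T.  Binomial sampling noise in the covariate shrinks
the slope by the factor 1/(1 + 3/S_T); dividing the fitted slope by that
factor recovers the true effect per unit pool frequency (b = 2a).  Variable
depth across families is summarized by the harmonic mean depth of the
families that received reads.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .popgen import attenuation_factor, harmonic_mean_depth

__all__ = [
    "AssociationResult",
    "DegenerateDesignError",
    "InsufficientDataError",
    "fit_regression",
    "correct_attenuation",
    "estimate_effect",
]


class DegenerateDesignError(ValueError):
    """Covariate is constant; the slope is not identifiable."""


class InsufficientDataError(ValueError):
    """Fewer than three usable (phenotype, frequency) pairs."""


@dataclass(frozen=True)
class AssociationResult:
    """Slope fit of phenotype on observed pool frequency, raw and corrected.

    ``b_hat`` estimates the effect per unit pool frequency but is biased
    toward zero by sequencing noise; after :func:`correct_attenuation`,
    ``b_corrected = b_hat / bias_factor`` and ``a_hat = b_corrected / 2``
    is the allele-substitution effect.  The p-value always comes from the
    uncorrected t-test (significance is unaffected by a multiplicative
    rescaling of the slope and its SE).
    """

    b_hat: float
    se: float
    t_stat: float
    p_value: float
    df: int
    n_used: int
    intercept: float
    effective_depth: float | None = None
    n_zero_depth: int | None = None
    bias_factor: float | None = None
    b_corrected: float | None = None
    se_corrected: float | None = None
    a_hat: float | None = None

    @property
    def corrected(self) -> bool:
        return self.bias_factor is not None

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


def fit_regression(phenotypes, g_obs) -> AssociationResult:
    """OLS of phenotype on observed pool allele frequency.

    Families with a missing frequency (NaN, from zero sequencing depth) are
    excluded.  The slope's two-sided p-value uses the t distribution with
    n_used - 2 degrees of freedom.
    """
    y = np.asarray(phenotypes, dtype=float)
    x = np.asarray(g_obs, dtype=float)
    if y.shape != x.shape:
        raise ValueError("phenotypes and g_obs must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise InsufficientDataError(
            f"need at least 3 non-missing families, got {n}"
        )
    if np.ptp(x) == 0.0:
        raise DegenerateDesignError(
            "observed pool frequency is constant; slope not identifiable"
        )
    fit = stats.linregress(x, y)
    slope = float(fit.slope)
    se = float(fit.stderr)
    # linregress reports t via rvalue; recompute directly for the se=0 edge
    t = slope / se if se > 0 else np.inf * np.sign(slope)
    df = n - 2
    p = float(fit.pvalue)
    return AssociationResult(
        b_hat=slope,
        se=se,
        t_stat=float(t),
        p_value=p,
        df=df,
        n_used=n,
        intercept=float(fit.intercept),
    )


def correct_attenuation(
    result: AssociationResult, depths: Sequence[float]
) -> AssociationResult:
    """Divide the fitted slope by the depth-implied attenuation factor.

    ``depths`` are the per-family total read counts; their harmonic mean
    over families with reads gives the effective depth S_T, and the raw
    slope and SE are both divided by 1/(1 + 3/S_T).  A first-order
    treatment: the p-value is left at its uncorrected value.
    """
    eff_depth, n_excluded = harmonic_mean_depth(depths)
    bias = attenuation_factor(eff_depth)
    return replace(
        result,
        effective_depth=eff_depth,
        n_zero_depth=n_excluded,
        bias_factor=bias,
        b_corrected=result.b_hat / bias,
        se_corrected=result.se / bias,
        a_hat=result.b_hat / bias / 2.0,
    )


def estimate_effect(data) -> AssociationResult:
    """Fit and correct in one step from a dataset table or TSV path.

    ``data`` is a :class:`pandas.DataFrame` with columns ``s1``, ``s2``,
    ``depth``, ``phenotype`` (the format written by
    :func:`poolassoc.simulate.write_dataset`) or a path to such a file.
    """
    if isinstance(data, (str, Path)):
        from .io import read_dataset

        data = read_dataset(data)
    depth = data["depth"].to_numpy(dtype=float)
    s1 = data["s1"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        g_obs = np.where(depth > 0, s1 / np.maximum(depth, 1.0), np.nan)
    result = fit_regression(data["phenotype"].to_numpy(dtype=float), g_obs)
    return correct_attenuation(result, depth)
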