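"""Empirical-Bayes moderated one-sample testing of log2 ratios.

The design mirrors the isobaric-label study layout: each treated channel is
expressed as a log2 ratio against its plex's S/L reference, the four cell
lines act as biological replicates (blocks), and each (treatment, timepoint)
comparison is a one-sample test of the per-cell-line ratios against zero.

Variance moderation follows the classic empirical-Bayes construction: the
per-feature sample variances s² are assumed to be scaled chi-square draws
around a common prior (d0, s0²); hyperparameters are fitted by matching the
mean and variance of log(s²) to the theoretical scaled-F distribution, and
each feature's variance is shrunk to the posterior
    s̃² = (d0·s0² + d·s²) / (d0 + d),
giving moderated t statistics on d0 + d degrees of freedom (a z-test against
s0 when d0 is infinite).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .io_formats import ExpressionMatrix

logger = logging.getLogger(__name__)

#: Default regulation gates: BH q below 5% and at least 0.1 log2 fold change.
Q_MAX_DEFAULT = 0.05
FC_MIN_DEFAULT = 0.1


@dataclass(frozen=True)
class VariancePrior:
    """Hyperparameters of the inverse-chi-square variance prior.

    d0 is the prior degrees of freedom (``math.inf`` when the observed
    variances show no excess dispersion beyond sampling noise) and s0_sq the
    prior variance in squared log2 units.
    """

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if not (self.d0 > 0):
            raise ValueError("d0 must be positive")
        if not (self.s0_sq > 0):
            raise ValueError("s0_sq must be positive")


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation with its two-tailed t-transform p-value."""

    r: float
    n: int
    p: float


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        return math.inf
    # trigamma(y) ~ 1/y + 1/(2y^2); start from the 1/y approximation
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = float(special.polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(special.polygamma(2, y))
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return y


def estimate_variance_prior(s_sq: np.ndarray, d: float | np.ndarray) -> VariancePrior:
    """Method-of-moments fit of (d0, s0²) from per-feature sample variances.

    Works on z = log(s²): under the model z is log s0² plus a log-F(d, d0)
    variable, whose mean and variance involve digamma/trigamma terms.  Excess
    variance of z beyond trigamma(d/2) determines d0; non-positive excess
    yields d0 = inf (all features share one variance).
    """
    s_sq = np.asarray(s_sq, dtype=float)
    d_arr = np.broadcast_to(np.asarray(d, dtype=float), s_sq.shape)
    ok = np.isfinite(s_sq) & (d_arr >= 1)
    s_sq, d_arr = s_sq[ok], d_arr[ok]
    if s_sq.size < 30:
        raise ValueError("need at least 30 features with residual df >= 1")
    if np.all(s_sq == 0):
        raise ValueError("all sample variances are zero")
    # Guard exact zeros (degenerate replicates) with the smallest positive s².
    tiny = s_sq[s_sq > 0].min()
    z = np.log(np.maximum(s_sq, tiny * 1e-12))
    e = z - special.digamma(d_arr / 2.0) + np.log(d_arr / 2.0)
    if np.ptp(z) == 0 and np.ptp(d_arr) == 0:
        # zero-dispersion limit: no sampling spread at all, so the common
        # variance IS the prior variance
        return VariancePrior(math.inf, float(s_sq[0]))
    e_mean = float(np.mean(e))
    excess = float(np.var(e, ddof=1) - np.mean(special.polygamma(1, d_arr / 2.0)))
    if excess <= 0:
        return VariancePrior(math.inf, float(np.exp(e_mean)))
    d0 = 2.0 * _trigamma_inverse(excess)
    s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return VariancePrior(d0, s0_sq)


def moderated_ttest(ratios: pd.DataFrame | np.ndarray,
                    prior: VariancePrior) -> pd.DataFrame:
    """One-sample moderated t on per-replicate log2 ratios (features x reps).

    Missing entries are ignored per feature.  Features with fewer than two
    observed replicates are reported with NaN statistics (and are excluded
    from multiplicity correction downstream).
    """
    values = np.asarray(ratios, dtype=float)
    index = ratios.index if isinstance(ratios, pd.DataFrame) else pd.RangeIndex(len(values))
    n = np.sum(np.isfinite(values), axis=1).astype(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(np.where(np.isfinite(values), values, np.nan), axis=1)
        s_sq = np.nanvar(np.where(np.isfinite(values), values, np.nan), axis=1, ddof=1)
    d = n - 1.0
    usable = n >= 2
    d0, s0 = prior.d0, prior.s0_sq
    if math.isinf(d0):
        s_tilde_sq = np.full_like(s_sq, s0)
        df_total = np.full_like(s_sq, math.inf)
    else:
        s_tilde_sq = (d0 * s0 + d * s_sq) / (d0 + d)
        df_total = d0 + d
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / np.sqrt(s_tilde_sq / n)
    if math.isinf(d0):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    out = pd.DataFrame(
        {
            "log2FC": mean,
            "t": t,
            "se": np.sqrt(s_tilde_sq / n),
            "df_resid": d,
            "df_total": df_total,
            "p": p,
            "n": n.astype(int),
        },
        index=index,
    )
    out.loc[~usable, ["log2FC", "t", "se", "df_total", "p"]] = np.nan
    out.loc[~usable, "df_resid"] = np.nan
    return out


def bh_adjust(p: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        return arr.copy()
    if np.any((arr < 0) | (arr > 1) | ~np.isfinite(arr)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def call_regulated(table: pd.DataFrame, q_max: float = Q_MAX_DEFAULT,
                   fc_min: float = FC_MIN_DEFAULT) -> pd.DataFrame:
    """Flag rows up/down/none from the q-value and fold-change gates."""
    out = table.copy()
    up = (out["log2FC"] >= fc_min) & (out["q"] < q_max)
    down = (out["log2FC"] <= -fc_min) & (out["q"] < q_max)
    out["regulated"] = np.where(up, "up", np.where(down, "down", "none"))
    return out


def differential_table(ratios: ExpressionMatrix, q_max: float = Q_MAX_DEFAULT,
                       fc_min: float = FC_MIN_DEFAULT,
                       replicate_on: str = "cell_line") -> pd.DataFrame:
    """Moderated differential analysis per (treatment, timepoint) family.

    ``ratios`` must hold log2 ratios vs the S/L reference.  Within each
    non-reference (treatment, timepoint) group, samples are collapsed to one
    ratio per replicate block (``replicate_on``, the cell line by default),
    a variance prior is fitted across features, and one-sample moderated
    tests with per-family BH correction are run.  Returns the long-format
    table: feature, treatment, timepoint, log2FC, t, df_total, p, q,
    regulated.
    """
    design = ratios.design.table
    frames = []
    for (treatment, timepoint), grp in design.groupby(["treatment", "timepoint"], sort=True):
        if treatment == "SL":
            continue
        cols = grp["sample_id"].tolist()
        block = grp.set_index("sample_id")[replicate_on]
        # collapse technical replicates within a block to their mean
        per_block = ratios.values[cols].T.groupby(block).mean().T
        prior = estimate_variance_prior(
            per_block.var(axis=1, ddof=1).to_numpy(),
            per_block.notna().sum(axis=1).to_numpy() - 1.0,
        )
        res = moderated_ttest(per_block, prior)
        res["q"] = np.nan
        tested = res["p"].notna()
        if tested.any():
            res.loc[tested, "q"] = bh_adjust(res.loc[tested, "p"].to_numpy())
        res = call_regulated(res, q_max=q_max, fc_min=fc_min)
        res.insert(0, "timepoint", timepoint)
        res.insert(0, "treatment", treatment)
        res.insert(0, "feature", res.index)
        frames.append(res.reset_index(drop=True))
    if not frames:
        raise ValueError("no non-reference (treatment, timepoint) groups in design")
    return pd.concat(frames, ignore_index=True)


def paired_shift_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Paired two-sample t-test for means: one-sample t on the differences.

    Returns (t, df, two-sided p).  Constant non-zero differences have zero
    standard error; these are reported as p = 0 with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be matched 1-d vectors")
    n = x.size
    if n < 3:
        raise ValueError("paired test needs at least 3 pairs")
    diff = x - y
    sd = diff.std(ddof=1)
    df = float(n - 1)
    if sd == 0:
        if np.all(diff == 0):
            return 0.0, df, 1.0
        logger.warning("constant non-zero differences: zero variance, p reported as 0")
        return math.copysign(math.inf, diff[0]), df, 0.0
    t = diff.mean() / (sd / math.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), df, float(p)


def pearson_cor_test(a: np.ndarray, b: np.ndarray) -> CorrelationResult:
    """Pearson correlation with the two-tailed t-transform p-value.

    p is computed from t = r sqrt(n-2) / sqrt(1-r²) on n-2 df.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("vectors must be matched and 1-dimensional")
    n = a.size
    if n < 3:
        raise ValueError("correlation test needs n >= 3")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("vectors must be finite")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("correlation undefined for a zero-variance vector")
    r = float(np.corrcoef(a, b)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) >= 1.0 - 1e-12:   # snap numerically-perfect correlations
        r = math.copysign(1.0, r)
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * math.sqrt(n - 2) / math.sqrt(1.0 - r * r)
        p = 2.0 * stats.t.sf(abs(t), n - 2)
    return CorrelationResult(r=r, n=n, p=float(p))
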