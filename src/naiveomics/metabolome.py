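"""Metabolite-layer preprocessing: presence filtering, missingness
classification, left-censored imputation, and quantile-median centering.

Metabolomics intensities carry two kinds of missingness.  Values missing at
random (MAR) scatter across samples and are imputed from the feature's
observed distribution within the same treatment.  Values missing in an
entire condition (MEC) indicate abundances below the detection limit in
that treatment and are imputed as left-censored draws bounded above by a
low percentile of the receiving sample's observed values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix

logger = logging.getLogger(__name__)

PRESENCE_FRACTION_DEFAULT = 0.75
MEC_QUANTILE_DEFAULT = 2.5       # percentile bounding left-censored draws
MEC_DRAW_WIDTH = 0.5             # log2 width of the uniform draw interval


@dataclass
class MissingnessMap:
    """Per-cell class (observed / MAR / MEC) and per-treatment observed counts.

    ``classes`` mirrors the matrix shape with string labels; ``observed`` is
    a feature x treatment table of observed-sample counts.  MEC holds exactly
    when every sample of one treatment is missing for that feature.
    """

    classes: pd.DataFrame
    observed: pd.DataFrame


@dataclass(frozen=True)
class ImputeConfig:
    """Imputation parameters: left-censor percentile bound, MAR method, seed."""

    mec_quantile_bound: float = MEC_QUANTILE_DEFAULT
    mar_method: str = "condition_normal"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.mec_quantile_bound < 50):
            raise ValueError("mec_quantile_bound must lie in (0, 50)")
        if self.mar_method not in ("condition_normal",):
            raise ValueError(f"unknown MAR method {self.mar_method!r}")


def _treatment_columns(m: ExpressionMatrix) -> dict[str, list[str]]:
    design = m.design.table
    return {t: g["sample_id"].tolist() for t, g in design.groupby("treatment", sort=True)}


def filter_by_presence(m: ExpressionMatrix,
                       min_fraction: float = PRESENCE_FRACTION_DEFAULT) -> ExpressionMatrix:
    """Keep features observed in >= ``min_fraction`` of at least one treatment."""
    if not (0 <= min_fraction <= 1):
        raise ValueError("min_fraction must lie in [0, 1]")
    groups = _treatment_columns(m)
    keep = pd.Series(False, index=m.values.index)
    for cols in groups.values():
        frac = m.values[cols].notna().mean(axis=1)
        keep |= frac >= min_fraction
    dropped = int((~keep).sum())
    if dropped:
        logger.info("presence filter removed %d / %d features", dropped, len(keep))
    return m.copy_with(m.values.loc[keep])


def drop_sparse_samples(m: ExpressionMatrix, max_missing: float = 0.5) -> ExpressionMatrix:
    """Drop whole samples whose missing fraction exceeds ``max_missing``."""
    frac = m.values.isna().mean(axis=0)
    bad = frac.index[frac > max_missing].tolist()
    if not bad:
        return m
    logger.warning("dropping %d sample(s) with >%d%% missing values: %s",
                   len(bad), int(max_missing * 100), bad)
    keep = [c for c in m.values.columns if c not in bad]
    return ExpressionMatrix(m.values[keep], m.design.subset(keep), m.layer,
                            m.row_attrs)


def classify_missingness(m: ExpressionMatrix) -> MissingnessMap:
    """Label every cell observed / MAR / MEC.

    MEC applies where an entire (feature, treatment) block is missing; any
    other missing cell is MAR.
    """
    groups = _treatment_columns(m)
    classes = pd.DataFrame("observed", index=m.values.index, columns=m.values.columns)
    observed = pd.DataFrame(index=m.values.index, columns=list(groups), dtype=int)
    isna = m.values.isna()
    for treatment, cols in groups.items():
        block_na = isna[cols]
        n_obs = (~block_na).sum(axis=1)
        observed[treatment] = n_obs
        mec_rows = n_obs == 0
        for col in cols:
            classes.loc[mec_rows & block_na[col], col] = "MEC"
            classes.loc[(~mec_rows) & block_na[col], col] = "MAR"
    return MissingnessMap(classes=classes, observed=observed)


def impute(m: ExpressionMatrix, miss: MissingnessMap,
           cfg: ImputeConfig | None = None) -> ExpressionMatrix:
    """Impute MAR cells from the treatment-conditional normal and MEC cells
    as left-censored draws.

    MAR: draw from Normal(mean, sd) of the feature's observed values within
    the same treatment (falling back to all treatments when that treatment
    has no observations; sd = 0 gives the deterministic mean).  MEC: draw
    uniformly from (q - 0.5, q], where q is the configured percentile of the
    receiving sample's observed values, so imputations never exceed q.
    Observed cells are never altered.
    """
    cfg = cfg or ImputeConfig()
    rng = np.random.default_rng(cfg.seed)
    values = m.values.copy()
    if values.isna().all(axis=1).any():
        bad = values.index[values.isna().all(axis=1)].tolist()
        raise ValueError(f"feature(s) with zero observations anywhere: {bad}")
    groups = _treatment_columns(m)
    col_treatment = {c: t for t, cols in groups.items() for c in cols}
    sample_bounds = {}
    for c in values.columns:
        col = m.values[c].to_numpy(dtype=float)
        observed = col[np.isfinite(col)]
        sample_bounds[c] = (np.percentile(observed, cfg.mec_quantile_bound)
                            if observed.size else np.nan)
    # iterate column-major so the draw order is a pure function of the layout
    for col in values.columns:
        cls = miss.classes[col]
        q = sample_bounds[col]
        treatment = col_treatment[col]
        tcols = groups[treatment]
        mar_rows = values.index[cls == "MAR"]
        for fid in mar_rows:
            obs = m.values.loc[fid, tcols].dropna()
            if obs.empty:
                obs = m.values.loc[fid].dropna()
            mu = float(obs.mean())
            sd = float(obs.std(ddof=1)) if len(obs) > 1 else 0.0
            if not np.isfinite(sd):
                sd = 0.0
            values.loc[fid, col] = mu if sd == 0 else rng.normal(mu, sd)
        mec_rows = values.index[cls == "MEC"]
        if len(mec_rows):
            draws = q - MEC_DRAW_WIDTH * rng.random(len(mec_rows))
            values.loc[mec_rows, col] = draws
    return m.copy_with(values)


def quantile_center_median(m: ExpressionMatrix) -> ExpressionMatrix:
    """Equalise sample medians: subtract each sample's median and add back
    the grand median of the pre-centering sample medians."""
    values = m.values
    if values.isna().any().any():
        raise ValueError("median centering requires a complete matrix")
    medians = values.median(axis=0)
    grand = float(medians.median())
    centred = values.sub(medians, axis=1) + grand
    return m.copy_with(centred)


def cell_line_ratios(m: ExpressionMatrix, treatment: str,
                     reference: str = "SL") -> pd.DataFrame:
    """Per-cell-line log2 ratios of a treatment against the S/L reference.

    Replicates are averaged within each (cell line, treatment) block first;
    the result has one ratio column per cell line, ready for the one-sample
    moderated test.
    """
    design = m.design.table
    out = {}
    for cell_line, grp in design.groupby("cell_line", sort=True):
        t_cols = grp.loc[grp["treatment"] == treatment, "sample_id"].tolist()
        r_cols = grp.loc[grp["treatment"] == reference, "sample_id"].tolist()
        if not t_cols or not r_cols:
            raise ValueError(
                f"cell line {cell_line!r} lacks {treatment!r} or {reference!r} samples"
            )
        out[cell_line] = m.values[t_cols].mean(axis=1) - m.values[r_cols].mean(axis=1)
    return pd.DataFrame(out)
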