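"""Preranked gene-set enrichment (ES / NES / permutation FDR) and Fisher's
exact category enrichment against a declared background.

The enrichment score walks the list ranked by decreasing score: set members
("hits") increment the running sum by |score|^p normalised over the set's
hits, non-members decrement by 1/(N - N_hits); ES is the signed maximum
deviation.  The null is built by gene-set (member) permutation — the only
option for preranked input — and NES divides ES by the mean |null ES| of
matching sign.  FDR follows the standard pooled-NES ratio, clipped to
[0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats.contingency import odds_ratio as _odds_ratio

from .io_formats import GeneSetCollection
from .trend_overlap import hypergeom_overlap

logger = logging.getLogger(__name__)

MIN_SET_SIZE_DEFAULT = 5
MAX_SET_SIZE_DEFAULT = 500
N_PERM_DEFAULT = 1000
WEIGHT_DEFAULT = 1.0


@dataclass
class GseaResult:
    """Per-set enrichment: ES, NES, nominal p, FDR q and the leading edge."""

    name: str
    size: int
    es: float
    nes: float
    p: float
    q: float
    leading_edge: list[str]


def _es_from_positions(pos: np.ndarray, weights: np.ndarray, n_total: int
                       ) -> tuple[float, int]:
    """Signed maximum deviation of the running sum, evaluated at the points
    where the extremum can occur (just before and just after each hit).

    ``pos`` are 0-based hit positions in ranked order; ``weights`` the
    |score|^p values at those positions.  Returns (ES, extremum hit index)
    where the index supports leading-edge extraction.
    """
    m = pos.size
    w = weights / weights.sum() if weights.sum() > 0 else np.full(m, 1.0 / m)
    miss_step = 1.0 / (n_total - m)
    cum = np.cumsum(w)
    hits_before = np.arange(m)                       # hits strictly before pos i
    misses_before = pos - hits_before
    after = cum - (misses_before) * miss_step        # running just after hit i
    before = np.concatenate([[0.0], cum[:-1]]) - misses_before * miss_step
    candidates = np.concatenate([after, before])
    idx = int(np.argmax(np.abs(candidates)))
    es = float(candidates[idx])
    extremum_hit = idx % m
    return es, extremum_hit


def _ranked_order(scores: pd.Series) -> pd.Series:
    """Sort by decreasing score; ties keep the stable input order."""
    order = np.argsort(-scores.to_numpy(), kind="stable")
    return scores.iloc[order]


def gsea_preranked(scores: pd.Series, sets: GeneSetCollection,
                   n_perm: int = N_PERM_DEFAULT, weight: float = WEIGHT_DEFAULT,
                   min_size: int = MIN_SET_SIZE_DEFAULT,
                   max_size: int = MAX_SET_SIZE_DEFAULT,
                   seed: int = 0) -> pd.DataFrame:
    """Preranked GSEA over a feature -> score series.

    Sets are intersected with the ranked list; those below ``min_size`` or
    above ``max_size`` members are skipped with a log line.  Returns a
    DataFrame indexed by set name with columns size, es, nes, p, q and
    leading_edge (comma-joined ids).
    """
    if scores.isna().any() or not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    if scores.index.duplicated().any():
        raise ValueError("duplicated feature ids in the ranked list")
    ranked = _ranked_order(scores)
    ids = ranked.index.to_numpy()
    absw = np.abs(ranked.to_numpy()) ** weight
    n_total = len(ranked)
    position = {fid: i for i, fid in enumerate(ids)}
    rng = np.random.default_rng(seed)

    results: list[GseaResult] = []
    null_nes_pool: list[np.ndarray] = []
    for name, members in sets.sets.items():
        pos = np.array(sorted(position[g] for g in members if g in position))
        size = pos.size
        if size < min_size or size > max_size:
            logger.info("set %s skipped: %d members in list outside [%d, %d]",
                        name, size, min_size, max_size)
            continue
        if size >= n_total:
            logger.info("set %s skipped: covers the whole ranked list", name)
            continue
        es, extremum = _es_from_positions(pos, absw[pos], n_total)
        null_es = np.empty(n_perm)
        for b in range(n_perm):
            rpos = np.sort(rng.choice(n_total, size=size, replace=False))
            null_es[b], _ = _es_from_positions(rpos, absw[rpos], n_total)
        same_sign = null_es[np.sign(null_es) == np.sign(es)] if es != 0 else null_es
        if same_sign.size == 0:
            same_sign = np.array([es])
        p = (1.0 + np.sum(np.abs(same_sign) >= abs(es))) / (1.0 + same_sign.size)
        denom = np.abs(same_sign).mean()
        nes = es / denom if denom > 0 else 0.0
        # normalise the null the same way for the pooled FDR
        pos_null = null_es[null_es >= 0]
        neg_null = null_es[null_es < 0]
        norm_null = np.concatenate([
            pos_null / pos_null.mean() if pos_null.size else pos_null,
            neg_null / np.abs(neg_null).mean() if neg_null.size else neg_null,
        ])
        null_nes_pool.append(norm_null)
        if es >= 0:
            leading = [ids[p_] for p_ in pos[: extremum + 1]]
        else:
            leading = [ids[p_] for p_ in pos[extremum:]]
        results.append(GseaResult(name=name, size=size, es=es, nes=float(nes),
                                  p=float(p), q=np.nan, leading_edge=leading))

    if results:
        pooled = np.concatenate(null_nes_pool)
        obs_nes = np.array([r.nes for r in results])
        for r in results:
            if r.nes >= 0:
                null_frac = np.mean(pooled >= r.nes) if pooled.size else 0.0
                obs_frac = np.mean(obs_nes >= r.nes)
            else:
                null_frac = np.mean(pooled <= r.nes) if pooled.size else 0.0
                obs_frac = np.mean(obs_nes <= r.nes)
            r.q = float(np.clip(null_frac / obs_frac if obs_frac > 0 else 1.0, 0.0, 1.0))

    return pd.DataFrame(
        [
            {"name": r.name, "size": r.size, "es": r.es, "nes": r.nes,
             "p": r.p, "q": r.q, "leading_edge": ",".join(map(str, r.leading_edge))}
            for r in results
        ]
    ).set_index("name") if results else pd.DataFrame(
        columns=["size", "es", "nes", "p", "q", "leading_edge"])


@dataclass(frozen=True)
class FisherResult:
    """One-sided (enrichment) exact test on a 2x2 table with conditional OR."""

    a: int            # category members inside the group
    n: int            # group size
    K: int            # category members in the background
    N: int            # background size
    p: float
    odds_ratio: float


def fisher_enrichment(a: int, n: int, K: int, N: int) -> FisherResult:
    """Fisher's exact one-sided enrichment p for a category within a group.

    ``a`` of the ``n`` group members carry the category; ``K`` of the ``N``
    background features do.  The p-value is the hypergeometric upper tail
    P(X >= a); the reported odds ratio is the conditional MLE.
    """
    if not (0 <= a <= n <= N and a <= K <= N and (n - a) <= (N - K)):
        raise ValueError(f"inconsistent 2x2 counts: a={a}, n={n}, K={K}, N={N}")
    tail = hypergeom_overlap(a, K, n, N)
    table = np.array([[a, n - a], [K - a, (N - K) - (n - a)]])
    try:
        orr = float(_odds_ratio(table).statistic)
    except ValueError:
        orr = float("nan")
    return FisherResult(a=a, n=n, K=K, N=N, p=tail.p, odds_ratio=orr)
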