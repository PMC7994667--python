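"""Class-I phosphosite filtering, Gsk3 motif annotation, and priming-pair
substrate inference.

Gsk3 is a constitutively active kinase that phosphorylates S/T residues four
positions N-terminal of a pre-phosphorylated priming site (motif
S/T-x-x-x-pS/pT; e.g. Myc T58 primed by S62).  When Gsk3 is inhibited, the
di-phosphorylated peptidoform (target + priming site) collapses while the
priming-only mono-phosphorylated form persists or even accumulates — that
coordinated pattern across peptidoforms is the substrate call.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .enrichment import FisherResult, fisher_enrichment
from .io_formats import PhosphoSiteTable

logger = logging.getLogger(__name__)

CLASS1_MIN_PROB = 0.75           # conventional class-I localization cutoff
PRIMING_OFFSET = 4               # priming residue sits at target position + 4
EARLY_2I_TIMEPOINTS = (0.5, 1.0, 2.0, 6.0)   # hours
FC_DOWN_DEFAULT = -0.5


def filter_class1(t: PhosphoSiteTable, min_prob: float = CLASS1_MIN_PROB
                  ) -> PhosphoSiteTable:
    """Keep sites with localization probability >= ``min_prob`` (inclusive)."""
    keep = t.table["localization_prob"].astype(float) >= min_prob
    return PhosphoSiteTable(t.table.loc[keep], t.design)


def annotate_gsk3_motif(t: PhosphoSiteTable) -> pd.Series:
    """Boolean per-row flag: center residue S/T with S/T four positions
    C-terminal (the Gsk3 S/T-x-x-x-pS/pT consensus read on the window)."""
    flags = []
    for win in t.table["window"]:
        center = len(win) // 2
        if center + PRIMING_OFFSET >= len(win):
            logger.warning("window %r too short for the +4 priming position", win)
            flags.append(False)
            continue
        flags.append(win[center] in "ST" and win[center + PRIMING_OFFSET] in "ST")
    return pd.Series(flags, index=t.table.index, name="gsk3_motif")


@dataclass
class GskCall:
    """Verdict for one candidate Gsk3 target site.

    ``substrate`` requires the di-phosphorylated form to drop significantly
    in 2i at some early timepoint while the priming-only mono form at the
    same timepoint is non-decreasing or non-significant; ``motif_only``
    marks motif matches without the coordinated pattern (or without a paired
    mono form); ``rejected`` marks whole-site loss (both forms down).
    """

    protein: str
    position: int
    priming_position: int
    di_site_id: str
    mono_site_id: str | None
    di_min_log2fc: float
    di_min_q: float
    mono_log2fc: float
    mono_q: float
    verdict: str
    reason: str = ""


def _site_lookup(t: PhosphoSiteTable) -> pd.DataFrame:
    return t.table.reset_index().set_index(["protein", "position", "multiplicity"])


def call_gsk3_substrates(t: PhosphoSiteTable, diff_2i: pd.DataFrame,
                         q_max: float = 0.05, fc_down: float = FC_DOWN_DEFAULT,
                         timepoints: tuple[float, ...] = EARLY_2I_TIMEPOINTS
                         ) -> list[GskCall]:
    """Infer Gsk3 substrates from coordinated di- vs mono-peptidoform shifts.

    ``diff_2i`` is a differential table over peptidoform rows (feature = the
    phosphosite row id) restricted to or containing the 2i treatment.
    Candidates are motif-matching di-phosphorylated rows; each is paired with
    the mono-phosphorylated row of its priming site (position + 4).
    """
    motif = annotate_gsk3_motif(t)
    diff = diff_2i[diff_2i["treatment"] == "2i"] if "treatment" in diff_2i else diff_2i
    diff = diff[diff["timepoint"].astype(float).isin(timepoints)]
    by_feature = dict(tuple(diff.groupby("feature", sort=False)))
    lookup = _site_lookup(t)

    calls: list[GskCall] = []
    di_rows = t.table[(t.table["multiplicity"] >= 2) & motif]
    for site_id, row in di_rows.iterrows():
        protein, pos = row["protein"], int(row["position"])
        priming_pos = pos + PRIMING_OFFSET
        mono_key = (protein, priming_pos, 1)
        mono_id = None
        if mono_key in lookup.index:
            mono_id = lookup.loc[mono_key, "site_id"]
            if isinstance(mono_id, pd.Series):
                mono_id = mono_id.iloc[0]
        di_stats = by_feature.get(site_id)
        if di_stats is None or di_stats["p"].isna().all():
            continue
        di_min_fc = float(di_stats["log2FC"].min())
        di_min_q = float(di_stats["q"].min())
        if mono_id is None:
            calls.append(GskCall(protein, pos, priming_pos, site_id, None,
                                 di_min_fc, di_min_q, np.nan, np.nan,
                                 "motif_only", "unpaired"))
            continue
        mono_stats = by_feature.get(mono_id)
        down_tps = di_stats[(di_stats["log2FC"] <= fc_down) & (di_stats["q"] < q_max)]
        verdict, reason = "motif_only", "di form not significantly down"
        mono_fc_at, mono_q_at = np.nan, np.nan
        if len(down_tps):
            if mono_stats is None:
                verdict, reason = "motif_only", "unpaired"
            else:
                # the priming form must stay unaltered (or rise) at EVERY
                # timepoint where the di form drops: a parallel loss of both
                # forms is whole-site loss, not Gsk3-specific inhibition
                verdict, reason = "substrate", ""
                seen_any = False
                for tp in down_tps["timepoint"]:
                    ms = mono_stats[mono_stats["timepoint"] == tp]
                    if ms.empty:
                        continue
                    seen_any = True
                    fc, q = float(ms["log2FC"].iloc[0]), float(ms["q"].iloc[0])
                    mono_fc_at, mono_q_at = fc, q
                    if fc < 0 and q < q_max:
                        verdict, reason = "rejected", "priming form lost in parallel"
                        break
                if not seen_any:
                    verdict, reason = "motif_only", "unpaired"
        calls.append(GskCall(protein, pos, priming_pos, site_id, mono_id,
                             di_min_fc, di_min_q, mono_fc_at, mono_q_at,
                             verdict, reason))
    return calls


def gsk_calls_table(calls: list[GskCall]) -> pd.DataFrame:
    """Flatten GskCall records for writing."""
    return pd.DataFrame([c.__dict__ for c in calls])


def priming_cophosphorylation_fraction(t: PhosphoSiteTable,
                                       class1_only: bool = True) -> float:
    """Fraction of motif-matching sites whose priming position is itself
    observed phosphorylated (any multiplicity).

    With ``class1_only`` the motif universe is restricted to class-I sites;
    both readings are reported by the pipeline since the field convention is
    ambiguous on the universe.
    """
    universe = filter_class1(t) if class1_only else t
    motif = annotate_gsk3_motif(universe)
    observed = set(zip(t.table["protein"], t.table["position"].astype(int)))
    matched = universe.table[motif.to_numpy()]
    if matched.empty:
        return float("nan")
    co = [
        (p, int(pos) + PRIMING_OFFSET) in observed
        for p, pos in zip(matched["protein"], matched["position"])
    ]
    return float(np.mean(co))


def motif_cluster_enrichment(cluster_sites: set[str], background_sites: set[str],
                             motif_flags: pd.Series) -> FisherResult:
    """Fisher enrichment of the Gsk3 motif in a cluster vs the class-I
    background (delegates to the exact hypergeometric upper tail)."""
    if not cluster_sites:
        raise ValueError("cluster is empty")
    if not set(cluster_sites) <= set(background_sites):
        raise ValueError("cluster sites must be a subset of the background")
    flags = motif_flags.reindex(list(background_sites)).fillna(False)
    a = int(flags.loc[list(cluster_sites)].sum())
    K = int(flags.sum())
    return fisher_enrichment(a, len(cluster_sites), K, len(background_sites))
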