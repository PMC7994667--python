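"""End-to-end synthetic pipeline: simulate, preprocess, test, cluster,
enrich, and integrate, writing plain-TSV stage artifacts plus a manifest.

Every stage reads and writes flat tables so any stage can be re-run
standalone; the manifest records the configuration, seeds and SHA-256
checksums of all outputs, and re-running with an identical configuration
reproduces identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .differential import differential_table
from .enrichment import gsea_preranked
from .integration import aggregate_divergence, classify_posttranscriptional, subset_shift_report
from .io_formats import ExpressionMatrix, GeneSetCollection, write_table
from .metabolome import (ImputeConfig, cell_line_ratios, classify_missingness,
                         drop_sparse_samples, filter_by_presence, impute,
                         quantile_center_median)
from .phospho import annotate_gsk3_motif, call_gsk3_substrates, filter_class1, gsk_calls_table
from .preprocess import (batch_adjust_eb, collapse_and_zscore, cyclic_loess_normalize,
                         drop_reference_columns, pca_scores, ratios_vs_reference)
from .synthetic_data import SimulationConfig, simulate_metabolome, simulate_phospho_layer, simulate_study
from .trend_overlap import gap_statistic, kmeans_trajectories, overlap_from_sets

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Pipeline-wide parameters; every seed is explicit and serialized."""

    out_dir: str = "naiveomics_run"
    seed: int = 0
    simulation: SimulationConfig | None = None
    loess_span: float = 0.7
    loess_iters: int = 3
    q_max: float = 0.05
    fc_min: float = 0.1
    gap_k_max: int = 8
    gap_B: int = 50
    kmeans_restarts: int = 25
    n_perm: int = 1000
    mec_quantile_bound: float = 2.5
    trend_zscore_mode: str = "concatenated"
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        sim = raw.pop("simulation", None)
        unknown = [k for k in raw if k not in cls.__dataclass_fields__]
        if unknown:
            raise ValueError(f"unknown configuration key(s): {unknown}")
        cfg = cls(**raw)
        if sim is not None:
            cfg.simulation = SimulationConfig(**sim)
        return cfg

    def resolved_simulation(self) -> SimulationConfig:
        if self.simulation is not None:
            return self.simulation
        return SimulationConfig(seed=self.seed)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulation"] = dataclasses.asdict(self.resolved_simulation())
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def simulate_stage(cfg: PipelineConfig, out: Path):
    sim = cfg.resolved_simulation()
    proteome, mrna, truth = simulate_study(sim)
    phospho, truth = simulate_phospho_layer(sim, truth)
    metabolome, truth = simulate_metabolome(sim, truth)
    write_table(proteome, out / "proteome.tsv")
    write_table(proteome.design, out / "proteome_design.tsv")
    write_table(mrna, out / "mrna_ratios.tsv")
    write_table(phospho, out / "phospho_sites.tsv")
    write_table(metabolome, out / "metabolome.tsv")
    write_table(metabolome.design, out / "metabolome_design.tsv")
    truth.write(out)
    return proteome, mrna, phospho, metabolome, truth


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Execute all stages in dependency order on synthetic inputs.

    Returns the output directory.  Any stage exception aborts the run with
    the stage name in the error message.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = cfg.resolved_simulation()
    stage = "simulate"
    try:
        proteome, mrna, phospho, metabolome, truth = simulate_stage(cfg, out)

        stage = "preprocess"
        norm = cyclic_loess_normalize(proteome, span=cfg.loess_span, n_iter=cfg.loess_iters)
        adjusted = batch_adjust_eb(norm)
        ratios = drop_reference_columns(ratios_vs_reference(adjusted))
        scores, var_frac = pca_scores(adjusted, n_components=2)
        write_table(scores, out / "proteome_pca.tsv")

        stage = "differential"
        prot_diff = differential_table(ratios, q_max=cfg.q_max, fc_min=cfg.fc_min)
        write_table(prot_diff, out / "proteome_differential.tsv")

        stage = "trends"
        regulated = prot_diff.loc[prot_diff["regulated"] != "none", "feature"].unique()
        universe = set(prot_diff["feature"].unique())
        overlaps = []
        for tp, grp in prot_diff.groupby("timepoint"):
            for direction in ("up", "down"):
                s1 = set(grp.loc[(grp["treatment"] == "2i") & (grp["regulated"] == direction), "feature"])
                s2 = set(grp.loc[(grp["treatment"] == "Cdk8i") & (grp["regulated"] == direction), "feature"])
                ov = overlap_from_sets(s1, s2, universe)
                overlaps.append({"timepoint": tp, "direction": direction,
                                 **dataclasses.asdict(ov)})
        write_table(pd.DataFrame(overlaps), out / "treatment_overlaps.tsv")
        trajectories = collapse_and_zscore(ratios, mode=cfg.trend_zscore_mode)
        reg_traj_data = trajectories.data.loc[sorted(regulated)]
        reg_traj = dataclasses.replace(trajectories, data=reg_traj_data)
        gap = gap_statistic(reg_traj_data.to_numpy(), k_max=cfg.gap_k_max,
                            B=cfg.gap_B, seed=cfg.seed)
        model = kmeans_trajectories(reg_traj, K=gap.chosen_K, seed=cfg.seed,
                                    restarts=cfg.kmeans_restarts, gap=gap)
        write_table(gap.table, out / "gap_profile.tsv")
        write_table(model.assignments.rename("cluster"), out / "cluster_assignments.tsv")
        write_table(model.centroid_correlations, out / "centroid_correlations.tsv")

        stage = "enrichment"
        day14 = prot_diff[(prot_diff["treatment"] == "2i")
                          & (prot_diff["timepoint"] == prot_diff["timepoint"].max())]
        ranking = day14.set_index("feature")["log2FC"].dropna()
        up_set = set(truth.proteins.index[truth.proteins["dir_2i"] > 0])
        down_set = set(truth.proteins.index[truth.proteins["dir_2i"] < 0])
        sets = GeneSetCollection({"planted_up_2i": up_set, "planted_down_2i": down_set})
        gsea = gsea_preranked(ranking, sets, n_perm=cfg.n_perm, seed=cfg.seed)
        write_table(gsea, out / "gsea_results.tsv")

        stage = "phospho"
        class1 = filter_class1(phospho)
        motif = annotate_gsk3_motif(class1)
        p_ratios = drop_reference_columns(
            ratios_vs_reference(class1.values_matrix()))
        p_diff = differential_table(p_ratios, q_max=cfg.q_max, fc_min=cfg.fc_min)
        calls = call_gsk3_substrates(class1, p_diff, q_max=cfg.q_max)
        write_table(gsk_calls_table(calls), out / "gsk3_calls.tsv")
        write_table(motif.rename("gsk3_motif"), out / "gsk3_motif_flags.tsv")

        stage = "metabolome"
        filtered = filter_by_presence(drop_sparse_samples(metabolome))
        miss = classify_missingness(filtered)
        imputed = impute(filtered, miss,
                         ImputeConfig(mec_quantile_bound=cfg.mec_quantile_bound,
                                      seed=cfg.seed))
        centred = quantile_center_median(imputed)
        write_table(centred, out / "metabolome_imputed.tsv")
        write_table(miss.classes, out / "metabolome_missingness.tsv")
        met_frames = []
        for treatment in ("2i", "Cdk8i"):
            r = cell_line_ratios(centred, treatment)
            d = differential_table(
                _ratio_matrix(r, treatment), q_max=cfg.q_max, fc_min=cfg.fc_min)
            met_frames.append(d)
        met_diff = pd.concat(met_frames, ignore_index=True)
        write_table(met_diff, out / "metabolome_differential.tsv")
        met_universe = set(met_diff["feature"].unique())
        down_2i = set(met_diff.loc[(met_diff["treatment"] == "2i")
                                   & (met_diff["regulated"] == "down"), "feature"])
        down_cdk = set(met_diff.loc[(met_diff["treatment"] == "Cdk8i")
                                    & (met_diff["regulated"] == "down"), "feature"])
        met_overlap = overlap_from_sets(down_2i, down_cdk, met_universe)
        write_table(met_overlap, out / "metabolite_down_overlap.tsv")

        stage = "integration"
        mrna_diff = differential_table(mrna, q_max=cfg.q_max, fc_min=cfg.fc_min,
                                       replicate_on="replicate")
        calls_pt = classify_posttranscriptional(prot_diff, mrna_diff,
                                                fc_min=cfg.fc_min, q_max=cfg.q_max)
        write_table(aggregate_divergence(calls_pt), out / "divergence_calls.tsv")
        posttx = set(truth.proteins.index[truth.proteins["posttx"]])
        last_tp = prot_diff["timepoint"].max()
        prot_fc = prot_diff[(prot_diff["treatment"] == "2i")
                            & (prot_diff["timepoint"] == last_tp)].set_index("feature")["log2FC"]
        rna_fc = mrna_diff[(mrna_diff["treatment"] == "2i")
                           & (mrna_diff["timepoint"] == last_tp)].set_index("feature")["log2FC"]
        if len(posttx) >= 3:
            report = subset_shift_report(prot_fc, rna_fc, posttx)
            write_table(pd.DataFrame([{"subset_size": report.subset_size,
                                       "t": report.t, "df": report.df, "p": report.p}]),
                        out / "posttx_subset_shift.tsv")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "config": cfg.to_dict(),
        "outputs": {p.name: _sha256(p) for p in sorted(out.glob("*.tsv"))},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out


def _ratio_matrix(ratios: pd.DataFrame, treatment: str,
                  timepoint: float = 14.0) -> ExpressionMatrix:
    """Wrap a per-cell-line ratio frame as a one-timepoint ratio layer."""
    from .preprocess import SampleDesignView

    cols = {}
    rows = []
    for cell_line in ratios.columns:
        sid = f"{cell_line}_{treatment}_ratio"
        cols[sid] = ratios[cell_line]
        rows.append((sid, cell_line, treatment, timepoint, cell_line, 1))
    design = SampleDesignView(pd.DataFrame(rows, columns=[
        "sample_id", "cell_line", "treatment", "timepoint", "plex", "replicate"]))
    return ExpressionMatrix(pd.DataFrame(cols, index=ratios.index), design, "metabolite_ratio")
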