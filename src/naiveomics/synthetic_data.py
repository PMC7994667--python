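"""Synthetic multi-omics study generator with exported ground truth.

Emulates the study layout: four mESC cell lines, each one isobaric plex,
profiled under S/L (reference), 2i, and Cdk8/19i; proteome timepoints in
days {0,1,2,4,7,10,14}, phosphoproteome timepoints in hours {0,0.5,1,2,6},
and a metabolome of 3 treatments x 4 cell lines x 4 replicates.  Planted
truth covers differential direction per treatment, temporal trend modules
(monotone rise/fall, transient pulse, late plateau), Gsk3 priming-pair
substrates, post-transcriptionally divergent features, and MAR / entire-
condition metabolite missingness.

Determinism: one PCG64 stream per layer, split from the master seed with
``numpy.random.SeedSequence.spawn`` in a fixed order (proteome, mRNA,
phospho, metabolome), so enabling or disabling one layer never perturbs the
others.  All effects are additive on the log2 scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix, PhosphoSiteTable, SampleDesign, write_table
from .phospho import PRIMING_OFFSET
from .preprocess import SampleDesignView

logger = logging.getLogger(__name__)

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
WINDOW_LENGTH = 15
TREATED = ("2i", "Cdk8i")

#: canonical trajectory shapes, as non-negative profiles peaking at 1; the
#: feature's planted direction (+1/-1) supplies the sign, so "monotone" with
#: direction -1 is the monotone fall, "transient_pulse" with -1 a transient
#: dip, and so on
TREND_SHAPES = ("monotone", "transient_pulse", "late_plateau", "early_saturation")


@dataclass(frozen=True)
class SimulationConfig:
    """Study-scale parameters for the synthetic generator.

    Feature counts mirror the study's layer sizes (about 4.4k proteins, a
    phosphosite table subsampled to 5k rows, 440 metabolites); noise_sd is
    the per-channel replicate noise and batch_sd the per-plex offset spread,
    both in log2 units.
    """

    seed: int = 0
    n_proteins: int = 4000
    n_phosphosites: int = 5000
    n_metabolites: int = 440
    n_cell_lines: int = 4
    timepoints_protein: tuple[float, ...] = (0, 1, 2, 4, 7, 10, 14)   # days
    timepoints_phospho: tuple[float, ...] = (0, 0.5, 1, 2, 6)         # hours
    batch_sd: float = 0.5
    noise_sd: float = 0.25
    frac_shared_up: float = 0.08
    frac_shared_down: float = 0.08
    frac_specific: float = 0.08
    n_trend_modules: int = 4
    n_gsk3_substrates: int = 50
    n_posttx: int = 200
    mar_rate: float = 0.05
    mec_rate: float = 0.05
    frac_low_localization: float = 0.1
    n_mrna_replicates: int = 3
    n_metabolite_replicates: int = 4
    baseline_mean: float = 25.0
    baseline_sd: float = 2.0

    def __post_init__(self) -> None:
        fracs = (self.frac_shared_up, self.frac_shared_down, self.frac_specific,
                 self.mar_rate, self.mec_rate, self.frac_low_localization)
        if any(not (0.0 <= f <= 1.0) for f in fracs):
            raise ValueError("all fractions must lie in [0, 1]")
        if self.frac_shared_up + self.frac_shared_down + self.frac_specific > 1.0:
            raise ValueError("planted fractions sum above 1")
        for name in ("n_proteins", "n_phosphosites", "n_metabolites", "n_cell_lines"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.noise_sd <= 0 or self.batch_sd < 0:
            raise ValueError("noise_sd must be positive and batch_sd non-negative")

    def streams(self) -> dict[str, np.random.Generator]:
        children = np.random.SeedSequence(self.seed).spawn(4)
        names = ("proteome", "mrna", "phospho", "metabolome")
        return {n: np.random.default_rng(c) for n, c in zip(names, children)}

    @property
    def peak_amplitude(self) -> float:
        """Minimum planted peak effect: four replicate-noise sds."""
        return 4.0 * self.noise_sd


@dataclass
class SyntheticTruth:
    """Planted ground truth, one table per layer."""

    proteins: pd.DataFrame = field(default_factory=pd.DataFrame)
    batch_offsets: pd.DataFrame = field(default_factory=pd.DataFrame)
    phospho: pd.DataFrame = field(default_factory=pd.DataFrame)
    metabolites: pd.DataFrame = field(default_factory=pd.DataFrame)

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        for name in ("proteins", "phospho", "metabolites"):
            table = getattr(self, name)
            if len(table):
                write_table(table, directory / f"truth_{name}.tsv")


def _shape_profile(shape: str, t: np.ndarray, t_max: float) -> np.ndarray:
    """Non-negative trajectory profile with peak value 1 at some timepoint."""
    t = np.asarray(t, dtype=float)
    if shape == "monotone":
        return t / t_max
    if shape == "transient_pulse":
        center, width = 0.15 * t_max, 0.15 * t_max
        prof = np.exp(-((t - center) ** 2) / (2 * width**2))
        return prof
    if shape == "late_plateau":
        prof = 1.0 / (1.0 + np.exp(-(t - 0.4 * t_max) / (0.1 * t_max)))
        prof = np.where(t == 0, 0.0, prof)
        return prof / (1.0 / (1.0 + np.exp(-(t_max - 0.4 * t_max) / (0.1 * t_max))))
    if shape == "early_saturation":
        return (1.0 - np.exp(-4.0 * t / t_max)) / (1.0 - np.exp(-4.0))
    raise ValueError(f"unknown trend shape {shape!r}")


def trend_module_shape(module: int, t: np.ndarray, t_max: float) -> np.ndarray:
    return _shape_profile(TREND_SHAPES[module % len(TREND_SHAPES)], t, t_max)


# ---------------------------------------------------------------------------
# Proteome + mRNA
# ---------------------------------------------------------------------------


def _proteome_design(cfg: SimulationConfig) -> SampleDesign:
    rows = []
    nonzero = [t for t in cfg.timepoints_protein if t > 0]
    for c in range(1, cfg.n_cell_lines + 1):
        plex, line = f"plex{c}", f"CL{c}"
        for r in (1, 2):
            rows.append((f"{line}_SL_r{r}", line, "SL", 0.0, plex, r))
        for treatment in TREATED:
            for t in nonzero:
                rows.append((f"{line}_{treatment}_d{t:g}", line, treatment,
                             float(t), plex, 1))
    return SampleDesign(pd.DataFrame(rows, columns=[
        "sample_id", "cell_line", "treatment", "timepoint", "plex", "replicate"]))


def _plant_assignments(cfg: SimulationConfig, n: int, rng: np.random.Generator
                       ) -> pd.DataFrame:
    """Pick planted feature classes and trend modules for one feature space."""
    n_up = round(cfg.frac_shared_up * n)
    n_down = round(cfg.frac_shared_down * n)
    n_spec = round(cfg.frac_specific * n)
    if n_up + n_down + n_spec > n:
        raise ValueError("planted fractions exceed the feature count")
    perm = rng.permutation(n)
    dir_2i = np.zeros(n, dtype=int)
    dir_cdk = np.zeros(n, dtype=int)
    shared_up = perm[:n_up]
    shared_down = perm[n_up:n_up + n_down]
    spec = perm[n_up + n_down:n_up + n_down + n_spec]
    half = len(spec) // 2
    dir_2i[shared_up] = 1
    dir_cdk[shared_up] = 1
    dir_2i[shared_down] = -1
    dir_cdk[shared_down] = -1
    dir_2i[spec[:half]] = rng.choice([-1, 1], size=half)
    dir_cdk[spec[half:]] = rng.choice([-1, 1], size=len(spec) - half)
    planted = (dir_2i != 0) | (dir_cdk != 0)
    module = np.full(n, -1, dtype=int)
    module[planted] = rng.integers(cfg.n_trend_modules, size=int(planted.sum()))
    amplitude = np.zeros(n)
    amplitude[planted] = cfg.peak_amplitude * (1.0 + 0.5 * rng.random(int(planted.sum())))
    return pd.DataFrame({
        "dir_2i": dir_2i, "dir_Cdk8i": dir_cdk, "module": module,
        "amplitude": amplitude,
    })


def _effect(cfg: SimulationConfig, plant: pd.DataFrame, treatment: str,
            t: float, t_max: float) -> np.ndarray:
    """Per-feature planted log2 effect at one treatment x timepoint."""
    direction = plant[f"dir_{treatment}"].to_numpy()
    out = np.zeros(len(plant))
    active = direction != 0
    if not active.any() or t == 0:
        return out
    amplitude = plant["amplitude"].to_numpy()
    modules = plant["module"].to_numpy()
    for module in np.unique(modules[active]):
        sel = active & (modules == module)
        prof = float(trend_module_shape(int(module), np.array([t]), t_max)[0])
        out[sel] = direction[sel] * amplitude[sel] * prof
    return out


def simulate_study(cfg: SimulationConfig
                   ) -> tuple[ExpressionMatrix, ExpressionMatrix, SyntheticTruth]:
    """Generate the proteome (log2 abundances) and matched mRNA log2 ratios.

    The proteome carries baseline ~ Normal(25, 2), planted trajectory
    effects with peak magnitude >= 4 x noise_sd, per-(feature, plex) batch
    offsets ~ Normal(0, batch_sd) and channel noise ~ Normal(0, noise_sd).
    The mRNA ratio layer mirrors every protein effect except for the
    ``n_posttx`` planted post-transcriptional features, whose mRNA effect is
    exactly zero.
    """
    streams = cfg.streams()
    rng = streams["proteome"]
    n = cfg.n_proteins
    features = [f"P{i:05d}" for i in range(1, n + 1)]
    design = _proteome_design(cfg)
    t_max = max(cfg.timepoints_protein)

    plant = _plant_assignments(cfg, n, rng)
    plant.index = pd.Index(features, name="feature")
    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=n)
    plexes = sorted(design.table["plex"].unique())
    batch = pd.DataFrame(rng.normal(0.0, cfg.batch_sd, size=(n, len(plexes))),
                         index=features, columns=plexes)

    cols = {}
    for _, row in design.table.iterrows():
        eff = _effect(cfg, plant, row["treatment"], row["timepoint"], t_max) \
            if row["treatment"] != "SL" else np.zeros(n)
        noise = rng.normal(0.0, cfg.noise_sd, size=n)
        cols[row["sample_id"]] = baseline + eff + batch[row["plex"]].to_numpy() + noise
    proteome = ExpressionMatrix(pd.DataFrame(cols, index=features), design, "protein")

    # mRNA: ratio layer on the same grid, 3 replicates, post-transcriptional
    # features get zero mRNA effect
    rng_m = streams["mrna"]
    planted_idx = plant.index[(plant["dir_2i"] != 0) | (plant["dir_Cdk8i"] != 0)]
    n_posttx = cfg.n_posttx
    if n_posttx > len(planted_idx):
        logger.warning("n_posttx=%d exceeds the %d planted features; capping",
                       n_posttx, len(planted_idx))
        n_posttx = len(planted_idx)
    posttx = pd.Index(rng_m.choice(planted_idx, size=n_posttx, replace=False))
    plant["posttx"] = plant.index.isin(posttx)
    plant["posttx_sign"] = np.where(
        plant["posttx"], np.where(plant["dir_2i"] != 0, plant["dir_2i"],
                                  plant["dir_Cdk8i"]), 0)

    nonzero = [t for t in cfg.timepoints_protein if t > 0]
    mrna_rows, mrna_cols = [], {}
    for treatment in TREATED:
        for t in nonzero:
            eff = _effect(cfg, plant, treatment, t, t_max)
            eff = np.where(plant["posttx"], 0.0, eff)
            for r in range(1, cfg.n_mrna_replicates + 1):
                sid = f"RNA_{treatment}_d{t:g}_r{r}"
                mrna_rows.append((sid, f"R{r}", treatment, float(t), "rna", r))
                mrna_cols[sid] = eff + rng_m.normal(0.0, cfg.noise_sd, size=n)
    mrna_design = SampleDesignView(pd.DataFrame(mrna_rows, columns=[
        "sample_id", "cell_line", "treatment", "timepoint", "plex", "replicate"]))
    mrna = ExpressionMatrix(pd.DataFrame(mrna_cols, index=features), mrna_design, "mrna")

    truth = SyntheticTruth(proteins=plant, batch_offsets=batch)
    return proteome, mrna, truth


# ---------------------------------------------------------------------------
# Phosphoproteome
# ---------------------------------------------------------------------------


def _phospho_design(cfg: SimulationConfig) -> SampleDesign:
    rows = []
    nonzero = [t for t in cfg.timepoints_phospho if t > 0]
    for c in range(1, cfg.n_cell_lines + 1):
        plex, line = f"pplex{c}", f"CL{c}"
        for r in (1, 2, 3):
            rows.append((f"{line}_pSL_r{r}", line, "SL", 0.0, plex, r))
        for treatment in TREATED:
            for t in nonzero:
                rows.append((f"{line}_p{treatment}_h{t:g}", line, treatment,
                             float(t), plex, 1))
    return SampleDesign(pd.DataFrame(rows, columns=[
        "sample_id", "cell_line", "treatment", "timepoint", "plex", "replicate"]))


def _random_window(rng: np.random.Generator, center_pool: str = "ST") -> list[str]:
    win = list(rng.choice(AMINO_ACIDS, size=WINDOW_LENGTH))
    win[WINDOW_LENGTH // 2] = str(rng.choice(list(center_pool)))
    return win


def _phospho_ramp(t: float, scale: float) -> float:
    """Saturating early-response ramp: full effect from 2 h onwards."""
    return scale * min(t / 2.0, 1.0)


def simulate_phospho_layer(cfg: SimulationConfig, truth: SyntheticTruth
                           ) -> tuple[PhosphoSiteTable, SyntheticTruth]:
    """Generate multiplicity-resolved phosphosite rows with planted Gsk3
    substrate pairs.

    Each planted substrate emits a di-phosphorylated peptidoform (target S/T
    at the window center, priming S/T at center+4) whose 2i trajectory drops
    to -1.4 log2 by 2 h, and a priming-only mono form whose 2i effect is a
    mild increase.  Decoys include whole-site-loss pairs (both forms drop:
    not Gsk3-specific) and motif-matching windows with no coordinated
    decline.  A configurable fraction of decoy localization probabilities
    falls below the class-I cutoff; planted substrate sites are
    well-localized by construction.
    """
    rng = cfg.streams()["phospho"]
    design = _phospho_design(cfg)
    n_sub = cfg.n_gsk3_substrates
    n_total = cfg.n_phosphosites
    if 2 * n_sub > n_total:
        raise ValueError("n_gsk3_substrates pairs exceed n_phosphosites rows")

    records: list[dict] = []

    def add_row(protein: str, position: int, window: list[str], mult: int,
                role: str, effect_2i: float, prob: float) -> None:
        center = window[WINDOW_LENGTH // 2]
        records.append({
            "protein": protein, "position": position, "residue": center,
            "localization_prob": prob, "multiplicity": mult,
            "window": "".join(window), "role": role, "effect_2i": effect_2i,
        })

    for j in range(1, n_sub + 1):
        protein = f"GSK{j:03d}"
        pos = int(rng.integers(8, 200))
        win = _random_window(rng, "ST")
        win[WINDOW_LENGTH // 2 + PRIMING_OFFSET] = str(rng.choice(["S", "T"]))
        add_row(protein, pos, win, 2, "substrate_di", -1.4,
                float(rng.uniform(0.85, 1.0)))
        mono = _random_window(rng, win[WINDOW_LENGTH // 2 + PRIMING_OFFSET])
        mono[WINDOW_LENGTH // 2 - PRIMING_OFFSET] = win[WINDOW_LENGTH // 2]
        add_row(protein, pos + PRIMING_OFFSET, mono, 1, "substrate_mono", 0.5,
                float(rng.uniform(0.85, 1.0)))

    n_rest = n_total - 2 * n_sub
    n_pair_decoys = n_rest // 20            # whole-site-loss pairs (2 rows each)
    n_motif_decoys = n_rest // 10
    n_background = n_rest - 2 * n_pair_decoys - n_motif_decoys
    low_prob = rng.random(n_rest) < cfg.frac_low_localization

    def decoy_prob(i: int) -> float:
        return float(rng.uniform(0.3, 0.745)) if low_prob[i] else float(rng.uniform(0.8, 1.0))

    i = 0
    for k in range(1, n_pair_decoys + 1):
        protein = f"DEC{k:04d}"
        pos = int(rng.integers(8, 200))
        win = _random_window(rng, "ST")
        win[WINDOW_LENGTH // 2 + PRIMING_OFFSET] = str(rng.choice(["S", "T"]))
        add_row(protein, pos, win, 2, "decoy_pair_di", -1.4, decoy_prob(i)); i += 1
        mono = _random_window(rng, win[WINDOW_LENGTH // 2 + PRIMING_OFFSET])
        add_row(protein, pos + PRIMING_OFFSET, mono, 1, "decoy_pair_mono", -1.4,
                decoy_prob(i)); i += 1
    for k in range(1, n_motif_decoys + 1):
        win = _random_window(rng, "ST")
        win[WINDOW_LENGTH // 2 + PRIMING_OFFSET] = str(rng.choice(["S", "T"]))
        add_row(f"PH{k:05d}M", int(rng.integers(8, 200)), win, 2, "motif_decoy",
                0.0, decoy_prob(i)); i += 1
    for k in range(1, n_background + 1):
        win = _random_window(rng, "STY")
        add_row(f"PH{k:05d}B", int(rng.integers(8, 200)), win,
                int(rng.choice([1, 2])), "background", 0.0, decoy_prob(i)); i += 1

    table = pd.DataFrame.from_records(records)
    table.index = pd.Index(
        [f"{p}_{r}{pos}_M{m}" for p, r, pos, m in
         zip(table["protein"], table["residue"], table["position"], table["multiplicity"])],
        name="site_id",
    )
    if table.index.duplicated().any():
        table = table[~table.index.duplicated()]

    n_rows = len(table)
    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=n_rows)
    plexes = sorted(design.table["plex"].unique())
    batch = pd.DataFrame(rng.normal(0.0, cfg.batch_sd, size=(n_rows, len(plexes))),
                         index=table.index, columns=plexes)
    role = table["role"].to_numpy()
    eff_scale = table["effect_2i"].to_numpy()
    for _, srow in design.table.iterrows():
        if srow["treatment"] == "2i":
            eff = np.array([_phospho_ramp(srow["timepoint"], s) for s in eff_scale])
        else:
            eff = np.zeros(n_rows)
        noise = rng.normal(0.0, cfg.noise_sd, size=n_rows)
        table[srow["sample_id"]] = baseline + eff + batch[srow["plex"]].to_numpy() + noise

    phospho_truth = table[["protein", "position", "multiplicity", "role"]].copy()
    phospho_truth["substrate"] = role == "substrate_di"
    truth.phospho = phospho_truth

    cols = list(PhosphoSiteTable.SITE_COLUMNS) + design.sample_ids
    return PhosphoSiteTable(table[cols], design), truth


# ---------------------------------------------------------------------------
# Metabolome
# ---------------------------------------------------------------------------


def _metabolome_design(cfg: SimulationConfig) -> SampleDesign:
    rows = []
    for c in range(1, cfg.n_cell_lines + 1):
        line = f"CL{c}"
        for treatment in ("SL",) + TREATED:
            tp = 0.0 if treatment == "SL" else 14.0
            for r in range(1, cfg.n_metabolite_replicates + 1):
                rows.append((f"{line}_{treatment}_m{r}", line, treatment, tp, line, r))
    return SampleDesign(pd.DataFrame(rows, columns=[
        "sample_id", "cell_line", "treatment", "timepoint", "plex", "replicate"]))


def simulate_metabolome(cfg: SimulationConfig, truth: SyntheticTruth | None = None
                        ) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Generate the metabolite matrix with planted shifts and missingness.

    Planted per-treatment up/down sets use the shared/specific fractions;
    MAR cells are masked uniformly at ``mar_rate``; MEC features have one
    randomly chosen treatment masked entirely.  Any feature left with zero
    observations is repaired by unmasking one MAR cell (logged).
    """
    truth = truth or SyntheticTruth()
    rng = cfg.streams()["metabolome"]
    design = _metabolome_design(cfg)
    n = cfg.n_metabolites
    features = [f"M{i:04d}" for i in range(1, n + 1)]

    plant = _plant_assignments(cfg, n, rng)
    plant.index = pd.Index(features, name="feature")
    amp = plant["amplitude"].to_numpy()
    baseline = rng.normal(20.0, 2.0, size=n)
    line_offsets = {f"CL{c}": rng.normal(0.0, cfg.batch_sd / 2.0, size=n)
                    for c in range(1, cfg.n_cell_lines + 1)}

    cols = {}
    for _, srow in design.table.iterrows():
        treatment = srow["treatment"]
        if treatment == "SL":
            eff = np.zeros(n)
        else:
            eff = plant[f"dir_{treatment}"].to_numpy() * amp
        noise = rng.normal(0.0, cfg.noise_sd, size=n)
        cols[srow["sample_id"]] = baseline + eff + line_offsets[srow["plex"]] + noise
    values = pd.DataFrame(cols, index=features)

    # MAR mask
    mar_mask = rng.random(values.shape) < cfg.mar_rate
    # MEC plants: one fully-missing treatment per selected feature
    n_mec = round(cfg.mec_rate * n)
    mec_features = rng.choice(n, size=n_mec, replace=False)
    mec_treatment = rng.choice(list(("SL",) + TREATED), size=n_mec)
    tcols = {t: g["sample_id"].tolist()
             for t, g in design.table.groupby("treatment")}
    mec_label = np.full(n, "", dtype=object)
    for fi, tr in zip(mec_features, mec_treatment):
        mec_label[fi] = tr
        for c in tcols[tr]:
            mar_mask[fi, values.columns.get_loc(c)] = True
    masked = values.mask(pd.DataFrame(mar_mask, index=values.index,
                                      columns=values.columns))

    # repair features that lost every observation
    sample_treatment = design.table.set_index("sample_id")["treatment"]
    empty = masked.isna().all(axis=1)
    for fid in masked.index[empty]:
        label = mec_label[values.index.get_loc(fid)]
        candidates = [c for c in values.columns if sample_treatment[c] != label]
        col = candidates[int(rng.integers(len(candidates)))]
        masked.loc[fid, col] = values.loc[fid, col]
        logger.info("restored one observation for fully-masked feature %s", fid)

    plant["mec_treatment"] = mec_label
    truth.metabolites = plant
    return ExpressionMatrix(masked, design, "metabolite"), truth
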