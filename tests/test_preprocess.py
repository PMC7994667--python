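import numpy as np
import pandas as pd
import pytest

from naiveomics.io_formats import ExpressionMatrix, SampleDesign
from naiveomics.preprocess import (batch_adjust_eb, collapse_and_zscore,
                                   cyclic_loess_normalize, pca_scores,
                                   ratios_vs_reference)
from tests.conftest import make_matrix


def two_sample_design(n_plex=1):
    rows = []
    for c in range(1, n_plex + 1):
        rows.append((f"a{c}", f"CL{c}", "SL", 0.0, f"p{c}", 1))
        rows.append((f"b{c}", f"CL{c}", "2i", 1.0, f"p{c}", 1))
    return SampleDesign(pd.DataFrame(rows, columns=[
        "sample_id", "cell_line", "treatment", "timepoint", "plex", "replicate"]))


class TestCyclicLoess:
    def test_identical_samples_unchanged(self):
        rng = np.random.default_rng(0)
        x = rng.normal(25, 2, size=2000)
        m = make_matrix(two_sample_design(), np.column_stack([x, x]))
        out = cyclic_loess_normalize(m)
        assert np.allclose(out.values, m.values, atol=1e-9)

    def test_constant_offset_removed(self):
        rng = np.random.default_rng(1)
        a = rng.normal(25, 2, size=2000)
        m = make_matrix(two_sample_design(), np.column_stack([a, a + 0.8]))
        out = cyclic_loess_normalize(m)
        diff = out.values.iloc[:, 1] - out.values.iloc[:, 0]
        assert abs(np.median(diff)) < 0.01

    def test_intensity_dependent_bias_removed_in_every_decile(self):
        rng = np.random.default_rng(2)
        a = rng.normal(25, 2, size=4000)
        scaled = (a - a.mean()) / a.std()
        b = a + 0.5 * np.sin(scaled)
        m = make_matrix(two_sample_design(), np.column_stack([a, b]))
        out = cyclic_loess_normalize(m)
        mm = (out.values.iloc[:, 1] - out.values.iloc[:, 0]).to_numpy()
        aa = ((out.values.iloc[:, 1] + out.values.iloc[:, 0]) / 2).to_numpy()
        deciles = np.quantile(aa, np.linspace(0, 1, 11))
        for lo, hi in zip(deciles[:-1], deciles[1:]):
            sel = (aa >= lo) & (aa <= hi)
            assert abs(np.median(mm[sel])) < 0.05

    def test_grand_mean_preserved_per_plex(self):
        rng = np.random.default_rng(3)
        x = rng.normal(25, 2, size=(1000, 2))
        x[:, 1] += 0.6
        m = make_matrix(two_sample_design(), x)
        out = cyclic_loess_normalize(m)
        assert out.values.to_numpy().mean() == pytest.approx(x.mean(), abs=1e-6)

    def test_single_sample_plex_left_unchanged(self, caplog):
        rows = [("only", "CL1", "SL", 0.0, "p1", 1)]
        d = SampleDesign(pd.DataFrame(rows, columns=[
            "sample_id", "cell_line", "treatment", "timepoint", "plex", "replicate"]))
        m = make_matrix(d, np.arange(50.0).reshape(-1, 1))
        out = cyclic_loess_normalize(m)
        assert out.values.equals(m.values)


def batch_design():
    rows = []
    for c, plex in ((1, "p1"), (2, "p2")):
        for t, tp in (("SL", 0.0), ("2i", 1.0), ("2i", 2.0), ("Cdk8i", 1.0)):
            rows.append((f"CL{c}_{t}_{tp}", f"CL{c}", t, tp, plex, 1))
    return SampleDesign(pd.DataFrame(rows, columns=[
        "sample_id", "cell_line", "treatment", "timepoint", "plex", "replicate"]))


class TestBatchAdjust:
    def test_single_batch_is_identity(self):
        d = two_sample_design()
        m = make_matrix(d, np.random.default_rng(0).normal(25, 2, size=(200, 2)))
        out = batch_adjust_eb(m)
        assert np.allclose(out.values, m.values, atol=1e-9)

    def test_planted_location_shift_removed(self):
        rng = np.random.default_rng(1)
        d = batch_design()
        base = rng.normal(25, 2, size=(500, 1))
        x = base + rng.normal(0, 0.3, size=(500, 8))
        x[:, 4:] += 2.0  # batch 2 shifted
        out = batch_adjust_eb(make_matrix(d, x))
        gap = out.values.iloc[:, 4:].mean(axis=1) - out.values.iloc[:, :4].mean(axis=1)
        assert abs(gap.mean()) < 0.05          # the planted shift is gone
        assert gap.abs().mean() < 0.25         # residual is noise-sized, not 2

    def test_treatment_effect_preserved_through_adjustment(self):
        rng = np.random.default_rng(2)
        d = batch_design()
        x = rng.normal(25, 0.3, size=(800, 8))
        treated = [i for i, t in enumerate(d.table["treatment"]) if t == "2i"]
        x[:, treated] += 1.0                     # true effect
        batch2 = [i for i, p in enumerate(d.table["plex"]) if p == "p2"]
        x[:, batch2] += 2.0                      # confounding shift
        out = batch_adjust_eb(make_matrix(d, x))
        sl = [i for i, t in enumerate(d.table["treatment"]) if t == "SL"]
        est = (out.values.iloc[:, treated].mean(axis=1)
               - out.values.iloc[:, sl].mean(axis=1)).mean()
        assert est == pytest.approx(1.0, rel=0.1)

    def test_idempotent_in_distribution(self):
        # strong feature-specific batch effects relative to noise: the first
        # pass removes them; a second pass finds no excess dispersion and is
        # a near no-op
        rng = np.random.default_rng(3)
        d = batch_design()
        x = rng.normal(25, 0.1, size=(400, 8))
        x[:, 4:] += rng.normal(0, 2.0, size=(400, 1))
        once = batch_adjust_eb(make_matrix(d, x))
        twice = batch_adjust_eb(once)
        delta = np.abs(twice.values.to_numpy() - once.values.to_numpy()).mean()
        assert delta < 1e-3

    def test_confounded_batch_rejected_with_name(self):
        from naiveomics.io_formats import ExpressionMatrix
        from naiveomics.preprocess import SampleDesignView
        rows = [("a", "CL1", "SL", 0.0, "p1", 1), ("b", "CL1", "SL", 0.0, "p1", 2),
                ("d", "CL2", "2i", 2.0, "p2", 1), ("e", "CL2", "2i", 2.0, "p2", 2)]
        view = SampleDesignView(pd.DataFrame(rows, columns=[
            "sample_id", "cell_line", "treatment", "timepoint", "plex", "replicate"]))
        values = pd.DataFrame(np.random.default_rng(0).normal(size=(50, 4)),
                              index=[f"F{i}" for i in range(50)],
                              columns=view.sample_ids)
        m = ExpressionMatrix(values, view, "protein")
        with pytest.raises(ValueError, match="confounded"):
            batch_adjust_eb(m)


class TestRatios:
    def test_subtracts_mean_of_reference_channels(self):
        rows = [("r1", "CL1", "SL", 0.0, "p1", 1), ("r2", "CL1", "SL", 0.0, "p1", 2),
                ("t1", "CL1", "2i", 1.0, "p1", 1)]
        d = SampleDesign(pd.DataFrame(rows, columns=[
            "sample_id", "cell_line", "treatment", "timepoint", "plex", "replicate"]))
        m = make_matrix(d, np.array([[24.0, 26.0, 26.0]]))
        out = ratios_vs_reference(m)
        assert out.values.loc["F0", "t1"] == pytest.approx(1.0)   # 26 - mean(24,26)
        assert out.values.loc["F0", ["r1", "r2"]].mean() == pytest.approx(0.0)

    def test_missing_reference_is_an_error(self, tiny_design):
        from naiveomics.io_formats import ExpressionMatrix
        from naiveomics.preprocess import SampleDesignView
        view = SampleDesignView(
            tiny_design.table[tiny_design.table["sample_id"] != "CL1_SL"])
        values = pd.DataFrame(np.zeros((3, 5)), index=["A", "B", "C"],
                              columns=view.sample_ids)
        with pytest.raises(ValueError, match="lacks"):
            ratios_vs_reference(ExpressionMatrix(values, view, "protein"))


def trajectory_design():
    rows = []
    for c in (1, 2):
        rows.append((f"CL{c}_SL", f"CL{c}", "SL", 0.0, f"p{c}", 1))
        for t in (1.0, 2.0, 4.0):
            rows.append((f"CL{c}_2i_{t:g}", f"CL{c}", "2i", t, f"p{c}", 1))
            rows.append((f"CL{c}_C_{t:g}", f"CL{c}", "Cdk8i", t, f"p{c}", 1))
    return SampleDesign(pd.DataFrame(rows, columns=[
        "sample_id", "cell_line", "treatment", "timepoint", "plex", "replicate"]))


class TestCollapseZscore:
    def _matrix(self, per_sample):
        d = trajectory_design()
        vals = np.array([[per_sample[s] for s in d.sample_ids]])
        return make_matrix(d, vals)

    def test_linear_trajectory_zscores_to_unit_steps(self):
        d = trajectory_design()
        vals = {s: 0.0 for s in d.sample_ids}
        for c in (1, 2):
            for v, t in ((1.0, 1.0), (2.0, 2.0), (3.0, 4.0)):
                vals[f"CL{c}_2i_{t:g}"] = v
                vals[f"CL{c}_C_{t:g}"] = v
        tm = collapse_and_zscore(self._matrix(vals), mode="per_treatment")
        assert np.allclose(tm.treatment_block("2i").iloc[0], [-1, 0, 1])

    def test_constant_trajectory_maps_to_zeros(self):
        d = trajectory_design()
        vals = {s: 2.0 for s in d.sample_ids}
        tm = collapse_and_zscore(self._matrix(vals), mode="per_treatment")
        assert np.allclose(tm.data.iloc[0], 0.0)

    def test_replicates_averaged_before_zscoring(self):
        d = trajectory_design()
        vals = {s: 0.0 for s in d.sample_ids}
        # cell lines disagree (1 vs 3) at t=1: mean 2 should be used
        vals["CL1_2i_1"] = 1.0
        vals["CL2_2i_1"] = 3.0
        vals["CL1_2i_2"] = vals["CL2_2i_2"] = 3.0
        vals["CL1_2i_4"] = vals["CL2_2i_4"] = 4.0
        tm = collapse_and_zscore(self._matrix(vals), mode="per_treatment")
        row = tm.treatment_block("2i").iloc[0].to_numpy()
        collapsed = np.array([2.0, 3.0, 4.0])
        expected = (collapsed - collapsed.mean()) / collapsed.std(ddof=1)
        assert np.allclose(row, expected)

    def test_zscore_invariant_holds_exactly(self, small_study):
        proteome, _, _ = small_study
        ratios = ratios_vs_reference(proteome)
        tm = collapse_and_zscore(ratios, mode="per_treatment")
        for treatment in tm.treatments:
            block = tm.treatment_block(treatment)
            nondeg = block.std(axis=1, ddof=1) > 0
            assert np.allclose(block[nondeg].mean(axis=1), 0, atol=1e-12)
            assert np.allclose(block[nondeg].std(axis=1, ddof=1), 1, atol=1e-12)


class TestPca:
    def test_rank_one_matrix_explained_by_first_component(self, tiny_design):
        u = np.arange(1, 7, dtype=float)
        v = np.array([1.0, 2.0, 3.0])
        m = make_matrix(tiny_design, np.outer(v, u))
        scores, frac = pca_scores(m, n_components=2)
        assert frac[0] == pytest.approx(1.0)

    def test_two_group_shift_separates_on_pc1(self, tiny_design):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 0.1, size=(100, 6))
        x[:, 3:] += 5.0
        scores, _ = pca_scores(make_matrix(tiny_design, x), n_components=1)
        signs = np.sign(scores["PC1"].to_numpy())
        assert len(set(signs[:3])) == 1 and len(set(signs[3:])) == 1
        assert signs[0] != signs[3]

    def test_duplicate_samples_have_identical_scores(self, tiny_design):
        rng = np.random.default_rng(1)
        col = rng.normal(size=50)
        x = np.column_stack([col] * 3 + [col + 1] * 3)
        scores, _ = pca_scores(make_matrix(tiny_design, x), n_components=2)
        assert np.allclose(scores.iloc[0], scores.iloc[1], atol=1e-9)

    def test_missing_values_direct_to_imputation(self, tiny_design):
        x = np.zeros((5, 6))
        x[0, 0] = np.nan
        with pytest.raises(ValueError, match="impute"):
            pca_scores(make_matrix(tiny_design, x))
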