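import numpy as np
import pandas as pd
import pytest
from scipy import stats

from naiveomics.phospho import PRIMING_OFFSET, annotate_gsk3_motif
from naiveomics.synthetic_data import (SimulationConfig, simulate_metabolome,
                                       simulate_phospho_layer, simulate_study)


def cfg(**kw):
    base = dict(seed=1, n_proteins=80, n_phosphosites=200, n_metabolites=60,
                n_posttx=5, n_gsk3_substrates=8)
    base.update(kw)
    return SimulationConfig(**base)


class TestConfigValidation:
    def test_fraction_sum_above_one_rejected(self):
        with pytest.raises(ValueError):
            cfg(frac_shared_up=0.5, frac_shared_down=0.4, frac_specific=0.2)

    def test_substrate_pairs_must_fit(self):
        with pytest.raises(ValueError):
            simulate_phospho_layer(cfg(n_phosphosites=10, n_gsk3_substrates=8),
                                   simulate_study(cfg())[2])


class TestDeterminism:
    def test_fixed_seed_reproduces_every_layer(self):
        c = cfg()
        a_p, a_m, a_t = simulate_study(c)
        b_p, b_m, b_t = simulate_study(c)
        assert a_p.values.equals(b_p.values)
        assert a_m.values.equals(b_m.values)
        assert a_t.proteins.equals(b_t.proteins)
        pa, _ = simulate_phospho_layer(c, a_t)
        pb, _ = simulate_phospho_layer(c, b_t)
        assert pa.table.equals(pb.table)
        ma, _ = simulate_metabolome(c)
        mb, _ = simulate_metabolome(c)
        assert ma.values.equals(mb.values)

    def test_layer_streams_independent(self):
        # generating (or not) the phospho layer must not perturb the metabolome
        c = cfg()
        _, _, t = simulate_study(c)
        m_before, _ = simulate_metabolome(c)
        simulate_phospho_layer(c, t)
        m_after, _ = simulate_metabolome(c)
        assert m_before.values.equals(m_after.values)


class TestProteomeLayer:
    def test_no_planted_fractions_no_differential_labels(self):
        c = cfg(frac_shared_up=0.0, frac_shared_down=0.0, frac_specific=0.0,
                n_posttx=0)
        _, _, truth = simulate_study(c)
        assert (truth.proteins[["dir_2i", "dir_Cdk8i"]] == 0).all().all()
        assert (truth.proteins["amplitude"] == 0).all()

    def test_truth_labels_cover_generated_features(self):
        prot, mrna, truth = simulate_study(cfg())
        assert list(truth.proteins.index) == prot.feature_ids
        assert prot.feature_ids == mrna.feature_ids

    def test_planted_effect_detectable_at_peak(self):
        # +1 log2 peak effect, 0.2 noise, 4 cell lines: day-14 one-sample t
        # rejects essentially always (direct Monte-Carlo oracle of the test)
        hits = attempts = 0
        for seed in range(60):
            c = cfg(seed=seed, n_proteins=100, noise_sd=0.2, n_posttx=0,
                    frac_shared_up=0.2, frac_shared_down=0.0, frac_specific=0.0)
            prot, _, truth = simulate_study(c)
            up = truth.proteins.index[(truth.proteins["dir_2i"] > 0)
                                      & (truth.proteins["module"] == 0)
                                      & (truth.proteins["amplitude"] >= 1.0)]
            if not len(up):
                continue
            attempts += 1
            fid = up[0]
            design = prot.design.table
            ratios = []
            for cl, grp in design.groupby("cell_line"):
                t_col = grp.loc[(grp["treatment"] == "2i")
                                & (grp["timepoint"] == 14.0), "sample_id"].iloc[0]
                refs = grp.loc[grp["treatment"] == "SL", "sample_id"]
                ratios.append(prot.values.loc[fid, t_col]
                              - prot.values.loc[fid, refs].mean())
            hits += stats.ttest_1samp(ratios, 0).pvalue < 0.05
        assert attempts >= 40
        assert hits / attempts >= 0.95

    def test_mrna_effect_zero_only_for_posttx_features(self):
        c = cfg(n_proteins=300, n_posttx=20, noise_sd=0.1)
        _, mrna, truth = simulate_study(c)
        design = mrna.design.table
        cols = design.loc[(design["treatment"] == "2i")
                          & (design["timepoint"] == 14.0), "sample_id"]
        mono = truth.proteins["module"] == 0
        posttx = truth.proteins["posttx"] & (truth.proteins["dir_2i"] != 0) & mono
        planted = (~truth.proteins["posttx"]) & (truth.proteins["dir_2i"] != 0) & mono
        # amplitudes are at least 4 x noise_sd = 0.4; the replicate mean has
        # se ~ 0.06, so 0.2 cleanly separates zero from planted mRNA effects
        if posttx.any():
            assert mrna.values.loc[posttx, cols].mean(axis=1).abs().max() < 0.2
        if planted.any():
            assert mrna.values.loc[planted, cols].mean(axis=1).abs().min() > 0.2


class TestPhosphoLayer:
    def test_substrate_windows_carry_the_priming_pair(self):
        c = cfg()
        _, _, truth = simulate_study(c)
        ph, truth = simulate_phospho_layer(c, truth)
        flags = annotate_gsk3_motif(ph)
        di = truth.phospho["role"] == "substrate_di"
        assert flags[di.to_numpy()].all()
        # every substrate has a mono row at position + 4
        for sid in truth.phospho.index[di]:
            row = truth.phospho.loc[sid]
            mono = truth.phospho[(truth.phospho["protein"] == row["protein"])
                                 & (truth.phospho["position"] == row["position"] + PRIMING_OFFSET)
                                 & (truth.phospho["multiplicity"] == 1)]
            assert len(mono) == 1

    def test_no_substrates_means_no_coordinated_pattern(self):
        c = cfg(n_gsk3_substrates=0)
        _, _, truth = simulate_study(c)
        ph, truth = simulate_phospho_layer(c, truth)
        assert not truth.phospho["substrate"].any()

    def test_configured_fraction_falls_below_class1_cutoff(self):
        c = cfg(n_phosphosites=2000, n_gsk3_substrates=0, frac_low_localization=0.2)
        _, _, truth = simulate_study(c)
        ph, _ = simulate_phospho_layer(c, truth)
        frac = (ph.table["localization_prob"] < 0.75).mean()
        assert frac == pytest.approx(0.2, abs=0.05)


class TestMetabolomeLayer:
    def test_no_missingness_gives_complete_matrix(self):
        m, _ = simulate_metabolome(cfg(mar_rate=0.0, mec_rate=0.0))
        assert not m.values.isna().any().any()

    def test_mec_feature_missing_exactly_its_treatment_block(self):
        c = cfg(seed=4, mar_rate=0.0, mec_rate=0.1)
        m, truth = simulate_metabolome(c)
        design = m.design.table
        planted = truth.metabolites[truth.metabolites["mec_treatment"] != ""]
        assert len(planted)
        for fid, row in planted.iterrows():
            block = design.loc[design["treatment"] == row["mec_treatment"], "sample_id"]
            assert m.values.loc[fid, block].isna().all()
            others = design.loc[design["treatment"] != row["mec_treatment"], "sample_id"]
            assert m.values.loc[fid, others].notna().all()

    def test_observed_missing_fraction_tracks_mar_rate(self):
        fracs = []
        for seed in range(30):
            c = cfg(seed=seed, n_metabolites=200, mar_rate=0.05, mec_rate=0.0)
            m, _ = simulate_metabolome(c)
            fracs.append(m.values.isna().to_numpy().mean())
        assert np.mean(fracs) == pytest.approx(0.05, abs=0.02)

    def test_every_feature_keeps_at_least_one_observation(self):
        c = cfg(seed=2, mar_rate=0.4, mec_rate=0.2)
        m, _ = simulate_metabolome(c)
        assert (m.values.notna().sum(axis=1) >= 1).all()
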