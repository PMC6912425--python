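import numpy as np
import pandas as pd
import pytest

from autoreg.errors import CapacityError, ValidationError
from autoreg.simulate import (GROUPS, SimConfig, generate_annotation,
                              generate_gene_sets, generate_knockdown_counts,
                              generate_peak_counts, generate_timecourse_counts)
from autoreg.staging import assign_stage


class TestAnnotation:
    def test_single_gene_fits(self):
        ann = generate_annotation(1, chrom_length=10000, seed=1)
        assert len(ann) == 1
        assert 0 <= ann.iloc[0]["tss"] < 10000

    def test_determinism(self):
        a = generate_annotation(100, seed=7)
        b = generate_annotation(100, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_minus_strand_tss_is_end(self):
        ann = generate_annotation(50, seed=2)
        minus = ann[ann["strand"] == "-"]
        assert (minus["tss"] == minus["end"]).all()
        plus = ann[ann["strand"] == "+"]
        assert (plus["tss"] == plus["start"]).all()

    def test_capacity_error(self):
        with pytest.raises(CapacityError):
            generate_annotation(1, chrom_length=2000, seed=0)

    def test_no_overlap_and_spacing(self):
        ann = generate_annotation(200, seed=3)
        for _, sub in ann.groupby("chrom"):
            s = sub.sort_values("start")
            assert (s["start"].to_numpy()[1:] >= s["end"].to_numpy()[:-1]).all()
            # promoter windows never overlap: TSS spacing > 6 kb
            assert np.diff(np.sort(s["tss"])).min() > 6000

    def test_utrs_within_gene_span(self):
        ann = generate_annotation(60, seed=4)
        assert (ann["utr5_start"] >= ann["start"]).all()
        assert (ann["utr3_end"] <= ann["end"]).all()


class TestConfigValidation:
    def test_bad_frac_null(self):
        with pytest.raises(ValidationError):
            SimConfig(frac_null=1.5)

    def test_bad_samples_per_stage(self):
        with pytest.raises(ValidationError):
            SimConfig(samples_per_stage=2)

    def test_time_point_stage_consistency(self):
        with pytest.raises(ValidationError):
            SimConfig(time_points_h={"non": (4.0,), "early": (24.0,),
                                     "late": (96.0,)})


class TestTimecourse:
    def test_determinism(self, small_cfg):
        a, _, _ = generate_timecourse_counts(small_cfg)
        b, _, _ = generate_timecourse_counts(small_cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_pure_null_truth_all_zero(self):
        cfg = SimConfig(n_genes=100, n_autophagy=20, frac_null=1.0, seed=0)
        _, _, truth = generate_timecourse_counts(cfg)
        assert (truth.genes["lfc_early"] == 0).all()
        assert (truth.genes["lfc_late"] == 0).all()
        assert not truth.true_links()

    def test_sample_table_consistent(self, small_dataset):
        samples = small_dataset["samples"]
        for _, row in samples.iterrows():
            assert assign_stage(row["time_h"]) == row["stage"]

    def test_truth_labels_closed_vocabulary(self, small_dataset):
        truth = small_dataset["truth"]
        assert set(truth.genes["group"]) <= set(GROUPS)
        assert not truth.genes["gene_id"].duplicated().any()

    def test_planted_lfc_mean_ratio(self):
        # one planted gene at log2FC=2 early vs non; empirical mean ratio
        # averaged over replicate seeds approaches 2^2 = 4
        ratios = []
        for seed in range(100):
            cfg = SimConfig(n_genes=30, n_autophagy=4, n_autophagy_tf=2,
                            n_lipogenic=2, n_factors=1, n_direct_targets=0,
                            tf_regulon_size=0, coexpr_sd=0.0, seed=seed,
                            effect_table={
                                "adipogenic_tf": {"early": 2.0, "late": 2.0},
                                "autophagy_tf": {"early": 0.0, "late": 0.0},
                                "autophagy_up": {"early": 0.0, "late": 0.0},
                                "autophagy_down": {"early": 0.0, "late": 0.0},
                                "lipogenic": {"early": 0.0, "late": 0.0}},
                            frac_null=0.5)
            cm, st, truth = generate_timecourse_counts(cfg)
            factor = truth.factors[0]
            by = st.set_index("sample_id")["stage"]
            early = [s for s in cm.columns if by[s] == "early"]
            non = [s for s in cm.columns if by[s] == "non"]
            ratios.append(cm.loc[factor, early].mean() / cm.loc[factor, non].mean())
        assert 3.0 <= np.mean(ratios) <= 5.3

    def test_mean_variance_law(self):
        # pooled within-group variance ~ mu + alpha mu^2 over replicates
        alpha, mu_target = 0.2, 200.0
        means, varis = [], []
        for seed in range(100):
            cfg = SimConfig(n_genes=20, n_autophagy=2, n_autophagy_tf=2,
                            n_lipogenic=2, frac_null=1.0, dispersion=alpha,
                            baseline_mean=mu_target, baseline_log2_sd=0.0,
                            samples_per_stage=8, seed=seed, coexpr_sd=0.0)
            cm, st, _ = generate_timecourse_counts(cfg)
            by = st.set_index("sample_id")["stage"]
            cols = [s for s in cm.columns if by[s] == "non"]
            # undo the planted per-sample size factors via column means
            norm = cm[cols] / (cm[cols].mean(axis=0) / cm[cols].mean(axis=0).mean())
            means.append(norm.mean(axis=1).to_numpy())
            varis.append(norm.var(axis=1, ddof=1).to_numpy())
        mu = np.concatenate(means).mean()
        var = np.concatenate(varis).mean()
        expected = mu + alpha * mu**2
        assert var == pytest.approx(expected, rel=0.3)


class TestPeaks:
    def test_planted_targets_have_promoter_peak(self, small_dataset):
        truth, ann = small_dataset["truth"], small_dataset["ann"]
        peaks = small_dataset["peaks"]
        tss = ann.set_index("gene_id")["tss"]
        eff = truth.peak_effects
        half = small_dataset["cfg"].promoter_halfwidth_bp
        for factor, targets in truth.direct_targets.items():
            for target in targets:
                rows = eff[(eff["factor"] == factor) & (eff["gene"] == target)
                           & eff["is_target"]]
                assert len(rows) >= 1
                peak = peaks.set_index("peak_id").loc[rows.iloc[0]["peak_id"]]
                mid = (peak["start"] + peak["end"]) // 2
                assert abs(mid - tss[target]) <= half

    def test_zero_target_factor_has_null_promoter_effects(self):
        cfg = SimConfig(n_genes=100, n_autophagy=10, n_direct_targets=0,
                        tf_regulon_size=0, seed=5)
        cm, st, truth = generate_timecourse_counts(cfg)
        # only auto/feedback links remain planted; drop them too
        truth.direct_targets = {f: {} for f in truth.factors}
        ann = generate_annotation(cfg.n_genes, seed=5)
        peaks, pc, truth, cs = generate_peak_counts(cfg, ann, truth)
        eff = truth.peak_effects
        assert (eff.loc[~eff["is_target"], ["lfc_early", "lfc_late"]] == 0).all().all()
        assert not eff["is_target"].any()

    def test_determinism(self, small_cfg, small_dataset):
        peaks2, pc2, _, _ = generate_peak_counts(
            small_cfg, small_dataset["ann"], small_dataset["truth"])
        pd.testing.assert_frame_equal(pc2, small_dataset["peak_counts"])


class TestKnockdown:
    def test_unknown_factor_rejected(self, small_cfg, small_dataset):
        with pytest.raises(ValidationError):
            generate_knockdown_counts(small_cfg, small_dataset["truth"], "g99999")

    def test_determinism(self, small_cfg, small_dataset):
        f = small_dataset["truth"].factors[0]
        a, _ = generate_knockdown_counts(small_cfg, small_dataset["truth"], f)
        b, _ = generate_knockdown_counts(small_cfg, small_dataset["truth"], f)
        pd.testing.assert_frame_equal(a, b)

    def test_zero_strength_arms_match_in_distribution(self, small_dataset):
        import dataclasses
        cfg = dataclasses.replace(small_dataset["cfg"], kd_strength=0.0,
                                  kd_target_effect=0.0)
        truth = small_dataset["truth"]
        factor = truth.factors[0]
        cm, st = generate_knockdown_counts(cfg, truth, factor)
        by = st.set_index("sample_id")["arm"]
        kd = [s for s in cm.columns if by[s] == "knockdown"]
        ctrl = [s for s in cm.columns if by[s] == "control"]
        # same generating distribution: per-gene mean log-ratios center on 0
        lr = np.log2(cm[kd].mean(axis=1) + 1) - np.log2(cm[ctrl].mean(axis=1) + 1)
        assert abs(lr.mean()) < 0.2

    def test_kd_strength_recovered_end_to_end(self, small_cfg, small_dataset):
        from autoreg.diffexp import kd_contrasts
        truth = small_dataset["truth"]
        factor = truth.factors[0]
        cm, st = generate_knockdown_counts(small_cfg, truth, factor)
        res = kd_contrasts(cm, st)
        own = res[res["feature_id"] == factor]["log2fc"]
        assert -2.6 <= own.mean() <= -1.4  # kd_strength = 2


class TestGeneSets:
    def test_label_count_conservation(self):
        cfg = SimConfig(n_genes=1000, n_autophagy=152, n_autophagy_tf=6, seed=0)
        _, _, truth = generate_timecourse_counts(cfg)
        sets = generate_gene_sets(truth)
        # autophagy set = autophagy genes plus the 6 autophagy TFs
        assert len(sets["autophagy"]) == 158
        assert len(sets["autophagy_tf"]) == 6

    def test_intersection_defines_autophagy_tf(self, small_dataset):
        sets = generate_gene_sets(small_dataset["truth"])
        inter = set(sets["autophagy"]) & set(sets["transcription_factor"])
        assert inter == set(sets["autophagy_tf"])

    def test_empty_group_omitted_with_warning(self):
        cfg = SimConfig(n_genes=100, n_autophagy=10, n_lipogenic=0, seed=0)
        _, _, truth = generate_timecourse_counts(cfg)
        with pytest.warns(UserWarning, match="lipogenic"):
            sets = generate_gene_sets(truth)
        assert "lipogenic" not in sets
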