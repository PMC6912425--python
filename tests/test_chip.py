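import numpy as np
import pandas as pd
import pytest

from autoreg.chip import (annotate_peaks, assign_nearest_gene, classify_region,
                          differential_binding, occupancy_change,
                          occupancy_correlation, occupancy_matrix)
from autoreg.diffexp import DesignSpec
from autoreg.errors import ValidationError
from autoreg.simulate import generate_annotation


def _peak(chrom, start, end, pid="p1", factor="F"):
    return pd.DataFrame([{"peak_id": pid, "chrom": chrom, "start": start,
                          "end": end, "score": 0.0, "strand": ".",
                          "factor": factor}])


def _ann(rows):
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "strand", "start",
                                       "end", "tss", "utr5_start", "utr5_end",
                                       "utr3_start", "utr3_end"])


SIMPLE_ANN = _ann([
    ("gA", "chr1", "+", 10000, 12000, 10000, 10000, 10200, 11700, 12000),
    ("gB", "chr1", "-", 30000, 33000, 33000, 32800, 33000, 30000, 30300),
])


class TestNearestGene:
    def test_midpoint_at_tss(self):
        out = assign_nearest_gene(_peak("chr1", 9900, 10100), SIMPLE_ANN)
        assert out.iloc[0]["assigned_gene"] == "gA"
        assert out.iloc[0]["distance_to_tss"] == 0

    def test_upstream_plus_strand_negative(self):
        out = assign_nearest_gene(_peak("chr1", 8900, 9100), SIMPLE_ANN)
        assert out.iloc[0]["distance_to_tss"] == -1000

    def test_upstream_minus_strand_negative(self):
        # midpoint 1000 bp beyond the - strand TSS (genomically right)
        out = assign_nearest_gene(_peak("chr1", 33900, 34100), SIMPLE_ANN)
        assert out.iloc[0]["assigned_gene"] == "gB"
        assert out.iloc[0]["distance_to_tss"] == -1000

    def test_unassigned_chromosome(self):
        out = assign_nearest_gene(_peak("chrX", 100, 200), SIMPLE_ANN)
        assert out.iloc[0]["assigned_gene"] == ""
        assert np.isnan(out.iloc[0]["distance_to_tss"])

    def test_tie_broken_by_gene_id(self):
        ann = _ann([
            ("gB", "chr1", "+", 2000, 3000, 2000, 2000, 2200, 2700, 3000),
            ("gA", "chr1", "+", 0, 1000, 0, 0, 200, 700, 1000),
        ])
        out = assign_nearest_gene(_peak("chr1", 900, 1100), ann)  # mid 1000
        assert out.iloc[0]["assigned_gene"] == "gA"

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        ann = generate_annotation(80, seed=3)
        chrom = ann["chrom"].iloc[0]
        on_chrom = ann[ann["chrom"] == chrom]
        lo, hi = int(on_chrom["start"].min()), int(on_chrom["end"].max())
        starts = rng.integers(lo, hi, size=200)
        peaks = pd.DataFrame({
            "peak_id": [f"p{i}" for i in range(200)], "chrom": chrom,
            "start": starts, "end": starts + 200, "score": 0.0, "strand": ".",
            "factor": "F"})
        out = assign_nearest_gene(peaks, ann)
        for _, row in out.iterrows():
            mid = (row["start"] + row["end"]) // 2
            dists = (on_chrom["tss"] - mid).abs()
            best = dists.min()
            candidates = sorted(on_chrom.loc[dists == best, "gene_id"])
            assert row["assigned_gene"] == candidates[0]
            assert abs(row["distance_to_tss"]) == best


class TestRegion:
    @pytest.mark.parametrize("offset,expected", [
        (2999, "Promoter"),
        (-2999, "Promoter"),   # symmetric in distance sign
        (3000, "Promoter"),
        (3301, "other"),
    ])
    def test_promoter_boundary(self, offset, expected):
        mid = 10000 + offset
        out = annotate_peaks(_peak("chr1", mid - 100, mid + 100), SIMPLE_ANN)
        assert out.iloc[0]["region"] == expected

    def test_promoter_takes_precedence_over_utr5(self):
        # midpoint inside gA's 5'UTR and inside the promoter window
        out = annotate_peaks(_peak("chr1", 10000, 10200), SIMPLE_ANN)
        assert out.iloc[0]["region"] == "Promoter"

    def test_utr3_detected_outside_promoter(self):
        ann = _ann([("gL", "chr1", "+", 0, 10000, 0, 0, 200, 9700, 10000)])
        out = annotate_peaks(_peak("chr1", 9700, 9900), ann)  # mid 9800
        assert out.iloc[0]["region"] == "3UTR"

    def test_utr5_detected_outside_promoter(self):
        ann = _ann([("gL", "chr1", "+", 0, 20000, 0, 3500, 8000, 19700, 20000)])
        out = annotate_peaks(_peak("chr1", 5000, 5200), ann)
        assert out.iloc[0]["region"] == "5UTR"


class TestOccupancy:
    @staticmethod
    def _annotated():
        peaks = pd.concat([
            _peak("chr1", 0, 100, "p1"), _peak("chr1", 100, 200, "p2"),
            _peak("chr1", 200, 300, "p3"), _peak("chr1", 300, 400, "p4"),
        ], ignore_index=True)
        peaks["assigned_gene"] = ["gA", "gA", "gB", "gB"]
        peaks["region"] = ["Promoter", "other", "Promoter", "3UTR"]
        return peaks

    def test_manual_aggregation_oracle(self):
        peaks = self._annotated()
        pc = pd.DataFrame([[4, 8], [6, 2], [10, 10], [0, 4]],
                          index=pd.Index(["p1", "p2", "p3", "p4"]),
                          columns=["s1", "s2"])
        sf = pd.Series([1.0, 2.0], index=["s1", "s2"])
        occ = occupancy_matrix(pc, peaks, group_by="gene", sf=sf)
        assert occ.loc["gA", "s1"] == pytest.approx(10.0)   # (4+6)/1
        assert occ.loc["gA", "s2"] == pytest.approx(5.0)    # (8+2)/2
        assert occ.loc["gB", "s2"] == pytest.approx(7.0)

    def test_region_sums_equal_gene_totals(self):
        peaks = self._annotated()
        rng = np.random.default_rng(1)
        pc = pd.DataFrame(rng.integers(0, 100, size=(4, 3)),
                          index=pd.Index(["p1", "p2", "p3", "p4"]),
                          columns=["s1", "s2", "s3"])
        total = occupancy_matrix(pc, peaks, group_by="gene")
        split = occupancy_matrix(pc, peaks, group_by="gene_region")
        recon = split.groupby(level="gene_id").sum()
        pd.testing.assert_frame_equal(recon, total, check_like=True)

    def test_unknown_peak_id_rejected(self):
        peaks = self._annotated()
        pc = pd.DataFrame([[1, 1]], index=pd.Index(["p9"]), columns=["s1", "s2"])
        with pytest.raises(ValidationError, match="missing"):
            occupancy_matrix(pc, peaks)


class TestOccupancyCorrelation:
    def test_self_and_scaled(self):
        rng = np.random.default_rng(2)
        base = rng.integers(1, 200, size=10).astype(float)
        occ = pd.DataFrame({"s1": base, "s2": base * 2})
        corr = occupancy_correlation(occ)
        assert corr.loc["s1", "s1"] == pytest.approx(1.0)
        # doubling is not affine in log2(x+1) space, but nearly so at
        # moderate occupancy
        assert corr.loc["s1", "s2"] > 0.99

    def test_zero_variance_sample_is_nan(self):
        occ = pd.DataFrame({"s1": [1.0, 2, 3], "s2": [5.0, 5, 5]})
        corr = occupancy_correlation(occ)
        assert np.isnan(corr.loc["s2", "s1"]) and np.isnan(corr.loc["s2", "s2"])

    def test_co_occupying_factors_correlate(self, small_dataset):
        # samples of the same factor share peak means -> high mutual PCC
        pc, cs = small_dataset["peak_counts"], small_dataset["chip_samples"]
        peaks = annotate_peaks(small_dataset["peaks"], small_dataset["ann"])
        occ = occupancy_matrix(pc, peaks)
        corr = occupancy_correlation(occ)
        idx = cs.set_index("sample_id")["target"]
        same = [corr.loc[a, b] for a in corr.index for b in corr.index
                if a < b and idx[a] == idx[b]]
        diff = [corr.loc[a, b] for a in corr.index for b in corr.index
                if a < b and idx[a] != idx[b]]
        assert np.mean(same) > np.mean(diff)


class TestOccupancyChange:
    def test_identical_means_zero(self):
        occ = pd.DataFrame({"a1": [4.0, 8], "a2": [4.0, 8],
                            "b1": [4.0, 8], "b2": [4.0, 8]})
        change = occupancy_change(occ, ["a1", "a2"], ["b1", "b2"])
        assert np.allclose(change, 0.0)

    def test_doubling_with_pseudocount(self):
        occ = pd.DataFrame({"a1": [9.0], "b1": [19.0]})
        change = occupancy_change(occ, ["a1"], ["b1"])
        assert change.iloc[0] == pytest.approx(1.0)  # log2(20/10)

    def test_missing_stage_rejected(self):
        occ = pd.DataFrame({"a1": [1.0]})
        with pytest.raises(ValidationError):
            occupancy_change(occ, ["a1"], [])


class TestDifferentialBinding:
    def test_planted_occupancy_recovered(self, small_dataset):
        truth = small_dataset["truth"]
        pc, cs = small_dataset["peak_counts"], small_dataset["chip_samples"]
        peaks = small_dataset["peaks"]
        eff = truth.peak_effects.set_index("peak_id")
        factor = truth.factors[0]
        fac_samples = cs.set_index("sample_id").query("target == @factor")
        fac_peaks = peaks.loc[peaks["factor"] == factor, "peak_id"]
        design = DesignSpec(groups=fac_samples["stage"], lfc_threshold=0.5)
        res = differential_binding(pc.loc[fac_peaks, fac_samples.index], design,
                                   contrast=("early", "non")).set_index("feature_id")
        planted = eff[(eff["factor"] == factor) & eff["is_target"]]
        err = res.loc[planted.index, "log2fc"] - planted["lfc_early"]
        assert err.abs().mean() < 0.5
        assert (res.loc[planted.index, "label"] != "none").mean() > 0.9

    def test_tau_boundary_strict(self):
        from autoreg.diffexp import classify_de
        res = pd.DataFrame({"log2fc": [0.5], "fdr": [0.1]})
        assert classify_de(res, tau=0.5)["label"].iloc[0] == "none"
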