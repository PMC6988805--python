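import numpy as np
import pandas as pd
import pytest

from methsponge import preprocess
from methsponge.types import (
    GeneAnnotation,
    MethylationProfile,
    ProbeAnnotation,
    ValidationError,
)


class TestFilterProbes:
    def test_constructed_six_probe_fixture(self, six_probe_fixture):
        profile, ann = six_probe_fixture
        out = preprocess.filter_probes(profile, ann)
        assert list(out.values.index) == ["cg4", "cg5"]

    def test_all_clean_is_identity(self, six_probe_fixture):
        profile, ann = six_probe_fixture
        clean = MethylationProfile(
            profile.values.loc[["cg4", "cg5"]], "probe", profile.groups
        ).validate()
        out = preprocess.filter_probes(clean, ann)
        pd.testing.assert_frame_equal(out.values, clean.values)

    def test_all_fail_gives_empty(self, six_probe_fixture):
        profile, ann = six_probe_fixture
        bad = MethylationProfile(
            profile.values.loc[["cg0", "cg1", "cg2", "cg3"]], "probe",
            profile.groups,
        ).validate()
        assert len(preprocess.filter_probes(bad, ann).values) == 0

    def test_unannotated_probe_is_error(self, six_probe_fixture):
        profile, ann = six_probe_fixture
        extra = profile.values.copy()
        extra.loc["cg_unknown"] = 0.5
        profile2 = MethylationProfile(extra, "probe", profile.groups).validate()
        with pytest.raises(ValidationError, match="cg_unknown"):
            preprocess.filter_probes(profile2, ann)


class TestAggregateGene:
    @pytest.mark.parametrize(
        "betas,expected",
        [([0.2, 0.4], 0.3), ([0.7], 0.7), ([0.1, 0.5, 0.9], 0.5)],
    )
    def test_mean_of_member_probes(self, betas, expected, tiny_groups):
        idx = [f"cg{i}" for i in range(len(betas))]
        values = pd.DataFrame({s: betas for s in tiny_groups.index}, index=idx)
        profile = MethylationProfile(values, "probe", tiny_groups).validate()
        ann = ProbeAnnotation(
            pd.DataFrame(
                {"chrom": "chr1", "pos": range(1, len(betas) + 1),
                 "genes": [("gZ",)] * len(betas), "snp_overlap": False},
                index=idx,
            )
        ).validate()
        out = preprocess.aggregate_gene_methylation(profile, ann)
        assert out.resolution == "gene"
        assert out.values.loc["gZ"].to_numpy() == pytest.approx(expected)


class TestPromoterWindow:
    def _setup(self, positions, strand, tss=10_000):
        samples = ["S0", "S1"]
        idx = [f"cg{i}" for i in range(len(positions))]
        betas = np.linspace(0.2, 0.8, len(positions))
        values = pd.DataFrame({s: betas for s in samples}, index=idx)
        profile = MethylationProfile(values, "probe").validate()
        ann = ProbeAnnotation(
            pd.DataFrame(
                {"chrom": "chr1", "pos": positions,
                 "genes": [("gP",)] * len(positions), "snp_overlap": False},
                index=idx,
            )
        ).validate()
        genes = GeneAnnotation(
            pd.DataFrame({"chrom": ["chr1"], "strand": [strand], "tss": [tss]},
                         index=pd.Index(["gP"], name="gene_id"))
        ).validate()
        return profile, ann, genes

    def test_plus_strand_window(self):
        profile, ann, genes = self._setup([9_000, 10_250], "+")
        out = preprocess.promoter_methylation(profile, ann, genes)
        expected = profile.values.loc[["cg0", "cg1"]].mean(axis=0)
        assert np.allclose(out.values.loc["gP"], expected)

    def test_minus_strand_upstream_included(self):
        # on the - strand, 10_800 is 800 bp upstream of TSS=10_000
        profile, ann, genes = self._setup([10_800], "-")
        out = preprocess.promoter_methylation(profile, ann, genes)
        assert "gP" in out.values.index

    @pytest.mark.parametrize(
        "pos,strand,included",
        [
            (10_500, "+", True),   # TSS+500 boundary inclusive
            (10_501, "+", False),  # one past the downstream boundary
            (8_500, "+", True),    # TSS-1500 boundary inclusive
            (8_499, "+", False),
            (9_499, "-", False),   # mirrored: downstream boundary at TSS-500
            (9_500, "-", True),
            (11_500, "-", True),   # mirrored upstream boundary
            (11_501, "-", False),
        ],
    )
    def test_window_boundaries(self, pos, strand, included):
        profile, ann, genes = self._setup([pos], strand)
        out = preprocess.promoter_methylation(profile, ann, genes)
        assert ("gP" in out.values.index) is included

    def test_strand_mirror_symmetry(self):
        """Mirroring strand and probe offsets leaves the included set unchanged."""
        tss = 10_000
        offsets = [-1_500, -700, 0, 499, 500, 501, 2_000]
        plus = self._setup([tss + o for o in offsets], "+", tss)
        minus = self._setup([tss - o for o in offsets], "-", tss)
        out_p = preprocess.promoter_methylation(*plus)
        out_m = preprocess.promoter_methylation(*minus)
        # per-probe inclusion must match, hence identical aggregated values
        pd.testing.assert_frame_equal(out_p.values, out_m.values)


class TestLogTransform:
    @pytest.mark.parametrize("raw,expected", [(0, 0), (1, 1), (7, 3)])
    def test_log2_plus_one(self, raw, expected, tiny_groups):
        values = pd.DataFrame(
            float(raw), index=["f"], columns=tiny_groups.index
        )
        from methsponge.types import ExpressionMatrix

        mat = ExpressionMatrix(values, tiny_groups).validate()
        out = preprocess.log_transform(mat)
        assert out.values.iloc[0, 0] == pytest.approx(expected)

    def test_betas_stay_in_unit_interval(self, six_probe_fixture):
        profile, ann = six_probe_fixture
        clean = preprocess.filter_probes(profile, ann)
        out = preprocess.aggregate_gene_methylation(clean, ann)
        arr = out.values.to_numpy()
        assert ((arr >= 0) & (arr <= 1)).all()
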