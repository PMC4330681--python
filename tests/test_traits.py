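import math

import numpy as np
import pandas as pd
import pytest

from traitniche import (
    InvalidRecordError,
    UndefinedTraitError,
    generate_measurement_records,
    generate_trait_targets,
)
from traitniche.synthetic import trait_table_from_records
from traitniche.traits import (
    DepthProfile,
    IntersectCount,
    LeafRecord,
    RootSampleRecord,
    compute_depth95,
    compute_fine_root_traits,
    compute_leaf_traits,
    compute_mycorrhization_rate,
    compute_rld,
    compute_taproot_traits,
    summarize_traits,
)


def leaf(area=20.0, fresh=0.5, dry=0.1):
    return LeafRecord("x", leaf_area=area, leaf_fresh_mass=fresh, leaf_dry_mass=dry)


class TestLeafTraits:
    def test_unit_conversion(self):
        sla, ldmc = compute_leaf_traits(leaf())
        assert sla == pytest.approx(20.0)  # m2.kg-1
        assert ldmc == pytest.approx(200.0)  # mg.g-1

    def test_fully_dry_leaf_hits_ldmc_ceiling(self):
        _, ldmc = compute_leaf_traits(leaf(fresh=0.1, dry=0.1))
        assert ldmc == pytest.approx(1000.0)

    @pytest.mark.parametrize("kwargs", [
        {"dry": -0.1}, {"dry": 0.0}, {"area": 0.0}, {"fresh": 0.05},
    ])
    def test_invalid_records_rejected(self, kwargs):
        with pytest.raises(InvalidRecordError):
            leaf(**kwargs)


def root_sample(classes=((0.15, 3.0), (0.35, 1.0)), dry=0.02, vol=0.1,
                p_conc=float("nan"), nodule=0.0):
    return RootSampleRecord(
        "x", length_by_diameter_class=classes,
        total_length=sum(l for _, l in classes), dry_mass=dry, volume=vol,
        p_concentration=p_conc, nodule_dry_mass=nodule,
    )


class TestFineRootTraits:
    def test_forced_arithmetic(self):
        out = compute_fine_root_traits(root_sample())
        assert out["D"] == pytest.approx(0.20)
        assert out["SRL"] == pytest.approx(200.0)
        assert out["very_fine_pct"] == pytest.approx(75.0)
        assert out["RTD"] == pytest.approx(200.0)  # 0.02 g / 0.1 cm3 in mg.cm-3

    def test_rpue_from_p_concentration(self):
        out = compute_fine_root_traits(root_sample(p_conc=2.0))
        assert out["RPUE"] == pytest.approx(100.0)

    def test_single_class_identities(self):
        out = compute_fine_root_traits(
            root_sample(classes=((0.18, 5.0),), dry=0.025))
        assert out["SRL"] == pytest.approx(5.0 / 0.025)
        assert out["D"] == pytest.approx(0.18)
        assert out["very_fine_pct"] == pytest.approx(100.0)

    def test_sra_is_cylinder_surface(self):
        out = compute_fine_root_traits(root_sample())
        expected = 0.1 * math.pi * (0.15 * 3 + 0.35 * 1) / 0.02
        assert out["SRA"] == pytest.approx(expected)

    def test_zero_p_concentration_is_undefined_not_inf(self):
        with pytest.raises(UndefinedTraitError):
            compute_fine_root_traits(root_sample(p_conc=0.0))

    def test_empty_class_list_rejected(self):
        with pytest.raises(InvalidRecordError):
            root_sample(classes=())

    def test_inconsistent_total_length_rejected(self):
        with pytest.raises(InvalidRecordError):
            RootSampleRecord("x", length_by_diameter_class=((0.15, 3.0),),
                             total_length=4.0, dry_mass=0.02, volume=0.1)


class TestTaprootTraits:
    def test_forced_arithmetic(self):
        strl, trtd, pct = compute_taproot_traits(1.0, 0.5, 0.2, 0.5, 1.0)
        assert strl == pytest.approx(2.0)
        assert trtd == pytest.approx(2.5)  # mass over volume, g.cm-3
        assert pct == pytest.approx(50.0)

    @pytest.mark.parametrize("coarse,total,expected", [
        (0.0, 2.0, 0.0), (2.0, 2.0, 100.0),
    ])
    def test_percentage_boundaries(self, coarse, total, expected):
        *_, pct = compute_taproot_traits(1.0, 0.5, 0.2, coarse, total)
        assert pct == pytest.approx(expected)

    def test_coarse_exceeding_total_rejected(self):
        with pytest.raises(InvalidRecordError):
            compute_taproot_traits(1.0, 0.5, 0.2, 3.0, 2.0)


def profile(lengths, **kwargs):
    return DepthProfile("x", fine_root_length_per_segment=lengths, **kwargs)


class TestDepth95:
    def test_uniform_profile_is_exactly_95(self):
        assert compute_depth95(profile((2.0,) * 5)) == pytest.approx(95.0)

    def test_matches_explicit_ols_oracle(self):
        # nearly all length in the first segment: shallow cumulative curve
        lengths = (5.0, 1.0, 0.0, 0.0, 0.0)
        x = np.array([20.0, 40.0, 60.0, 80.0, 100.0])
        y = np.cumsum(lengths)
        xc = x - x.mean()
        slope = float(xc @ (y - y.mean())) / float(xc @ xc)
        intercept = y.mean() - slope * x.mean()
        expected = (0.95 * 6.0 - intercept) / slope
        assert compute_depth95(profile(lengths)) == pytest.approx(expected)

    def test_exactly_flat_cumulative_curve_is_undefined(self):
        # every root in segment 1: zero OLS slope, no 95% crossing
        with pytest.raises(UndefinedTraitError):
            compute_depth95(profile((5.0, 0.0, 0.0, 0.0, 0.0)))

    def test_scale_invariance(self, rng):
        lengths = tuple(rng.random(5) + 0.1)
        doubled = tuple(2 * v for v in lengths)
        assert compute_depth95(profile(lengths)) == pytest.approx(
            compute_depth95(profile(doubled)))

    def test_zero_total_and_flat_profiles_undefined(self):
        with pytest.raises(UndefinedTraitError):
            compute_depth95(profile((0.0,) * 5))


class TestRld:
    def test_forced_arithmetic(self):
        p = profile((2.0,) * 5, fine_root_mass_per_segment=(0.4,) * 5,
                    taproot_length=100.0, pot_volume=10_000.0)
        assert compute_rld(p, srl=100.0) == pytest.approx(2.01)

    def test_zero_taproot_is_fine_root_only(self):
        p = profile((2.0,) * 5, fine_root_mass_per_segment=(0.4,) * 5,
                    taproot_length=0.0, pot_volume=10_000.0)
        assert compute_rld(p, srl=100.0) == pytest.approx(2.0)

    def test_missing_pot_volume_rejected(self):
        with pytest.raises(InvalidRecordError):
            compute_rld(profile((2.0,) * 5,
                                fine_root_mass_per_segment=(0.4,) * 5), 100.0)


class TestMycorrhization:
    @pytest.mark.parametrize("amf,total,expected", [
        (45, 300, 15.0), (0, 300, 0.0), (300, 300, 100.0),
    ])
    def test_rate(self, amf, total, expected):
        c = IntersectCount("x", amf_intersects=amf, total_intersects=total)
        assert compute_mycorrhization_rate(c) == pytest.approx(expected)

    def test_invalid_counts_rejected(self):
        with pytest.raises(InvalidRecordError):
            IntersectCount("x", amf_intersects=5, total_intersects=0)
        with pytest.raises(InvalidRecordError):
            IntersectCount("x", amf_intersects=10, total_intersects=5)


class TestSummarizeTraits:
    def test_constant_column(self):
        summary, flagged = summarize_traits(pd.DataFrame({"a": [1.0, 1.0, 1.0]}))
        row = summary.loc["a"]
        assert (row["min"], row["mean"], row["max"], row["cv_pct"]) == (1, 1, 1, 0)
        assert not flagged

    def test_cv_against_hand_computed_sd(self):
        # sd of [0, 10] with n-1 denominator is sqrt(50)
        summary, _ = summarize_traits(pd.DataFrame({"a": [0.0, 10.0]}))
        assert summary.loc["a", "mean"] == pytest.approx(5.0)
        assert summary.loc["a", "cv_pct"] == pytest.approx(100 * math.sqrt(50) / 5)

    def test_na_dropped_and_all_na_flagged(self):
        df = pd.DataFrame({"a": [1.0, np.nan, 3.0], "b": [np.nan] * 3})
        summary, flagged = summarize_traits(df)
        assert summary.loc["a", "n"] == 2
        assert summary.loc["a", "mean"] == pytest.approx(2.0)
        assert flagged == ["b"]

    def test_cv_scale_invariant(self, rng):
        vals = rng.random(10) + 0.5
        s1, _ = summarize_traits(pd.DataFrame({"a": vals}))
        s2, _ = summarize_traits(pd.DataFrame({"a": 7.3 * vals}))
        assert s1.loc["a", "cv_pct"] == pytest.approx(s2.loc["a", "cv_pct"])


class TestRoundTrip:
    def test_records_invert_to_targets(self):
        targets = generate_trait_targets(8, seed=42)
        computed = trait_table_from_records(generate_measurement_records(targets))
        rel = (computed - targets).abs() / targets.abs().clip(lower=1e-12)
        assert float(rel.max().max()) < 1e-9

    def test_positive_and_bounded_outputs(self):
        targets = generate_trait_targets(6, seed=7)
        computed = trait_table_from_records(generate_measurement_records(targets))
        for col in ["Specific root length", "Root tissue density",
                    "Specific leaf area", "Leaf dry matter content",
                    "Root phosphorus use efficiency"]:
            assert (computed[col] > 0).all()
        for col in ["Very fine root percentage", "Taproot percentage",
                    "Mycorrhizal rate"]:
            assert computed[col].between(0, 100).all()
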