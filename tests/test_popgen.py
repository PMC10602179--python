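"""Population-genetic statistics: Hudson F_ST, PBS, private alleles,
EHH/iHS and the normality check."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from caparch import (
    ParameterError,
    UndefinedStatisticError,
    classify_private,
    ehh,
    hudson_fst,
    ihs,
    ihs_unstandardized,
    normality_check,
    pbs,
    pbs_outlier_percentile,
    simulate_haplotypes,
    standardize_ihs,
)


class TestHudsonFst:
    def test_hand_computed_differentiation(self):
        # p1=0.2, p2=0.8, huge samples: 0.36 / 0.68
        assert hudson_fst(0.2, 10**9, 0.8, 10**9) == pytest.approx(0.36 / 0.68,
                                                                   abs=1e-6)

    def test_no_differentiation_vanishes_with_sample_size(self):
        assert hudson_fst(0.4, 10**9, 0.4, 10**9) == pytest.approx(0.0, abs=1e-6)
        # small samples: slightly negative (unbiasedness correction)
        assert hudson_fst(0.4, 20, 0.4, 20) < 0.0

    def test_fixed_difference_is_one(self):
        assert hudson_fst(0.0, 10**9, 1.0, 10**9) == pytest.approx(1.0, abs=1e-6)

    def test_shared_monomorphism_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            hudson_fst(0.0, 100, 0.0, 100)

    def test_tiny_samples_rejected(self):
        with pytest.raises(ParameterError):
            hudson_fst(0.5, 1, 0.5, 100)


class TestPbs:
    def test_no_drift_gives_zero(self):
        assert pbs(0.0, 0.0, 0.0) == 0.0

    def test_hand_computed_branch(self):
        # T = -ln(0.9) twice, opposite branch 0
        assert pbs(0.1, 0.1, 0.0) == pytest.approx(-np.log(0.9), abs=1e-5)
        assert pbs(0.1, 0.1, 0.0) == pytest.approx(0.10536, abs=1e-4)

    def test_monotone_in_focal_branch(self):
        vals = [pbs(f, 0.1, 0.05) for f in np.linspace(0.0, 0.6, 10)]
        assert np.all(np.diff(vals) > 0)

    def test_negative_fst_clamped(self):
        assert pbs(-0.05, -0.05, -0.05) == 0.0

    def test_relabelled_branch_matches_brute_force(self):
        fab, fac, fbc = 0.12, 0.07, 0.2
        t = {k: -np.log(1 - v) for k, v in
             dict(ab=fab, ac=fac, bc=fbc).items()}
        # PBS for branch B swaps the roles of A and B
        assert pbs(fab, fbc, fac) == pytest.approx(
            (t["ab"] + t["bc"] - t["ac"]) / 2)

    def test_fst_at_one_rejected(self):
        with pytest.raises(ParameterError):
            pbs(1.5, 0.0, 0.0)


class TestPbsOutlierPercentile:
    def test_background_extremes(self):
        bg = [1.0, 2.0, 3.0, 4.0]
        assert pbs_outlier_percentile(4.0, bg)[0] == pytest.approx(100.0)
        assert pbs_outlier_percentile(1.0, bg)[0] == pytest.approx(0.0)

    def test_median_of_odd_background(self):
        assert pbs_outlier_percentile(2.0, [1.0, 2.0, 3.0])[0] == pytest.approx(50.0)

    def test_interpolated_rank(self):
        assert pbs_outlier_percentile(2.5, [1.0, 2.0, 3.0, 4.0])[0] == pytest.approx(50.0)

    def test_out_of_range_clipped(self):
        assert pbs_outlier_percentile(-10.0, [1.0, 2.0])[0] == 0.0
        assert pbs_outlier_percentile(10.0, [1.0, 2.0])[0] == 100.0

    def test_empty_background_rejected(self):
        with pytest.raises(ParameterError):
            pbs_outlier_percentile(1.0, [])


class TestClassifyPrivate:
    def test_africa_private_lead_snp(self):
        # effect allele absent in Europe, polymorphic in all of Africa
        freqs = {"West": 0.068, "East": 0.062, "South": 0.081, "EUR": 0.00}
        merged = {"Africa": min(freqs[r] for r in ("West", "East", "South")),
                  "EUR": freqs["EUR"]}
        assert classify_private(merged, "Africa") == "private_to_target"

    def test_globally_common_is_shared(self):
        assert classify_private({"A": 0.5, "B": 0.5}, "A") == "shared"

    def test_absent_in_target(self):
        assert classify_private({"A": 0.0, "B": 0.3}, "A") == "absent_in_target"

    @given(flip=st.booleans(), f_target=st.floats(min_value=0.0, max_value=1.0),
           f_other=st.floats(min_value=0.0, max_value=1.0))
    def test_invariant_to_allele_label_flips(self, flip, f_target, f_other):
        base = {"T": f_target, "O": f_other}
        flipped = {k: 1.0 - v for k, v in base.items()} if flip else base
        assert classify_private(base, "T") == classify_private(flipped, "T")

    def test_missing_target_rejected(self):
        with pytest.raises(ParameterError):
            classify_private({"A": 0.5}, "B")


class TestEhh:
    def test_identical_carriers_keep_full_homozygosity(self):
        h = np.tile([1, 0, 1, 1, 0], (6, 1))
        sites, vals = ehh(h, core_site=2, core_allele=1, direction="right")
        assert sites.tolist() == [2, 3, 4]
        assert vals.tolist() == [1.0, 1.0, 1.0]

    def test_two_two_split_drops_to_third(self):
        # 4 carriers split 2/2 at the first flanking site:
        # identical pairs = C(2,2)*2 = 2 of C(4,2) = 6
        h = np.array([[1, 0],
                      [1, 0],
                      [1, 1],
                      [1, 1],
                      [0, 0]])
        _, vals = ehh(h, core_site=0, core_allele=1, direction="right")
        assert vals[0] == 1.0
        assert vals[1] == pytest.approx(1 / 3)

    def test_curve_is_non_increasing(self, rng):
        h = simulate_haplotypes(40, 25, 0.5, ld_decay=0.3, rng=rng)
        for direction in ("left", "right"):
            _, vals = ehh(h, core_site=12, core_allele=1, direction=direction)
            assert np.all(np.diff(vals) <= 1e-12)

    def test_single_carrier_undefined(self):
        h = np.array([[1, 0], [0, 0], [0, 1]])
        with pytest.raises(UndefinedStatisticError):
            ehh(h, core_site=0, core_allele=1, direction="right")


class TestIhs:
    def test_mirror_symmetric_alleles_score_zero(self):
        # derived and ancestral carriers have identical flank structure
        flank = np.array([[0, 1, 0], [0, 1, 0], [1, 0, 1], [1, 0, 1]])
        core_d = np.ones((4, 1), dtype=int)
        core_a = np.zeros((4, 1), dtype=int)
        h = np.vstack([np.hstack([flank[:, :2], core_d, flank[:, 2:]]),
                       np.hstack([flank[:, :2], core_a, flank[:, 2:]])])
        table = ihs_unstandardized(h, positions=np.arange(4), maf_min=0.01)
        row = table[table["site"] == 2]
        assert row["ihs_unstd"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_low_maf_sites_excluded(self, rng):
        h = simulate_haplotypes(200, 10, 0.3, ld_decay=0.2, rng=rng)
        h[:, 4] = 0
        h[:1, 4] = 1  # MAF = 0.005 < 0.01
        table = ihs_unstandardized(h, positions=np.arange(10))
        assert 4 not in set(table["site"])

    def test_standardisation_is_self_consistent(self, rng):
        tables = []
        for _ in range(30):
            freqs = rng.uniform(0.1, 0.9, 40)
            h = simulate_haplotypes(120, 40, freqs, ld_decay=0.15, rng=rng)
            tables.append(ihs_unstandardized(h, positions=np.arange(40)))
        import pandas as pd
        pooled = standardize_ihs(pd.concat(tables, ignore_index=True))
        for _, grp in pooled.groupby("freq_bin"):
            z = grp["ihs"].dropna()
            if len(z) >= 2:
                assert z.mean() == pytest.approx(0.0, abs=1e-9)
                assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-9)


class TestNormalityCheck:
    def test_normal_draws_pass(self):
        z = np.random.default_rng(7).normal(size=200)
        report = normality_check(z)
        assert report.p > 0.01
        assert report.n == 200

    def test_constant_input_degenerate(self):
        with pytest.raises(UndefinedStatisticError):
            normality_check(np.ones(50))

    def test_extreme_scores_flagged(self):
        z = np.array([5.0, -5.0] * 30)
        with np.errstate(invalid="ignore"):
            report = normality_check(z + np.random.default_rng(0).normal(0, 0.01, 60))
        assert report.n_extreme == 60
        assert report.extreme_p < 1e-20

    @pytest.mark.parametrize("n", [2, 5001])
    def test_size_limits(self, n):
        with pytest.raises(ParameterError):
            normality_check(np.random.default_rng(0).normal(size=n))
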