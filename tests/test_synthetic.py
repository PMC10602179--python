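"""Generator calibration: Balding-Nichols moments, odds-ratio
inversion, count simulation and the Markov haplotype model."""

import numpy as np
import pytest

from caparch import (
    DEFAULT_REGION_SIZES,
    ParameterError,
    ScenarioConfig,
    case_freq_from_or,
    draw_regional_freqs,
    heterogeneous_beta_scenario,
    null_scenario,
    regional_association,
    simulate_counts,
    simulate_haplotypes,
)
from caparch.exceptions import ConfigError


class TestDrawRegionalFreqs:
    def test_no_drift_is_identity(self, rng):
        assert draw_regional_freqs(0.3, 0.0, rng) == 0.3

    def test_balding_nichols_moments(self, rng):
        p, f = 0.3, 0.01
        draws = draw_regional_freqs(np.full(10_000, p), f, rng)
        var = f * p * (1 - p)
        assert np.mean(draws) == pytest.approx(p, abs=3 * np.sqrt(var / draws.size))
        assert np.var(draws) == pytest.approx(var, rel=3 * np.sqrt(2 / draws.size) / 1)

    def test_high_drift_concentrates_near_fixation(self, rng):
        draws = draw_regional_freqs(np.full(10_000, 0.5), 0.95, rng)
        # variance approaches the maximal p(1-p) as F -> 1
        assert np.var(draws) > 0.2

    @pytest.mark.parametrize("p,f", [(0.0, 0.1), (1.0, 0.1), (0.5, 1.0), (0.5, -0.1)])
    def test_domain_errors(self, p, f, rng):
        with pytest.raises(ParameterError):
            draw_regional_freqs(p, f, rng)


class TestCaseFreqFromOr:
    @pytest.mark.parametrize("p0,oratio,expected", [
        (0.5, 1.0, 0.5),
        (0.2, 2.0, 1.0 / 3.0),
        (0.0, 7.0, 0.0),
    ])
    def test_values(self, p0, oratio, expected):
        assert case_freq_from_or(p0, oratio) == pytest.approx(expected)

    def test_strictly_increasing_in_or(self):
        ors = np.linspace(0.2, 5.0, 40)
        out = case_freq_from_or(0.3, ors)
        assert np.all(np.diff(out) > 0)

    def test_nonpositive_or_rejected(self):
        with pytest.raises(ParameterError):
            case_freq_from_or(0.3, 0.0)


class TestSimulateCounts:
    def test_study_region_sizes_give_three_tables(self):
        cfg = null_scenario(m_variants=5, seed=1)
        df = simulate_counts(cfg)
        assert sorted(set(df["Region"])) == ["East", "South", "West"]
        for region, (n_case, n_ctrl) in DEFAULT_REGION_SIZES.items():
            sub = df[df["Region"] == region]
            assert (sub["CaseTotal"] == 2 * n_case).all()
            assert (sub["CtrlTotal"] == 2 * n_ctrl).all()
            assert (sub["CaseEffCount"] <= sub["CaseTotal"]).all()
            assert (sub["CtrlEffCount"] >= 0).all()

    def test_same_seed_is_byte_identical(self):
        cfg = null_scenario(m_variants=8, seed=42)
        a = simulate_counts(cfg).to_csv()
        b = simulate_counts(null_scenario(m_variants=8, seed=42)).to_csv()
        assert a == b

    def test_null_scenario_case_control_freqs_agree(self):
        cfg = null_scenario(m_variants=200, seed=3,
                            region_sizes={"One": (20_000, 20_000)})
        cfg.beta[:] = 0.0
        df = simulate_counts(cfg)
        p_case = df["CaseEffCount"] / df["CaseTotal"]
        p_ctrl = df["CtrlEffCount"] / df["CtrlTotal"]
        # difference is pure binomial noise, sd ~ sqrt(2 p q / 2N)
        sd = np.sqrt(2 * p_ctrl * (1 - p_ctrl) / df["CtrlTotal"])
        assert np.mean(np.abs(p_case - p_ctrl) < 3 * sd) > 0.95

    def test_effect_recovery_on_large_cohorts(self):
        # configured log-OR recovered within 3 SE for >= 95% of variants
        cfg = heterogeneous_beta_scenario(
            m_variants=150, n_hetero=10, seed=7,
            region_sizes={"Big": (25_000, 25_000), "Other": (25_000, 25_000)})
        assoc = regional_association(simulate_counts(cfg))
        sub = assoc[assoc["Region"] == "Big"]
        true_beta = cfg.beta[0]
        covered = np.abs(sub["BETA"].to_numpy() - true_beta) <= 3 * sub["SE"].to_numpy()
        assert covered.mean() >= 0.95


class TestScenarioConfig:
    def test_shape_validation(self):
        with pytest.raises(ConfigError):
            ScenarioConfig(regions=("A", "B"), n_cases=[10], n_controls=[10, 10],
                           p_anc=[0.5], f_drift=0.0, beta=[[0.1], [0.1]])

    def test_freq_domain_validation(self):
        with pytest.raises(ConfigError):
            ScenarioConfig(regions=("A",), n_cases=[10], n_controls=[10],
                           p_anc=[1.5], f_drift=0.0, beta=[[0.1]])

    def test_from_dict_broadcasts(self):
        cfg = ScenarioConfig.from_dict({
            "regions": ["A", "B"], "n_cases": [50, 60], "n_controls": [50, 60],
            "p_anc": [0.2, 0.4], "beta": 0.1, "f_drift": 0.02, "seed": 9})
        assert cfg.beta.shape == (2, 2)
        assert cfg.f_drift.tolist() == [0.02, 0.02]


class TestSimulateHaplotypes:
    def test_independent_sites_have_negligible_ld(self, rng):
        h = simulate_haplotypes(10_000, 4, 0.5, ld_decay=1.0, rng=rng)
        from caparch import ld_r2
        r2, _ = ld_r2(h[:, 0], h[:, 1])
        assert r2 < 9 / 10_000  # |r| < 3/sqrt(n)

    def test_perfect_linkage_gives_two_patterns(self, rng):
        h = simulate_haplotypes(500, 6, 0.4, ld_decay=0.0, rng=rng)
        patterns = {tuple(row) for row in h}
        assert patterns <= {(0,) * 6, (1,) * 6}
        from caparch import ld_r2
        r2, dprime = ld_r2(h[:, 0], h[:, 1])
        assert r2 == pytest.approx(1.0)
        assert dprime == pytest.approx(1.0)

    def test_marginal_frequency(self, rng):
        h = simulate_haplotypes(10_000, 3, 0.3, ld_decay=0.5, rng=rng)
        se = np.sqrt(0.3 * 0.7 / 10_000)
        assert np.mean(h[:, 1]) == pytest.approx(0.3, abs=3 * se)

    def test_odd_haplotype_count_rejected(self, rng):
        with pytest.raises(ParameterError):
            simulate_haplotypes(7, 3, 0.5, 0.5, rng)
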