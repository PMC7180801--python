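import numpy as np
import pytest

from uplimb.datamodel import AngleWaveform, ValidationError
from uplimb.evaluate import (
    bland_altman,
    build_report,
    cmc,
    paired_comparison,
    pta,
    rmse,
    rom,
)


def brute_force_cmc(Y):
    """Independent, literal implementation of the within-group CMC."""
    G, T = Y.shape
    mean_t = [sum(Y[g][t] for g in range(G)) / G for t in range(T)]
    grand = sum(Y[g][t] for g in range(G) for t in range(T)) / (G * T)
    num = sum((Y[g][t] - mean_t[t]) ** 2 for g in range(G) for t in range(T))
    den = sum((Y[g][t] - grand) ** 2 for g in range(G) for t in range(T))
    num /= G * (T - 1)
    den /= G * T - 1
    rad = 1.0 - num / den
    return np.sqrt(rad) if rad >= 0 else 0.0


class TestCmc:
    def test_identical_nonconstant_pair_is_one(self):
        x = np.sin(np.linspace(0, 3, 101))
        assert cmc(np.stack([x, x])) == pytest.approx(1.0)

    def test_constant_pair_clamps_to_zero_with_flag(self):
        Y = np.stack([np.zeros(101), np.ones(101)])
        value, flag = cmc(Y, return_flag=True)
        assert value == 0.0 and flag

    def test_identical_constant_pair_is_flagged_nan(self):
        Y = np.full((2, 101), 7.0)
        value, flag = cmc(Y, return_flag=True)
        assert np.isnan(value) and flag

    def test_matches_brute_force_on_random_inputs(self, rng):
        for _ in range(50):
            G = rng.integers(2, 5)
            T = rng.integers(5, 60)
            Y = rng.normal(0, 30, (G, T))
            assert cmc(Y) == pytest.approx(brute_force_cmc(Y), abs=1e-10)

    def test_noisy_sinusoid_against_brute_force(self, rng):
        t = np.linspace(0, 1, 101)
        a = 50 * np.sin(2 * np.pi * t)
        b = a + rng.normal(0, 0.05 * 50, 101)
        Y = np.stack([a, b])
        assert cmc(Y) == pytest.approx(brute_force_cmc(Y), abs=1e-12)

    def test_noise_decreases_cmc_in_expectation(self, rng):
        t = np.linspace(0, 1, 101)
        a = 50 * np.sin(2 * np.pi * t)
        means = []
        for sigma in (1.0, 5.0, 15.0):
            vals = [cmc(np.stack([a, a + rng.normal(0, sigma, 101)]))
                    for _ in range(40)]
            means.append(np.mean(vals))
        assert means[0] > means[1] > means[2]

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValidationError):
            cmc(np.zeros((2,)))


class TestRmse:
    def test_identity_zero(self):
        x = np.arange(10.0)
        assert rmse(x, x) == 0.0

    def test_hand_computed_value(self):
        a = np.array([3.0, 4.0])
        b = np.zeros(2)
        assert rmse(a, b) == pytest.approx(np.sqrt(12.5))

    def test_constant_offset(self):
        x = np.arange(50.0)
        assert rmse(x, x - 7.3) == pytest.approx(7.3)

    def test_triangle_inequality_on_random_triples(self, rng):
        for _ in range(100):
            a, b, c = rng.normal(0, 20, (3, 37))
            assert rmse(a, c) <= rmse(a, b) + rmse(b, c) + 1e-12


class TestRomPta:
    def test_monotone_curve(self):
        from uplimb.synthetic import minimum_jerk

        x = 90 * minimum_jerk(np.linspace(0, 1, 101))
        assert rom(x) == pytest.approx(90.0)
        assert pta(x) == pytest.approx(90.0)

    def test_overshooting_curve(self):
        t = np.linspace(0, 1, 101)
        x = 120 * np.sin(np.pi * t * 0.75) / np.sin(np.pi * 0.75)
        x = x / x.max() * 120
        x[-1] = 100.0
        assert rom(x) == pytest.approx(120.0)
        assert pta(x) == pytest.approx(100.0)

    def test_constant_waveform(self):
        x = np.full(101, 42.0)
        assert rom(x) == 0.0
        assert pta(x) == 42.0

    def test_non_normalized_waveform_rejected(self):
        wf = AngleWaveform(values=np.zeros((60, 4)))
        with pytest.raises(ValidationError):
            rom(wf, "FE")


class TestBlandAltman:
    def test_identical_lists(self):
        x = np.arange(10.0)
        ba = bland_altman(x, x)
        assert ba["mean_diff"] == 0.0
        assert ba["loa_lower"] == 0.0 and ba["loa_upper"] == 0.0

    def test_hand_computed_loa(self):
        x = np.array([1.0, 2.0, 3.0])
        y = np.zeros(3)
        ba = bland_altman(x, y)
        assert ba["mean_diff"] == pytest.approx(2.0)
        assert ba["loa_lower"] == pytest.approx(0.04)
        assert ba["loa_upper"] == pytest.approx(3.96)

    def test_monte_carlo_gaussian_differences(self):
        rng = np.random.default_rng(99)
        y = np.zeros(10_000)
        x = rng.normal(5.0, 2.0, 10_000)
        ba = bland_altman(x, y)
        assert ba["loa_lower"] == pytest.approx(5 - 1.96 * 2, abs=0.1)
        assert ba["loa_upper"] == pytest.approx(5 + 1.96 * 2, abs=0.1)

    def test_single_pair_rejected(self):
        with pytest.raises(ValidationError):
            bland_altman([1.0], [2.0])


class TestPairedComparison:
    def test_zero_variance_flagged_degenerate(self):
        x = np.arange(10.0)
        name, stat, p = paired_comparison(x, x + 1.0)
        assert name == "degenerate"
        assert np.isnan(p)

    def test_normal_differences_select_paired_t(self):
        from scipy import stats

        rng = np.random.default_rng(4)
        y = np.zeros(13)
        x = rng.normal(1.0, 1.0, 13)
        name, stat, p = paired_comparison(x, y)
        assert name == "paired-t"
        ref = stats.ttest_rel(x, y)
        assert stat == pytest.approx(ref.statistic, abs=1e-10)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_heavy_tailed_differences_select_wilcoxon(self):
        rng = np.random.default_rng(8)
        d = np.exp(rng.normal(0, 1.5, 40))
        d -= np.median(d)
        name, _, _ = paired_comparison(d, np.zeros_like(d))
        assert name == "wilcoxon"


class TestBuildReport:
    @staticmethod
    def _fold(subject, task="t3_comb_hair", seed=0):
        from uplimb.refine import FoldResult

        rng = np.random.default_rng(seed)
        t = np.linspace(0, 1, 101)
        mk = lambda amp: AngleWaveform(
            values=np.column_stack([amp * np.sin(np.pi * t / 2)] * 4),
            normalized=True)
        target = mk(90 + rng.normal(0, 3))
        inp = mk(120 + rng.normal(0, 5))
        ref = mk(92 + rng.normal(0, 2))
        one = lambda a, b: np.array(
            [[rmse(a.values[:, c], b.values[:, c]) for c in range(4)]])
        onec = lambda a, b: np.array(
            [[cmc(np.stack([a.values[:, c], b.values[:, c]])) for c in range(4)]])
        return FoldResult(subject_id=subject, task=task, inputs=[inp],
                          targets=[target], refined=[ref],
                          rmse_before=one(inp, target),
                          rmse_after=one(ref, target),
                          cmc_before=onec(inp, target),
                          cmc_after=onec(ref, target))

    def test_single_fold_equals_trial_statistics(self):
        f = self._fold("S01")
        rep = build_report([f]).to_dict()
        entry = rep["t3_comb_hair"]["FE"]
        assert entry["rmse"]["refined"][0] == pytest.approx(f.rmse_after[0, 0])
        assert entry["pta"]["refined"]["mean"] == pytest.approx(
            pta(f.refined[0].values[:, 0]))

    def test_means_are_across_fold_averages(self):
        folds = [self._fold(f"S{i:02d}", seed=i) for i in range(5)]
        rep = build_report(folds).to_dict()
        expected = np.mean([f.rmse_after[0, 1] for f in folds])
        assert rep["t3_comb_hair"]["AA"]["rmse"]["refined"][0] == \
            pytest.approx(expected)

    def test_report_totals_match_recomputation(self):
        folds = [self._fold(f"S{i:02d}", seed=i) for i in range(6)]
        rep = build_report(folds).to_dict()
        ptas_hat = np.array([pta(f.refined[0].values[:, 2]) for f in folds])
        ptas_ref = np.array([pta(f.targets[0].values[:, 2]) for f in folds])
        entry = rep["t3_comb_hair"]["IE"]["pta"]["refined"]
        assert entry["mean_diff"] == pytest.approx(
            float((ptas_hat - ptas_ref).mean()))
        ba = bland_altman(ptas_hat, ptas_ref)
        assert entry["loa"][0] == pytest.approx(ba["loa_lower"])

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            build_report([])
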