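import itertools

import numpy as np
import pytest
from scipy import stats

from adaptnet.connectivity import NetworkSpec, generate_dale
from adaptnet.dynamics import ModelParams
from adaptnet.exceptions import ParameterError, UndefinedTestError
from adaptnet.experiments import (
    CONDITIONS,
    SweepSettings,
    run_condition,
    run_spectral_gallery,
    run_sweep,
    wilcoxon_signed_rank,
)
from adaptnet.lyapunov import perturbation_direction
from adaptnet.stimuli import random_step


def brute_force_wilcoxon(diffs):
    """Literal enumeration of all sign assignments (drop zeros, midranks)."""
    d = np.asarray(diffs, float)
    d = d[d != 0]
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([False, True], repeat=d.size)
    ]
    ws = np.asarray(ws)
    tol = 1e-9
    p_le = np.mean(ws <= w_obs + tol)
    p_ge = np.mean(ws >= w_obs - tol)
    return min(1.0, 2.0 * min(p_le, p_ge))


class TestWilcoxon:
    def test_all_positive_n5(self):
        stat, p = wilcoxon_signed_rank([1.0, 2.0, 3.0, 4.0, 5.0])
        assert stat == 15.0
        assert p == pytest.approx(0.0625)

    def test_symmetric_pair_with_tied_magnitudes(self):
        _, p = wilcoxon_signed_rank([+1.0, -1.0])
        assert p == pytest.approx(1.0)

    def test_sign_flip_invariance(self):
        rng = np.random.default_rng(0)
        d = rng.normal(0.2, 1.0, size=15)
        _, p1 = wilcoxon_signed_rank(d)
        _, p2 = wilcoxon_signed_rank(-d)
        assert p1 == pytest.approx(p2)

    def test_zeros_dropped(self):
        _, p_with = wilcoxon_signed_rank([0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 0.0])
        _, p_without = wilcoxon_signed_rank([1.0, 2.0, 3.0, 4.0, 5.0])
        assert p_with == pytest.approx(p_without)

    def test_all_zero_raises(self):
        with pytest.raises(UndefinedTestError):
            wilcoxon_signed_rank([0.0, 0.0])

    @pytest.mark.parametrize("n", [3, 5, 8, 10, 12])
    def test_exact_matches_brute_force_enumeration(self, n):
        rng = np.random.default_rng(n)
        for trial in range(4):
            d = np.round(rng.normal(0.3, 1.0, size=n), 1)  # induces ties
            if np.all(d == 0):
                continue
            _, p = wilcoxon_signed_rank(d)
            assert p == pytest.approx(brute_force_wilcoxon(d), abs=1e-12)

    def test_matches_scipy_on_tie_free_data(self):
        rng = np.random.default_rng(5)
        d = rng.normal(0.4, 1.0, size=14)
        stat, p = wilcoxon_signed_rank(d)
        ref = stats.wilcoxon(d, alternative="two-sided", method="exact")
        assert p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_large_sample_normal_approximation(self):
        rng = np.random.default_rng(6)
        d = rng.normal(0.3, 1.0, size=40)
        _, p = wilcoxon_signed_rank(d)
        ref = stats.wilcoxon(d, alternative="two-sided", method="approx",
                             correction=False)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)


FAST = SweepSettings(post_duration=4.0, window=0.5, transient=1.0)
FAST_NET = NetworkSpec(N=80, d=0.5, seed=0)


def fast_stim(W, seed, amp_max=0.5):
    return random_step(W.n, W.labels, t_on=4.0, t_off=8.0, amp_max=amp_max,
                       seed=seed)


class TestRunCondition:
    def test_zero_amplitude_stimulus_gives_near_zero_diff(self):
        W = generate_dale(FAST_NET)
        stim = fast_stim(W, 1, amp_max=0.0)
        r = run_condition(W, stim, "none", ModelParams(), FAST, seed=2)
        assert abs(r.diff) < 0.05

    def test_diff_recomputable_from_epoch_means(self):
        W = generate_dale(FAST_NET)
        r = run_condition(W, fast_stim(W, 3), "sfa_std", ModelParams(), FAST,
                          seed=4)
        assert r.diff == pytest.approx(r.lambda_stim - r.lambda_base,
                                       abs=1e-12)
        assert r.lambda_stim == pytest.approx(
            r.lambda_stim_raw * ModelParams().tau_d, abs=1e-12
        )

    def test_unknown_condition_rejected(self):
        W = generate_dale(FAST_NET)
        with pytest.raises(ParameterError):
            run_condition(W, fast_stim(W, 1), "both", ModelParams(), FAST)

    def test_pairing_shares_rng_draws_across_conditions(self):
        # the perturbation direction consumes a full-state draw regardless of
        # which mechanisms are enabled, so paired runs stay aligned
        W = generate_dale(NetworkSpec(N=40, seed=1))
        dirs = {}
        for cond, (sfa, std) in CONDITIONS.items():
            rng = np.random.default_rng(99)
            rng.normal(0.0, 0.01, size=W.n)  # x0 draw
            p = ModelParams(sfa_enabled=sfa, std_enabled=std)
            dirs[cond] = perturbation_direction(W, p, rng)
        x_none = dirs["none"][: W.n]
        for cond in ("sfa_only", "std_only", "sfa_std"):
            x = dirs[cond][: W.n]
            ratio = np.linalg.norm(x_none) / np.linalg.norm(x)
            np.testing.assert_allclose(x * ratio, x_none, rtol=1e-12)


@pytest.fixture(scope="module")
def table():
    return run_sweep(
        n_networks=5,
        base_spec=FAST_NET,
        params=ModelParams(),
        settings=FAST,
        t_on=4.0,
        t_off=8.0,
        master_seed=7,
    )


class TestRunSweep:
    def test_row_count_and_structure(self, table):
        assert len(table.rows) == 20
        for cond in CONDITIONS:
            assert sum(r.condition == cond for r in table.rows) == 5
        f_Es = sorted({r.f_E for r in table.rows})
        np.testing.assert_allclose(f_Es, np.linspace(0.4, 0.6, 5))

    def test_conditions_share_network_and_stimulus(self, table):
        by_net = {}
        for r in table.rows:
            by_net.setdefault(r.network_id, []).append(r)
        for rows in by_net.values():
            assert len({r.f_E for r in rows}) == 1
            assert len(rows) == 4

    def test_summary_contents(self, table):
        for cond in CONDITIONS:
            s = table.summary[cond]
            assert s["n"] == 5
            assert 0.0 <= s["p_value"] <= 1.0
            assert s["ci_low"] <= s["median_diff"] <= s["ci_high"]

    def test_median_invariant_to_row_order(self, table):
        import random

        rows = list(table.rows)
        random.Random(0).shuffle(rows)
        from adaptnet.experiments import ExperimentTable

        shuffled = ExperimentTable(rows)
        shuffled.summarize(seed=0)
        for cond in CONDITIONS:
            assert shuffled.summary[cond]["median_diff"] == pytest.approx(
                table.summary[cond]["median_diff"]
            )

    def test_determinism(self, table):
        again = run_sweep(
            n_networks=5,
            base_spec=FAST_NET,
            params=ModelParams(),
            settings=FAST,
            t_on=4.0,
            t_off=8.0,
            master_seed=7,
        )
        for r1, r2 in zip(table.rows, again.rows):
            assert r1.diff == r2.diff

    def test_too_few_networks_rejected(self):
        with pytest.raises(ParameterError):
            run_sweep(n_networks=3)


@pytest.fixture(scope="module")
def gallery():
    return run_spectral_gallery(seed=0)


class TestGallery:
    def test_positive_mean_outlier(self, gallery):
        sc = gallery["A"]
        assert sc.n_outliers >= 1
        top = sc.outliers[np.argmax(sc.outliers.real)]
        assert abs(top.imag) < 1e-8
        assert top.real > sc.radius

    def test_diagonal_feedback_reaches_stability(self, gallery):
        from adaptnet.spectra import spectral_abscissa

        assert spectral_abscissa(gallery["B"].spectrum) <= 0.05

    def test_dale_outliers_without_balancing(self, gallery):
        assert gallery["C"].n_outliers > 0

    def test_balancing_suppresses_dense_outliers(self, gallery):
        assert gallery["D"].n_outliers == 0

    def test_unequal_variances_concentrate_spectrum(self, gallery):
        # central concentration: more mass well inside the disk than for the
        # balanced equal-variance ensemble
        r_d = np.abs(gallery["D"].spectrum.eigenvalues) / gallery["D"].radius
        r_e = np.abs(gallery["E"].spectrum.eigenvalues) / gallery["E"].radius
        assert np.median(r_e) < np.median(r_d)

    def test_sparsity_defeats_balancing(self, gallery):
        assert gallery["F"].n_outliers > 0
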