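import numpy as np
import pandas as pd
import pytest

from pavbias import HierarchicalGNG, SubjectParameters, simulate_session, transform
from pavbias.agent import SUBJECT_PARAM_NAMES
from pavbias.hierarchical import (
    effective_sample_size,
    hdi,
    split_rhat,
    summarize,
)
from pavbias.task import TaskDesign

from conftest import trials_frame


class TestSplitRhat:
    def test_stationary_chains_near_one(self):
        rng = np.random.default_rng(0)
        assert split_rhat(rng.standard_normal((4, 2000))) == pytest.approx(1.0, abs=0.01)

    def test_separated_chains_flagged(self):
        rng = np.random.default_rng(1)
        chains = np.stack([rng.normal(0, 1, 1000), rng.normal(10, 1, 1000)])
        assert split_rhat(chains) > 1.1 * 3

    def test_within_chain_drift_detected_by_splitting(self):
        # two identical half-drifting chains: plain R-hat would miss this
        drift = np.concatenate([np.random.default_rng(2).normal(0, 1, 500),
                                np.random.default_rng(3).normal(5, 1, 500)])
        assert split_rhat(np.stack([drift, drift])) > 1.5

    def test_constant_chains_undefined(self):
        assert np.isnan(split_rhat(np.ones((2, 100))))

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            split_rhat(np.random.default_rng(0).standard_normal((1, 100)))

    def test_agrees_with_arviz_rank_free_formula(self):
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(5)
        draws = rng.standard_normal((2, 500)) + 0.3 * rng.standard_normal((2, 1))
        ours = split_rhat(draws)
        theirs = az.rhat(az.convert_to_dataset(draws[:, :, None]), method="split")["x"].values.item()
        assert ours == pytest.approx(theirs, abs=0.02)


class TestHdi:
    def test_standard_normal_interval(self):
        rng = np.random.default_rng(0)
        lo, hi = hdi(rng.standard_normal(10_000), 0.95)
        assert lo == pytest.approx(-1.96, abs=0.08)
        assert hi == pytest.approx(1.96, abs=0.08)

    def test_constant_draws_zero_width(self):
        lo, hi = hdi(np.full(50, 2.5), 0.95)
        assert lo == hi == 2.5

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_window_search(self, seed):
        rng = np.random.default_rng(seed)
        x = np.sort(rng.gamma(2.0, 1.0, 100))
        mass = 0.8
        m = int(np.ceil(mass * x.size))
        best = min(
            ((x[i + m - 1] - x[i], (x[i], x[i + m - 1])) for i in range(x.size - m + 1)),
            key=lambda w: w[0],
        )[1]
        assert hdi(x, mass) == pytest.approx(best)

    def test_invalid_mass_rejected(self):
        with pytest.raises(ValueError):
            hdi(np.zeros(100), 1.5)


class TestSummaries:
    def test_symmetric_draws_half_positive(self):
        rng = np.random.default_rng(0)
        d = rng.standard_normal(4000)
        table = summarize({"x": d})
        assert table.loc["x", "p_gt_zero"] == pytest.approx(0.5, abs=0.05)

    def test_all_positive_draws_exclude_zero(self):
        d = np.random.default_rng(1).gamma(3.0, 1.0, 1000) + 0.1
        row = summarize({"x": d}).loc["x"]
        assert row["hdi95_lo"] > 0

    def test_median_matches_sort_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            d = rng.normal(rng.normal(), 1 + rng.random(), 101)
            srt = np.sort(d)
            assert summarize({"x": d}).loc["x", "median"] == srt[50]

    def test_ess_sane_for_iid_draws(self):
        rng = np.random.default_rng(3)
        ess = effective_sample_size(rng.standard_normal((2, 1000)))
        assert 1000 < ess < 3500


def _two_subject_frame(seed=0):
    rng = np.random.default_rng(seed)
    frames = []
    for i, subj in enumerate(["a", "b"]):
        eta1 = rng.normal(0, 0.5, 7)
        sp = SubjectParameters(eta1=eta1, delta=rng.normal(0, 0.2, 7))
        design = TaskDesign(trials_per_condition=10)
        for sess, p in ((1, sp.session1()), (2, sp.session2())):
            frames.append(trials_frame(simulate_session(p, design, rng, subject=subj, session=sess)))
    return pd.concat(frames, ignore_index=True)


class TestModelStructure:
    def test_free_quantity_count_two_subjects(self):
        model = HierarchicalGNG(_two_subject_frame())
        # 14 group means + 14 group SDs + 2 x 14 subject z-scores
        assert model.n_free_parameters == 14 + 14 + 2 * 14
        assert model.n_subject_parameters == 14

    def test_group_indicator_doubles_means(self):
        df = _two_subject_frame()
        model = HierarchicalGNG(df, groups={"a": "quit", "b": "nonquit"})
        assert model.n_free_parameters == 2 * 14 + 14 + 2 * 14
        assert model.group_labels == ["nonquit", "quit"]

    def test_empty_covariates_identical_to_none(self):
        df = _two_subject_frame()
        m0 = HierarchicalGNG(df)
        m1 = HierarchicalGNG(df, covariates=pd.DataFrame(index=["a", "b"]))
        x = np.random.default_rng(0).normal(0, 0.1, m0.n_free_parameters)
        f0, g0 = m0.logp_and_grad(x)
        f1, g1 = m1.logp_and_grad(x)
        assert f0 == f1 and np.array_equal(g0, g1)

    def test_subject_without_session1_rejected(self):
        df = _two_subject_frame()
        df = df[~((df["subject"] == "a") & (df["session"] == 1))]
        with pytest.raises(ValueError, match="session-1"):
            HierarchicalGNG(df)

    @pytest.mark.parametrize("centered", [False, True])
    def test_gradient_matches_finite_differences(self, centered):
        model = HierarchicalGNG(_two_subject_frame(), centered=centered)
        rng = np.random.default_rng(4)
        x = 0.1 * rng.standard_normal(model.n_free_parameters)
        f, g = model.logp_and_grad(x)
        for k in rng.choice(model.n_free_parameters, size=8, replace=False):
            e = np.zeros_like(x)
            e[k] = 1e-6
            fd = (model.logp_and_grad(x + e)[0] - model.logp_and_grad(x - e)[0]) / 2e-6
            assert g[k] == pytest.approx(fd, rel=1e-4, abs=1e-5)


class TestSampling:
    def test_same_seed_identical_draws(self):
        model = HierarchicalGNG(_two_subject_frame())
        r1 = model.fit(chains=2, iterations=80, warmup=40, seed=7)
        r2 = model.fit(chains=2, iterations=80, warmup=40, seed=7)
        assert np.array_equal(r1._x, r2._x)

    def test_centered_and_noncentered_agree_on_group_means(self):
        # the centered funnel needs enough subjects to identify the group
        # SDs; 8 subjects x 80 trials is the smallest comfortable case
        rng = np.random.default_rng(3)
        frames = []
        for i in range(8):
            sp = SubjectParameters(eta1=rng.normal(0, 0.5, 7), delta=rng.normal(0, 0.2, 7))
            design = TaskDesign(trials_per_condition=20)
            for sess, p in ((1, sp.session1()), (2, sp.session2())):
                frames.append(
                    trials_frame(simulate_session(p, design, rng, subject=f"s{i}", session=sess))
                )
        df = pd.concat(frames, ignore_index=True)
        res = {}
        # the centered chain random-walks through the funnel, so it needs
        # many more iterations to reach the same stationary distribution
        for centered, (iters, warm) in ((False, (500, 250)), (True, (2000, 1000))):
            model = HierarchicalGNG(df, centered=centered)
            fit = model.fit(chains=2, iterations=iters, warmup=warm, seed=2)
            res[centered] = {
                p: np.mean(fit.group_mean_draws(p)) for p in ("pi_rew", "go_bias", "eps")
            }
        for p in res[False]:
            assert res[False][p] == pytest.approx(res[True][p], abs=0.3)

    def test_posterior_draws_labeling_roundtrip(self, fit15):
        post = fit15.posterior
        df = post.to_dataframe()
        assert set(df.columns) == {"chain", "iteration", "parameter", "value"}
        name = "mu[quit][d_pi_rew]"
        sub = df[df["parameter"] == name]
        assert np.array_equal(
            sub["value"].to_numpy().reshape(post.get(name).shape), post.get(name)
        )

    def test_diagnostics_cover_group_and_subject_levels(self, fit15):
        diag = fit15.diagnostics
        names = diag.table.index
        assert any(n.startswith("mu[") for n in names)
        assert any(n.startswith("sigma[") for n in names)
        assert any(n.startswith("eta[") for n in names)
        assert diag.divergences >= 0

    def test_shrinkage_relative_to_unpooled_estimates(self, cohort15, fit15):
        """Partial pooling shrinks subject estimates toward the group mean:
        posterior means are less dispersed than near-ML per-subject fits,
        for every session-1 parameter."""
        model = fit15.model
        post = fit15.subject_posterior_mean()
        for k, name in enumerate(SUBJECT_PARAM_NAMES[:7]):
            unpooled = np.array(
                [model.map_estimate(s, penalty_scale=10.0)[0].eta1[k] for s in model.subjects]
            )
            assert post[name].to_numpy().var() < unpooled.var()


class TestMapEstimate:
    def test_recovers_generating_pi_rew(self):
        rng = np.random.default_rng(0)
        for pi_true in (-1.5, 0.0, 1.5):
            eta1 = np.array([-0.5, 1.2, 1.2, 0.2, pi_true, 0.5, -1.3])
            sp = SubjectParameters(eta1=eta1, delta=np.zeros(7))
            frames = [
                trials_frame(simulate_session(sp.session1(), TaskDesign(), rng, "x", sess))
                for sess in (1, 2)
            ]
            model = HierarchicalGNG(pd.concat(frames, ignore_index=True))
            est, _ = model.map_estimate("x")
            assert est.eta1[4] == pytest.approx(pi_true, abs=0.5)

    def test_missing_session2_leaves_delta_at_penalty_mode(self):
        rng = np.random.default_rng(1)
        sp = SubjectParameters(eta1=np.zeros(7), delta=np.zeros(7))
        df = trials_frame(simulate_session(sp.session1(), TaskDesign(), rng, "x", 1))
        model = HierarchicalGNG(df)
        est, _ = model.map_estimate("x")
        assert np.allclose(est.delta, 0.0, atol=1e-5)

    def test_objective_at_optimum_beats_truth(self):
        rng = np.random.default_rng(2)
        eta1 = np.array([-0.5, 1.2, 1.2, 0.2, 0.8, 0.8, -1.3])
        sp = SubjectParameters(eta1=eta1, delta=np.zeros(7))
        frames = [
            trials_frame(simulate_session(sp.session1(), TaskDesign(), rng, "x", sess))
            for sess in (1, 2)
        ]
        df = pd.concat(frames, ignore_index=True)
        model = HierarchicalGNG(df)
        est, _ = model.map_estimate("x")
        packed = model.packed

        def objective(eta14):
            _, g = packed.loglik_and_grad(eta14[None, :])
            ll, _ = packed.loglik_and_grad(eta14[None, :])
            return ll - 0.5 * np.sum(eta14**2)

        opt = np.concatenate([est.eta1, est.delta])
        truth = np.concatenate([eta1, np.zeros(7)])
        assert objective(opt) >= objective(truth) - 1e-6
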