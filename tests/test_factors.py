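"""Multi-view factor model: recovery, variance decomposition, discrimination."""

import numpy as np
import pandas as pd
import pytest

from cihmet import factors, synthio


def _complete_view(rng, n=60, p=30, k=2, noise=1e-3, prefix="f"):
    Z = rng.normal(size=(n, k))
    W = rng.normal(size=(p, k))
    X = Z @ W.T + noise * rng.normal(size=(n, p))
    df = pd.DataFrame(X, index=[f"s{i}" for i in range(n)], columns=[f"{prefix}{j}" for j in range(p)])
    return df, Z, W


def _match_correlation(Z_true, Z_hat):
    """Greedy max |corr| assignment of recovered to true factors."""
    corr = np.abs(np.corrcoef(Z_true.T, Z_hat.T)[: Z_true.shape[1], Z_true.shape[1]:])
    best = []
    used = set()
    for i in range(Z_true.shape[1]):
        order = np.argsort(-corr[i])
        for j in order:
            if j not in used:
                used.add(j)
                best.append(corr[i, j])
                break
    return best


class TestFitFactorModel:
    def test_low_noise_two_factor_view_fully_explained(self, rng):
        df, _, _ = _complete_view(rng, noise=1e-3)
        model = factors.fit_factor_model({"v": df}, k=4, max_iter=300, seed=0)
        top2 = model.R2["v"].sort_values(ascending=False).iloc[:2].sum()
        assert top2 > 0.99

    def test_three_view_missing_pattern_recovers_planted_factors(self):
        # the study's coverage pattern: 63 patients, views on 54/49/44
        spec = synthio.CohortSpec(seed=5)
        truth = synthio.plan_truth(
            spec, {"CRT": 40, "plasma": 40, "urine": 40}, n_dems=0, n_biomarkers=0,
            k_factors=3, loading_scale=1.0,
        )
        views, meta, mask = synthio.generate_views(spec, truth, noise_sd=0.3, missing_rate=0.0)
        logged = {v: np.log2(df.dropna(how="all")) for v, df in views.items()}
        model = factors.fit_factor_model(logged, k=5, max_iter=2000, seed=1)
        # reconstruct the true scores for all patients (metadata row order)
        rng = synthio.substream(spec.seed, "views")
        Z_true = pd.DataFrame(rng.normal(size=(63, 3)), index=meta.index)
        common = Z_true.index.intersection(model.Z.index)  # patients with >=1 view
        match = _match_correlation(Z_true.loc[common].to_numpy(), model.Z.loc[common].to_numpy())
        assert min(match) > 0.9

    def test_pure_noise_views_have_negligible_r2(self, rng):
        dfs = {}
        for v in ("a", "b"):
            dfs[v] = pd.DataFrame(
                rng.normal(size=(200, 25)),
                index=[f"s{i}" for i in range(200)],
                columns=[f"{v}{j}" for j in range(25)],
            )
        model = factors.fit_factor_model(dfs, k=5, max_iter=200, seed=2)
        assert model.R2.to_numpy().max(initial=0.0) < 0.05  # all pruned as noise

    def test_objective_is_monotone_non_decreasing(self, rng):
        df, _, _ = _complete_view(rng, noise=0.5)
        model = factors.fit_factor_model({"v": df}, k=3, max_iter=100, seed=3)
        trace = np.asarray(model.objective_trace)
        assert (np.diff(trace) >= -1e-6).all()

    def test_k_larger_than_feature_count_rejected(self, rng):
        df, _, _ = _complete_view(rng, p=4)
        with pytest.raises(ValueError, match="k="):
            factors.fit_factor_model({"v": df}, k=10)

    def test_disjoint_sample_sets_rejected(self, rng):
        a = pd.DataFrame(rng.normal(size=(5, 6)), index=[f"a{i}" for i in range(5)])
        b = pd.DataFrame(rng.normal(size=(5, 6)), index=[f"b{i}" for i in range(5)])
        with pytest.raises(ValueError, match="non-overlapping"):
            factors.fit_factor_model({"x": a, "y": b}, k=2)

    def test_seeded_fit_is_deterministic(self, rng):
        df, _, _ = _complete_view(rng, noise=0.5)
        m1 = factors.fit_factor_model({"v": df}, k=3, max_iter=50, seed=7)
        m2 = factors.fit_factor_model({"v": df}, k=3, max_iter=50, seed=7)
        pd.testing.assert_frame_equal(m1.Z, m2.Z)

    def test_missing_view_scores_depend_only_on_observed_views(self, rng):
        # a patient lacking view b: their score row must satisfy the
        # single-view normal equations built from view a alone
        a = pd.DataFrame(rng.normal(size=(30, 10)), index=[f"s{i}" for i in range(30)])
        b = pd.DataFrame(rng.normal(size=(20, 10)), index=[f"s{i}" for i in range(20)])
        model = factors.fit_factor_model({"a": a, "b": b}, k=2, max_iter=100, seed=0, min_factors=2)
        assert np.isfinite(model.Z.to_numpy()).all()
        Wa = model.W["a"].to_numpy()
        tau = model.tau["a"]
        xa = model.X_scaled["a"]
        for s in [f"s{i}" for i in range(20, 30)]:  # only view a observed
            lhs = np.eye(2) + tau * Wa.T @ Wa
            rhs = tau * Wa.T @ xa.loc[s].to_numpy()
            np.testing.assert_allclose(model.Z.loc[s], np.linalg.solve(lhs, rhs), atol=1e-8)

    def test_single_view_solution_spans_pca_subspace(self, rng):
        df, _, _ = _complete_view(rng, n=80, p=20, k=3, noise=0.05)
        df = df - df.mean()  # the model has no mean term; center like PCA
        model = factors.fit_factor_model({"v": df}, k=3, max_iter=500, seed=0, scale=False)
        U = np.linalg.svd(df.to_numpy(), full_matrices=False)[0][:, :3]
        Q, _ = np.linalg.qr(model.Z.reindex(df.index).to_numpy())
        principal_cos = np.linalg.svd(U.T @ Q)[1]
        assert np.arccos(np.clip(principal_cos.min(), -1, 1)) < 1e-3


class TestVarianceExplained:
    def test_exact_rank_one_view_gives_unit_r2(self, rng):
        z = rng.normal(size=(40, 1))
        w = rng.normal(size=(15, 1))
        df = pd.DataFrame(z @ w.T, index=[f"s{i}" for i in range(40)])
        model = factors.fit_factor_model({"v": df}, k=2, max_iter=300, seed=0, scale=False)
        assert model.R2["v"].max() > 0.999

    def test_zero_loading_factor_has_zero_r2(self, rng):
        # a factor with all-zero loadings explains exactly nothing
        Z = pd.DataFrame(rng.normal(size=(20, 2)), index=[f"s{i}" for i in range(20)], columns=["LF1", "LF2"])
        W = pd.DataFrame({"LF1": rng.normal(size=6), "LF2": np.zeros(6)}, index=[f"f{j}" for j in range(6)])
        X = pd.DataFrame(Z["LF1"].to_numpy()[:, None] * W["LF1"].to_numpy(), index=Z.index, columns=W.index)
        model = factors.FactorModel(Z=Z, W={"v": W}, tau={}, alpha={}, R2=pd.DataFrame(), X_scaled={"v": X})
        r2 = factors.variance_explained(model)
        assert r2.loc["LF2", "v"] == pytest.approx(0.0, abs=1e-12)
        assert r2.loc["LF1", "v"] == pytest.approx(1.0, abs=1e-12)

    def test_orthogonalized_factors_are_additive(self, rng):
        # with exactly orthogonal score columns, per-factor R2 sums to at
        # most the total R2 of the joint fit (<= 1)
        df, _, _ = _complete_view(rng, k=3, noise=0.3)
        model = factors.fit_factor_model({"v": df}, k=3, max_iter=300, seed=0)
        X = model.X_scaled["v"].to_numpy()
        Q, _ = np.linalg.qr(model.Z.to_numpy())
        ss = (X**2).sum()
        total = 0.0
        for j in range(Q.shape[1]):
            z = Q[:, j : j + 1]
            w = z.T @ X  # least-squares loading for a unit-norm score
            total += 1.0 - ((X - z @ w) ** 2).sum() / ss
        assert total <= 1.0 + 1e-6


class TestDiscriminativeFactor:
    def test_factor_equal_to_label_has_unit_auc(self, rng):
        y = pd.Series([0] * 20 + [1] * 20, index=[f"s{i}" for i in range(40)])
        Z = pd.DataFrame({"LF1": y.astype(float), "LF2": rng.normal(size=40)}, index=y.index)
        model = factors.FactorModel(Z=Z, W={}, tau={}, alpha={}, R2=pd.DataFrame())
        disc = factors.discriminative_factor(model, y)
        assert disc.factor == "LF1"
        assert disc.auc == 1.0

    def test_permuted_labels_give_chance_auc(self, rng):
        y = pd.Series([0] * 30 + [1] * 30, index=[f"s{i}" for i in range(60)])
        Z = pd.DataFrame(rng.normal(size=(60, 4)), index=y.index, columns=[f"LF{i+1}" for i in range(4)])
        model = factors.FactorModel(Z=Z, W={}, tau={}, alpha={}, R2=pd.DataFrame())
        aucs = []
        for _ in range(200):
            perm = pd.Series(rng.permutation(y.to_numpy()), index=y.index)
            aucs.append(factors.discriminative_factor(model, perm).auc)
        # argmax over 4 factors inflates above 0.5; median stays near chance
        assert 0.5 <= float(np.median(aucs)) < 0.65

    def test_group_shifted_factor_is_selected(self):
        spec = synthio.CohortSpec(seed=13)
        truth = synthio.plan_truth(
            spec, {"CRT": 30, "plasma": 30, "urine": 30}, n_dems=0, n_biomarkers=0,
            k_factors=3, factor_group_shift=[2.0, 0.0, 0.0], loading_scale=1.0,
        )
        views, meta, _ = synthio.generate_views(spec, truth, noise_sd=0.5, missing_rate=0.0)
        logged = {v: np.log2(df.dropna(how="all")) for v, df in views.items()}
        model = factors.fit_factor_model(logged, k=4, max_iter=500, seed=0)
        disc = factors.discriminative_factor(model, meta["group"])
        # the chosen factor must track the true group-shifted factor, not the
        # group-independent ones
        Z_true = synthio.substream(spec.seed, "views").normal(size=(63, 3))
        Z_true[:, 0] += 2.0 * meta["group"].to_numpy()
        chosen = model.Z[disc.factor].reindex(meta.index).to_numpy()
        corr = [abs(np.corrcoef(Z_true[:, j], chosen)[0, 1]) for j in range(3)]
        assert np.argmax(corr) == 0
        assert disc.auc > 0.75


class TestTopWeights:
    def _model(self, weights):
        W = pd.DataFrame({"LF1": weights}, index=list("abcdefgh"[: len(weights)]))
        Z = pd.DataFrame({"LF1": [0.0]}, index=["s0"])
        return factors.FactorModel(Z=Z, W={"v": W}, tau={}, alpha={}, R2=pd.DataFrame())

    def test_ranked_by_absolute_weight(self):
        out = factors.top_weights(self._model([0.1, -0.5, 0.3]), "LF1")
        assert list(out.index) == ["b", "c", "a"]

    def test_ties_break_lexicographically(self):
        out = factors.top_weights(self._model([0.5, -0.5]), "LF1")
        assert list(out.index) == ["a", "b"]

    def test_planted_top_loading_feature_ranks_first(self):
        hits = 0
        for seed in range(30):
            spec = synthio.CohortSpec(n_total=63, n_case=19, view_coverage={"v": 63}, seed=seed)
            truth = synthio.plan_truth(
                spec, {"v": 30}, n_dems=1, n_biomarkers=1, biomarker_log2fc=0.5,
                biomarker_module_loading=2.5, loading_scale=0.5, k_factors=2,
            )
            views, meta, _ = synthio.generate_views(spec, truth, noise_sd=0.5, missing_rate=0.0)
            model = factors.fit_factor_model({"v": np.log2(views["v"])}, k=3, max_iter=200, seed=seed)
            # the factor carrying the module is the one with the top R2
            ranked = factors.top_weights(model, model.R2.sum(axis=1).idxmax(), "v")
            hits += ranked.index[0] == truth.biomarker_ids["v"][0]
        assert hits >= 27  # >0.9 recovery probability
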