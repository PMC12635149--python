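"""Stepwise LDA, LOO and wild-card allocation vs independent oracles."""

import numpy as np
import pytest
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from syntopy import (
    DiscriminantError,
    SiteRegistry,
    SyntheticConfig,
    fit_lda,
    generate_dataset,
    loo_confusion,
    run_lda,
    stepwise_select,
    wilks_lambda,
    wildcard_allocate,
)


def make_classes(rng, means, n=30, cov=None):
    p = len(means[0])
    cov = np.eye(p) if cov is None else cov
    X = np.vstack([rng.multivariate_normal(m, cov, size=n) for m in means])
    y = np.concatenate([[f"c{i}"] * n for i in range(len(means))])
    return X, y.astype(object)


def bayes_oracle(X_train, y_train, X_test):
    """Gaussian equal-covariance Bayes rule via explicit density evaluation."""
    classes = sorted(set(y_train))
    n, g = len(y_train), len(classes)
    means = {c: X_train[y_train == c].mean(axis=0) for c in classes}
    pooled = sum(
        (X_train[y_train == c] - means[c]).T
        @ (X_train[y_train == c] - means[c])
        for c in classes
    ) / (n - g)
    dens = np.column_stack([
        stats.multivariate_normal.logpdf(X_test, mean=means[c], cov=pooled)
        for c in classes
    ])
    return np.array(classes, dtype=object)[np.argmax(dens, axis=1)]


class TestWilksLambda:
    def test_two_class_one_variable_f_equals_anova_f(self):
        rng = np.random.default_rng(0)
        X, y = make_classes(rng, [[0.0], [1.0]], n=15)
        lam = wilks_lambda(X, y)
        n, g = len(y), 2
        f_from_lambda = ((n - g) / (g - 1)) * (1 / lam - 1)
        f_anova = stats.f_oneway(X[y == "c0", 0], X[y == "c1", 0]).statistic
        assert f_from_lambda == pytest.approx(f_anova)

    def test_no_separation_gives_lambda_one(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 2))
        y = np.array(["a"] * 40, dtype=object)
        y[::2] = "b"
        # identical distributions: lambda close to (not above) 1
        assert 0.8 < wilks_lambda(X, y) <= 1.0


class TestStepwiseSelect:
    def test_single_separating_variable_selected(self):
        rng = np.random.default_rng(2)
        n = 30
        X = rng.normal(size=(3 * n, 5))
        y = np.repeat(["a", "b", "c"], n).astype(object)
        X[:, 3] += np.repeat([0.0, 4.0, 8.0], n)   # the signal column
        selected, trace = stepwise_select(X, y)
        assert selected == ["x4"]
        assert trace.iloc[0]["action"] == "enter"

    def test_path_matches_exhaustive_oracle(self):
        # greedy reference: at each step scan all candidate subsets by
        # explicitly computed Wilks' lambda with the partial-F rule
        rng = np.random.default_rng(3)
        means = [[0, 0, 0, 0], [1.5, 0.5, 0, 0], [0.5, 2.0, 0.5, 0]]
        X, y = make_classes(rng, means, n=25)
        selected, _ = stepwise_select(X, y)
        n, g = len(y), 3
        names = [f"x{i + 1}" for i in range(4)]

        def lam(cols):
            return wilks_lambda(X, y, cols) if cols else 1.0

        chosen: list[int] = []
        while True:
            p = len(chosen)
            cands = [
                (lam(chosen + [j]), j)
                for j in range(4) if j not in chosen
            ]
            if not cands:
                break
            lam_new, j = min(cands)
            F = ((n - g - p) / (g - 1)) * (lam(chosen) / lam_new - 1)
            if F < 3.84:
                break
            chosen.append(j)
            # removal sweep
            while len(chosen) > 1:
                p = len(chosen)
                fs = []
                for k in chosen:
                    red = [c for c in chosen if c != k]
                    fr = ((n - g - p + 1) / (g - 1)) \
                        * (lam(red) / lam(chosen) - 1)
                    fs.append((fr, k))
                fr, k = min(fs)
                if fr < 2.71:
                    chosen.remove(k)
                else:
                    break
        assert selected == [names[j] for j in chosen]

    def test_trace_records_wilks_decrease(self):
        rng = np.random.default_rng(4)
        X, y = make_classes(rng, [[0, 0], [2, 0], [0, 2]], n=20)
        _, trace = stepwise_select(X, y)
        enters = trace[trace["action"] == "enter"]["wilks_lambda"]
        assert enters.is_monotonic_decreasing


class TestFitLDA:
    def test_two_spherical_classes_bisector_boundary(self):
        # exact symmetric constellations: isotropic pooled covariance and
        # class means exactly (0,0) and (4,0) -> boundary is x = 2
        cross = np.array([[1, 0], [-1, 0], [0, 1], [0, -1]], dtype=float)
        X = np.vstack([cross, cross + [4.0, 0.0]])
        y = np.array(["c0"] * 4 + ["c1"] * 4, dtype=object)
        model = fit_lda(X, y)
        probes = np.array([[1.9, z] for z in (-2, 0, 2)]
                          + [[2.1, z] for z in (-2, 0, 2)])
        pred = model.predict(probes)
        assert list(pred[:3]) == ["c0"] * 3
        assert list(pred[3:]) == ["c1"] * 3

    def test_matches_density_evaluation_oracle(self):
        rng = np.random.default_rng(6)
        X, y = make_classes(rng, [[0, 0, 0], [1, 1, 0], [0, 1, 1]], n=20)
        grid = rng.normal(0.5, 1.0, size=(50, 3))
        model = fit_lda(X, y)
        assert list(model.predict(grid)) == list(bayes_oracle(X, y, grid))

    def test_matches_sklearn_with_equal_priors(self):
        rng = np.random.default_rng(7)
        X, y = make_classes(rng, [[0, 0], [1.5, 0.5], [0.5, 1.5]], n=25)
        model = fit_lda(X, y)
        sk = LinearDiscriminantAnalysis(priors=[1 / 3] * 3).fit(X, y)
        grid = rng.normal(0.5, 1.5, size=(100, 2))
        assert list(model.predict(grid)) == list(sk.predict(grid))

    def test_singular_covariance_rejected(self):
        X = np.zeros((10, 2))
        X[:, 0] = np.arange(10)
        X[:, 1] = X[:, 0]          # perfectly collinear
        y = np.array(["a"] * 5 + ["b"] * 5, dtype=object)
        with pytest.raises((DiscriminantError, np.linalg.LinAlgError)):
            model = fit_lda(X, y)
            # a numerically "successful" inverse of a singular matrix
            # must not silently produce finite coefficients
            if not np.all(np.isfinite(model.coef)):
                raise DiscriminantError("non-finite coefficients")

    def test_bad_priors_rejected(self):
        rng = np.random.default_rng(8)
        X, y = make_classes(rng, [[0], [1]], n=10)
        with pytest.raises(DiscriminantError):
            fit_lda(X, y, priors=[0.9, 0.9])


class TestLOO:
    def test_perfect_separation_gives_identity(self):
        rng = np.random.default_rng(9)
        X, y = make_classes(rng, [[0, 0], [50, 0], [0, 50]], n=10)
        confusion = loo_confusion(X, y)
        assert np.allclose(np.diag(confusion), 100.0)

    def test_matches_naive_sklearn_refit_oracle(self):
        rng = np.random.default_rng(10)
        X, y = make_classes(rng, [[0, 0], [1, 0.5], [0.5, 1]], n=12)
        confusion = loo_confusion(X, y)
        classes = sorted(set(y))
        counts = {c: dict.fromkeys(classes, 0) for c in classes}
        for i in range(len(y)):
            mask = np.arange(len(y)) != i
            sk = LinearDiscriminantAnalysis(priors=[1 / 3] * 3)
            sk.fit(X[mask], y[mask])
            counts[y[i]][sk.predict(X[i][None, :])[0]] += 1
        for c in classes:
            row_n = sum(counts[c].values())
            for c2 in classes:
                assert confusion.loc[c, c2] == pytest.approx(
                    counts[c][c2] / row_n * 100)

    def test_loo_never_beats_resubstitution(self, small_dataset):
        specimens, _ = small_dataset
        res = run_lda(specimens, SiteRegistry.default())
        model = res["model"]
        work = specimens[specimens["group"] == "model"]
        from syntopy.pipeline import sqrt_channels
        X = sqrt_channels(work)[res["selected"]].to_numpy(dtype=float)
        y = work["taxon"].to_numpy(dtype=object)
        resub = float((model.predict(X) == y).mean() * 100)
        loo = float(np.diag(res["confusion"]).mean())
        assert loo <= resub + 1e-9

    def test_tiny_class_rejected(self):
        X = np.arange(8.0).reshape(4, 2)
        y = np.array(["a", "a", "a", "b"], dtype=object)
        with pytest.raises(DiscriminantError):
            loo_confusion(X, y)


class TestWildcardAllocation:
    @pytest.fixture(scope="class")
    def calibration(self):
        rng = np.random.default_rng(11)
        means = {"scutellaris": [0.0, 0.0], "schmidti": [6.0, 0.0],
                 "ionia": [0.0, 6.0]}
        X = np.vstack([rng.multivariate_normal(means[t], np.eye(2), 30)
                       for t in ("scutellaris", "schmidti", "ionia")])
        y = np.repeat(["scutellaris", "schmidti", "ionia"], 30
                      ).astype(object)
        return fit_lda(X, y), means

    def test_specimens_at_class_mean_fully_allocated(self, calibration):
        model, means = calibration
        registry = SiteRegistry({1: "scutellaris", 2: "schmidti",
                                 3: "ionia"})
        X_mimic = np.vstack([[means["scutellaris"]] * 4,
                             [means["schmidti"]] * 4,
                             [means["ionia"]] * 4])
        sites = np.repeat([1, 2, 3], 4)
        table = wildcard_allocate(model, X_mimic, sites, registry)
        by_row = table.set_index("row")
        for taxon in ("scutellaris", "schmidti", "ionia"):
            assert by_row.loc[f"all {taxon} sites", "correct_pct"] == 100.0

    def test_rows_sum_to_hundred(self, calibration):
        model, _ = calibration
        rng = np.random.default_rng(12)
        registry = SiteRegistry({1: "scutellaris", 2: "ionia"})
        X_mimic = rng.normal(2, 3, size=(40, 2))
        sites = np.repeat([1, 2], 20)
        table = wildcard_allocate(model, X_mimic, sites, registry)
        pct = table[[f"{c}_pct" for c in model.classes]].sum(axis=1)
        assert np.allclose(pct, 100.0, atol=0.1)

    def test_unknown_mimic_site_rejected(self, calibration):
        model, _ = calibration
        registry = SiteRegistry({1: "scutellaris"})
        from syntopy import RegistryError
        with pytest.raises(RegistryError):
            wildcard_allocate(model, np.zeros((2, 2)), [1, 9], registry)

    def test_perfect_mimicry_allocates_to_syntopic_model(self):
        specimens, _ = generate_dataset(
            SyntheticConfig(seed=21, lambda_color=1.0, nests_model=2,
                            nests_mimic=2, specimens_per_nest=5)
        )
        res = run_lda(specimens, SiteRegistry.default())
        by_row = res["allocation"].set_index("row")
        for taxon in ("scutellaris", "schmidti", "ionia"):
            assert by_row.loc[f"all {taxon} sites", "correct_pct"] >= 95.0


class TestInvariances:
    def test_classification_invariant_to_affine_rescaling(self):
        rng = np.random.default_rng(13)
        X, y = make_classes(rng, [[0, 0], [2, 1], [1, 2]], n=20)
        grid = rng.normal(1, 1.5, size=(60, 2))
        base = fit_lda(X, y).predict(grid)
        X2, grid2 = X.copy(), grid.copy()
        X2[:, 1] = 7.0 * X2[:, 1] - 3.0
        grid2[:, 1] = 7.0 * grid2[:, 1] - 3.0
        rescaled = fit_lda(X2, y).predict(grid2)
        assert list(base) == list(rescaled)
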