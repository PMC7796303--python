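"""Forward-LDA selection, plateau rule and GA-PLS subset search."""

import numpy as np
import pytest
from sklearn.cross_decomposition import PLSRegression
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from sfqsar import (
    SyntheticSpec,
    forward_select_lda,
    ga_pls_select,
    generate_classification_fixture,
    generate_regression_fixture,
    select_plateau,
)
from sfqsar.selection import _PLS, _bootstrap_indices, _lda_bootstrap_fitness, point_biserial


@pytest.fixture(scope="module")
def separating_matrix():
    """200×20 noise with one perfectly separating descriptor planted."""
    rng = np.random.default_rng(5)
    x = rng.standard_normal((200, 20))
    labels = rng.integers(0, 2, 200)
    x[:, 13] = labels * 4.0 + rng.uniform(-1, 1, 200)  # no class overlap
    names = [f"d{j:02d}" for j in range(20)]
    return x, labels, names


class TestForwardSelection:
    def test_perfect_separator_chosen_first(self, separating_matrix):
        x, labels, names = separating_matrix
        res = forward_select_lda(x, labels, names, max_features=3,
                                 n_boot=10, seed=0)
        assert res.ordered_features[0] == "d13"
        # brute force: evaluate every single-descriptor LDA fit
        accs = []
        for j in range(20):
            clf = LinearDiscriminantAnalysis().fit(x[:, [j]], labels)
            accs.append(np.mean(clf.predict(x[:, [j]]) == labels))
        assert names[int(np.argmax(accs))] == "d13"

    def test_first_pick_matches_correlation_scan(self, separating_matrix):
        x, labels, names = separating_matrix
        res = forward_select_lda(x, labels, names, max_features=2,
                                 n_boot=5, seed=1)
        oracle = names[int(np.argmax(point_biserial(x, labels)))]
        assert res.ordered_features[0] == oracle

    def test_identical_columns_tie_break(self):
        rng = np.random.default_rng(2)
        labels = rng.integers(0, 2, 80)
        informative = labels * 2.0 + rng.normal(0, 0.5, 80)
        x = np.column_stack([informative, informative, rng.standard_normal(80)])
        res = forward_select_lda(x, labels, ["b_dup", "a_dup", "noise"],
                                 max_features=2, n_boot=5, seed=0)
        assert res.ordered_features[0] == "a_dup"  # name-sorted first

    def test_trace_length_and_determinism(self, separating_matrix):
        x, labels, names = separating_matrix
        r1 = forward_select_lda(x, labels, names, max_features=4,
                                n_boot=8, seed=3)
        r2 = forward_select_lda(x, labels, names, max_features=4,
                                n_boot=8, seed=3)
        assert len(r1.fitness_trace) == 4
        assert r1.ordered_features == r2.ordered_features
        assert r1.fitness_trace == r2.fitness_trace

    def test_second_step_matches_brute_force(self, separating_matrix):
        """The added descriptor equals an exhaustive scan under the same
        bootstrap draws (paired-resample contract)."""
        x, labels, names = separating_matrix
        seed, n_boot = 7, 6
        res = forward_select_lda(x, labels, names, max_features=2,
                                 n_boot=n_boot, seed=seed)
        first = names.index(res.ordered_features[0])
        rng = np.random.default_rng(seed)
        _bootstrap_indices(len(labels), n_boot, rng)  # draw 0: seeding trace
        draws = _bootstrap_indices(len(labels), n_boot, rng)
        fits = {}
        for j in sorted(range(20), key=lambda j: names[j]):
            if j == first:
                continue
            fits[j] = _lda_bootstrap_fitness(x[:, [first, j]], labels, draws)
        best = max(fits, key=lambda j: fits[j])
        assert res.ordered_features[1] == names[best]

    def test_errors(self, separating_matrix):
        x, labels, names = separating_matrix
        with pytest.raises(ValueError):
            forward_select_lda(x, np.zeros(200, dtype=int), names)
        with pytest.raises(ValueError):
            forward_select_lda(x, labels, names, max_features=21)


class TestPlateau:
    @pytest.mark.parametrize(
        "trace,tol,expected",
        [
            ((0.5, 0.7, 0.80, 0.805, 0.802), 0.01, 3),
            ((0.1, 0.3, 0.5, 0.7), 0.01, 4),  # strictly increasing
            ((0.6, 0.6, 0.6), 0.01, 1),  # constant
            ((0.9,), 0.05, 1),
        ],
    )
    def test_cases(self, trace, tol, expected):
        assert select_plateau(trace, tol) == expected

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            select_plateau([], 0.01)


class TestPlsKernel:
    def test_matches_sklearn(self):
        rng = np.random.default_rng(8)
        x = rng.standard_normal((60, 7))
        y = x[:, :3] @ np.array([1.0, -2.0, 0.5]) + rng.normal(0, 0.2, 60)
        for c in (1, 2, 4):
            ours = _PLS(c).fit(x, y).predict(x)
            ref = PLSRegression(n_components=c).fit(x, y).predict(x).ravel()
            np.testing.assert_allclose(ours, ref, atol=1e-8)

    def test_path_consistent(self):
        rng = np.random.default_rng(9)
        x = rng.standard_normal((40, 5))
        y = rng.standard_normal(40)
        m = _PLS(4).fit(x, y)
        path = m.predict_path(x)
        for c in range(1, 5):
            np.testing.assert_allclose(path[:, c - 1],
                                       _PLS(c).fit(x, y).predict(x),
                                       atol=1e-10)


class TestGaPls:
    @pytest.fixture(scope="class")
    def small_run(self):
        spec = SyntheticSpec(n=80, n_descriptors=15, n_informative=3,
                             effect_weights=(2.0, 2.0, 2.0),
                             noise_sd=0.3, seed=21)
        m, y = generate_regression_fixture(spec)
        res = ga_pls_select(m.values, y, m.descriptor_names,
                            population=40, generations=8,
                            min_vars=3, max_vars=6, seed=4, n_elites=4)
        return res

    def test_trace_nondecreasing(self, small_run):
        t = small_run.fitness_trace
        assert all(a <= b + 1e-12 for a, b in zip(t, t[1:]))

    def test_subset_sizes_bounded(self, small_run):
        assert all(3 <= len(s) <= 6 for s in small_run.elite_subsets)
        assert 3 <= small_run.chosen_size <= 6

    def test_deterministic(self):
        spec = SyntheticSpec(n=60, n_descriptors=10, n_informative=2,
                             noise_sd=0.2, seed=30)
        m, y = generate_regression_fixture(spec)
        kw = dict(population=20, generations=4, min_vars=2, max_vars=5,
                  seed=11, n_elites=3)
        r1 = ga_pls_select(m.values, y, m.descriptor_names, **kw)
        r2 = ga_pls_select(m.values, y, m.descriptor_names, **kw)
        assert r1.ordered_features == r2.ordered_features
        assert r1.fitness_trace == r2.fitness_trace
        assert r1.elite_subsets == r2.elite_subsets

    def test_planted_subset_recovered(self, small_run):
        planted = {"d000", "d001", "d002"}
        assert planted <= set(small_run.ordered_features)

    def test_errors(self):
        spec = SyntheticSpec(n=50, n_descriptors=8, n_informative=2, seed=1)
        m, y = generate_regression_fixture(spec)
        with pytest.raises(ValueError):
            ga_pls_select(m.values, y, m.descriptor_names, min_vars=6,
                          max_vars=5)
        with pytest.raises(ValueError):
            ga_pls_select(m.values, y, m.descriptor_names, max_vars=9)
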