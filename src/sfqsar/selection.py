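"""Descriptor subset selection for the two model branches.

Classification uses forward selection: the first descriptor is the one
most correlated (absolute point-biserial correlation) with the class
labels; each later iteration adds the descriptor maximizing a bootstrap
cross-validated LDA fitness — the sum of mean accuracy, sensitivity and
specificity over out-of-bag evaluations.  The subset size is then chosen
at the plateau of the fitness trace.

Regression uses a genetic algorithm over descriptor subsets of bounded
size, scored by the cross-validated r² of a PLS regression under
repeated double cross-validation (outer folds assess, inner folds pick
the PLS component count).  The GA uses tournament selection, uniform
membership crossover with size repair, swap mutation and elitism, so the
best-so-far fitness never decreases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .metrics import regression_metrics


@dataclass
class FeatureSelectionResult:
    ordered_features: list[str]
    fitness_trace: list[float]
    chosen_size: int
    method: str  # forward_lda | ga_pls
    seed: int
    elite_subsets: list[list[str]] = field(default_factory=list)
    elite_fitness: list[float] = field(default_factory=list)

    @property
    def selected(self) -> list[str]:
        return self.ordered_features[: self.chosen_size]


# --------------------------------------------------- forward LDA branch

def _bootstrap_indices(n: int, n_boot: int, rng: np.random.Generator):
    """One fixed set of bootstrap resamples, shared by every candidate in
    an iteration so the comparison between descriptors is paired."""
    draws = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), idx)
        draws.append((idx, oob))
    return draws


def _lda_bootstrap_fitness(x: np.ndarray, y: np.ndarray, draws) -> float:
    """Mean accuracy + mean sensitivity + mean specificity over bootstrap
    out-of-bag evaluations; undefined rates in a draw are skipped."""
    accs, sens, specs = [], [], []
    for idx, oob in draws:
        if len(oob) == 0 or len(np.unique(y[idx])) < 2:
            continue
        clf = LinearDiscriminantAnalysis()
        clf.fit(x[idx], y[idx])
        pred = clf.predict(x[oob])
        yo = y[oob]
        accs.append(np.mean(pred == yo))
        if (yo == 1).any():
            sens.append(np.mean(pred[yo == 1] == 1))
        if (yo == 0).any():
            specs.append(np.mean(pred[yo == 0] == 0))
    if not accs:
        return -np.inf
    return float(np.mean(accs) + np.mean(sens) + np.mean(specs))


def point_biserial(x: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Absolute Pearson correlation of each column with the binary labels."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(labels, dtype=float)
    xc = x - x.mean(axis=0)
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum(axis=0) * (yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc * yc[:, None]).sum(axis=0) / denom
    return np.abs(np.nan_to_num(r))


def forward_select_lda(
    values: np.ndarray,
    labels: np.ndarray,
    descriptor_names: list[str],
    max_features: int = 25,
    n_boot: int = 100,
    seed: int = 0,
) -> FeatureSelectionResult:
    """Forward selection with bootstrap-LDA fitness.

    Deterministic under the seed: the bootstrap resamples of an iteration
    are drawn once and reused for every candidate, and ties between
    candidates break toward the name-sorted-first descriptor.
    """
    x = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("labels must contain both classes")
    p = x.shape[1]
    if max_features > p:
        raise ValueError("max_features exceeds available descriptors")

    # candidate scan order = name-sorted, so argmax ties keep the first name
    order = sorted(range(p), key=lambda j: descriptor_names[j])
    rng = np.random.default_rng(seed)

    corr = point_biserial(x, y)
    first = max(order, key=lambda j: (corr[j],))
    # max() keeps the earliest in scan order on exact ties
    best_corr = corr[first]
    for j in order:
        if corr[j] == best_corr:
            first = j
            break

    chosen = [first]
    trace: list[float] = []
    draws = _bootstrap_indices(len(y), n_boot, rng)
    trace.append(_lda_bootstrap_fitness(x[:, chosen], y, draws))

    while len(chosen) < max_features:
        draws = _bootstrap_indices(len(y), n_boot, rng)
        best_j, best_fit = None, -np.inf
        for j in order:
            if j in chosen:
                continue
            fit = _lda_bootstrap_fitness(x[:, chosen + [j]], y, draws)
            if fit > best_fit:
                best_j, best_fit = j, fit
        chosen.append(best_j)
        trace.append(best_fit)

    names = [descriptor_names[j] for j in chosen]
    size = select_plateau(trace, tolerance=0.01)
    return FeatureSelectionResult(
        ordered_features=names,
        fitness_trace=trace,
        chosen_size=size,
        method="forward_lda",
        seed=seed,
    )


def select_plateau(trace, tolerance: float) -> int:
    """Smallest size s whose fitness no later value beats by > tolerance."""
    trace = list(trace)
    if not trace:
        raise ValueError("empty fitness trace")
    for s in range(1, len(trace) + 1):
        if all(later <= trace[s - 1] + tolerance for later in trace[s:]):
            return s
    return len(trace)


# ----------------------------------------------------- GA-PLS branch

class _PLS:
    """Minimal NIPALS PLS1 (fit + predict), matching sklearn's algorithm.

    Used inside the GA fitness loop where sklearn's per-call validation
    overhead dominates; equivalence with PLSRegression is pinned by test.
    """

    def __init__(self, n_components: int):
        self.n_components = n_components

    def fit(self, x: np.ndarray, y: np.ndarray) -> "_PLS":
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        self.x_mean_ = x.mean(axis=0)
        self.x_std_ = x.std(axis=0, ddof=1)
        self.x_std_[self.x_std_ == 0] = 1.0
        self.y_mean_ = y.mean()
        xk = (x - self.x_mean_) / self.x_std_
        yk = y - self.y_mean_
        n, p = xk.shape
        a = min(self.n_components, p, n - 1)
        W = np.zeros((p, a))
        P = np.zeros((p, a))
        Q = np.zeros(a)
        for k in range(a):
            w = xk.T @ yk
            norm = np.linalg.norm(w)
            if norm < 1e-12:
                a = k
                W, P, Q = W[:, :a], P[:, :a], Q[:a]
                break
            w /= norm
            t = xk @ w
            tt = t @ t
            if tt < 1e-12:
                a = k
                W, P, Q = W[:, :a], P[:, :a], Q[:a]
                break
            pvec = xk.T @ t / tt
            q = yk @ t / tt
            xk = xk - np.outer(t, pvec)
            yk = yk - q * t
            W[:, k], P[:, k], Q[k] = w, pvec, q
        if a == 0:
            self.coef_ = np.zeros(p)
            self.coef_path_ = np.zeros((1, p))
        else:
            # coefficient path: predictions for every component count
            # come from a single NIPALS pass (the solve is cheap at a ≤ 5)
            self.coef_path_ = np.stack([
                (W[:, : k + 1] @ np.linalg.solve(
                    P[:, : k + 1].T @ W[:, : k + 1], Q[: k + 1]))
                for k in range(a)
            ])
            self.coef_ = self.coef_path_[-1]
        return self

    def predict(self, x: np.ndarray) -> np.ndarray:
        xs = (np.asarray(x, dtype=float) - self.x_mean_) / self.x_std_
        return xs @ self.coef_ + self.y_mean_

    def predict_path(self, x: np.ndarray) -> np.ndarray:
        """Predictions for every component count 1..a, shape (n, a)."""
        xs = (np.asarray(x, dtype=float) - self.x_mean_) / self.x_std_
        return xs @ self.coef_path_.T + self.y_mean_


def _kfold_indices(n: int, k: int, rng: np.random.Generator):
    perm = rng.permutation(n)
    return np.array_split(perm, k)


def _double_cv_r2(
    x: np.ndarray,
    y: np.ndarray,
    rng: np.random.Generator,
    outer_folds: int,
    inner_folds: int,
    repeats: int,
    max_components: int,
) -> float:
    """Repeated double cross-validation r² of a PLS model on (x, y).

    Inner folds pick the component count for each outer training set;
    outer held-out predictions are pooled into one r² per repeat.
    """
    n = len(y)
    r2s = []
    for _ in range(repeats):
        folds = _kfold_indices(n, outer_folds, rng)
        pooled = np.empty(n)
        for fold in folds:
            tr = np.setdiff1d(np.arange(n), fold)
            xt, yt = x[tr], y[tr]
            a_max = min(max_components, x.shape[1], len(tr) - 2)
            inner = _kfold_indices(len(tr), inner_folds, rng)
            press = np.zeros(a_max)
            for ifold in inner:
                itr = np.setdiff1d(np.arange(len(tr)), ifold)
                m = _PLS(a_max).fit(xt[itr], yt[itr])
                path = m.predict_path(xt[ifold])  # (n_val, a_fit)
                resid = path - yt[ifold, None]
                sq = (resid**2).sum(axis=0)
                press[: len(sq)] += sq
                if len(sq) < a_max:  # rank-deficient fold: reuse last
                    press[len(sq):] += sq[-1]
            best_c = int(np.argmin(press)) + 1
            m = _PLS(best_c).fit(xt, yt)
            pooled[fold] = m.predict(x[fold])
        r2s.append(regression_metrics(y, pooled)["r2"])
    return float(np.mean(r2s))


def _repair_size(subset: set, pool: range, min_vars: int, max_vars: int,
                 rng: np.random.Generator) -> frozenset:
    subset = set(subset)
    while len(subset) < min_vars:
        subset.add(int(rng.choice(np.setdiff1d(np.arange(pool.stop), list(subset)))))
    while len(subset) > max_vars:
        subset.discard(int(rng.choice(sorted(subset))))
    return frozenset(subset)


def ga_pls_select(
    values: np.ndarray,
    y: np.ndarray,
    descriptor_names: list[str],
    population: int = 2000,
    generations: int = 5000,
    min_vars: int = 5,
    max_vars: int = 12,
    seed: int = 0,
    n_elites: int = 10,
    tournament: int = 3,
    mutation_rate: float = 0.1,
    outer_folds: int = 4,
    inner_folds: int = 3,
    repeats: int = 1,
    max_components: int = 5,
) -> FeatureSelectionResult:
    """GA search over descriptor subsets scored by double-CV PLS r².

    Chromosomes are subsets with size in [min_vars, max_vars]; crossover
    and mutation repair sizes back into range.  Fitness of a subset is
    evaluated once (seeded by the subset itself for reproducibility) and
    memoized.  Returns the ``n_elites`` best distinct subsets and the
    non-decreasing best-so-far trace.
    """
    x = np.asarray(values, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    p = x.shape[1]
    if min_vars > max_vars:
        raise ValueError("min_vars > max_vars")
    if max_vars > p:
        raise ValueError("max_vars exceeds descriptor count")
    if len(y) < 2 * max_vars:
        raise ValueError("too few compounds for the subset size bound")

    rng = np.random.default_rng(seed)
    cache: dict[frozenset, float] = {}

    def fitness(subset: frozenset) -> float:
        if subset not in cache:
            cols = sorted(subset)
            # per-subset deterministic CV seed, independent of visit order
            sub_seed = (hash(subset) ^ seed) & 0x7FFFFFFF
            sub_rng = np.random.default_rng(sub_seed)
            cache[subset] = _double_cv_r2(
                x[:, cols], y, sub_rng, outer_folds, inner_folds,
                repeats, max_components,
            )
        return cache[subset]

    def random_subset() -> frozenset:
        size = int(rng.integers(min_vars, max_vars + 1))
        return frozenset(rng.choice(p, size=size, replace=False).tolist())

    pop = [random_subset() for _ in range(population)]
    fits = [fitness(s) for s in pop]
    trace: list[float] = []
    best_sub, best_fit = pop[int(np.argmax(fits))], max(fits)

    for _ in range(generations):
        ranked = sorted(zip(fits, range(len(pop))), reverse=True)
        elite_idx = []
        seen = set()
        for _, i in ranked:
            if pop[i] not in seen:
                seen.add(pop[i])
                elite_idx.append(i)
            if len(elite_idx) == n_elites:
                break
        next_pop = [pop[i] for i in elite_idx]

        def pick() -> frozenset:
            contenders = rng.integers(0, len(pop), size=tournament)
            return pop[max(contenders, key=lambda i: fits[i])]

        while len(next_pop) < population:
            a, b = pick(), pick()
            union = sorted(a | b)
            child = {g for g in union
                     if (g in a and g in b) or rng.random() < 0.5}
            child = _repair_size(child, range(p), min_vars, max_vars, rng)
            if rng.random() < mutation_rate:
                outside = np.setdiff1d(np.arange(p), sorted(child))
                if len(outside):
                    child = set(child)
                    child.discard(int(rng.choice(sorted(child))))
                    child.add(int(rng.choice(outside)))
                    child = frozenset(child)
            next_pop.append(frozenset(child))

        pop = next_pop
        fits = [fitness(s) for s in pop]
        gen_best = int(np.argmax(fits))
        if fits[gen_best] > best_fit:
            best_fit, best_sub = fits[gen_best], pop[gen_best]
        trace.append(best_fit)

    ranked = sorted(cache.items(), key=lambda kv: -kv[1])
    elites = ranked[:n_elites]
    return FeatureSelectionResult(
        ordered_features=[descriptor_names[j] for j in sorted(best_sub)],
        fitness_trace=trace,
        chosen_size=len(best_sub),
        method="ga_pls",
        seed=seed,
        elite_subsets=[[descriptor_names[j] for j in sorted(s)]
                       for s, _ in elites],
        elite_fitness=[f for _, f in elites],
    )
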