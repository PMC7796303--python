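"""Final learners: a cost-complexity-pruned CART classifier and an MLP
regressor trained with resilient backpropagation (RPROP).

The classification tree is grown on Gini impurity (minimum leaf size 5)
and pruned by cost-complexity with 10-fold internal cross-validation
under the 1-SE rule, so the final tree typically uses fewer descriptors
than it was given.

The regression network has one hidden layer of 10 logistic-sigmoid
units and a linear output.  Inputs are min-max scaled to [0, 1] with
bounds taken from the training set and stored in the model; targets are
raw log10 slope factors.  Training is full-batch RPROP⁻ (no weight
backtracking): each weight keeps its own step size, multiplied by η⁺=1.2
when the gradient keeps its sign and by η⁻=0.5 when it flips, clipped to
[Δmin, Δmax] = [1e-6, 50], starting from Δ₀=0.1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier


# ---------------------------------------------------------------- CART

@dataclass
class CartNode:
    # internal node: feature + threshold + children; leaf: class + proportions
    feature: str | None = None
    threshold: float | None = None
    left: int | None = None
    right: int | None = None
    leaf_class: int | None = None
    proportions: tuple[float, float] | None = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None


@dataclass
class CartModel:
    feature_names: list[str]
    nodes: list[CartNode]
    complexity_trace: list[dict] = field(default_factory=list)
    seed: int | None = None

    @property
    def used_descriptors(self) -> set[str]:
        return {n.feature for n in self.nodes if not n.is_leaf}

    def to_json(self) -> str:
        return json.dumps(
            {
                "schema": "sfqsar.cart.v1",
                "feature_names": self.feature_names,
                "seed": self.seed,
                "nodes": [
                    {
                        "feature": n.feature,
                        "threshold": n.threshold,
                        "left": n.left,
                        "right": n.right,
                        "leaf_class": n.leaf_class,
                        "proportions": n.proportions,
                    }
                    for n in self.nodes
                ],
                "complexity_trace": self.complexity_trace,
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "CartModel":
        obj = json.loads(text)
        nodes = [
            CartNode(
                feature=d["feature"],
                threshold=d["threshold"],
                left=d["left"],
                right=d["right"],
                leaf_class=d["leaf_class"],
                proportions=None if d["proportions"] is None
                else tuple(d["proportions"]),
            )
            for d in obj["nodes"]
        ]
        return cls(feature_names=obj["feature_names"], nodes=nodes,
                   complexity_trace=obj["complexity_trace"], seed=obj["seed"])


def _prune_sequence(tree) -> list[tuple[float, frozenset]]:
    """Weakest-link cost-complexity pruning on misclassification risk.

    Returns the nested sequence [(alpha_k, pruned_internal_nodes)] with
    alpha_0 = 0 (full tree) up to the root-only tree.  Risk of a node is
    its misclassified sample fraction if collapsed to a leaf; the weakest
    link minimizes g = (R(node) − R(subtree)) / (leaves − 1).  Splits
    whose children agree with the parent majority have g = 0 and collapse
    immediately, which is what lets noise-grown trees fall to the root.
    """
    t = tree.tree_
    counts = t.value * t.weighted_n_node_samples[:, None, None]
    total = t.weighted_n_node_samples[0]
    r_node = (t.weighted_n_node_samples - counts[:, 0, :].max(axis=1)) / total
    left, right = t.children_left, t.children_right
    depth = np.zeros(t.node_count, dtype=int)
    for i in range(t.node_count):
        if left[i] != -1:
            depth[left[i]] = depth[i] + 1
            depth[right[i]] = depth[i] + 1
    bottom_up = np.argsort(-depth)

    pruned = np.zeros(t.node_count, dtype=bool)
    pruned[left == -1] = True
    seq: list[tuple[float, frozenset]] = [(0.0, frozenset())]
    collapsed: set[int] = set()
    while not pruned[0]:
        r_sub = r_node.copy()
        n_leaves = np.ones(t.node_count, dtype=int)
        for i in bottom_up:
            if left[i] != -1 and not pruned[i]:
                r_sub[i] = r_sub[left[i]] + r_sub[right[i]]
                n_leaves[i] = n_leaves[left[i]] + n_leaves[right[i]]
        best_g, weakest = np.inf, []
        for i in range(t.node_count):
            if left[i] != -1 and not pruned[i]:
                g = (r_node[i] - r_sub[i]) / (n_leaves[i] - 1)
                if g < best_g - 1e-12:
                    best_g, weakest = g, [i]
                elif g <= best_g + 1e-12:
                    weakest.append(i)
        for i in weakest:
            stack = [i]
            while stack:
                j = stack.pop()
                if not pruned[j] and left[j] != -1:
                    stack.extend((left[j], right[j]))
                pruned[j] = True
                if left[j] != -1:
                    collapsed.add(j)
        seq.append((max(best_g, 0.0), frozenset(collapsed)))
    return seq


def _subtree_at(seq: list[tuple[float, frozenset]], beta: float) -> frozenset:
    chosen: frozenset = frozenset()
    for alpha, pruned in seq:
        if alpha <= beta:
            chosen = pruned
        else:
            break
    return chosen


def _predict_sk(tree, pruned: frozenset, x: np.ndarray) -> np.ndarray:
    t = tree.tree_
    out = np.empty(len(x), dtype=int)
    for i, row in enumerate(x):
        node = 0
        while t.children_left[node] != -1 and node not in pruned:
            node = (t.children_left[node]
                    if row[t.feature[node]] <= t.threshold[node]
                    else t.children_right[node])
        out[i] = int(np.argmax(t.value[node][0]))
    return out


def _tree_to_nodes(tree, pruned: frozenset,
                   feature_names: list[str]) -> list[CartNode]:
    """Flatten the pruned sklearn tree into the portable node list."""
    t = tree.tree_
    index: dict[int, int] = {}
    nodes: list[CartNode] = []

    def visit(i: int) -> int:
        counts = t.value[i][0]
        props = (float(counts[0] / counts.sum()),
                 float(counts[1] / counts.sum()))
        pos = len(nodes)
        index[i] = pos
        if t.children_left[i] == -1 or i in pruned:
            nodes.append(CartNode(leaf_class=int(np.argmax(counts)),
                                  proportions=props))
            return pos
        nodes.append(CartNode(
            feature=feature_names[t.feature[i]],
            threshold=float(t.threshold[i]),
            proportions=props,
        ))
        nodes[pos].left = visit(t.children_left[i])
        nodes[pos].right = visit(t.children_right[i])
        return pos

    visit(0)
    return nodes


def fit_cart(
    values: np.ndarray,
    labels: np.ndarray,
    feature_names: list[str],
    seed: int = 0,
    min_leaf: int = 5,
    min_split: int = 20,
    cv_folds: int = 10,
    cv_repeats: int = 5,
) -> CartModel:
    """Grow a Gini tree, prune by misclassification-risk cost-complexity
    with repeated 10-fold internal CV and the 1-SE rule.

    Candidate pruning strengths are the geometric midpoints of the grown
    tree's weakest-link alpha sequence plus a guaranteed root-only
    candidate.  Each is scored by pooled cross-validated misclassification
    error averaged over ``cv_repeats`` fold shufflings; the strongest
    pruning whose error is within one (binomial) standard error of the
    minimum wins, so on signal-free labels the tree usually collapses to
    the root majority rule.
    """
    x = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("need both classes to fit a classification tree")
    n = len(y)

    def grow(xt: np.ndarray, yt: np.ndarray) -> DecisionTreeClassifier:
        return DecisionTreeClassifier(
            criterion="gini", min_samples_leaf=min_leaf,
            min_samples_split=min_split, random_state=seed,
        ).fit(xt, yt)

    master = grow(x, y)
    seq = _prune_sequence(master)
    alphas = np.array([a for a, _ in seq])
    if len(alphas) > 1:
        mids = np.sqrt(np.maximum(alphas[1:], 1e-12)
                       * np.maximum(alphas[:-1], 1e-12))
        betas = np.unique(np.concatenate([[0.0], mids, [np.inf]]))
    else:
        betas = np.array([0.0, np.inf])

    folds = min(cv_folds, int(np.bincount(y).min()), n)
    trace: list[dict] = []
    if folds >= 2 and len(betas) > 1:
        errs = np.zeros((cv_repeats, len(betas)))
        for r in range(cv_repeats):
            skf = StratifiedKFold(n_splits=folds, shuffle=True,
                                  random_state=seed + 9973 * r)
            pooled = np.zeros((len(betas), n), dtype=int)
            for tr, te in skf.split(x, y):
                fold_tree = grow(x[tr], y[tr])
                fold_seq = _prune_sequence(fold_tree)
                for bi, beta in enumerate(betas):
                    pooled[bi, te] = _predict_sk(
                        fold_tree, _subtree_at(fold_seq, beta), x[te]
                    )
            errs[r] = (pooled != y).mean(axis=1)
        err = errs.mean(axis=0)
        best = int(np.argmin(err))
        se = float(np.sqrt(err[best] * (1 - err[best]) / n))
        chosen = float(betas[np.max(np.where(err <= err[best] + se))])
        trace = [{"alpha": float(b), "cv_error": float(e)}
                 for b, e in zip(betas, err)]
    else:
        chosen = 0.0

    pruned = _subtree_at(seq, chosen)
    return CartModel(
        feature_names=list(feature_names),
        nodes=_tree_to_nodes(master, pruned, list(feature_names)),
        complexity_trace=trace,
        seed=seed,
    )


def predict_cart(
    model: CartModel, values: np.ndarray, feature_names: list[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Route each compound to a leaf ("value ≤ threshold goes left").

    Returns predicted classes and the leaf class-1 proportions.
    """
    col = {}
    for f in model.used_descriptors:
        if f not in feature_names:
            raise ValueError(f"missing descriptor column {f!r}")
        col[f] = feature_names.index(f)
    x = np.asarray(values, dtype=float)
    preds = np.empty(len(x), dtype=int)
    probs = np.empty(len(x), dtype=float)
    for i, row in enumerate(x):
        node = model.nodes[0]
        while not node.is_leaf:
            j = col[node.feature]
            node = model.nodes[node.left if row[j] <= node.threshold
                               else node.right]
        preds[i] = node.leaf_class
        probs[i] = node.proportions[1]
    return preds, probs


# ----------------------------------------------------------------- MLP

@dataclass
class MlpModel:
    feature_names: list[str]
    w1: np.ndarray  # (n_inputs, n_hidden)
    b1: np.ndarray  # (n_hidden,)
    w2: np.ndarray  # (n_hidden,)
    b2: float
    norm_min: np.ndarray  # per-descriptor training minimum
    norm_max: np.ndarray
    training_iterations: int = 100
    seed: int | None = None

    @property
    def layer_sizes(self) -> tuple[int, int, int]:
        return (self.w1.shape[0], self.w1.shape[1], 1)

    def to_json(self) -> str:
        return json.dumps(
            {
                "schema": "sfqsar.mlp.v1",
                "feature_names": self.feature_names,
                "w1": self.w1.tolist(),
                "b1": self.b1.tolist(),
                "w2": self.w2.tolist(),
                "b2": self.b2,
                "norm_min": self.norm_min.tolist(),
                "norm_max": self.norm_max.tolist(),
                "training_iterations": self.training_iterations,
                "seed": self.seed,
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "MlpModel":
        o = json.loads(text)
        return cls(
            feature_names=o["feature_names"],
            w1=np.array(o["w1"]), b1=np.array(o["b1"]),
            w2=np.array(o["w2"]), b2=o["b2"],
            norm_min=np.array(o["norm_min"]), norm_max=np.array(o["norm_max"]),
            training_iterations=o["training_iterations"], seed=o["seed"],
        )


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _forward(model_or_params, x01: np.ndarray):
    w1, b1, w2, b2 = model_or_params
    h = _sigmoid(x01 @ w1 + b1)
    return h, h @ w2 + b2


def fit_mlp(
    values: np.ndarray,
    y: np.ndarray,
    feature_names: list[str],
    iterations: int = 100,
    n_hidden: int = 10,
    seed: int = 0,
    eta_plus: float = 1.2,
    eta_minus: float = 0.5,
    delta0: float = 0.1,
    delta_min: float = 1e-6,
    delta_max: float = 50.0,
) -> MlpModel:
    """Train the regression network with full-batch RPROP⁻.

    Gradients of the mean squared error are computed over the whole
    training set each epoch; only their signs drive the update.  Weights
    initialize uniform(−0.5, 0.5) from the seed.
    """
    x = np.asarray(values, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if len(x) < 2:
        raise ValueError("need at least two training compounds")
    lo = x.min(axis=0)
    hi = x.max(axis=0)
    if np.any(hi <= lo):
        bad = [feature_names[j] for j in np.where(hi <= lo)[0]]
        raise ValueError(f"constant descriptor(s) in selected set: {bad}")
    x01 = (x - lo) / (hi - lo)

    rng = np.random.default_rng(seed)
    n_in = x.shape[1]
    params = [
        rng.uniform(-0.5, 0.5, size=(n_in, n_hidden)),
        rng.uniform(-0.5, 0.5, size=n_hidden),
        rng.uniform(-0.5, 0.5, size=n_hidden),
        rng.uniform(-0.5, 0.5),
    ]
    steps = [np.full_like(np.asarray(p, dtype=float), delta0) for p in params]
    prev_grads = [np.zeros_like(np.asarray(p, dtype=float)) for p in params]

    n = len(y)
    for _ in range(iterations):
        w1, b1, w2, b2 = params
        h = _sigmoid(x01 @ w1 + b1)
        yhat = h @ w2 + b2
        err = yhat - y  # d(MSE/2)/d(yhat) up to 1/n
        # backprop
        g_w2 = h.T @ err / n
        g_b2 = float(err.mean())
        dh = np.outer(err, w2) * h * (1 - h)
        g_w1 = x01.T @ dh / n
        g_b1 = dh.mean(axis=0)
        grads = [g_w1, g_b1, g_w2, np.asarray(g_b2)]

        for p in range(4):
            g = np.asarray(grads[p], dtype=float)
            sign_agree = np.sign(g) * np.sign(prev_grads[p])
            steps[p] = np.where(
                sign_agree > 0,
                np.minimum(steps[p] * eta_plus, delta_max),
                np.where(sign_agree < 0,
                         np.maximum(steps[p] * eta_minus, delta_min),
                         steps[p]),
            )
            # RPROP⁻: on sign flip the gradient is zeroed (no update this
            # epoch for that weight) and no backtracking occurs
            effective = np.where(sign_agree < 0, 0.0, g)
            params[p] = params[p] - np.sign(effective) * steps[p]
            prev_grads[p] = effective

    w1, b1, w2, b2 = params
    return MlpModel(
        feature_names=list(feature_names),
        w1=np.asarray(w1), b1=np.asarray(b1),
        w2=np.asarray(w2), b2=float(b2),
        norm_min=lo, norm_max=hi,
        training_iterations=iterations, seed=seed,
    )


def predict_mlp(
    model: MlpModel, values: np.ndarray, feature_names: list[str] | None = None
) -> np.ndarray:
    """Scale with the stored training bounds and run the forward pass.

    Values falling outside [0, 1] after scaling are NOT clipped — such
    compounds are outside the training range and are expected to be
    caught by the applicability domain, not silently squashed here.
    """
    x = np.asarray(values, dtype=float)
    if feature_names is not None and feature_names != model.feature_names:
        idx = [feature_names.index(f) for f in model.feature_names]
        x = x[:, idx]
    x01 = (x - model.norm_min) / (model.norm_max - model.norm_min)
    _, out = _forward((model.w1, model.b1, model.w2, model.b2), x01)
    return out
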