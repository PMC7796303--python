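"""End-to-end orchestration: train both model branches and apply them
hierarchically.

Training runs split → descriptor pruning → feature selection → learner →
applicability domain, and evaluates each subset.  For regression under
split scheme A, one network is trained per elite GA subset; candidates
are ranked by their AD-filtered r² on the test set and the winner is
reported on the external set.  Under scheme B, candidates are ranked by
10-fold cross-validated r² on the training set and reported on the
external set.

Prediction is hierarchical: a compound is first classified; the potency
regressor is applied only to predicted carcinogens, with its
applicability domain flagged per compound.  Out-of-domain potencies are
emitted with a warning flag rather than suppressed, so that downstream
coverage statistics remain computable; evaluation statistics exclude
them as the metrics layer does.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

from . import admodel, learners, metrics, selection, splitting
from .curation import CuratedDataset, log_transform_endpoint
from .descriptors import DescriptorMatrix, compute_descriptors, prune_descriptors
from .splitting import Subset


@dataclass
class PipelineConfig:
    route: str = "oral"  # oral | inhalation
    branch: str = "both"  # classification | regression | both
    split_scheme: str = "A"  # A | B
    seed: int = 0
    # descriptor pruning
    corr_threshold: float = 0.95
    semiconstant_frac: float = 0.95
    # classification branch
    train_frac: float = 0.8
    max_features: int = 25
    n_boot: int = 100
    plateau_tolerance: float = 0.01
    balance: bool = False
    # regression branch
    n_bins: int = 10
    ga_population: int = 2000
    ga_generations: int = 5000
    min_vars: int = 5
    max_vars: int = 12
    n_elites: int = 10
    outer_folds: int = 5
    inner_folds: int = 5
    dcv_repeats: int = 3
    mlp_iterations: int = 100
    cv_folds: int = 10

    @classmethod
    def test_scale(cls, **overrides) -> "PipelineConfig":
        """Reduced search sizes for fast simulation studies; the model
        architecture and split rules are unchanged."""
        cfg = dict(
            ga_population=200, ga_generations=50, n_boot=20,
            max_features=10, outer_folds=4, inner_folds=3, dcv_repeats=1,
            n_elites=5,
        )
        cfg.update(overrides)
        return cls(**cfg)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class HierarchicalPrediction:
    compound_id: str
    predicted_class: str  # carcinogen | non_carcinogen
    potency_log10_sf: float | None = None
    ad_flag: str = "not_applicable"  # inside | outside | not_applicable
    error: str | None = None

    def __post_init__(self) -> None:
        if self.predicted_class == "non_carcinogen" and (
            self.potency_log10_sf is not None
        ):
            raise ValueError("non-carcinogen cannot carry a potency value")


@dataclass
class RegressionArtifacts:
    model: learners.MlpModel
    ad: admodel.AdDefinition
    selection: selection.FeatureSelectionResult
    split: splitting.SplitAssignment
    reports: dict[str, metrics.MetricsReport]
    candidate_scores: list[dict]
    log: list[dict] = field(default_factory=list)


@dataclass
class ClassificationArtifacts:
    model: learners.CartModel
    selection: selection.FeatureSelectionResult
    split: splitting.SplitAssignment
    reports: dict[str, metrics.MetricsReport]
    log: list[dict] = field(default_factory=list)


def _subset_xy(matrix: DescriptorMatrix, y: np.ndarray,
               split: splitting.SplitAssignment, subset: Subset):
    mask = split.mask(matrix.compound_ids, subset)
    return matrix.values[mask], np.asarray(y)[mask]


def train_classification(
    matrix: DescriptorMatrix,
    labels: np.ndarray,
    config: PipelineConfig,
    block_matrix: DescriptorMatrix | None = None,
) -> ClassificationArtifacts:
    """Venetian-blind split, forward-LDA selection at the plateau, CART.

    ``block_matrix`` carries the constitutional+ring descriptors used for
    the PCA ranking; when absent the full matrix stands in (synthetic
    fixtures have no block structure).
    """
    labels = np.asarray(labels, dtype=int)
    log: list[dict] = []
    split = splitting.pca_venetian_split(
        block_matrix if block_matrix is not None else matrix,
        labels, train_frac=config.train_frac,
    )
    log.append({"step": "split", "scheme": split.scheme,
                "n_train": len(split.ids(Subset.TRAIN)),
                "n_test": len(split.ids(Subset.TEST))})

    xt, yt = _subset_xy(matrix, labels, split, Subset.TRAIN)
    sel = selection.forward_select_lda(
        xt, yt, matrix.descriptor_names,
        max_features=min(config.max_features, matrix.shape[1]),
        n_boot=config.n_boot, seed=config.seed,
    )
    sel.chosen_size = selection.select_plateau(
        sel.fitness_trace, config.plateau_tolerance
    )
    log.append({"step": "selection", "method": sel.method,
                "chosen_size": sel.chosen_size,
                "features": sel.selected})

    feat_idx = [matrix.descriptor_names.index(f) for f in sel.selected]
    model = learners.fit_cart(
        xt[:, feat_idx], yt, sel.selected, seed=config.seed
    )
    reports: dict[str, metrics.MetricsReport] = {}
    for subset in (Subset.TRAIN, Subset.TEST):
        xs, ys = _subset_xy(matrix, labels, split, subset)
        pred, _ = learners.predict_cart(model, xs[:, feat_idx], sel.selected)
        rep = metrics.classification_metrics(ys, pred)
        rep.subset = subset.value
        reports[subset.value] = rep
    log.append({"step": "evaluate",
                "accuracy": {k: r["accuracy"] for k, r in reports.items()}})
    return ClassificationArtifacts(
        model=model, selection=sel, split=split, reports=reports, log=log
    )


def _evaluate_candidate(
    matrix: DescriptorMatrix,
    y: np.ndarray,
    split: splitting.SplitAssignment,
    features: list[str],
    config: PipelineConfig,
    seed: int,
):
    """Train an MLP + AD on one descriptor subset; score per scheme."""
    feat_idx = [matrix.descriptor_names.index(f) for f in features]
    xt, yt = _subset_xy(matrix, y, split, Subset.TRAIN)
    xt = xt[:, feat_idx]
    try:
        model = learners.fit_mlp(
            xt, yt, features, iterations=config.mlp_iterations, seed=seed
        )
        ad = admodel.fit_ad(xt, features)
    except ValueError:
        # degenerate subset (constant descriptor within TrS, or too few
        # training rows for the AD percentiles): not trainable
        return None, None, -np.inf

    if config.split_scheme == "A":
        xs, ys = _subset_xy(matrix, y, split, Subset.TEST)
        xs = xs[:, feat_idx]
        inside = admodel.ad_mask(ad, xs)
        if inside.sum() < 2 or np.var(ys[inside]) == 0:
            score = -np.inf
        else:
            pred = learners.predict_mlp(model, xs[inside])
            score = metrics.regression_metrics(ys[inside], pred)["r2"]
    else:
        rep = metrics.cross_validate_regression(
            lambda xa, ya, s: learners.fit_mlp(
                xa, ya, features, iterations=config.mlp_iterations, seed=s
            ),
            lambda m, xa: learners.predict_mlp(m, xa),
            xt, yt, k=min(config.cv_folds, len(yt)), seed=seed,
        )
        score = rep["r2"]
    return model, ad, float(score)


def train_regression(
    matrix: DescriptorMatrix,
    y: np.ndarray,
    config: PipelineConfig,
) -> RegressionArtifacts:
    """Activity-sampled split, GA-PLS selection, one MLP per elite subset,
    model selection per the split scheme, AD-filtered evaluation."""
    y = np.asarray(y, dtype=float)
    log: list[dict] = []
    split = splitting.activity_sampling_split(
        y, scheme=config.split_scheme, n_bins=config.n_bins,
        seed=config.seed, compound_ids=matrix.compound_ids,
    )
    sizes = {s.value: len(split.ids(s)) for s in Subset}
    log.append({"step": "split", "scheme": split.scheme, "sizes": sizes})

    xt, yt = _subset_xy(matrix, y, split, Subset.TRAIN)
    sel = selection.ga_pls_select(
        xt, yt, matrix.descriptor_names,
        population=config.ga_population, generations=config.ga_generations,
        min_vars=min(config.min_vars, matrix.shape[1]),
        max_vars=min(config.max_vars, matrix.shape[1]),
        seed=config.seed, n_elites=config.n_elites,
        outer_folds=config.outer_folds, inner_folds=config.inner_folds,
        repeats=config.dcv_repeats,
    )
    log.append({"step": "selection", "method": sel.method,
                "n_elites": len(sel.elite_subsets),
                "best_fitness": sel.fitness_trace[-1] if sel.fitness_trace
                else None})

    candidates: list[dict] = []
    best = None
    for i, features in enumerate(sel.elite_subsets):
        model, ad, score = _evaluate_candidate(
            matrix, y, split, features, config, seed=config.seed + i
        )
        candidates.append({"features": features, "score": score})
        if model is not None and (best is None or score > best[2]):
            best = (model, ad, score, features)
    if best is None:
        raise RuntimeError("no elite subset could be trained")
    model, ad, score, features = best
    log.append({"step": "model_selection", "scheme": config.split_scheme,
                "winner_features": features, "winner_score": score})

    feat_idx = [matrix.descriptor_names.index(f) for f in features]
    reports: dict[str, metrics.MetricsReport] = {}
    eval_subsets = ([Subset.TRAIN, Subset.TEST, Subset.EXTERNAL]
                    if config.split_scheme == "A"
                    else [Subset.TRAIN, Subset.EXTERNAL])
    for subset in eval_subsets:
        xs, ys = _subset_xy(matrix, y, split, subset)
        if len(ys) == 0:
            continue
        xs = xs[:, feat_idx]
        if subset == Subset.TRAIN:
            inside = np.ones(len(ys), dtype=bool)  # TrS is never AD-filtered
        else:
            inside = admodel.ad_mask(ad, xs)
        cov = float(inside.mean())
        if inside.sum() >= 3 and np.var(ys[inside]) > 0:
            pred = learners.predict_mlp(model, xs[inside])
            rep = metrics.regression_metrics(ys[inside], pred)
            rm = metrics.rm2_metrics(ys[inside], pred)
            rep.metrics.update(rm.metrics)
        else:
            rep = metrics.MetricsReport(metrics={}, n_used=int(inside.sum()))
        rep.coverage = cov
        rep.subset = subset.value
        reports[subset.value] = rep
    log.append({"step": "evaluate",
                "r2": {k: r.metrics.get("r2") for k, r in reports.items()},
                "coverage": {k: r.coverage for k, r in reports.items()}})
    return RegressionArtifacts(
        model=model, ad=ad, selection=sel, split=split,
        reports=reports, candidate_scores=candidates, log=log,
    )


def train_pipeline(config: PipelineConfig, dataset: CuratedDataset) -> dict:
    """Curated records in, trained artifacts out (both branches).

    The classification branch uses all records of the route; the
    regression branch uses the subset with defined endpoints (log10
    scale), which is by construction a subset of the classification
    positives.
    """
    from .curation import Route, build_classification_dataset

    route = Route(config.route)
    out: dict = {"config": config.to_dict()}

    clf_ds = build_classification_dataset(dataset.records, route)
    smiles = [r.smiles for r in clf_ds.records]
    ids = [r.identifier for r in clf_ds.records]
    full = compute_descriptors(smiles, ids)
    pruned, removal_log = prune_descriptors(
        full, config.corr_threshold, config.semiconstant_frac
    )
    out["n_descriptors"] = {"computed": full.shape[1],
                            "after_pruning": pruned.shape[1]}

    if config.branch in ("classification", "both"):
        labels = np.array([r.label for r in clf_ds.records])
        block = full.restrict_blocks({"constitutional", "ring"})
        keep = [n for n in block.descriptor_names
                if n in pruned.descriptor_names]
        block = block.restrict(keep) if keep else pruned
        out["classification"] = train_classification(
            pruned, labels, config, block_matrix=block
        )

    if config.branch in ("regression", "both"):
        reg_records = [r for r in clf_ds.records if r.raw_value is not None]
        reg_ids = [r.identifier for r in reg_records]
        sub_idx = [pruned.compound_ids.index(i) for i in reg_ids]
        reg_matrix = DescriptorMatrix(
            compound_ids=reg_ids,
            descriptor_names=list(pruned.descriptor_names),
            values=pruned.values[sub_idx],
            missing_mask=pruned.missing_mask[sub_idx],
            block_tags=dict(pruned.block_tags),
        )
        y = np.array([log_transform_endpoint(r.raw_value) for r in reg_records])
        out["regression"] = train_regression(reg_matrix, y, config)

    return out


def hierarchical_predict(
    classifier: ClassificationArtifacts | learners.CartModel,
    regressor: RegressionArtifacts | None,
    matrix: DescriptorMatrix,
) -> list[HierarchicalPrediction]:
    """Classify first; quantify potency only for predicted carcinogens."""
    cart = (classifier.model
            if isinstance(classifier, ClassificationArtifacts) else classifier)
    preds: list[HierarchicalPrediction] = []
    classes, _ = learners.predict_cart(
        cart, matrix.values, matrix.descriptor_names
    )
    for i, cid in enumerate(matrix.compound_ids):
        if classes[i] == 0:
            preds.append(HierarchicalPrediction(
                compound_id=cid, predicted_class="non_carcinogen"
            ))
            continue
        if regressor is None:
            preds.append(HierarchicalPrediction(
                compound_id=cid, predicted_class="carcinogen"
            ))
            continue
        try:
            feat_idx = [matrix.descriptor_names.index(f)
                        for f in regressor.model.feature_names]
        except ValueError as exc:
            preds.append(HierarchicalPrediction(
                compound_id=cid, predicted_class="carcinogen",
                error=str(exc),
            ))
            continue
        row = matrix.values[i, feat_idx]
        potency = float(learners.predict_mlp(regressor.model, row[None, :])[0])
        flag = "inside" if admodel.in_ad(regressor.ad, row) else "outside"
        preds.append(HierarchicalPrediction(
            compound_id=cid, predicted_class="carcinogen",
            potency_log10_sf=potency, ad_flag=flag,
        ))
    return preds


def write_run_log(log_entries: list[dict], path) -> None:
    """JSON-lines run log (seeds, sizes, selection traces)."""
    with open(path, "w") as fh:
        for entry in log_entries:
            fh.write(json.dumps(entry, sort_keys=True, default=str) + "\n")
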