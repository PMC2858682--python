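"""Training-design and enrichment experiments.

These procedures probe how the classifier behaves under the conditions a
clinical CNV cohort imposes: a heavy class imbalance (a handful of
pathogenic CNVs against thousands of benign ones), the choice of which
benign CNVs enter a balanced training set, the contribution of each
genomic feature, and whether a query CNV set is enriched for
pathogenic-looking regions relative to size-matched random genomic
regions.

All operations are driven by an integer seed and are bit-reproducible
given (inputs, parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import AnnotationTrack, CnvRecord, GeneIndex, build_feature_matrix
from .evaluation import accuracy_of
from .nbtree import NbTreeModel, NbTreeParams, classify_table, train_nbtree

__all__ = [
    "SweepResult",
    "EnrichmentResult",
    "default_sweep_grid",
    "imbalance_sweep",
    "select_optimal_training_set",
    "default_feature_groups",
    "feature_contribution",
    "jackknife_retrain",
    "size_matched_random_regions",
    "enrichment_test",
]


def _split_classes(X: pd.DataFrame, y: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y)
    return np.flatnonzero(y == "mr"), np.flatnonzero(y == "benign")


def _tree_params(params: NbTreeParams | None, seed: int) -> NbTreeParams:
    base = params or NbTreeParams()
    return NbTreeParams(
        min_node=base.min_node,
        utility_folds=base.utility_folds,
        min_rel_improvement=base.min_rel_improvement,
        max_depth=base.max_depth,
        laplace=base.laplace,
        seed=seed,
    )


def _train_and_score(
    X: pd.DataFrame,
    y: np.ndarray,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    params: NbTreeParams | None,
    tree_seed: int,
) -> float | None:
    if test_idx.size == 0:
        return None
    model = train_nbtree(X.iloc[train_idx], y[train_idx], _tree_params(params, tree_seed))
    pred = classify_table(model, X.iloc[test_idx])["predicted"].to_numpy()
    return accuracy_of(pred, y[test_idx])


def _train_and_score_full(
    X: pd.DataFrame,
    y: np.ndarray,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    params: NbTreeParams | None,
    tree_seed: int,
) -> dict[str, float] | None:
    """Natural accuracy plus per-class accuracies on the test set; None
    when the test set is empty or lacks a class (metrics undefined)."""
    if test_idx.size == 0:
        return None
    yt = y[test_idx]
    pos = yt == "mr"
    if not pos.any() or pos.all():
        return None
    model = train_nbtree(X.iloc[train_idx], y[train_idx], _tree_params(params, tree_seed))
    pred = classify_table(model, X.iloc[test_idx])["predicted"].to_numpy()
    sens = float((pred[pos] == "mr").mean())
    spec = float((pred[~pos] == "benign").mean())
    return {
        "natural_accuracy": accuracy_of(pred, yt),
        "sensitivity": sens,
        "specificity": spec,
        "balanced_accuracy": (sens + spec) / 2.0,
    }


# ---------------------------------------------------------------------------
# Class-imbalance sweep
# ---------------------------------------------------------------------------

@dataclass
class SweepResult:
    """Per-imbalance-level accuracy summary plus the raw per-run scores.

    ``table`` holds per level: training counts, completed runs, and the
    mean and standard deviation of the headline metric;
    ``per_run[level_index]`` is a frame with every run's natural
    accuracy, sensitivity, specificity and balanced accuracy.
    """

    table: pd.DataFrame
    per_run: list[pd.DataFrame]
    metric: str

    @property
    def accuracies(self) -> list[np.ndarray]:
        """Per-level arrays of the headline metric, one value per run."""
        return [df[self.metric].to_numpy() for df in self.per_run]


def default_sweep_grid(n_benign_available: int, n_mr_train: int, n_levels: int = 30) -> list[int]:
    """Benign training counts from half of the available benign CNVs down
    to parity with the pathogenic training count, evenly spaced."""
    hi = n_benign_available // 2
    lo = n_mr_train
    if hi < lo:
        raise ValueError("fewer benign CNVs available than the balanced level needs")
    grid = np.unique(np.round(np.linspace(hi, lo, n_levels)).astype(int))[::-1]
    return [int(g) for g in grid]


def imbalance_sweep(
    X: pd.DataFrame,
    y: Sequence[str],
    levels: Sequence[int] | None = None,
    runs_per_level: int = 1000,
    params: NbTreeParams | None = None,
    seed: int = 0,
    n_mr_train: int | None = None,
    metric: str = "balanced_accuracy",
) -> SweepResult:
    """Measure classifier accuracy across training-set imbalance levels.

    For each level (a benign training count) and run: sample that many
    benign CNVs and a fixed number of pathogenic CNVs (default: half of
    the pathogenic set) into training, leave the rest as a natural-
    frequency test set, train, and score the test set.

    The headline ``metric`` defaults to balanced accuracy — the mean of
    sensitivity and specificity — because the test set's class mix
    shifts with the level (training CNVs come out of it), and plain
    accuracy on an overwhelmingly benign test set is dominated by
    specificity alone, rewarding whichever level best matches the test
    prior rather than measuring class separation.  Plain
    natural-frequency accuracy is computed for every run and available
    via ``metric="natural_accuracy"`` or the per-run tables.
    """
    if metric not in ("balanced_accuracy", "natural_accuracy", "sensitivity", "specificity"):
        raise ValueError(f"unknown sweep metric {metric!r}")
    y = np.asarray(y)
    mr_idx, benign_idx = _split_classes(X, y)
    mr_train = n_mr_train if n_mr_train is not None else mr_idx.size // 2
    if mr_train < 1 or mr_train > mr_idx.size:
        raise ValueError(f"pathogenic training count {mr_train} out of range")
    if levels is None:
        levels = default_sweep_grid(benign_idx.size, mr_train)
    for lv in levels:
        if lv > benign_idx.size:
            raise ValueError(f"level {lv} exceeds the {benign_idx.size} benign CNVs available")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    rows = []
    per_level: list[pd.DataFrame] = []
    for lv in levels:
        runs = []
        for _ in range(runs_per_level):
            tr_mr = rng.choice(mr_idx, size=mr_train, replace=False)
            tr_benign = rng.choice(benign_idx, size=lv, replace=False)
            train = np.concatenate([tr_mr, tr_benign])
            test = np.setdiff1d(np.arange(len(X)), train)
            scores = _train_and_score_full(X, y, train, test, params, int(rng.integers(2**31)))
            if scores is not None:
                runs.append(scores)
        run_df = pd.DataFrame(runs)
        per_level.append(run_df)
        arr = run_df[metric].to_numpy() if len(run_df) else np.array([])
        rows.append(
            {
                "n_mr_train": mr_train,
                "n_benign_train": int(lv),
                "runs": int(arr.size),
                "mean_accuracy": float(arr.mean()) if arr.size else None,
                "sd_accuracy": float(arr.std(ddof=1)) if arr.size > 1 else None,
            }
        )
    return SweepResult(table=pd.DataFrame(rows), per_run=per_level, metric=metric)


# ---------------------------------------------------------------------------
# Optimal-training-set search
# ---------------------------------------------------------------------------

def select_optimal_training_set(
    X: pd.DataFrame,
    y: Sequence[str],
    n_each: int = 82,
    iterations: int = 10_000,
    params: NbTreeParams | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, float, np.ndarray]:
    """Re-sample balanced training sets and keep the most accurate one.

    Each iteration draws ``n_each`` CNVs per class without replacement
    into training, scores on the held-out remainder, and the draw with
    the highest held-out accuracy wins.  Returns (training row indices,
    best accuracy, accuracy distribution over all iterations).
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    y = np.asarray(y)
    mr_idx, benign_idx = _split_classes(X, y)
    if n_each > mr_idx.size or n_each > benign_idx.size:
        raise ValueError(f"n_each={n_each} exceeds an available class count")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    best_idx: np.ndarray | None = None
    best_acc = -np.inf
    dist = np.empty(iterations)
    for i in range(iterations):
        train = np.concatenate(
            [
                rng.choice(mr_idx, size=n_each, replace=False),
                rng.choice(benign_idx, size=n_each, replace=False),
            ]
        )
        test = np.setdiff1d(np.arange(len(X)), train)
        acc = _train_and_score(X, y, train, test, params, int(rng.integers(2**31)))
        dist[i] = np.nan if acc is None else acc
        if acc is not None and acc > best_acc:
            best_acc = acc
            best_idx = train
    assert best_idx is not None
    return best_idx, float(best_acc), dist


# ---------------------------------------------------------------------------
# Leave-one-feature-out contribution
# ---------------------------------------------------------------------------

LENGTH_COUPLED = ("n_line", "n_sine", "n_segdup", "n_gene")


def default_feature_groups(feature_names: Sequence[str]) -> dict[str, tuple[str, ...]]:
    """One removal group per feature, except that removing the length also
    removes the element/gene count features, whose values scale with
    length and would otherwise leak it back into the model."""
    groups: dict[str, tuple[str, ...]] = {}
    for f in feature_names:
        if f == "length_bp":
            coupled = tuple(c for c in LENGTH_COUPLED if c in feature_names)
            groups["length_bp"] = ("length_bp", *coupled)
        else:
            groups[f] = (f,)
    return groups


def feature_contribution(
    X_train: pd.DataFrame,
    y_train: Sequence[str],
    X_test: pd.DataFrame,
    y_test: Sequence[str],
    feature_groups: Mapping[str, tuple[str, ...]] | None = None,
    params: NbTreeParams | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Accuracy decline, in percentage points, from retraining without
    each feature (or coupled feature group).

    A zero-or-negative decline marks a feature as droppable.  Returns a
    table indexed by group name with ``accuracy_without`` and
    ``decline_pct_points`` columns plus an ``__all__`` baseline row.
    """
    y_train = np.asarray(y_train)
    y_test = np.asarray(y_test)
    groups = dict(feature_groups or default_feature_groups(list(X_train.columns)))
    for name, cols in groups.items():
        if len(cols) >= X_train.shape[1]:
            raise ValueError(f"group {name!r} would remove every feature")
    base_params = _tree_params(params, seed)
    base_model = train_nbtree(X_train, y_train, base_params)
    base_acc = accuracy_of(
        classify_table(base_model, X_test)["predicted"].to_numpy(), y_test
    )
    rows = {"__all__": {"accuracy_without": base_acc, "decline_pct_points": 0.0}}
    for name, cols in groups.items():
        keep = [c for c in X_train.columns if c not in cols]
        model = train_nbtree(X_train[keep], y_train, base_params)
        acc = accuracy_of(classify_table(model, X_test[keep])["predicted"].to_numpy(), y_test)
        rows[name] = {
            "accuracy_without": acc,
            "decline_pct_points": (base_acc - acc) * 100.0,
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "removed"
    return out


# ---------------------------------------------------------------------------
# Jack-knife retraining against a fixed validation set
# ---------------------------------------------------------------------------

def jackknife_retrain(
    X_pool: pd.DataFrame,
    y_pool: Sequence[str],
    X_val: pd.DataFrame,
    y_val: Sequence[str],
    n_each: int = 164,
    iterations: int = 10_000,
    params: NbTreeParams | None = None,
    seed: int = 0,
) -> tuple[float, float]:
    """Repeatedly draw balanced training sets from the pooled CNVs and
    score each resulting model on a fixed, independent validation set;
    returns (mean accuracy, max accuracy) over the iterations.

    The validation set must be disjoint from the pool (checked on the
    row index) — overlap would leak training instances into validation.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    overlap = X_pool.index.intersection(X_val.index)
    if len(overlap) > 0:
        raise ValueError(f"validation set overlaps the training pool: {list(overlap)[:5]}")
    y_pool = np.asarray(y_pool)
    y_val = np.asarray(y_val)
    mr_idx, benign_idx = _split_classes(X_pool, y_pool)
    if n_each > mr_idx.size or n_each > benign_idx.size:
        raise ValueError(f"n_each={n_each} exceeds an available class count in the pool")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    accs = np.empty(iterations)
    for i in range(iterations):
        train = np.concatenate(
            [
                rng.choice(mr_idx, size=n_each, replace=False),
                rng.choice(benign_idx, size=n_each, replace=False),
            ]
        )
        model = train_nbtree(
            X_pool.iloc[train], y_pool[train], _tree_params(params, int(rng.integers(2**31)))
        )
        accs[i] = accuracy_of(classify_table(model, X_val)["predicted"].to_numpy(), y_val)
    return float(accs.mean()), float(accs.max())


# ---------------------------------------------------------------------------
# Size-matched permutation enrichment
# ---------------------------------------------------------------------------

def size_matched_random_regions(
    query_cnvs: Sequence[CnvRecord],
    genome: Mapping[str, int],
    n_sets: int = 1000,
    seed: int = 0,
) -> list[list[CnvRecord]]:
    """Random genomic region sets matched for size to the query CNVs.

    Each set holds one region per query CNV with identical length and
    type, placed uniformly over all genome positions where it fits (the
    chromosome is chosen with probability proportional to its placeable
    positions).
    """
    chroms = list(genome)
    chrom_len = np.array([genome[c] for c in chroms], dtype=np.int64)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    sets: list[list[CnvRecord]] = []
    for s in range(n_sets):
        regions: list[CnvRecord] = []
        for q in query_cnvs:
            placeable = chrom_len - q.length + 1
            if (placeable <= 0).all():
                raise ValueError(
                    f"query region of length {q.length} fits no chromosome"
                )
            p = np.maximum(placeable, 0).astype(float)
            p /= p.sum()
            ci = int(rng.choice(len(chroms), p=p))
            start = int(rng.integers(0, placeable[ci]))
            regions.append(
                CnvRecord(
                    chrom=chroms[ci],
                    start=start,
                    end=start + q.length,
                    cnv_type=q.cnv_type,
                    cnv_id=f"perm{s}_{q.cnv_id or ''}",
                )
            )
        sets.append(regions)
    return sets


@dataclass
class EnrichmentResult:
    """Observed pathogenic-classified count against a size-matched random
    null; ``p_value`` is the proportion of null sets reaching the
    observed count."""

    observed_mr_count: int
    null_counts: np.ndarray
    p_value: float


def _count_mr(
    cnvs: Sequence[CnvRecord],
    model: NbTreeModel,
    tracks: Mapping[str, AnnotationTrack],
    genes: GeneIndex,
) -> int:
    feats = build_feature_matrix(cnvs, tracks, genes)
    feats = feats[[c for c in model.feature_names]]
    pred = classify_table(model, feats)["predicted"]
    return int((pred == "mr").sum())


def enrichment_test(
    query_cnvs: Sequence[CnvRecord],
    model: NbTreeModel,
    tracks: Mapping[str, AnnotationTrack],
    genes: GeneIndex,
    genome: Mapping[str, int],
    n_sets: int = 1000,
    seed: int = 0,
    plus_one: bool = False,
) -> EnrichmentResult:
    """Permutation test: are more query CNVs classified pathogenic than
    expected for random size-matched regions?

    Every null set is annotated and classified exactly like the query
    set.  ``p = #(null >= observed) / n_sets``; with ``plus_one`` the
    small-sample-corrected ``(#+1)/(n_sets+1)`` is reported instead.
    """
    if n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    observed = _count_mr(query_cnvs, model, tracks, genes)
    null_sets = size_matched_random_regions(query_cnvs, genome, n_sets, seed)
    null_counts = np.array(
        [_count_mr(regions, model, tracks, genes) for regions in null_sets]
    )
    ge = int((null_counts >= observed).sum())
    p = (ge + 1) / (n_sets + 1) if plus_one else ge / n_sets
    return EnrichmentResult(
        observed_mr_count=observed, null_counts=null_counts, p_value=float(p)
    )
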