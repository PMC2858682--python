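"""Hybrid decision-tree / Naive-Bayes classifier for CNV pathogenicity.

The model is a decision tree whose leaves are Naive-Bayes classifiers.
A node is split only when the best univariate split improves the
cross-validated accuracy of the node's Naive-Bayes model by a sufficient
relative error reduction and both children stay large enough; otherwise
the node becomes a leaf.  Continuous attributes inside the leaves are
handled by supervised entropy/MDL discretization rather than Gaussian
likelihoods.

The classifier output for a CNV is the posterior probability of the
pathogenic (``mr``) class — the "MR distance".  A CNV is called
pathogenic when the distance strictly exceeds 0.5; the tie goes to
``benign``, the conservative call in a diagnostic setting.

Missing attribute values never contribute evidence: they are skipped in
the Naive-Bayes product, and an instance missing an internal split
attribute is routed fractionally to the children in proportion to their
training mass, which keeps the posterior normalised.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

CLASSES = ("benign", "mr")  # index 1 is the positive (pathogenic) class

__all__ = [
    "CLASSES",
    "Discretization",
    "NaiveBayesLeaf",
    "NbTreeParams",
    "NbTreeModel",
    "ClassificationResult",
    "ModelFormatError",
    "mdl_cut_points",
    "train_nb_leaf",
    "nb_posterior",
    "train_nbtree",
    "classify",
    "classify_table",
    "save_model",
    "load_model",
]


class ModelFormatError(ValueError):
    """Raised when a serialized model file cannot be interpreted."""


# ---------------------------------------------------------------------------
# Supervised MDL discretization (recursive entropy partitioning)
# ---------------------------------------------------------------------------

def _entropy2(a: float, b: float) -> float:
    """Entropy in bits of a two-class count vector."""
    n = a + b
    if n == 0 or a == 0 or b == 0:
        return 0.0
    pa, pb = a / n, b / n
    return -(pa * math.log2(pa) + pb * math.log2(pb))


def mdl_cut_points(values: Sequence[float], labels: Sequence[object]) -> list[float]:
    """Supervised discretization cut points for one continuous attribute.

    Recursive binary partitioning on information gain; a candidate cut is
    accepted only when its gain passes the minimum-description-length
    criterion, so pure or uninformative attributes yield no cuts.  NaN
    values are ignored.  Deterministic: ties on gain resolve to the
    leftmost candidate.
    """
    v = np.asarray(values, dtype=float)
    y = _binarize_labels(labels)
    mask = ~np.isnan(v)
    v, y = v[mask], y[mask]
    if v.size < 2:
        return []
    order = np.argsort(v, kind="stable")
    v, y = v[order], y[order]
    cuts: list[float] = []
    _mdl_recurse(v, y, 0, v.size, cuts)
    return sorted(cuts)


def _mdl_recurse(v: np.ndarray, y: np.ndarray, lo: int, hi: int, cuts: list[float]) -> None:
    n = hi - lo
    if n < 2:
        return
    seg_v = v[lo:hi]
    seg_y = y[lo:hi]
    c1 = np.cumsum(seg_y)
    tot1 = int(c1[-1])
    tot0 = n - tot1
    if tot0 == 0 or tot1 == 0:
        return  # pure segment
    cand = np.flatnonzero(seg_v[1:] > seg_v[:-1]) + 1
    if cand.size == 0:
        return  # constant segment
    left1 = c1[cand - 1].astype(float)
    left0 = cand - left1
    right1 = tot1 - left1
    right0 = tot0 - left0
    ent = np.vectorize(_entropy2)
    e_all = _entropy2(tot0, tot1)
    e_l = ent(left0, left1)
    e_r = ent(right0, right1)
    w = cand / n
    gains = e_all - w * e_l - (1.0 - w) * e_r
    best = int(np.argmax(gains))
    gain = float(gains[best])
    k1 = int(left0[best] > 0) + int(left1[best] > 0)
    k2 = int(right0[best] > 0) + int(right1[best] > 0)
    # MDL acceptance: gain must pay for encoding the partition
    delta = math.log2(3**2 - 2) - (2 * e_all - k1 * e_l[best] - k2 * e_r[best])
    if gain <= (math.log2(n - 1) + delta) / n:
        return
    i = int(cand[best])
    cuts.append(float((seg_v[i - 1] + seg_v[i]) / 2.0))
    _mdl_recurse(v, y, lo, lo + i, cuts)
    _mdl_recurse(v, y, lo + i, hi, cuts)


def _binarize_labels(labels: Sequence[object]) -> np.ndarray:
    """Map class labels onto {0, 1} with ``mr`` (or the lexically larger
    label) as 1."""
    arr = np.asarray(labels)
    y = np.zeros(arr.shape[0], dtype=np.int64)
    y[arr == CLASSES[1]] = 1
    if not np.isin(arr, CLASSES).all():
        bad = sorted(set(arr) - set(CLASSES))
        raise ValueError(f"labels must be in {CLASSES}, got {bad}")
    return y


@dataclass(frozen=True)
class Discretization:
    """Cut points mapping a continuous value to a bin index.

    An empty cut list means a single bin.  Bin ``i`` spans
    ``(cut[i-1], cut[i]]``: values equal to a cut fall in the lower bin,
    matching the ``value <= threshold`` split convention of the tree.
    """

    feature_name: str
    cut_points: tuple[float, ...]

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.cut_points, self.cut_points[1:])):
            raise ValueError("cut points must be strictly increasing")

    @property
    def n_bins(self) -> int:
        return len(self.cut_points) + 1

    def bin(self, value: float) -> int:
        if value is None or (isinstance(value, float) and math.isnan(value)):
            return -1
        return int(np.searchsorted(self.cut_points, value, side="left"))


# ---------------------------------------------------------------------------
# Feature encoding shared by leaf and tree
# ---------------------------------------------------------------------------

class _Encoder:
    """Splits a feature frame into continuous columns (float, NaN missing)
    and categorical columns (integer codes, -1 missing)."""

    def __init__(self, X: pd.DataFrame):
        self.feature_names = list(X.columns)
        self.cat_names: list[str] = []
        self.cat_categories: dict[str, list] = {}
        self.cont_names: list[str] = []
        for col in X.columns:
            dtype = X[col].dtype
            if dtype == bool:
                self.cat_names.append(col)
                self.cat_categories[col] = [False, True]
            elif dtype == object or str(dtype) == "category":
                self.cat_names.append(col)
                vals = sorted({v for v in X[col] if not pd.isna(v)}, key=repr)
                self.cat_categories[col] = vals
            else:
                self.cont_names.append(col)

    def encode(self, X: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        n = len(X)
        cont = np.full((n, len(self.cont_names)), np.nan)
        for j, name in enumerate(self.cont_names):
            cont[:, j] = pd.to_numeric(X[name], errors="coerce").to_numpy(dtype=float)
        cat = np.full((n, len(self.cat_names)), -1, dtype=np.int64)
        for j, name in enumerate(self.cat_names):
            mapping = {v: i for i, v in enumerate(self.cat_categories[name])}
            col = X[name]
            cat[:, j] = [
                -1 if pd.isna(v) else mapping.get(bool(v) if isinstance(v, np.bool_) else v, -1)
                for v in col
            ]
        return cont, cat


# ---------------------------------------------------------------------------
# Naive-Bayes leaf
# ---------------------------------------------------------------------------

@dataclass
class NaiveBayesLeaf:
    """A Laplace-smoothed Naive-Bayes model over discretized attributes.

    ``cond[f]`` is an (n_bins, 2) table of class-conditional bin
    probabilities; each column sums to 1.  Missing attribute values are
    counted nowhere at fit time and skipped at prediction time.
    """

    feature_names: list[str]
    kinds: dict[str, str]                 # 'continuous' | 'categorical'
    cut_points: dict[str, list[float]]    # continuous features
    categories: dict[str, list]           # categorical features
    priors: np.ndarray                    # (2,) over CLASSES
    cond: dict[str, np.ndarray]           # feature -> (n_bins, 2)
    laplace: float
    n_train: int
    class_counts: np.ndarray              # (2,) raw counts

    # -- construction -------------------------------------------------

    @classmethod
    def fit(cls, X: pd.DataFrame, labels: Sequence[object], laplace: float = 1.0) -> "NaiveBayesLeaf":
        if len(X) == 0:
            raise ValueError("cannot train a Naive-Bayes leaf on an empty table")
        enc = _Encoder(X)
        cont, cat = enc.encode(X)
        y = _binarize_labels(labels)
        return cls._fit_encoded(enc, cont, cat, y, laplace)

    @classmethod
    def _fit_encoded(
        cls,
        enc: _Encoder,
        cont: np.ndarray,
        cat: np.ndarray,
        y: np.ndarray,
        laplace: float,
    ) -> "NaiveBayesLeaf":
        n = y.shape[0]
        class_counts = np.array([(y == 0).sum(), (y == 1).sum()], dtype=float)
        priors = (class_counts + laplace) / (n + 2 * laplace)
        kinds: dict[str, str] = {}
        cut_points: dict[str, list[float]] = {}
        categories: dict[str, list] = {}
        cond: dict[str, np.ndarray] = {}
        for j, name in enumerate(enc.cont_names):
            kinds[name] = "continuous"
            cuts = mdl_cut_points(cont[:, j], np.where(y == 1, CLASSES[1], CLASSES[0]))
            cut_points[name] = cuts
            codes = np.where(
                np.isnan(cont[:, j]), -1, np.searchsorted(cuts, cont[:, j], side="left")
            ).astype(np.int64)
            cond[name] = _conditional_table(codes, y, len(cuts) + 1, laplace)
        for j, name in enumerate(enc.cat_names):
            kinds[name] = "categorical"
            cats = enc.cat_categories[name]
            categories[name] = cats
            nbins = max(len(cats), 1)
            cond[name] = _conditional_table(cat[:, j], y, nbins, laplace)
        return cls(
            feature_names=list(enc.feature_names),
            kinds=kinds,
            cut_points=cut_points,
            categories=categories,
            priors=priors,
            cond=cond,
            laplace=laplace,
            n_train=n,
            class_counts=class_counts,
        )

    # -- prediction ---------------------------------------------------

    def _bin_column(self, name: str, values: pd.Series) -> np.ndarray:
        if self.kinds[name] == "continuous":
            v = pd.to_numeric(values, errors="coerce").to_numpy(dtype=float)
            codes = np.where(
                np.isnan(v), -1, np.searchsorted(self.cut_points[name], v, side="left")
            )
            return codes.astype(np.int64)
        mapping = {v: i for i, v in enumerate(self.categories[name])}
        return np.array(
            [
                -1 if pd.isna(v) else mapping.get(bool(v) if isinstance(v, np.bool_) else v, -1)
                for v in values
            ],
            dtype=np.int64,
        )

    def posterior_array(self, X: pd.DataFrame) -> np.ndarray:
        """Posterior P(mr | x) for every row; missing features skipped."""
        missing_cols = [f for f in self.feature_names if f not in X.columns]
        if missing_cols:
            raise KeyError(f"feature(s) {missing_cols} absent from input table")
        n = len(X)
        loglik = np.tile(np.log(self.priors), (n, 1))
        for name in self.feature_names:
            codes = self._bin_column(name, X[name])
            table = np.log(self.cond[name])
            valid = codes >= 0
            loglik[valid] += table[codes[valid]]
        m = loglik.max(axis=1, keepdims=True)
        p = np.exp(loglik - m)
        p /= p.sum(axis=1, keepdims=True)
        return p[:, 1]

    def posterior(self, x: Mapping[str, object]) -> float:
        """Posterior P(mr | x) for one feature mapping."""
        row = pd.DataFrame([dict(x)])
        for name in self.feature_names:
            if name not in row.columns:
                row[name] = np.nan
        return float(self.posterior_array(row)[0])


def _conditional_table(codes: np.ndarray, y: np.ndarray, n_bins: int, laplace: float) -> np.ndarray:
    """(n_bins, 2) Laplace-smoothed class-conditional bin probabilities;
    missing codes (-1) contribute to no count."""
    table = np.zeros((n_bins, 2))
    for c in (0, 1):
        sel = (y == c) & (codes >= 0)
        counts = np.bincount(codes[sel], minlength=n_bins).astype(float)
        table[:, c] = (counts + laplace) / (counts.sum() + laplace * n_bins)
    return table


def train_nb_leaf(
    X: pd.DataFrame, labels: Sequence[object], laplace: float = 1.0
) -> NaiveBayesLeaf:
    """Train a stand-alone Naive-Bayes model (a depth-0 tree's only leaf)."""
    return NaiveBayesLeaf.fit(X, labels, laplace)


def nb_posterior(leaf: NaiveBayesLeaf, feature_vector: Mapping[str, object]) -> float:
    """Posterior probability of the pathogenic class given one vector."""
    return leaf.posterior(feature_vector)


# ---------------------------------------------------------------------------
# Tree induction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NbTreeParams:
    """Tree-induction controls.

    ``min_node`` — minimum training instances each child must retain for a
    split to be considered; ``utility_folds`` — folds of the
    cross-validated accuracy used as split utility; ``min_rel_improvement``
    — required relative error reduction of the best split over the node's
    own Naive-Bayes model; ``max_depth=None`` leaves depth unbounded and
    ``max_depth=0`` forces a single Naive-Bayes leaf.  Fold assignment is
    the only randomness and is driven by ``seed``.
    """

    min_node: int = 30
    utility_folds: int = 5
    min_rel_improvement: float = 0.05
    max_depth: int | None = None
    laplace: float = 1.0
    seed: int = 0


@dataclass
class _Leaf:
    model: NaiveBayesLeaf
    n: int


@dataclass
class _Split:
    feature: str
    kind: str                       # 'continuous' | 'categorical'
    threshold: float | None         # continuous: go left iff value <= threshold
    categories: list | None         # categorical: one child per category
    children: list
    masses: list[int]


@dataclass
class NbTreeModel:
    """An induced tree with univariate internal splits and Naive-Bayes
    leaves."""

    root: object                    # _Leaf | _Split
    feature_names: list[str]
    params: NbTreeParams
    classes: tuple[str, str] = CLASSES

    @property
    def n_leaves(self) -> int:
        return sum(1 for _ in self._iter_leaves(self.root))

    @property
    def n_split_nodes(self) -> int:
        def count(node) -> int:
            if isinstance(node, _Leaf):
                return 0
            return 1 + sum(count(c) for c in node.children)

        return count(self.root)

    @property
    def depth(self) -> int:
        def d(node) -> int:
            if isinstance(node, _Leaf):
                return 0
            return 1 + max(d(c) for c in node.children)

        return d(self.root)

    def _iter_leaves(self, node):
        if isinstance(node, _Leaf):
            yield node
        else:
            for c in node.children:
                yield from self._iter_leaves(c)


@dataclass(frozen=True)
class ClassificationResult:
    """Predicted class plus the MR distance (posterior of the pathogenic
    class); pathogenic iff the distance strictly exceeds 0.5."""

    predicted_class: str
    mr_distance: float


class _TreeBuilder:
    def __init__(self, X: pd.DataFrame, labels: Sequence[object], params: NbTreeParams):
        if len(X) == 0:
            raise ValueError("cannot train on an empty feature matrix")
        self.params = params
        self.enc = _Encoder(X)
        self.cont, self.cat = self.enc.encode(X)
        self.y = _binarize_labels(labels)
        self.rng = np.random.default_rng(np.random.SeedSequence(params.seed))

    # -- fast binned NB machinery (node-local discretization) ----------

    def _node_binning(self, idx: np.ndarray) -> tuple[np.ndarray, np.ndarray, list[list[float]]]:
        """Bin the node's instances feature-by-feature: continuous features
        by MDL cuts computed on the node, categoricals by global codes.
        Returns (codes, n_bins per feature, cut lists per continuous
        feature)."""
        y = self.y[idx]
        labels = np.where(y == 1, CLASSES[1], CLASSES[0])
        n_cont = len(self.enc.cont_names)
        n_cat = len(self.enc.cat_names)
        codes = np.full((idx.size, n_cont + n_cat), -1, dtype=np.int64)
        nbins = np.ones(n_cont + n_cat, dtype=np.int64)
        cut_lists: list[list[float]] = []
        for j in range(n_cont):
            v = self.cont[idx, j]
            cuts = mdl_cut_points(v, labels)
            cut_lists.append(cuts)
            nbins[j] = len(cuts) + 1
            codes[:, j] = np.where(np.isnan(v), -1, np.searchsorted(cuts, v, side="left"))
        for j in range(n_cat):
            codes[:, n_cont + j] = self.cat[idx, j]
            nbins[n_cont + j] = max(len(self.enc.cat_categories[self.enc.cat_names[j]]), 1)
        return codes, nbins, cut_lists

    def _cv_accuracy(self, codes: np.ndarray, nbins: np.ndarray, y: np.ndarray) -> float:
        """Utility of a Naive-Bayes model on pre-binned data: accuracy under
        seeded k-fold cross-validation."""
        m = y.shape[0]
        folds = min(self.params.utility_folds, m)
        offsets = np.concatenate([[0], np.cumsum(nbins)])
        total = int(offsets[-1])
        flat = np.where(codes >= 0, codes + offsets[:-1], total)
        if folds < 2:
            logcond, logprior = self._tables(flat, y, np.ones(m, bool), nbins, offsets, total)
            pred = self._predict_flat(flat, logcond, logprior)
            return float((pred == y).mean())
        perm = self.rng.permutation(m)
        correct = 0
        for test_idx in np.array_split(perm, folds):
            train_mask = np.ones(m, dtype=bool)
            train_mask[test_idx] = False
            logcond, logprior = self._tables(flat, y, train_mask, nbins, offsets, total)
            pred = self._predict_flat(flat[test_idx], logcond, logprior)
            correct += int((pred == y[test_idx]).sum())
        return correct / m

    def _tables(self, flat, y, train_mask, nbins, offsets, total):
        laplace = self.params.laplace
        logcond = np.zeros((total + 1, 2))  # padded row `total` = missing, contributes 0
        counts = np.zeros((total, 2))
        for c in (0, 1):
            rows = flat[train_mask & (y == c)].ravel()
            counts[:, c] = np.bincount(rows[rows < total], minlength=total)
        per_feat_tot = np.add.reduceat(counts, offsets[:-1], axis=0)
        denom = np.repeat(per_feat_tot, nbins, axis=0) + laplace * np.repeat(
            nbins, nbins
        ).reshape(-1, 1)
        logcond[:total] = np.log((counts + laplace) / denom)
        n0 = float((y[train_mask] == 0).sum())
        n1 = float((y[train_mask] == 1).sum())
        logprior = np.log(
            (np.array([n0, n1]) + laplace) / (n0 + n1 + 2 * laplace)
        )
        return logcond, logprior

    @staticmethod
    def _predict_flat(flat, logcond, logprior) -> np.ndarray:
        ll = logcond[flat].sum(axis=1) + logprior
        return (ll[:, 1] > ll[:, 0]).astype(np.int64)  # tie -> benign

    # -- leaf fitting --------------------------------------------------

    def _fit_leaf(self, idx: np.ndarray) -> _Leaf:
        leaf = NaiveBayesLeaf._fit_encoded(
            self.enc, self.cont[idx], self.cat[idx], self.y[idx], self.params.laplace
        )
        return _Leaf(model=leaf, n=idx.size)

    # -- recursive growth ----------------------------------------------

    def grow(self, idx: np.ndarray, depth: int):
        p = self.params
        n = idx.size
        pure = len(np.unique(self.y[idx])) < 2
        if (
            (p.max_depth is not None and depth >= p.max_depth)
            or n < 2 * p.min_node
            or pure
        ):
            return self._fit_leaf(idx)
        codes, nbins, cut_lists = self._node_binning(idx)
        y = self.y[idx]
        u_node = self._cv_accuracy(codes, nbins, y)
        best = None  # (utility, feature_pos, partition list, descriptor)
        n_cont = len(self.enc.cont_names)
        for j, name in enumerate(self.enc.cont_names):
            v = self.cont[idx, j]
            missing = np.isnan(v)
            for theta in cut_lists[j]:
                left = (v <= theta) & ~missing
                right = (v > theta) & ~missing
                parts = self._assign_missing([left, right], missing)
                util = self._split_utility(parts, codes, nbins, y)
                if util is not None and (best is None or util > best[0]):
                    best = (util, name, parts, ("continuous", float(theta), None))
        for j, name in enumerate(self.enc.cat_names):
            col = self.cat[idx, j]
            cats = self.enc.cat_categories[name]
            if len(cats) < 2:
                continue
            missing = col < 0
            children = [(col == k) for k in range(len(cats))]
            if sum(1 for m in children if m.any()) < 2:
                continue
            parts = self._assign_missing(children, missing)
            util = self._split_utility(parts, codes, nbins, y)
            if util is not None and (best is None or util > best[0]):
                best = (util, name, parts, ("categorical", None, list(cats)))
        if best is None:
            return self._fit_leaf(idx)
        u_split, feature, parts, (kind, theta, cats) = best
        err_node = 1.0 - u_node
        err_split = 1.0 - u_split
        if err_node <= 0 or (err_node - err_split) / err_node < p.min_rel_improvement:
            return self._fit_leaf(idx)
        children = [self.grow(idx[mask], depth + 1) for mask in parts]
        return _Split(
            feature=feature,
            kind=kind,
            threshold=theta,
            categories=cats,
            children=children,
            masses=[int(mask.sum()) for mask in parts],
        )

    @staticmethod
    def _assign_missing(children: list[np.ndarray], missing: np.ndarray) -> list[np.ndarray]:
        """Training instances with a missing split value go to the largest
        child (each instance must land in exactly one leaf)."""
        if missing.any():
            sizes = [m.sum() for m in children]
            k = int(np.argmax(sizes))
            children = [m.copy() for m in children]
            children[k] |= missing
        return children

    def _split_utility(self, parts, codes, nbins, y) -> float | None:
        sizes = [int(m.sum()) for m in parts]
        if any(s < self.params.min_node for s in sizes):
            return None
        n = y.shape[0]
        util = 0.0
        for mask, s in zip(parts, sizes):
            util += (s / n) * self._cv_accuracy(codes[mask], nbins, y[mask])
        return util


def train_nbtree(
    X: pd.DataFrame,
    labels: Sequence[object],
    params: NbTreeParams | None = None,
) -> NbTreeModel:
    """Induce the hybrid tree.

    At each node the Naive-Bayes utility (cross-validated accuracy) is
    compared with the weighted utility of each candidate univariate
    split; the node splits only when the best candidate reduces the error
    by at least ``min_rel_improvement`` relatively and every child keeps
    ``min_node`` instances.  Candidate thresholds for a continuous
    attribute are its node-level MDL cut points.  Deterministic given
    (data, params, seed).
    """
    params = params or NbTreeParams()
    builder = _TreeBuilder(X, labels, params)
    root = builder.grow(np.arange(len(X)), 0)
    return NbTreeModel(root=root, feature_names=list(X.columns), params=params)


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def _leaf_weights(node, X: pd.DataFrame, w: np.ndarray, out: list) -> None:
    if isinstance(node, _Leaf):
        out.append((node, w))
        return
    values = X[node.feature]
    total_mass = float(sum(node.masses)) or 1.0
    if node.kind == "continuous":
        v = pd.to_numeric(values, errors="coerce").to_numpy(dtype=float)
        missing = np.isnan(v)
        masks = [(v <= node.threshold) & ~missing, (v > node.threshold) & ~missing]
    else:
        mapping = {c: i for i, c in enumerate(node.categories)}
        codes = np.array(
            [
                -1 if pd.isna(x) else mapping.get(bool(x) if isinstance(x, np.bool_) else x, -1)
                for x in values
            ]
        )
        missing = codes < 0
        masks = [codes == i for i in range(len(node.categories))]
    for child, mask, mass in zip(node.children, masks, node.masses):
        # hard routing where the value is known, mass-weighted fractional
        # routing where it is missing
        wc = w * mask + w * missing * (mass / total_mass)
        if wc.any():
            _leaf_weights(child, X, wc, out)


def classify_table(model: NbTreeModel, X: pd.DataFrame) -> pd.DataFrame:
    """Classify every row; returns a frame with ``predicted`` and
    ``mr_distance`` columns aligned to the input index."""
    missing_cols = [f for f in model.feature_names if f not in X.columns]
    if missing_cols:
        raise KeyError(f"feature(s) {missing_cols} absent from input table")
    n = len(X)
    out: list[tuple[_Leaf, np.ndarray]] = []
    _leaf_weights(model.root, X, np.ones(n), out)
    dist = np.zeros(n)
    for leaf, w in out:
        active = w > 0
        if active.any():
            dist[active] += w[active] * leaf.model.posterior_array(X.loc[active])
    predicted = np.where(dist > 0.5, CLASSES[1], CLASSES[0])
    return pd.DataFrame({"predicted": predicted, "mr_distance": dist}, index=X.index)


def classify(model: NbTreeModel, feature_vector: Mapping[str, object]) -> ClassificationResult:
    """Classify one CNV feature vector."""
    frame = pd.DataFrame([dict(feature_vector)])
    for name in model.feature_names:
        if name not in frame.columns:
            frame[name] = np.nan
    res = classify_table(model, frame)
    return ClassificationResult(
        predicted_class=str(res["predicted"].iloc[0]),
        mr_distance=float(res["mr_distance"].iloc[0]),
    )


# ---------------------------------------------------------------------------
# Serialization (versioned JSON text)
# ---------------------------------------------------------------------------

_FORMAT = "cnvtriage-nbtree"
_VERSION = 1


def _leaf_to_dict(leaf: _Leaf) -> dict:
    m = leaf.model
    return {
        "type": "leaf",
        "n": leaf.n,
        "priors": m.priors.tolist(),
        "class_counts": m.class_counts.tolist(),
        "laplace": m.laplace,
        "n_train": m.n_train,
        "features": [
            {
                "name": f,
                "kind": m.kinds[f],
                "cut_points": m.cut_points.get(f),
                "categories": m.categories.get(f),
                "cond": m.cond[f].tolist(),
            }
            for f in m.feature_names
        ],
    }


def _node_to_dict(node) -> dict:
    if isinstance(node, _Leaf):
        return _leaf_to_dict(node)
    return {
        "type": "split",
        "feature": node.feature,
        "kind": node.kind,
        "threshold": node.threshold,
        "categories": node.categories,
        "masses": node.masses,
        "children": [_node_to_dict(c) for c in node.children],
    }


def _leaf_from_dict(d: dict, feature_names: list[str]) -> _Leaf:
    kinds, cut_points, categories, cond = {}, {}, {}, {}
    for f in d["features"]:
        kinds[f["name"]] = f["kind"]
        if f["kind"] == "continuous":
            cut_points[f["name"]] = list(f["cut_points"] or [])
        else:
            categories[f["name"]] = list(f["categories"] or [])
        cond[f["name"]] = np.asarray(f["cond"], dtype=float)
    model = NaiveBayesLeaf(
        feature_names=[f["name"] for f in d["features"]],
        kinds=kinds,
        cut_points=cut_points,
        categories=categories,
        priors=np.asarray(d["priors"], dtype=float),
        cond=cond,
        laplace=float(d["laplace"]),
        n_train=int(d["n_train"]),
        class_counts=np.asarray(d["class_counts"], dtype=float),
    )
    return _Leaf(model=model, n=int(d["n"]))


def _node_from_dict(d: dict, feature_names: list[str]):
    if d["type"] == "leaf":
        return _leaf_from_dict(d, feature_names)
    return _Split(
        feature=d["feature"],
        kind=d["kind"],
        threshold=d["threshold"],
        categories=d["categories"],
        masses=list(d["masses"]),
        children=[_node_from_dict(c, feature_names) for c in d["children"]],
    )


def save_model(model: NbTreeModel, path: str | Path) -> None:
    doc = {
        "format": _FORMAT,
        "version": _VERSION,
        "classes": list(model.classes),
        "feature_names": model.feature_names,
        "params": {
            "min_node": model.params.min_node,
            "utility_folds": model.params.utility_folds,
            "min_rel_improvement": model.params.min_rel_improvement,
            "max_depth": model.params.max_depth,
            "laplace": model.params.laplace,
            "seed": model.params.seed,
        },
        "tree": _node_to_dict(model.root),
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_model(path: str | Path) -> NbTreeModel:
    try:
        doc = json.loads(Path(path).read_text())
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise ModelFormatError(f"{path}: not a valid model file ({exc})") from exc
    if not isinstance(doc, dict) or doc.get("format") != _FORMAT:
        raise ModelFormatError(f"{path}: unrecognized model format")
    if doc.get("version") != _VERSION:
        raise ModelFormatError(
            f"{path}: model version {doc.get('version')!r} not supported (expected {_VERSION})"
        )
    params = NbTreeParams(**doc["params"])
    root = _node_from_dict(doc["tree"], doc["feature_names"])
    return NbTreeModel(root=root, feature_names=list(doc["feature_names"]), params=params)
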