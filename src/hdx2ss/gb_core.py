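"""Gradient tree boosting for binary classification, from first principles.

The model is a stagewise additive ensemble on the log-odds scale. With
binary targets y and predicted class-1 probability p = sigma(F(x)):

* the initial model F_0 is the constant log-odds of the positive class,
  ln(p0 / (1 - p0)) with p0 = mean(y) — the argmin of the cross-entropy
  loss over a constant prediction;
* at each stage m the pseudo-residuals r_i = y_i - p_i (the negative
  gradient of the cross-entropy loss with respect to the log-odds) are
  fitted by a least-squares regression tree;
* each leaf's output gamma is the one-step Newton update
  sum(r_i) / sum(p_i (1 - p_i)) over the leaf's samples (second-order
  Taylor expansion of the loss in gamma);
* the model is updated F_m = F_{m-1} + nu * tree(x) with learning rate
  nu (default 0.2).

Trees are grown best-first by greedy squared-error reduction with
midpoint thresholds; ties break toward the lowest feature index, then
the lowest threshold, so fits are exactly reproducible.

The intended feature table is the four-dimensional HDX covariate
(k_obs, k_int, R-matrix, amino-acid ordinal) with a helix/strand target,
but nothing here is specific to that layout.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from hdx2ss._errors import DegenerateTargetError, ValidationError

logger = logging.getLogger(__name__)

PROB_CLIP = 1e-12
GAMMA_CAP = 10.0
DEFAULT_FEATURE_NAMES = ("k_obs", "k_int", "r_matrix", "aa_code")


@dataclass
class FeatureTable:
    """Numeric feature matrix with binary targets."""

    X: np.ndarray
    y: np.ndarray
    feature_names: Tuple[str, ...] = DEFAULT_FEATURE_NAMES

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2:
            raise ValidationError("feature matrix must be 2-D")
        if len(self.X) != len(self.y):
            raise ValidationError("feature matrix and targets differ in length")
        if not np.isfinite(self.X).all():
            raise ValidationError("feature table contains missing/non-finite values")
        if not np.isin(self.y, (0, 1)).all():
            raise ValidationError("targets must be binary 0/1")
        if len(self.feature_names) != self.X.shape[1]:
            self.feature_names = tuple(f"x{j}" for j in range(self.X.shape[1]))

    def __len__(self) -> int:
        return len(self.y)


@dataclass
class GBConfig:
    """Hyper-parameters of the boosting model."""

    n_stages: int = 500
    nu: float = 0.2
    max_leaf_nodes: int = 8
    min_samples_leaf: int = 5
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.nu <= 1.0):
            raise ValidationError("learning rate nu must be in (0, 1]; nu=0 allowed for diagnostics")
        if self.n_stages < 1:
            raise ValidationError("n_stages must be >= 1")
        if self.max_leaf_nodes < 1:
            raise ValidationError("max_leaf_nodes must be >= 1")


# ---------------------------------------------------------------------------
# elementary pieces

def initial_log_odds(y: Sequence[int]) -> float:
    """Constant initial prediction: log-odds of the positive class."""
    y = np.asarray(y)
    p0 = float(y.mean())
    if p0 <= 0.0 or p0 >= 1.0:
        raise DegenerateTargetError("targets contain a single class; log-odds undefined")
    return math.log(p0 / (1.0 - p0))


def prob_from_log_odds(z):
    """Logistic transform e^z / (1 + e^z), numerically stable."""
    z = np.asarray(z, dtype=float)
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out if out.ndim else float(out)


def cross_entropy(y: Sequence[int], p: Sequence[float]) -> float:
    """Summed binary cross-entropy -sum[y ln p + (1-y) ln(1-p)].

    Probabilities at exactly 0 or 1 are clipped to [1e-12, 1 - 1e-12]
    with a warning rather than producing infinities.
    """
    y = np.asarray(y, dtype=float)
    p = np.asarray(p, dtype=float)
    if len(y) != len(p):
        raise ValidationError("y and p differ in length")
    if ((p <= 0.0) | (p >= 1.0)).any():
        logger.warning("cross_entropy: probabilities at 0/1 clipped to [%g, %g]", PROB_CLIP, 1 - PROB_CLIP)
    p = np.clip(p, PROB_CLIP, 1.0 - PROB_CLIP)
    return float(-(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)).sum())


def pseudo_residuals(y: Sequence[int], p: Sequence[float]) -> np.ndarray:
    """Negative gradient of the cross-entropy loss w.r.t. log-odds: y - p."""
    y = np.asarray(y, dtype=float)
    p = np.asarray(p, dtype=float)
    if len(y) != len(p):
        raise ValidationError("y and p differ in length")
    return y - p


def leaf_gamma(residuals_in_leaf: Sequence[float], p_in_leaf: Sequence[float]) -> float:
    """Newton-step leaf output: sum(residuals) / sum(p (1 - p)).

    A vanishing denominator (all probabilities saturated) caps gamma at
    +/-10 with a warning.
    """
    r = np.asarray(residuals_in_leaf, dtype=float)
    p = np.asarray(p_in_leaf, dtype=float)
    if len(r) == 0:
        raise ValidationError("empty leaf")
    denom = float((p * (1.0 - p)).sum())
    num = float(r.sum())
    if denom < 1e-12:
        logger.warning("leaf_gamma: degenerate denominator; capping gamma")
        return math.copysign(GAMMA_CAP, num) if num != 0.0 else 0.0
    return num / denom


# ---------------------------------------------------------------------------
# regression trees

@dataclass
class _Node:
    """Internal split node or leaf of a regression tree."""

    feature: int = -1
    threshold: float = 0.0
    left: Optional["_Node"] = None
    right: Optional["_Node"] = None
    gamma: float = 0.0
    n_samples: int = 0
    gain: float = 0.0  # squared-error reduction of the split at this node

    @property
    def is_leaf(self) -> bool:
        return self.left is None

    def to_dict(self) -> dict:
        if self.is_leaf:
            return {"gamma": self.gamma, "n": self.n_samples}
        return {
            "feature": self.feature,
            "threshold": self.threshold,
            "gain": self.gain,
            "n": self.n_samples,
            "left": self.left.to_dict(),
            "right": self.right.to_dict(),
        }

    @staticmethod
    def from_dict(d: dict) -> "_Node":
        if "gamma" in d:
            return _Node(gamma=d["gamma"], n_samples=d.get("n", 0))
        return _Node(
            feature=d["feature"],
            threshold=d["threshold"],
            gain=d.get("gain", 0.0),
            n_samples=d.get("n", 0),
            left=_Node.from_dict(d["left"]),
            right=_Node.from_dict(d["right"]),
        )


@dataclass
class RegressionTree:
    """Binary regression tree with per-leaf log-odds increments."""

    root: _Node

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        out = np.empty(len(X))
        for i, row in enumerate(X):
            node = self.root
            while not node.is_leaf:
                node = node.left if row[node.feature] <= node.threshold else node.right
            out[i] = node.gamma
        return out

    def splits(self) -> List[_Node]:
        """All internal nodes, depth-first."""
        out, stack = [], [self.root]
        while stack:
            node = stack.pop()
            if not node.is_leaf:
                out.append(node)
                stack.append(node.right)
                stack.append(node.left)
        return out


def _best_split(X: np.ndarray, r: np.ndarray, idx: np.ndarray, min_leaf: int):
    """Exhaustive scan for the squared-error-optimal split of one leaf.

    Returns (gain, feature, threshold) or None. Gain is the reduction in
    total squared error; ties resolve to the lowest feature index, then
    the lowest threshold.
    """
    n = len(idx)
    if n < 2 * min_leaf:
        return None
    rr = r[idx]
    total = rr.sum()
    best = None  # (neg order key) -> track manually
    for f in range(X.shape[1]):
        vals = X[idx, f]
        order = np.argsort(vals, kind="mergesort")
        v_sorted = vals[order]
        r_sorted = rr[order]
        csum = np.cumsum(r_sorted)
        # candidate split after position i (0-based): left = first i+1
        pos = np.arange(1, n)
        distinct = v_sorted[1:] != v_sorted[:-1]
        valid = distinct & (pos >= min_leaf) & (n - pos >= min_leaf)
        if not valid.any():
            continue
        nl = pos[valid].astype(float)
        sl = csum[:-1][valid]
        gain = sl**2 / nl + (total - sl) ** 2 / (n - nl) - total**2 / n
        thresholds = 0.5 * (v_sorted[:-1][valid] + v_sorted[1:][valid])
        j = int(np.argmax(gain))
        g = float(gain[j])
        # among equal gains within this feature, take the lowest threshold
        tied = np.flatnonzero(np.isclose(gain, g, rtol=0, atol=1e-12))
        j = tied[int(np.argmin(thresholds[tied]))]
        g = float(gain[j])
        cand = (g, f, float(thresholds[j]))
        if g <= 1e-15:
            continue
        if best is None or g > best[0] + 1e-15:
            best = cand
        # equal gain across features: keep the earlier (lower) feature — already kept
    return best


def fit_tree(X: np.ndarray, residuals: np.ndarray, p: np.ndarray, cfg: GBConfig) -> RegressionTree:
    """Grow a least-squares tree on the residuals, best-first.

    Leaves are expanded in order of decreasing squared-error reduction
    until ``max_leaf_nodes`` is reached or no split improves the fit.
    Leaf outputs are Newton-step gammas from :func:`leaf_gamma`.
    """
    X = np.asarray(X, dtype=float)
    residuals = np.asarray(residuals, dtype=float)
    p = np.asarray(p, dtype=float)
    all_idx = np.arange(len(X))
    root = _Node(n_samples=len(X))
    # frontier entries: (negative gain, creation order, node, idx, split)
    frontier = []
    counter = itertools.count()

    def consider(node, idx):
        split = _best_split(X, residuals, idx, cfg.min_samples_leaf)
        if split is not None:
            frontier.append((-split[0], next(counter), node, idx, split))

    leaves: List[Tuple[_Node, np.ndarray]] = [(root, all_idx)]
    consider(root, all_idx)
    n_leaves = 1
    while frontier and n_leaves < cfg.max_leaf_nodes:
        frontier.sort(key=lambda e: (e[0], e[1]))
        _, _, node, idx, (gain, f, thr) = frontier.pop(0)
        mask = X[idx, f] <= thr
        li, ri = idx[mask], idx[~mask]
        node.feature, node.threshold, node.gain = f, thr, gain
        node.left = _Node(n_samples=len(li))
        node.right = _Node(n_samples=len(ri))
        leaves = [(nd, ix) for nd, ix in leaves if nd is not node]
        leaves.append((node.left, li))
        leaves.append((node.right, ri))
        consider(node.left, li)
        consider(node.right, ri)
        n_leaves += 1
    for node, idx in leaves:
        node.gamma = leaf_gamma(residuals[idx], p[idx])
        node.n_samples = len(idx)
    return RegressionTree(root=root)


# ---------------------------------------------------------------------------
# boosting

@dataclass
class GBModel:
    """Fitted gradient-boosting ensemble."""

    f0: float
    nu: float
    trees: List[RegressionTree] = field(default_factory=list)
    loss_trajectory: List[float] = field(default_factory=list)
    n_features: int = 4
    feature_names: Tuple[str, ...] = DEFAULT_FEATURE_NAMES

    def decision_function(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise ValidationError(
                f"feature arity {X.shape[1] if X.ndim == 2 else '?'} != training arity {self.n_features}"
            )
        z = np.full(len(X), self.f0)
        for tree in self.trees:
            z += self.nu * tree.predict(X)
        return z

    def to_dict(self) -> dict:
        return {
            "f0": self.f0,
            "nu": self.nu,
            "n_features": self.n_features,
            "feature_names": list(self.feature_names),
            "loss_trajectory": self.loss_trajectory,
            "trees": [t.root.to_dict() for t in self.trees],
        }

    @staticmethod
    def from_dict(d: dict) -> "GBModel":
        return GBModel(
            f0=d["f0"],
            nu=d["nu"],
            n_features=d["n_features"],
            feature_names=tuple(d.get("feature_names", DEFAULT_FEATURE_NAMES)),
            loss_trajectory=list(d.get("loss_trajectory", [])),
            trees=[RegressionTree(root=_Node.from_dict(td)) for td in d["trees"]],
        )


def fit(table: FeatureTable, cfg: GBConfig) -> GBModel:
    """Train the boosting ensemble.

    Each stage fits a regression tree to the pseudo-residuals of the
    current model and shrinks its contribution by ``cfg.nu``. The summed
    cross-entropy after each stage is recorded in ``loss_trajectory``.
    """
    f0 = initial_log_odds(table.y)
    model = GBModel(
        f0=f0,
        nu=cfg.nu,
        n_features=table.X.shape[1],
        feature_names=table.feature_names,
    )
    z = np.full(len(table), f0)
    for _ in range(cfg.n_stages):
        p = prob_from_log_odds(z)
        r = pseudo_residuals(table.y, p)
        tree = fit_tree(table.X, r, p, cfg)
        model.trees.append(tree)
        z = z + cfg.nu * tree.predict(table.X)
        model.loss_trajectory.append(cross_entropy(table.y, prob_from_log_odds(z)))
    return model


def predict_proba(model: GBModel, X) -> np.ndarray:
    """Class-1 probability via the logistic transform of the ensemble score."""
    return prob_from_log_odds(model.decision_function(X))


def predict(model: GBModel, X, threshold: float = 0.5) -> np.ndarray:
    return (predict_proba(model, X) >= threshold).astype(int)


def feature_importance(model: GBModel) -> np.ndarray:
    """Per-feature squared-error reduction summed over all splits, normalized to 1."""
    imp = np.zeros(model.n_features)
    for tree in model.trees:
        for node in tree.splits():
            imp[node.feature] += node.gain
    total = imp.sum()
    if total <= 0:
        logger.warning("feature_importance: model has no splits; returning zeros")
        return imp
    return imp / total


def grid_search(
    table: FeatureTable,
    grid: Dict[str, List],
    folds: int = 5,
    seed: int = 0,
) -> GBConfig:
    """Pick the config minimizing mean held-out cross-entropy over
    stratified folds. The full result table is logged. Deterministic
    given the seed; ties resolve to the first grid point in iteration
    order (sorted keys, listed values in order)."""
    from hdx2ss.validation import stratified_kfold

    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ValidationError("empty hyper-parameter grid")
    keys = sorted(grid)
    fold_of = stratified_kfold(table.y, folds, seed)
    best_cfg, best_loss = None, np.inf
    for combo in itertools.product(*(grid[k] for k in keys)):
        params = dict(zip(keys, combo))
        cfg = GBConfig(seed=seed, **params)
        losses = []
        for f in range(folds):
            tr, va = fold_of != f, fold_of == f
            sub = FeatureTable(table.X[tr], table.y[tr], table.feature_names)
            m = fit(sub, cfg)
            p = predict_proba(m, table.X[va])
            losses.append(cross_entropy(table.y[va], p) / va.sum())
        mean_loss = float(np.mean(losses))
        logger.info("grid point %s: mean CV cross-entropy %.5f", params, mean_loss)
        if mean_loss < best_loss:
            best_loss, best_cfg = mean_loss, cfg
    return best_cfg
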