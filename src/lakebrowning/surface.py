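"""Pairwise beta-diversity response surfaces over the browning gradient.

The regression problem: every pair of sites contributes a row
(g_site1, g_site2) -> Bray-Curtis distance, and a model of that map is
predicted over a square meshgrid of gradient values.  Nonmonotonic
structure (regime thresholds, alternative states) shows up as ridges and
valleys that a monotone (low-degree polynomial) baseline cannot represent.

Four model families are provided: gradient-boosted regression trees with
second-order (Newton) leaf weights and L2 leaf regularization, a random
forest, a small feed-forward network (Xavier init, ReLU, MSE loss, plain
mini-batch gradient descent), and an SVD-based polynomial least-squares
baseline with bias-variance degree selection.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    DegenerateGradientError,
    DivergenceError,
    InvalidHyperparameterError,
    SplitError,
    ZeroVarianceError,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# pair dataset
# ---------------------------------------------------------------------------

@dataclass
class PairDataset:
    """Rows of (g1, g2, d) with site-pair provenance.

    In symmetric mode both orderings (i, j) and (j, i) are present with the
    same distance, which encourages fitted surfaces to be symmetric; the
    ``pair_key`` column identifies the unordered pair so splits can keep
    mirrored rows together.
    """

    frame: pd.DataFrame
    symmetric: bool

    @property
    def x(self) -> np.ndarray:
        return self.frame[["g1", "g2"]].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.frame["d"].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.frame)


def build_pair_dataset(gradient, distances, symmetric: bool = True) -> PairDataset:
    """All site pairs (diagonal excluded) as a regression table."""
    g = np.asarray(gradient, dtype=float)
    dm = distances.to_numpy() if isinstance(distances, pd.DataFrame) else np.asarray(distances, float)
    n = len(g)
    if dm.shape != (n, n):
        raise ValueError(f"distance matrix shape {dm.shape} != ({n}, {n})")
    iu, ju = np.triu_indices(n, k=1)
    rows = {
        "i": iu, "j": ju, "g1": g[iu], "g2": g[ju], "d": dm[iu, ju],
        "pair_key": iu * n + ju,
    }
    frame = pd.DataFrame(rows)
    if symmetric:
        mirror = frame.rename(columns={"i": "j", "j": "i", "g1": "g2", "g2": "g1"})
        frame = pd.concat([frame, mirror], ignore_index=True)[
            ["i", "j", "g1", "g2", "d", "pair_key"]
        ]
    return PairDataset(frame, symmetric)


def split_train_test(
    pairs: PairDataset, train_frac: float = 0.8, seed: int = 0,
    *, site_blocked: bool = False,
) -> tuple[PairDataset, PairDataset]:
    """Seeded train/test split over unordered pairs.

    Mirrored rows always land in the same fold (the two orderings carry the
    identical target, so splitting them would leak).  ``site_blocked=True``
    instead holds out all pairs touching a random site subset, for users who
    want to respect the non-independence of distances sharing a site.
    """
    frame = pairs.frame
    if len(frame) < 5:
        raise SplitError(f"need >= 5 rows to split, got {len(frame)}")
    rng = np.random.default_rng(seed)
    if site_blocked:
        sites = np.unique(frame[["i", "j"]].to_numpy())
        held = rng.permutation(sites)[: max(1, int(round(len(sites) * (1 - train_frac))))]
        test_mask = frame["i"].isin(held) | frame["j"].isin(held)
    else:
        keys = frame["pair_key"].unique()
        perm = rng.permutation(keys)
        n_test = int(round(len(keys) * (1 - train_frac)))
        test_keys = set(perm[:n_test].tolist())
        test_mask = frame["pair_key"].isin(test_keys)
    train = PairDataset(frame[~test_mask].reset_index(drop=True), pairs.symmetric)
    test = PairDataset(frame[test_mask].reset_index(drop=True), pairs.symmetric)
    return train, test


# ---------------------------------------------------------------------------
# gradient-boosted trees (second-order, squared loss)
# ---------------------------------------------------------------------------

class _TreeNode:
    __slots__ = ("feature", "threshold", "left", "right", "value")

    def __init__(self, value: float):
        self.feature = -1
        self.threshold = 0.0
        self.left = None
        self.right = None
        self.value = value


class _RegressionTree:
    """Depth-limited exact-greedy regression tree on residuals.

    For squared loss the Newton leaf weight is sum(residuals)/(count+lam)
    and the split gain is the increase in sum g^2/(count+lam) over children,
    which reduces to the classic best-SSE split when lam = 0.
    """

    def __init__(self, max_depth: int, reg_lambda: float, min_samples_leaf: int = 1):
        self.max_depth = max_depth
        self.reg_lambda = reg_lambda
        self.min_samples_leaf = min_samples_leaf
        self.root: _TreeNode | None = None

    def _leaf_value(self, r: np.ndarray) -> float:
        return float(r.sum() / (len(r) + self.reg_lambda))

    def _score(self, s: float, n: int) -> float:
        return s * s / (n + self.reg_lambda)

    def _best_split(self, x: np.ndarray, r: np.ndarray):
        n = len(r)
        best = (0.0, -1, 0.0)  # gain, feature, threshold
        total = r.sum()
        parent = self._score(total, n)
        for f in range(x.shape[1]):
            order = np.argsort(x[:, f], kind="stable")
            xv, rv = x[order, f], r[order]
            csum = np.cumsum(rv)
            # candidate split after position k (1..n-1) where value changes
            valid = xv[1:] != xv[:-1]
            if not valid.any():
                continue
            ks = np.nonzero(valid)[0] + 1
            left = csum[ks - 1]
            gain = (
                left**2 / (ks + self.reg_lambda)
                + (total - left) ** 2 / (n - ks + self.reg_lambda)
                - parent
            )
            b = int(np.argmax(gain))
            if gain[b] > best[0] + 1e-15:
                thr = 0.5 * (xv[ks[b] - 1] + xv[ks[b]])
                best = (float(gain[b]), f, float(thr))
        return best

    def _grow(self, x: np.ndarray, r: np.ndarray, depth: int) -> _TreeNode:
        node = _TreeNode(self._leaf_value(r))
        if depth >= self.max_depth or len(r) < 2 * self.min_samples_leaf:
            return node
        gain, f, thr = self._best_split(x, r)
        if f < 0 or gain <= 0:
            return node
        mask = x[:, f] <= thr
        node.feature, node.threshold = f, thr
        node.left = self._grow(x[mask], r[mask], depth + 1)
        node.right = self._grow(x[~mask], r[~mask], depth + 1)
        return node

    def fit(self, x: np.ndarray, r: np.ndarray) -> "_RegressionTree":
        self.root = self._grow(x, r, 0)
        return self

    def predict(self, x: np.ndarray) -> np.ndarray:
        out = np.empty(len(x))
        stack = [(self.root, np.arange(len(x)))]
        while stack:
            node, idx = stack.pop()
            if node.feature < 0:
                out[idx] = node.value
                continue
            mask = x[idx, node.feature] <= node.threshold
            stack.append((node.left, idx[mask]))
            stack.append((node.right, idx[~mask]))
        return out


@dataclass
class SurfaceModel:
    """A fitted distance-surface model with its training data attached."""

    method: str
    params: dict
    _predict: object
    train_x: np.ndarray
    train_y: np.ndarray
    train_history: list = field(default_factory=list)

    def predict(self, x) -> np.ndarray:
        return self._predict(np.asarray(x, dtype=float))


def fit_gradient_boost(
    train: PairDataset,
    rounds: int = 300,
    depth: int = 3,
    learning_rate: float = 0.1,
    reg_lambda: float = 1.0,
    seed: int = 0,
) -> SurfaceModel:
    """Boosted depth-limited trees with shrinkage and Newton leaf weights.

    The base score is the training mean; each round fits a tree to the
    current residuals with leaf weight sum(r)/(n_leaf + lambda) and adds it
    scaled by ``learning_rate``.  Training MSE is recorded per round in
    ``train_history`` and is non-increasing for learning_rate in (0, 1] and
    lambda >= 0.  ``seed`` is accepted for interface uniformity; the exact
    greedy fit is deterministic.
    """
    if learning_rate <= 0:
        raise InvalidHyperparameterError("learning_rate must be > 0")
    if rounds < 0:
        raise InvalidHyperparameterError("rounds must be >= 0")
    if reg_lambda < 0:
        raise InvalidHyperparameterError("reg_lambda must be >= 0")
    x, y = train.x, train.y
    base = float(y.mean())
    trees: list[_RegressionTree] = []
    pred = np.full(len(y), base)
    history = [float(((y - pred) ** 2).mean())]
    for _ in range(rounds):
        tree = _RegressionTree(depth, reg_lambda).fit(x, y - pred)
        pred = pred + learning_rate * tree.predict(x)
        trees.append(tree)
        history.append(float(((y - pred) ** 2).mean()))

    def predict(xq: np.ndarray) -> np.ndarray:
        out = np.full(len(xq), base)
        for tree in trees:
            out += learning_rate * tree.predict(xq)
        return out

    params = dict(rounds=rounds, depth=depth, learning_rate=learning_rate,
                  reg_lambda=reg_lambda, seed=seed)
    return SurfaceModel("gbt", params, predict, x, y, history)


def fit_random_forest(
    train: PairDataset,
    n_trees: int = 300,
    bootstrap: bool = True,
    feature_subset: int | str | None = None,
    seed: int = 0,
) -> SurfaceModel:
    """Random-forest regressor (scikit-learn backed); prediction = mean of trees."""
    from sklearn.ensemble import RandomForestRegressor

    if n_trees < 1:
        raise InvalidHyperparameterError("n_trees must be >= 1")
    x, y = train.x, train.y
    rf = RandomForestRegressor(
        n_estimators=n_trees,
        bootstrap=bootstrap,
        max_features=feature_subset if feature_subset is not None else 1.0,
        random_state=seed,
    ).fit(x, y)
    params = dict(n_trees=n_trees, bootstrap=bootstrap,
                  feature_subset=feature_subset, seed=seed)
    model = SurfaceModel("random_forest", params, rf.predict, x, y)
    model.estimators_ = rf.estimators_
    return model


class _FFNN:
    """Minimal fully connected network: ReLU hidden layers, linear output.

    Weights start Xavier-uniform (bounded by +-sqrt(6/(fan_in+fan_out))),
    biases at zero; training is plain mini-batch gradient descent on the
    MSE.  Inputs are z-scored internally.
    """

    def __init__(self, layer_sizes, seed):
        rng = np.random.default_rng(seed)
        self.weights, self.biases = [], []
        for fan_in, fan_out in zip(layer_sizes[:-1], layer_sizes[1:]):
            bound = np.sqrt(6.0 / (fan_in + fan_out))
            self.weights.append(rng.uniform(-bound, bound, size=(fan_in, fan_out)))
            self.biases.append(np.zeros(fan_out))
        self.rng = rng

    def forward(self, x):
        acts = [x]
        h = x
        for w, b in zip(self.weights[:-1], self.biases[:-1]):
            h = np.maximum(h @ w + b, 0.0)
            acts.append(h)
        acts.append(h @ self.weights[-1] + self.biases[-1])
        return acts

    def train_epoch(self, x, y, lr, batch_size):
        idx = self.rng.permutation(len(x))
        for lo in range(0, len(x), batch_size):
            sel = idx[lo : lo + batch_size]
            acts = self.forward(x[sel])
            m = len(sel)
            delta = 2.0 * (acts[-1] - y[sel, None]) / m
            for li in range(len(self.weights) - 1, -1, -1):
                grad_w = acts[li].T @ delta
                grad_b = delta.sum(axis=0)
                if li > 0:
                    delta = (delta @ self.weights[li].T) * (acts[li] > 0)
                self.weights[li] -= lr * grad_w
                self.biases[li] -= lr * grad_b


def fit_ffnn(
    train: PairDataset,
    hidden_layers: tuple[int, ...] = (16, 16),
    epochs: int = 500,
    learning_rate: float = 0.01,
    batch_size: int = 32,
    seed: int = 0,
) -> SurfaceModel:
    """Feed-forward network on z-scored inputs; raises on non-finite loss."""
    if epochs < 1:
        raise InvalidHyperparameterError("epochs must be >= 1")
    x, y = train.x, train.y
    mu, sd = x.mean(axis=0), x.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    xs = (x - mu) / sd
    layer_sizes = [x.shape[1], *hidden_layers, 1]
    net = _FFNN(layer_sizes, seed)
    history = []
    for epoch in range(epochs):
        net.train_epoch(xs, y, learning_rate, batch_size)
        loss = float(((net.forward(xs)[-1][:, 0] - y) ** 2).mean())
        if not np.isfinite(loss):
            raise DivergenceError(f"non-finite training loss at epoch {epoch}")
        history.append(loss)

    def predict(xq: np.ndarray) -> np.ndarray:
        return net.forward((xq - mu) / sd)[-1][:, 0]

    params = dict(hidden_layers=tuple(hidden_layers), epochs=epochs,
                  learning_rate=learning_rate, batch_size=batch_size, seed=seed)
    model = SurfaceModel("ffnn", params, predict, x, y, history)
    model.network = net
    return model


def _poly_design(x: np.ndarray, degree: int) -> np.ndarray:
    cols = [
        x[:, 0] ** a * x[:, 1] ** b
        for total in range(degree + 1)
        for a in range(total + 1)
        for b in [total - a]
    ]
    return np.column_stack(cols)


def fit_polynomial(train: PairDataset, degree: int = 1, rcond: float = 1e-10) -> SurfaceModel:
    """OLS on all monomials g1^a g2^b with a+b <= degree, solved by SVD."""
    if degree < 0:
        raise InvalidHyperparameterError("degree must be >= 0")
    x, y = train.x, train.y
    if len(y) < 1:
        raise InvalidHyperparameterError("no training rows")
    design = _poly_design(x, degree)
    coef, *_ = np.linalg.lstsq(design, y, rcond=rcond)

    def predict(xq: np.ndarray) -> np.ndarray:
        return _poly_design(xq, degree) @ coef

    model = SurfaceModel("polynomial", dict(degree=degree, rcond=rcond), predict, x, y)
    model.coef_ = coef
    return model


@dataclass
class DegreeSelection:
    """Bias-variance bookkeeping of polynomial degree selection."""

    chosen: int
    degrees: list[int]
    error: list[float]
    variance: list[float]
    bias_sq_plus_noise: list[float]


def select_degree(
    pairs: PairDataset, degrees=range(0, 7), n_resamples: int = 30, seed: int = 0,
) -> DegreeSelection:
    """Choose a polynomial degree by the bias-variance trade-off.

    The pair table is split once (seeded) into train/test; for each degree,
    models are fitted on bootstrap resamples of the train fold and evaluated
    on the test fold.  Per test point, E[(pred - y)^2] decomposes exactly
    into Var(pred) + (mean_pred - y)^2; the latter confounds bias^2 with
    irreducible noise, which is reported as one term.  The chosen degree
    minimizes mean test error; ties go to the lowest degree.
    """
    degrees = list(degrees)
    if len(degrees) < 2:
        raise ValueError("need >= 2 candidate degrees")
    train, test = split_train_test(pairs, 0.8, seed)
    rng = np.random.default_rng(seed)
    err, var, bias = [], [], []
    for degree in degrees:
        preds = np.empty((n_resamples, len(test)))
        frame = train.frame
        for r in range(n_resamples):
            take = rng.integers(0, len(frame), size=len(frame))
            boot = PairDataset(frame.iloc[take].reset_index(drop=True), train.symmetric)
            preds[r] = fit_polynomial(boot, degree).predict(test.x)
        err.append(float(((preds - test.y[None, :]) ** 2).mean()))
        var.append(float(preds.var(axis=0).mean()))
        bias.append(float(((preds.mean(axis=0) - test.y) ** 2).mean()))
    err_arr = np.asarray(err)
    chosen = degrees[int(np.argmin(np.round(err_arr, 12)))]
    return DegreeSelection(chosen, degrees, err, var, bias)


# ---------------------------------------------------------------------------
# meshgrid prediction and metrics
# ---------------------------------------------------------------------------

@dataclass
class MeshSurface:
    """Predicted distance surface over a shared gradient axis."""

    axis: np.ndarray
    values: np.ndarray
    step: float
    baseline: float

    def to_frame(self) -> pd.DataFrame:
        labels = [f"{v:.6g}" for v in self.axis]
        return pd.DataFrame(self.values, index=labels, columns=labels)


def predict_meshgrid(model: SurfaceModel, gradient, max_grid: int = 500,
                     symmetrize: bool = True) -> MeshSurface:
    """Predict the surface on a square grid spanning the gradient range.

    The step is the smallest positive pairwise difference of the observed
    gradient values — the finest resolution the data can support — inflated
    (with a log message) whenever that rule would exceed ``max_grid`` axis
    points.  The baseline is the mean over off-diagonal cells.

    The target d(g1, g2) is a distance and therefore symmetric in its
    arguments; greedy tree fits reproduce that symmetry only approximately,
    so by default the two query orientations are averaged
    (``S <- (S + S^T) / 2``), which imposes the known invariance exactly.
    """
    g = np.unique(np.asarray(gradient, dtype=float))
    if g.size < 2:
        raise DegenerateGradientError("all gradient values are identical")
    step = float(np.diff(g).min())
    span = float(g[-1] - g[0])
    n_axis = int(np.floor(span / step + 1e-9)) + 1
    if n_axis > max_grid:
        step = span / (max_grid - 1)
        n_axis = max_grid
        logger.info("meshgrid step inflated to %.6g to respect max_grid=%d",
                    step, max_grid)
    axis = g[0] + step * np.arange(n_axis)
    u, v = np.meshgrid(axis, axis, indexing="ij")
    query = np.column_stack([u.ravel(), v.ravel()])
    values = model.predict(query).reshape(n_axis, n_axis)
    if symmetrize:
        values = 0.5 * (values + values.T)
    off = ~np.eye(n_axis, dtype=bool)
    return MeshSurface(axis, values, step, float(values[off].mean()))


@dataclass(frozen=True)
class FitMetrics:
    train_mse: float
    test_mse: float
    train_r2: float
    test_r2: float


def _r2(y: np.ndarray, pred: np.ndarray) -> float:
    ss_tot = ((y - y.mean()) ** 2).sum()
    if ss_tot == 0:
        raise ZeroVarianceError(
            "R^2 undefined: zero-variance targets",
            mse=float(((y - pred) ** 2).mean()),
        )
    return float(1.0 - ((y - pred) ** 2).sum() / ss_tot)


def evaluate_model(model: SurfaceModel, test: PairDataset) -> FitMetrics:
    """Train/test MSE and R^2 (each fold's own mean defines its SS_tot)."""
    if len(test) == 0:
        raise ValueError("test set is empty")
    pred_tr = model.predict(model.train_x)
    pred_te = model.predict(test.x)
    train_mse = float(((model.train_y - pred_tr) ** 2).mean())
    test_mse = float(((test.y - pred_te) ** 2).mean())
    return FitMetrics(train_mse, test_mse,
                      _r2(model.train_y, pred_tr), _r2(test.y, pred_te))
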