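"""Neural promoter classifier: a 7-2-1 logistic MLP trained by rprop+.

The seven dinucleotide free energies of the BRE+TATA slice feed a
multilayer perceptron with two logistic hidden neurons and one logistic
output neuron.  Training minimizes the sum-of-squared-errors
E = ½ Σ (o − y)² by resilient backpropagation with weight backtracking
(rprop+): each weight keeps its own step size, grown by η⁺ = 1.2 while the
partial derivative keeps its sign and shrunk by η⁻ = 0.5 (with the previous
step undone) when it flips.  Training stops when the largest partial
derivative falls below ``grad_threshold`` or after ``max_steps`` full-batch
steps.  Model assessment uses stratified k-fold cross-validation (default
k = 10) and ROC curves over a decision-threshold grid.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .coords import CORE_START, offset_from_anchor
from .evalmetrics import ConfusionMatrix, confusion, metric_report
from .statclf import SliceSpec
from .thermo import DinucleotideTable, encode_sequence

N_INPUT, N_HIDDEN, N_OUTPUT = 7, 2, 1


@dataclass
class TrainConfig:
    """rprop+ training configuration.

    Step-size constants are the conventional rprop defaults; the step cap
    of 200,000 balances convergence and compute.
    """

    algorithm: str = "rprop+"
    max_steps: int = 200_000
    grad_threshold: float = 0.01
    k_folds: int = 10
    eta_plus: float = 1.2
    eta_minus: float = 0.5
    delta0: float = 0.1
    delta_max: float = 50.0
    delta_min: float = 1e-6
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.max_steps < 1:
            raise ValueError("max_steps must be at least 1")
        if not (self.eta_minus < 1.0 < self.eta_plus):
            raise ValueError("rprop requires eta_minus < 1 < eta_plus")
        if self.k_folds < 2:
            raise ValueError("cross-validation needs at least 2 folds")


@dataclass
class MLPModel:
    """Trained 7→2→1 network (logistic activations throughout)."""

    w1: np.ndarray  # (2, 7)
    b1: np.ndarray  # (2,)
    w2: np.ndarray  # (2,)
    b2: float
    slice: SliceSpec = field(default_factory=SliceSpec)
    tag: str = ""
    train_log: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.w1 = np.asarray(self.w1, dtype=float).reshape(N_HIDDEN, N_INPUT)
        self.b1 = np.asarray(self.b1, dtype=float).reshape(N_HIDDEN)
        self.w2 = np.asarray(self.w2, dtype=float).reshape(N_HIDDEN)
        self.b2 = float(self.b2)
        for arr in (self.w1, self.b1, self.w2):
            if not np.all(np.isfinite(arr)):
                raise ValueError("model weights must be finite")

    def to_dict(self) -> dict:
        return {
            "kind": "ann",
            "w1": self.w1.tolist(),
            "b1": self.b1.tolist(),
            "w2": self.w2.tolist(),
            "b2": self.b2,
            "slice": asdict(self.slice),
            "tag": self.tag,
            "train_log": self.train_log,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MLPModel":
        return cls(
            w1=np.array(d["w1"]), b1=np.array(d["b1"]),
            w2=np.array(d["w2"]), b2=d["b2"],
            slice=SliceSpec(**d["slice"]), tag=d.get("tag", ""),
            train_log=d.get("train_log", {}),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "MLPModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def featurize(
    record,
    slice_spec: SliceSpec,
    table: DinucleotideTable,
    *,
    anchor: int = CORE_START,
) -> np.ndarray:
    """The 7 dinucleotide energies of the slice, 5'→3', fed raw (no rescaling)."""
    seq = getattr(record, "seq", record)
    i0 = offset_from_anchor(anchor, slice_spec.start)
    if i0 < 0 or i0 + slice_spec.span_nt > len(seq):
        raise ValueError(
            f"slice at {slice_spec.start} falls outside the {len(seq)}-nt sequence"
        )
    window = seq[i0 : i0 + slice_spec.span_nt]
    if slice_spec.gapped:
        window = window[0:2] + window[4:10]
    values = encode_sequence(window, table).values
    if len(values) != N_INPUT:
        raise ValueError(
            f"slice yields {len(values)} dinucleotide values; the network "
            f"expects {N_INPUT}"
        )
    return values


def featurize_set(records, slice_spec, table, *, anchor: int = CORE_START) -> np.ndarray:
    """Stack featurize over records into an (n, 7) design matrix."""
    return np.vstack([featurize(r, slice_spec, table, anchor=anchor) for r in records])


# --- forward / backward ---------------------------------------------------

_N_PARAMS = N_HIDDEN * N_INPUT + N_HIDDEN + N_HIDDEN + 1


def _unpack(theta: np.ndarray):
    w1 = theta[:14].reshape(N_HIDDEN, N_INPUT)
    b1 = theta[14:16]
    w2 = theta[16:18]
    b2 = theta[18]
    return w1, b1, w2, b2


def _forward(theta: np.ndarray, X: np.ndarray):
    w1, b1, w2, b2 = _unpack(theta)
    h = _sigmoid(X @ w1.T + b1)            # (n, 2)
    o = _sigmoid(h @ w2 + b2)              # (n,)
    return h, o


def sse_loss_and_grad(theta: np.ndarray, X: np.ndarray, y: np.ndarray):
    """SSE error E = ½Σ(o−y)² and its gradient w.r.t. all 19 parameters."""
    w1, b1, w2, b2 = _unpack(theta)
    h, o = _forward(theta, X)
    err = o - y
    E = 0.5 * float(err @ err)
    do = err * o * (1.0 - o)               # (n,)
    g_w2 = h.T @ do                        # (2,)
    g_b2 = float(do.sum())
    dh = np.outer(do, w2) * h * (1.0 - h)  # (n, 2)
    g_w1 = dh.T @ X                        # (2, 7)
    g_b1 = dh.sum(axis=0)
    grad = np.concatenate([g_w1.ravel(), g_b1, g_w2, [g_b2]])
    return E, grad


def _rprop_fit(X: np.ndarray, y: np.ndarray, cfg: TrainConfig, seed: int):
    rng = np.random.default_rng(seed)
    theta = rng.uniform(-0.5, 0.5, size=_N_PARAMS)
    delta = np.full(_N_PARAMS, cfg.delta0)
    prev_grad = np.zeros(_N_PARAMS)
    prev_step = np.zeros(_N_PARAMS)
    trace: list[tuple[int, float]] = []
    converged = False
    steps = 0
    E = np.inf
    for step in range(1, cfg.max_steps + 1):
        E, grad = sse_loss_and_grad(theta, X, y)
        if not np.isfinite(E) or not np.all(np.isfinite(grad)):
            raise FloatingPointError(f"non-finite training error at step {step}")
        if step == 1 or step % 1000 == 0:
            trace.append((step, E))
        steps = step
        if float(np.max(np.abs(grad))) < cfg.grad_threshold:
            converged = True
            break
        sign_change = grad * prev_grad
        inc, dec = sign_change > 0, sign_change < 0
        delta[inc] = np.minimum(delta[inc] * cfg.eta_plus, cfg.delta_max)
        delta[dec] = np.maximum(delta[dec] * cfg.eta_minus, cfg.delta_min)
        step_vec = -np.sign(grad) * delta
        step_vec[dec] = -prev_step[dec]  # backtrack weights whose gradient flipped
        grad_eff = grad.copy()
        grad_eff[dec] = 0.0
        theta = theta + step_vec
        prev_grad, prev_step = grad_eff, step_vec
    return theta, E, steps, converged, trace


def train_rprop(
    features: np.ndarray,
    labels: np.ndarray,
    cfg: TrainConfig | None = None,
    *,
    slice_spec: SliceSpec | None = None,
    tag: str = "",
) -> MLPModel:
    """Train the 7-2-1 network on a labeled feature matrix.

    On non-convergence within ``max_steps`` one restart with a derived seed
    is attempted; the ``converged`` flag in ``train_log`` reports the
    outcome either way.
    """
    cfg = cfg or TrainConfig()
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=float).ravel()
    if X.ndim != 2 or X.shape[1] != N_INPUT:
        raise ValueError(f"feature matrix must be (n, {N_INPUT}); got {X.shape}")
    if len(X) == 0:
        raise ValueError("empty training set")
    if len(set(y.tolist())) < 2:
        raise ValueError("training requires both classes to be present")

    theta, E, steps, converged, trace = _rprop_fit(X, y, cfg, cfg.rng_seed)
    restarted = False
    if not converged:
        derived = (cfg.rng_seed * 2654435761 + 1) % (2**31)
        theta2, E2, steps2, conv2, trace2 = _rprop_fit(X, y, cfg, derived)
        restarted = True
        if conv2 or E2 < E:
            theta, E, steps, converged, trace = theta2, E2, steps2, conv2, trace2

    w1, b1, w2, b2 = _unpack(theta)
    return MLPModel(
        w1=w1, b1=b1, w2=w2, b2=b2,
        slice=slice_spec or SliceSpec(), tag=tag,
        train_log={
            "steps": steps,
            "final_error": E,
            "converged": converged,
            "restarted": restarted,
            "error_trace": trace,
        },
    )


def predict(
    model: MLPModel, features: np.ndarray, threshold: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """Raw network outputs and hard labels (promoter iff output > threshold)."""
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if X.shape[1] != N_INPUT:
        raise ValueError(f"features must have {N_INPUT} values; got {X.shape[1]}")
    theta = np.concatenate(
        [model.w1.ravel(), model.b1, model.w2, [model.b2]]
    )
    _, raw = _forward(theta, X)
    labels = (raw > threshold).astype(int)
    return labels, raw


def stratified_folds(labels: np.ndarray, k: int, rng_seed: int) -> np.ndarray:
    """Seeded stratified partition: fold index per record, sizes within 1."""
    y = np.asarray(labels).ravel()
    rng = np.random.default_rng(rng_seed)
    fold_of = np.empty(len(y), dtype=int)
    cursor = 0
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        if len(idx) < k:
            raise ValueError(
                f"class {cls} has {len(idx)} records; cannot stratify into "
                f"{k} folds"
            )
        idx = rng.permutation(idx)
        for j, i in enumerate(idx):
            fold_of[i] = (cursor + j) % k
        cursor += len(idx)
    return fold_of


def kfold_cv(
    features: np.ndarray,
    labels: np.ndarray,
    cfg: TrainConfig | None = None,
    *,
    threshold: float = 0.5,
) -> dict:
    """Stratified k-fold cross-validation of the network.

    Each record is tested exactly once by a model trained on the other
    k−1 folds; test predictions are pooled into one confusion matrix.
    """
    cfg = cfg or TrainConfig()
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int).ravel()
    if len(X) < cfg.k_folds:
        raise ValueError("fewer records than folds")
    fold_of = stratified_folds(y, cfg.k_folds, cfg.rng_seed)
    per_fold: list[ConfusionMatrix] = []
    pooled = ConfusionMatrix()
    for fold in range(cfg.k_folds):
        test = fold_of == fold
        fold_cfg = TrainConfig(**{
            **asdict(cfg), "rng_seed": (cfg.rng_seed + 1000003 * (fold + 1)) % (2**31)
        })
        model = train_rprop(X[~test], y[~test], fold_cfg)
        pred, _ = predict(model, X[test], threshold)
        cm = confusion(pred, y[test])
        per_fold.append(cm)
        pooled = pooled + cm
    return {
        "per_fold": per_fold,
        "pooled": pooled,
        "metrics": metric_report(pooled),
        "fold_of": fold_of,
    }


def roc_curve(
    model: MLPModel,
    features: np.ndarray,
    labels: np.ndarray,
    thresholds: np.ndarray | None = None,
) -> np.ndarray:
    """ROC points over a threshold grid.

    Returns an array of rows (threshold, 1−specificity, recall), sorted by
    threshold and including the endpoints 0 (all positive → (1, 1)) and 1
    (all negative → (0, 0)).
    """
    y = np.asarray(labels, dtype=int).ravel()
    if len(set(y.tolist())) < 2:
        raise ValueError("ROC analysis requires both classes")
    if thresholds is None:
        thresholds = np.linspace(0.0, 1.0, 101)
    thresholds = np.unique(np.concatenate([[0.0, 1.0], np.asarray(thresholds)]))
    _, raw = predict(model, features)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    points = []
    for t in thresholds:
        pred = raw > t
        tp = int(np.sum(pred & (y == 1)))
        fp = int(np.sum(pred & (y == 0)))
        points.append((t, fp / n_neg, tp / n_pos))
    return np.array(points)
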