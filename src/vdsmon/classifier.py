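"""VDS classification: an SVM over velocity sequences.

The kernel mixes two notions of similarity between velocity sequences a
and b:

    K(a, b) = exp(-(alpha * D(a, b) + (1 - alpha) * V(a, b)) / (2 sigma^2))

where D is the DTW distance between the sequences (shape similarity,
robust to pace differences) and V = (mean(a) - mean(b))^2 compares their
overall speed level.  alpha in [0, 1] interpolates between a pure
sequence-shape kernel (alpha = 1) and a pure mean-speed RBF (alpha = 0).

Two normalizations keep D and V on a common scale so that one bandwidth
sigma serves both:

* D is divided by M + N (the two sequence lengths) by default, making it
  a per-alignment-step cost;
* with ``normalize_inputs="zscore_over_training"`` (the default) every
  speed value is z-scored by the global mean/sd of all training speeds
  before either term is computed.

DTW is not an inner-product distance, so the training Gram matrix is not
guaranteed positive semidefinite.  When its smallest eigenvalue is
materially negative the spectrum is clipped at zero before the dual
solve (a standard repair for indefinite similarity SVMs); the model
records whether this happened, and out-of-sample kernel rows are used
unrepaired.

The decision rule is sign(sum_i a_i* y_i K(x_i, x) + b*), with sign(0)
mapped to +1.  Two simpler baselines are included for comparison:
nearest-neighbour on DTW distance, and a conventional RBF SVM on
sequences linearly resampled to a common length.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.svm import SVC

from .dtw import DTWConfig, dtw_distance_matrix
from .features import VelocitySequence

__all__ = [
    "KernelConfig",
    "LabeledSample",
    "VDSModel",
    "velocity_term",
    "vds_kernel",
    "train",
    "classify",
    "decision_value",
    "baseline_dtw_1nn",
    "baseline_svm_fixedvec",
    "FixedLengthSVM",
    "resample_sequence",
    "evaluate",
    "detection_rate_table",
    "grid_search",
    "save_model",
    "load_model",
]

_NORMALIZE_MODES = ("none", "zscore_over_training")


@dataclass(frozen=True)
class KernelConfig:
    """VDS kernel and solver parameters.

    alpha — mixing weight between the DTW term (alpha) and the
    mean-speed term (1 - alpha); bandwidth — RBF sigma; penalty — SVM
    soft-margin C.
    """

    alpha: float = 0.5
    bandwidth: float = 1.0
    penalty: float = 10.0
    normalize_inputs: str = "zscore_over_training"
    normalize_dtw_by_length: bool = True
    dtw: DTWConfig = field(default_factory=DTWConfig)

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if not self.bandwidth > 0:
            raise ValueError("bandwidth must be positive")
        if not self.penalty > 0:
            raise ValueError("penalty must be positive")
        if self.normalize_inputs not in _NORMALIZE_MODES:
            raise ValueError(f"normalize_inputs must be one of {_NORMALIZE_MODES}")


@dataclass
class LabeledSample:
    sequence: VelocitySequence
    label: int

    def __post_init__(self) -> None:
        if self.label not in (+1, -1):
            raise ValueError("label must be +1 or -1")


@dataclass
class VDSModel:
    """A trained VDS classifier.

    ``dual_coefficients`` are the signed products a_i* y_i for the stored
    support samples; ``velocity_summary_stats`` is the (mean, sd) of all
    training speeds when z-scoring is on, else None; ``gram_repaired``
    records whether the training Gram matrix needed spectrum clipping.
    """

    support_samples: list[LabeledSample]
    dual_coefficients: np.ndarray
    bias: float
    kernel_config: KernelConfig
    velocity_summary_stats: tuple[float, float] | None
    gram_repaired: bool
    n_training_samples: int


def _values(seq) -> np.ndarray:
    arr = np.asarray(getattr(seq, "values", seq), dtype=float).ravel()
    if arr.size == 0:
        raise ValueError("velocity sequence is empty")
    return arr


def velocity_term(a, b) -> float:
    """V(a, b): squared difference of mean speeds.  Symmetric, >= 0."""
    return float((_values(a).mean() - _values(b).mean()) ** 2)


def _transform(arrs: list[np.ndarray], stats: tuple[float, float] | None) -> list[np.ndarray]:
    if stats is None:
        return arrs
    mu, sd = stats
    return [(a - mu) / sd for a in arrs]


def _kernel_matrix(
    seqs_a: list[np.ndarray],
    seqs_b: list[np.ndarray] | None,
    cfg: KernelConfig,
) -> np.ndarray:
    """K over already-transformed value arrays."""
    D = dtw_distance_matrix(seqs_a, seqs_b, cfg.dtw, length_normalize=cfg.normalize_dtw_by_length)
    ma = np.array([a.mean() for a in seqs_a])
    mb = ma if seqs_b is None else np.array([b.mean() for b in seqs_b])
    V = (ma[:, None] - mb[None, :]) ** 2
    return np.exp(-(cfg.alpha * D + (1.0 - cfg.alpha) * V) / (2.0 * cfg.bandwidth**2))


def vds_kernel(a, b, cfg: KernelConfig | None = None, stats: tuple[float, float] | None = None) -> float:
    """The combined DTW/velocity RBF kernel between two sequences.

    With the standard DTW boundary, K(a, a) = 1 and K is symmetric.
    ``stats`` (mean, sd), when given, z-scores both inputs first — a
    trained model passes its own training statistics here.
    """
    cfg = cfg or KernelConfig()
    av, bv = _transform([_values(a), _values(b)], stats)
    return float(_kernel_matrix([av], [bv], cfg)[0, 0])


def _prepare(samples: list[LabeledSample], cfg: KernelConfig):
    arrs = [_values(s.sequence) for s in samples]
    y = np.array([s.label for s in samples], dtype=int)
    stats = None
    if cfg.normalize_inputs == "zscore_over_training":
        allv = np.concatenate(arrs)
        sd = float(allv.std())
        if sd == 0.0:
            raise ValueError("degenerate training set: every speed value is identical")
        stats = (float(allv.mean()), sd)
    return arrs, y, stats


def train(samples: list[LabeledSample], cfg: KernelConfig | None = None) -> VDSModel:
    """Fit the VDS SVM on labeled velocity sequences.

    Precomputes the full Gram matrix with :func:`vds_kernel`, repairs it
    by eigenvalue clipping if it is materially indefinite, and solves the
    soft-margin dual with penalty C.  Deterministic given inputs and
    config.  Raises on a single-class training set or on degenerate
    all-identical sequences.
    """
    cfg = cfg or KernelConfig()
    if len(samples) < 2:
        raise ValueError("training needs at least 2 samples")
    labels = {s.label for s in samples}
    if labels != {+1, -1}:
        raise ValueError(f"training needs both classes, got labels {sorted(labels)}")
    arrs, y, stats = _prepare(samples, cfg)
    first = arrs[0]
    if all(len(a) == len(first) and np.array_equal(a, first) for a in arrs[1:]):
        raise ValueError("degenerate training set: all sequences are identical")

    Z = _transform(arrs, stats)
    G = _kernel_matrix(Z, None, cfg)

    eigvals = np.linalg.eigvalsh(G)
    repaired = False
    G_fit = G
    if eigvals[0] < -1e-8 * max(1.0, float(eigvals[-1])):
        w, Q = np.linalg.eigh(G)
        G_fit = (Q * np.clip(w, 0.0, None)) @ Q.T
        G_fit = 0.5 * (G_fit + G_fit.T)
        repaired = True

    svc = SVC(C=cfg.penalty, kernel="precomputed")
    svc.fit(G_fit, y)

    support_idx = svc.support_
    support = [samples[i] for i in support_idx]
    coef = svc.dual_coef_[0].astype(float)  # signed: a_i* y_i
    return VDSModel(
        support_samples=support,
        dual_coefficients=coef,
        bias=float(svc.intercept_[0]),
        kernel_config=cfg,
        velocity_summary_stats=stats,
        gram_repaired=repaired,
        n_training_samples=len(samples),
    )


def _decision_values(model: VDSModel, seqs: list) -> np.ndarray:
    if not model.support_samples:
        raise ValueError("model has no support samples; was it trained?")
    cfg = model.kernel_config
    sv = _transform([_values(s.sequence) for s in model.support_samples], model.velocity_summary_stats)
    qs = _transform([_values(s) for s in seqs], model.velocity_summary_stats)
    K = _kernel_matrix(sv, qs, cfg)  # (n_sv, n_query)
    return model.dual_coefficients @ K + model.bias


def decision_value(model: VDSModel, sample) -> float:
    """Raw decision function value for one sequence (before the sign)."""
    return float(_decision_values(model, [sample])[0])


def classify(model: VDSModel, sample) -> int:
    """Predicted label: sign of the decision value, with sign(0) -> +1."""
    return +1 if decision_value(model, sample) >= 0 else -1


def classify_batch(model: VDSModel, seqs: list) -> np.ndarray:
    d = _decision_values(model, seqs)
    return np.where(d >= 0, 1, -1)


# ---------------------------------------------------------------------------
# Baselines


def baseline_dtw_1nn(train_set: list[LabeledSample], query, dtw_cfg: DTWConfig | None = None) -> int:
    """Label of the DTW-nearest training template; ties keep the first."""
    if not train_set:
        raise ValueError("DTW-1NN needs a non-empty training set")
    d = dtw_distance_matrix([_values(query)], [_values(s.sequence) for s in train_set], dtw_cfg or DTWConfig())
    return train_set[int(np.argmin(d[0]))].label


def _dtw_1nn_batch(train_set: list[LabeledSample], queries: list, dtw_cfg: DTWConfig | None = None) -> np.ndarray:
    d = dtw_distance_matrix([_values(q) for q in queries], [_values(s.sequence) for s in train_set], dtw_cfg or DTWConfig())
    labels = np.array([s.label for s in train_set])
    return labels[np.argmin(d, axis=1)]


def resample_sequence(seq, length: int) -> np.ndarray:
    """Linear resampling of a sequence onto ``length`` evenly spaced points."""
    v = _values(seq)
    if length < 1:
        raise ValueError("length must be >= 1")
    if len(v) == 1:
        return np.full(length, v[0])
    return np.interp(np.linspace(0.0, 1.0, length), np.linspace(0.0, 1.0, len(v)), v)


class FixedLengthSVM:
    """Plain RBF SVM on sequences resampled to a fixed length.

    A conventional SVM needs same-length vectors; sequences are linearly
    resampled to the median training length (or an explicit one) before a
    standard RBF fit.
    """

    def __init__(self, penalty: float = 10.0, length: int | None = None):
        self.penalty = penalty
        self.length = length
        self._svc: SVC | None = None

    def fit(self, samples: list[LabeledSample]) -> "FixedLengthSVM":
        if {s.label for s in samples} != {+1, -1}:
            raise ValueError("training needs both classes")
        if self.length is None:
            self.length = int(np.median([len(_values(s.sequence)) for s in samples]))
        X = np.stack([resample_sequence(s.sequence, self.length) for s in samples])
        y = np.array([s.label for s in samples])
        self._svc = SVC(C=self.penalty, kernel="rbf", gamma="scale")
        self._svc.fit(X, y)
        return self

    def predict(self, seqs: list) -> np.ndarray:
        if self._svc is None:
            raise ValueError("FixedLengthSVM is not fitted")
        X = np.stack([resample_sequence(s, self.length) for s in seqs])
        return self._svc.predict(X)


def baseline_svm_fixedvec(train_set: list[LabeledSample], query, penalty: float = 10.0) -> int:
    """One-shot fixed-length-vector SVM prediction for a single query."""
    return int(FixedLengthSVM(penalty=penalty).fit(train_set).predict([query])[0])


# ---------------------------------------------------------------------------
# Evaluation


def _fit_predict(method: str, train_set, test_seqs, kernel_cfg: KernelConfig):
    if method == "vds":
        model = train(train_set, kernel_cfg)
        return classify_batch(model, test_seqs)
    if method == "dtw_1nn":
        return _dtw_1nn_batch(train_set, test_seqs, kernel_cfg.dtw)
    if method == "svm_fixedvec":
        return FixedLengthSVM(penalty=kernel_cfg.penalty).fit(train_set).predict(test_seqs)
    raise ValueError(f"unknown method {method!r}")


def _rates(y_true: np.ndarray, y_pred: np.ndarray) -> dict[str, float]:
    out = {}
    for cls, name in ((+1, "+1"), (-1, "-1")):
        m = y_true == cls
        out[name] = float((y_pred[m] == cls).mean()) if m.any() else np.nan
    out["overall"] = float((y_pred == y_true).mean())
    return out


def evaluate(
    samples: list[LabeledSample],
    methods: tuple[str, ...] = ("vds", "dtw_1nn", "svm_fixedvec"),
    kernel_cfg: KernelConfig | None = None,
    folds: int | str = "holdout",
    test_fraction: float = 0.3,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-method, per-class detection rates on held-out data.

    ``folds="holdout"`` does one stratified split of ``test_fraction``;
    an integer runs stratified k-fold cross-validation (error if the fold
    count exceeds the smaller class).  The detection rate of a class is
    the fraction of its test samples assigned their true label.
    """
    kernel_cfg = kernel_cfg or KernelConfig()
    y = np.array([s.label for s in samples])
    n_min = min((y == +1).sum(), (y == -1).sum())
    if n_min < 2:
        raise ValueError("evaluation needs at least 2 samples per class")

    if folds == "holdout":
        idx_tr, idx_te = train_test_split(
            np.arange(len(samples)), test_size=test_fraction, stratify=y, random_state=seed
        )
        splits = [(idx_tr, idx_te)]
    else:
        folds = int(folds)
        if folds > n_min:
            raise ValueError(f"fold count {folds} exceeds the smaller class size {n_min}")
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        splits = list(skf.split(np.zeros(len(samples)), y))

    acc: dict[str, list[dict[str, float]]] = {m: [] for m in methods}
    for idx_tr, idx_te in splits:
        tr = [samples[i] for i in idx_tr]
        te_seqs = [samples[i].sequence for i in idx_te]
        y_te = y[idx_te]
        for m in methods:
            acc[m].append(_rates(y_te, np.asarray(_fit_predict(m, tr, te_seqs, kernel_cfg))))

    rows = []
    for m in methods:
        for cls in ("+1", "-1", "overall"):
            rows.append(
                {"method": m, "class": cls,
                 "detection_rate": float(np.mean([r[cls] for r in acc[m]])),
                 "n_test": int(sum(len(s[1]) for s in splits))}
            )
    return pd.DataFrame(rows)


def detection_rate_table(
    train_pool: list[LabeledSample],
    test_set: list[LabeledSample],
    train_sizes: tuple[int, ...],
    methods: tuple[str, ...] = ("vds", "dtw_1nn", "svm_fixedvec"),
    kernel_cfg: KernelConfig | None = None,
) -> pd.DataFrame:
    """Detection rates vs training-set size on a fixed test set.

    For each n in ``train_sizes`` the first n samples of each class in
    ``train_pool`` are used for training.  Rows are training sizes
    (samples per class); columns are method x class detection rates.
    """
    kernel_cfg = kernel_cfg or KernelConfig()
    pos = [s for s in train_pool if s.label == +1]
    neg = [s for s in train_pool if s.label == -1]
    y_te = np.array([s.label for s in test_set])
    te_seqs = [s.sequence for s in test_set]
    rows = {}
    for n in train_sizes:
        if n > len(pos) or n > len(neg):
            raise ValueError(f"train size {n}/class exceeds the pool ({len(pos)}+, {len(neg)}-)")
        tr = pos[:n] + neg[:n]
        row = {}
        for m in methods:
            r = _rates(y_te, np.asarray(_fit_predict(m, tr, te_seqs, kernel_cfg)))
            for cls, v in r.items():
                row[f"{m}:{cls}"] = v
        rows[n] = row
    df = pd.DataFrame(rows).T
    df.index.name = "n_per_class"
    return df


def grid_search(
    samples: list[LabeledSample],
    alphas=(0.25, 0.5, 0.75),
    bandwidths=(0.5, 1.0, 2.0),
    penalties=(1.0, 10.0),
    folds: int = 3,
    seed: int = 0,
    base_cfg: KernelConfig | None = None,
) -> tuple[KernelConfig, float]:
    """Cross-validated search over (alpha, sigma, C); returns (best config, accuracy)."""
    base = base_cfg or KernelConfig()
    best_cfg, best_acc = base, -1.0
    for a in alphas:
        for s in bandwidths:
            for c in penalties:
                cfg = KernelConfig(alpha=a, bandwidth=s, penalty=c,
                                   normalize_inputs=base.normalize_inputs,
                                   normalize_dtw_by_length=base.normalize_dtw_by_length,
                                   dtw=base.dtw)
                df = evaluate(samples, methods=("vds",), kernel_cfg=cfg, folds=folds, seed=seed)
                acc = float(df.loc[df["class"] == "overall", "detection_rate"].iloc[0])
                if acc > best_acc:
                    best_cfg, best_acc = cfg, acc
    return best_cfg, best_acc


# ---------------------------------------------------------------------------
# Serialization


def save_model(model: VDSModel, path) -> None:
    """Serialize a trained model to one JSON file (support sequences inline)."""
    doc = {
        "kernel_config": {**asdict(model.kernel_config), "dtw": asdict(model.kernel_config.dtw)},
        "support_samples": [
            {"label": s.label, "values": [float(v) for v in _values(s.sequence)],
             "source_id": s.sequence.source_id if isinstance(s.sequence, VelocitySequence) else ""}
            for s in model.support_samples
        ],
        "dual_coefficients": [float(c) for c in model.dual_coefficients],
        "bias": model.bias,
        "velocity_summary_stats": list(model.velocity_summary_stats) if model.velocity_summary_stats else None,
        "gram_repaired": model.gram_repaired,
        "n_training_samples": model.n_training_samples,
    }
    Path(path).write_text(json.dumps(doc, sort_keys=True, indent=1))


def load_model(path) -> VDSModel:
    doc = json.loads(Path(path).read_text())
    kc = dict(doc["kernel_config"])
    kc["dtw"] = DTWConfig(**kc["dtw"])
    cfg = KernelConfig(**kc)
    support = [
        LabeledSample(VelocitySequence(np.array(s["values"]), source_id=s.get("source_id", "")), int(s["label"]))
        for s in doc["support_samples"]
    ]
    stats = doc["velocity_summary_stats"]
    return VDSModel(
        support_samples=support,
        dual_coefficients=np.array(doc["dual_coefficients"], dtype=float),
        bias=float(doc["bias"]),
        kernel_config=cfg,
        velocity_summary_stats=tuple(stats) if stats else None,
        gram_repaired=bool(doc["gram_repaired"]),
        n_training_samples=int(doc["n_training_samples"]),
    )
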