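"""AF/SR PPG classification: the validation harness for generated waveforms.

A deliberately simple 6-layer 1-D CNN (filters 4, 8, 16, 32, 64, 128; kernel
3; leaky-ReLU alpha 0.15; truncated-normal init SD 0.05, zero biases; global
average pooling into a 2-way softmax head; cross-entropy with Adam at
learning rate 0.001) consumes 15-second PPG segments sampled at 100 Hz
(1500 samples). Class 0 is sinus rhythm, class 1 is AF.

The harness composes training datasets from three pools — generated AF,
real AF and real SR segments — under four schemes:

    D1: all generated AF            + equally many real SR
    D2: half generated + half real AF + equally many real SR
    D3: all real AF                 + equally many real SR
    D4: half real AF                + half real SR (half the total data)

and evaluates each trained model on a held-out test store (accuracy, AUROC
with a stratified-bootstrap 95% CI, precision/recall/F1, confusion matrix).
Halves are drawn group-wise by parent segment so overlapping slices never
straddle a split, and a leakage guard rejects any train/test parent overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn import metrics as skm

from . import _nn as nn
from .preprocess import SegmentStore

__all__ = [
    "ClassifierSpec", "DatasetScheme", "EvalReport", "CNNClassifier",
    "compose_dataset", "build_classifier", "train_classifier",
    "evaluate_classifier", "run_validation_experiment",
]

SCHEMES = ("D1", "D2", "D3", "D4")


@dataclass(frozen=True)
class ClassifierSpec:
    input_len: int = 1500
    filters: tuple = (4, 8, 16, 32, 64, 128)
    kernel: int = 3
    leaky_alpha: float = 0.15
    init_sd: float = 0.05
    stride: int = 2          # between-layer downsampling (not part of the printed design)
    n_classes: int = 2
    lr: float = 0.001

    def __post_init__(self) -> None:
        if len(self.filters) != 6 or list(self.filters) != sorted(self.filters):
            raise ValueError("expected 6 strictly increasing filter counts")


@dataclass
class DatasetScheme:
    scheme_id: str
    af_generated: int
    af_real: int
    sr_real: int


@dataclass
class EvalReport:
    accuracy: float
    auroc: float
    auroc_ci_low: float
    auroc_ci_high: float
    precision: float
    recall: float
    f1: float
    confusion: tuple  # (TN, FP, FN, TP), class 1 = AF positive
    n_test: int


class CNNClassifier:
    def __init__(self, spec: ClassifierSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        layers: list = []
        in_ch = 1
        for f in spec.filters:
            layers += [
                nn.Conv1d(in_ch, f, spec.kernel, stride=spec.stride, rng=rng,
                          init_sd=spec.init_sd, trunc=True),
                nn.LeakyReLU(spec.leaky_alpha),
            ]
            in_ch = f
        self.features = nn.Sequential(layers)
        self.pool = nn.GlobalAvgPool()
        self.head = nn.Dense(spec.filters[-1], spec.n_classes, rng=rng,
                             init_sd=spec.init_sd, trunc=True)

    def params(self):
        return self.features.params() + self.head.params()

    def n_params(self) -> int:
        return sum(p.value.size for p in self.params())

    def logits(self, x: np.ndarray) -> np.ndarray:
        if x.ndim == 2:
            x = x[:, None, :]
        if x.shape[-1] != self.spec.input_len:
            raise ValueError(
                f"expected input length {self.spec.input_len}, got {x.shape[-1]}"
            )
        h = self.features.forward(x)
        return self.head.forward(self.pool.forward(h))

    def predict_proba(self, x: np.ndarray, batch: int = 256) -> np.ndarray:
        """Class probabilities (softmax), batched for memory."""
        outs = []
        for s in range(0, x.shape[0], batch):
            outs.append(nn.softmax(self.logits(x[s : s + batch])))
        return np.vstack(outs)

    def feature_map(self, x: np.ndarray, batch: int = 256) -> np.ndarray:
        """Pooled last-layer features (n, 128) — the embedding-comparison input."""
        outs = []
        for s in range(0, x.shape[0], batch):
            xb = x[s : s + batch]
            if xb.ndim == 2:
                xb = xb[:, None, :]
            outs.append(self.pool.forward(self.features.forward(xb)))
        return np.vstack(outs)

    def backward_from_logits(self, dlogits: np.ndarray) -> None:
        dy = self.head.backward(dlogits)
        self.features.backward(self.pool.backward(dy))


def _labels_from(store: SegmentStore) -> np.ndarray:
    return (store.labels == "AF").astype(int)


def _groupwise_half(store: SegmentStore, rng: np.random.Generator) -> SegmentStore:
    """Half the store by parent segments (sibling slices stay together)."""
    parents = pd.unique(store.parent_id)
    take = rng.choice(parents, size=len(parents) // 2, replace=False)
    mask = np.isin(store.parent_id, take)
    return store.subset(mask)


def compose_dataset(pools: dict[str, SegmentStore], scheme: str,
                    seed: int = 0) -> tuple[SegmentStore, DatasetScheme]:
    """Assemble a training store for one composition scheme.

    ``pools`` must hold 'generated_af', 'real_af' and 'real_sr' stores. The
    per-scheme counts follow the composition law scaled to the pool sizes;
    halves are selected by seeded group-wise sampling without replacement.
    """
    for key in ("generated_af", "real_af", "real_sr"):
        if key not in pools:
            raise ValueError(f"missing pool {key!r}")
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}")
    rng = np.random.default_rng(seed)
    gen_af, real_af, real_sr = pools["generated_af"], pools["real_af"], pools["real_sr"]
    if scheme == "D1":
        parts = [gen_af, real_sr]
    elif scheme == "D2":
        parts = [_groupwise_half(gen_af, rng), _groupwise_half(real_af, rng), real_sr]
    elif scheme == "D3":
        parts = [real_af, real_sr]
    else:  # D4
        parts = [_groupwise_half(real_af, rng), _groupwise_half(real_sr, rng)]
    data = SegmentStore.concat(parts)
    n_gen = int(np.sum((data.origin == "generated") & (data.labels == "AF")))
    n_raf = int(np.sum((data.origin == "real") & (data.labels == "AF")))
    n_sr = int(np.sum(data.labels == "SR"))
    if len(data) == 0:
        raise ValueError(f"scheme {scheme}: empty composition (pools too small)")
    return data, DatasetScheme(scheme, n_gen, n_raf, n_sr)


def build_classifier(spec: ClassifierSpec | None = None, seed: int = 0) -> CNNClassifier:
    return CNNClassifier(spec or ClassifierSpec(), seed=seed)


def train_classifier(data: SegmentStore, spec: ClassifierSpec | None = None,
                     epochs: int = 50, batch: int = 64, seed: int = 0,
                     verbose: bool = False) -> CNNClassifier:
    """Minimize cross-entropy with Adam (lr from the spec, default 0.001)."""
    spec = spec or ClassifierSpec()
    y = _labels_from(data)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    x = data.channel(data.channels[-1]) if data.n_channels > 1 else data.segments
    model = CNNClassifier(spec, seed=seed)
    opt = nn.Adam(model.params(), lr=spec.lr)
    rng = np.random.default_rng(seed)
    n = x.shape[0]
    model.train_log: list[float] = []
    for epoch in range(epochs):
        order = rng.permutation(n)
        losses = []
        for s in range(0, n, batch):
            idx = order[s : s + batch]
            opt.zero_grad()
            logits = model.logits(x[idx])
            loss, dlogits, _ = nn.softmax_cross_entropy(logits, y[idx])
            model.backward_from_logits(dlogits)
            opt.step()
            losses.append(loss)
        model.train_log.append(float(np.mean(losses)))
        if verbose:
            print(f"epoch {epoch + 1}/{epochs}: CE {model.train_log[-1]:.4f}")
    return model


def _bootstrap_auroc_ci(y: np.ndarray, scores: np.ndarray, n_boot: int,
                        seed: int, alpha: float = 0.05) -> tuple[float, float]:
    """Stratified bootstrap percentile CI for the AUROC."""
    rng = np.random.default_rng(seed)
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    stats = np.empty(n_boot)
    for b in range(n_boot):
        ip = rng.choice(pos, size=len(pos), replace=True)
        ineg = rng.choice(neg, size=len(neg), replace=True)
        idx = np.concatenate([ip, ineg])
        stats[b] = skm.roc_auc_score(y[idx], scores[idx])
    lo, hi = np.percentile(stats, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def evaluate_classifier(model: CNNClassifier, test: SegmentStore,
                        n_boot: int = 2000, seed: int = 0) -> EvalReport:
    """Threshold-free AUROC (class-1 probability) with a stratified-bootstrap
    95% CI, plus accuracy/precision/recall/F1 at the argmax decision and the
    confusion matrix with AF as the positive class."""
    if len(test) == 0:
        raise ValueError("test store is empty")
    y = _labels_from(test)
    x = test.channel(test.channels[-1]) if test.n_channels > 1 else test.segments
    probs = model.predict_proba(x)[:, 1]
    pred = (probs >= 0.5).astype(int)
    tn, fp, fn, tp = skm.confusion_matrix(y, pred, labels=[0, 1]).ravel()
    if len(np.unique(y)) < 2:
        raise ValueError("AUROC undefined on a one-class test set")
    auroc = float(skm.roc_auc_score(y, probs))
    ci_lo, ci_hi = _bootstrap_auroc_ci(y, probs, n_boot, seed)
    return EvalReport(
        accuracy=float(skm.accuracy_score(y, pred)),
        auroc=auroc, auroc_ci_low=ci_lo, auroc_ci_high=ci_hi,
        precision=float(skm.precision_score(y, pred, zero_division=0)),
        recall=float(skm.recall_score(y, pred, zero_division=0)),
        f1=float(skm.f1_score(y, pred, zero_division=0)),
        confusion=(int(tn), int(fp), int(fn), int(tp)),
        n_test=len(test),
    )


def run_validation_experiment(pools: dict[str, SegmentStore], schemes: list[str],
                              test: SegmentStore, epochs: int = 50, batch: int = 64,
                              seed: int = 0, n_boot: int = 2000,
                              spec: ClassifierSpec | None = None) -> pd.DataFrame:
    """Train one identically-configured classifier per scheme; tabulate reports.

    Raises if any training-pool parent segment also appears in the test
    store (slice-overlap leakage guard).
    """
    test_parents = set(test.parent_id.tolist())
    for name, pool in pools.items():
        shared = test_parents.intersection(pool.parent_id.tolist())
        if shared:
            raise ValueError(f"pool {name!r} shares {len(shared)} parent segments with the test set")
    rows = []
    for scheme in schemes:
        data, comp = compose_dataset(pools, scheme, seed=seed)
        model = train_classifier(data, spec=spec, epochs=epochs, batch=batch, seed=seed)
        rep = evaluate_classifier(model, test, n_boot=n_boot, seed=seed)
        rows.append({
            "Dataset": scheme, "GeneratedAF": comp.af_generated,
            "RealAF": comp.af_real, "RealSR": comp.sr_real,
            "Accuracy": rep.accuracy, "AUROC": rep.auroc,
            "CI_low": rep.auroc_ci_low, "CI_high": rep.auroc_ci_high,
            "Precision": rep.precision, "Recall": rep.recall, "F1": rep.f1,
        })
    return pd.DataFrame(rows)
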