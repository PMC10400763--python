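"""Comparison classifiers: SVM, KNN and a plain LSTM, under the same protocol.

The comparison models consume either a block-mean decimation of each segment
(``raw_downsampled``, 1500 -> 150 features) or a 12-dimensional summary
statistics vector (``summary_stats``): mean, sd, skewness, kurtosis, peak
rate, peak-amplitude mean/sd, peak-interval mean/sd, and band powers in the
0.04-0.15, 0.15-0.5 and 0.5-5 Hz bands.  The original experiment does not
state what its SVM/KNN consumed, so neither mode claims fidelity; they exist
to reproduce the comparative structure, not printed numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks, periodogram
from scipy.stats import kurtosis, skew
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .nn import ModelSpec, TrainConfig, build_model
from .nn.layers import Dense, ELU, LSTM, TakeLast
from .nn.network import SegmentNet
from .nn.training import predict as nn_predict, train as nn_train
from .segments import standardize

__all__ = ["BaselineSpec", "featurize", "fit_baseline", "FittedBaseline"]

SPECTRAL_BANDS = ((0.04, 0.15), (0.15, 0.5), (0.5, 5.0))


@dataclass(frozen=True)
class BaselineSpec:
    kind: str  # "svm" | "knn" | "lstm_only"
    feature_mode: str = "summary_stats"
    hyperparams: dict = field(default_factory=dict)

    _ALLOWED = {
        "svm": {"kernel", "C"},
        "knn": {"k", "metric"},
        "lstm_only": {"hidden", "layers", "decimate"},
    }

    def validate(self) -> None:
        if self.kind not in self._ALLOWED:
            raise ValueError(f"unknown baseline kind {self.kind!r}")
        if self.feature_mode not in ("raw_downsampled", "summary_stats"):
            raise ValueError(f"unknown feature_mode {self.feature_mode!r}")
        extra = set(self.hyperparams) - self._ALLOWED[self.kind]
        if extra:
            raise ValueError(f"hyperparams {sorted(extra)} do not apply to kind {self.kind!r}")


def _block_mean_decimate(x: np.ndarray, factor: int = 10) -> np.ndarray:
    n = x.shape[-1] // factor
    return x[..., :n * factor].reshape(*x.shape[:-1], n, factor).mean(axis=-1)


def _summary_features(seg: np.ndarray, fs: float) -> np.ndarray:
    sd = seg.std()
    feats = [seg.mean(), sd]
    if sd < 1e-8:  # constant segment: moments undefined, guard to 0
        feats += [0.0, 0.0]
    else:
        feats += [float(skew(seg)), float(kurtosis(seg))]
    # threshold above the dicrotic hump; min separation below one beat period
    height = seg.min() + 0.55 * (seg.max() - seg.min())
    peaks, props = find_peaks(seg, height=height, distance=max(int(0.4 * fs), 1))
    dur = len(seg) / fs
    feats.append(len(peaks) / dur)  # peak rate (Hz)
    if len(peaks) >= 2:
        amps = props["peak_heights"]
        ivals = np.diff(peaks) / fs
        feats += [amps.mean(), amps.std(), ivals.mean(), ivals.std()]
    else:
        feats += [0.0, 0.0, 0.0, 0.0]
    f, pxx = periodogram(seg, fs=fs)
    for lo, hi in SPECTRAL_BANDS:
        band = (f >= lo) & (f < hi)
        feats.append(float(pxx[band].sum()))
    return np.array(feats)


def featurize(samples: np.ndarray, mode: str = "summary_stats",
              sampling_rate_hz: float = 100.0) -> np.ndarray:
    """Feature table (n_segments, n_features) from standardized segments."""
    x = standardize(np.atleast_2d(samples))
    if mode == "raw_downsampled":
        return _block_mean_decimate(x, 10)
    if mode == "summary_stats":
        return np.stack([_summary_features(seg, sampling_rate_hz) for seg in x])
    raise ValueError(f"unknown feature mode {mode!r}")


class FittedBaseline:
    """Uniform predict surface over sklearn estimators and the LSTM net."""

    def __init__(self, spec: BaselineSpec, estimator, sampling_rate_hz: float):
        self.spec = spec
        self.estimator = estimator
        self.fs = sampling_rate_hz

    def predict(self, samples: np.ndarray, threshold: float = 0.5) -> tuple:
        if self.spec.kind == "lstm_only":
            x = _block_mean_decimate(standardize(samples),
                                     self.spec.hyperparams.get("decimate", 10))
            return nn_predict(self.estimator, x.astype(np.float32), threshold)
        feats = featurize(samples, self.spec.feature_mode, self.fs)
        if hasattr(self.estimator, "predict_proba"):
            p = self.estimator.predict_proba(feats)[:, 1]
        else:
            p = self.estimator.decision_function(feats)
            p = 1.0 / (1.0 + np.exp(-p))
        return p, (p >= threshold).astype(np.int64)


def _build_lstm_only(n_steps: int, hidden: int, n_layers: int, seed: int) -> SegmentNet:
    """2-layer standard LSTM straight on the (decimated) signal + linear head."""
    rng = np.random.default_rng(seed)
    layers: list = []
    feat = 1
    for _ in range(n_layers):
        layers.append(LSTM(feat, hidden, rng))
        feat = hidden
    layers += [TakeLast(), Dense(hidden, 32, rng), ELU(), Dense(32, 1, rng)]
    spec = ModelSpec(input_length=n_steps, conv_groups=(), lstm_layers=n_layers,
                     lstm_hidden=hidden, fc_sizes=(32, 1))
    net = SegmentNet(spec, layers, seed)
    # bypass the conv-stage reshape: feed (B, L) as a (B, L, 1) sequence
    net.forward_logits = lambda x, train=True, _l=layers: _run_seq(_l, x, train)
    return net


def _run_seq(layers, x, train):
    h = np.ascontiguousarray(x, dtype=np.float32)[:, :, None]
    for layer in layers:
        h = layer.forward(h, train=train)
    return h[:, 0]


def fit_baseline(spec: BaselineSpec, x_train: np.ndarray, y_train: np.ndarray,
                 x_val: np.ndarray | None = None, y_val: np.ndarray | None = None,
                 sampling_rate_hz: float = 100.0, seed: int = 0,
                 train_config: TrainConfig | None = None) -> FittedBaseline:
    """Fit one comparison classifier on raw segments (featurized internally)."""
    spec.validate()
    y_train = np.asarray(y_train)
    if len(np.unique(y_train)) < 2:
        raise ValueError("training set must contain both classes")

    if spec.kind == "svm":
        est = make_pipeline(StandardScaler(), SVC(
            kernel=spec.hyperparams.get("kernel", "rbf"),
            C=spec.hyperparams.get("C", 1.0),
            random_state=seed))
        est.fit(featurize(x_train, spec.feature_mode, sampling_rate_hz), y_train)
        return FittedBaseline(spec, est, sampling_rate_hz)

    if spec.kind == "knn":
        est = make_pipeline(StandardScaler(), KNeighborsClassifier(
            n_neighbors=spec.hyperparams.get("k", 5),
            metric=spec.hyperparams.get("metric", "euclidean")))
        est.fit(featurize(x_train, spec.feature_mode, sampling_rate_hz), y_train)
        return FittedBaseline(spec, est, sampling_rate_hz)

    # lstm_only: raw sequence, block-mean decimated for tractability
    factor = spec.hyperparams.get("decimate", 10)
    xd_train = _block_mean_decimate(standardize(x_train), factor).astype(np.float32)
    if x_val is None:
        x_val, y_val = x_train, y_train
    xd_val = _block_mean_decimate(standardize(x_val), factor).astype(np.float32)
    net = _build_lstm_only(xd_train.shape[1],
                           spec.hyperparams.get("hidden", 64),
                           spec.hyperparams.get("layers", 2), seed)
    nn_train(net, xd_train, y_train, xd_val, np.asarray(y_val),
             train_config or TrainConfig(seed=seed, max_epochs=6))
    return FittedBaseline(spec, net, sampling_rate_hz)
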