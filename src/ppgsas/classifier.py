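"""High-level modelling interface: a fit-from-data Model and a Results object.

:class:`ApneaDetector` binds the segment classifier to a SegmentSet and a
split; ``fit()`` trains the network and returns
:class:`ApneaDetectorResults`, which carries the trained network, the
training history, per-part metrics and a text ``summary()``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .metrics import MetricsReport, confusion, metrics
from .nn import ModelSpec, SegmentNet, TrainConfig, build_model, predict as _predict, train as _train
from .segments import SegmentSet, SplitAssignment, make_split, standardize

__all__ = ["ApneaDetector", "ApneaDetectorResults"]


class ApneaDetector:
    """Segment-level sleep-apnea detector (1D CNN-LSTM) bound to a dataset.

    Parameters
    ----------
    segments : SegmentSet
        Fixed-length labelled PPG segments.
    split : SplitAssignment, optional
        Train/validation/test partition; a seeded 6:2:2 segment-level split
        is drawn when omitted.
    model_spec : ModelSpec, optional
        Architecture; defaults to the 8-conv / 4-pool / 2-LSTM / 2-FC network.
    """

    def __init__(self, segments: SegmentSet, split: SplitAssignment | None = None,
                 model_spec: ModelSpec | None = None, seed: int = 0):
        self.segments = segments
        self.split = split if split is not None else make_split(segments, seed=seed)
        self.model_spec = model_spec or ModelSpec(input_length=segments.segment_length)
        if self.model_spec.input_length != segments.segment_length:
            raise ValueError(
                f"model input_length {self.model_spec.input_length} does not match "
                f"segment length {segments.segment_length}")
        self.seed = seed
        # standardized once; the network always sees zero-mean unit-sd segments
        self._x = standardize(segments.samples).astype(np.float32)
        self._y = segments.labels

    @classmethod
    def from_cohort(cls, records: list, segment_length: int = 1500,
                    labeling: str = "subject", **kwargs) -> "ApneaDetector":
        from .segments import segment_cohort
        return cls(segment_cohort(records, segment_length, labeling), **kwargs)

    def part_arrays(self, part: str) -> tuple:
        idx = self.split.parts()[part]
        return self._x[idx], self._y[idx]

    def fit(self, train_config: TrainConfig | None = None) -> "ApneaDetectorResults":
        config = train_config or TrainConfig(seed=self.seed)
        net = build_model(self.model_spec, seed=config.seed)
        x_tr, y_tr = self.part_arrays("train")
        x_va, y_va = self.part_arrays("validation")
        history = _train(net, x_tr, y_tr, x_va, y_va, config)
        return ApneaDetectorResults(self, net, history, config)


class ApneaDetectorResults:
    """Fit results: trained network, history, per-part metrics, summary table."""

    def __init__(self, model: ApneaDetector, net: SegmentNet, history: dict,
                 train_config: TrainConfig):
        self.model = model
        self.net = net
        self.history = history
        self.train_config = train_config
        self._part_metrics: dict[str, MetricsReport] = {}

    @property
    def n_params(self) -> int:
        return self.net.n_params()

    def predict(self, x: np.ndarray | None = None, part: str = "test",
                threshold: float = 0.5) -> tuple:
        """(probabilities, labels) for raw segments ``x`` or a named part."""
        if x is None:
            xs = self.model.part_arrays(part)[0]
        else:
            xs = standardize(np.asarray(x)).astype(np.float32)
        return _predict(self.net, xs, threshold)

    def part_metrics(self, part: str, threshold: float = 0.5) -> MetricsReport:
        key = f"{part}@{threshold}"
        if key not in self._part_metrics:
            x, y = self.model.part_arrays(part)
            _, yhat = _predict(self.net, x, threshold)
            self._part_metrics[key] = metrics(confusion(y, yhat), condition=part)
        return self._part_metrics[key]

    def metrics_frame(self, parts=("validation", "test")) -> pd.DataFrame:
        return pd.DataFrame([self.part_metrics(p).as_row() for p in parts])

    def per_segment_frame(self, part: str = "test", threshold: float = 0.5) -> pd.DataFrame:
        """Per-segment predictions, the raw material every metric cell is
        recomputable from."""
        idx = self.model.split.parts()[part]
        x, y = self.model.part_arrays(part)
        p, yhat = _predict(self.net, x, threshold)
        return pd.DataFrame({
            "segment_id": idx,
            "subject_id": self.model.segments.subject_ids[idx],
            "true": y, "prob": p, "pred": yhat,
        })

    def summary(self) -> str:
        spec = self.model.model_spec
        lines = [
            "Sleep-apnea PPG segment classifier (1D CNN-LSTM)",
            "=" * 52,
            f"segments: {len(self.model.segments)}  "
            f"(train {len(self.model.split.train)} / "
            f"val {len(self.model.split.validation)} / "
            f"test {len(self.model.split.test)}; {self.model.split.mode})",
            f"architecture: {sum(g[0] for g in spec.conv_groups)} conv "
            f"({'/'.join(str(g[1]) for g in spec.conv_groups)} ch, k={spec.kernel_size}), "
            f"{len(spec.conv_groups)} maxpool, "
            f"{spec.lstm_layers} LSTM ({spec.lstm_variant}, h={spec.lstm_hidden}), "
            f"{len(spec.fc_sizes)} FC -> sigmoid",
            f"trainable parameters: {self.n_params:,}",
            f"epochs run: {len(self.history['train_loss'])}  "
            f"best val loss: {self.history['best_val_loss']:.4f}",
            "",
            self.metrics_frame().to_string(index=False),
        ]
        return "\n".join(lines)

    def save(self, path: str | Path) -> None:
        self.net.save(path)
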