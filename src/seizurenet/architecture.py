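"""Declarative model configurations and the network builder.

Every study x task combination has one published hyperparameter set (shared
by the BiLSTM and BiGRU variants), stored in ``data/registry.yaml`` and
validated at load.  ``build_model`` instantiates the repeating
Conv1D -> Bi-RNN -> AvgPool unit stack with dropout between consecutive
units, then Flatten -> ReLU dense stack -> softmax output.  ``ablate``
produces the layer-removal variants used in the ablation experiments.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import yaml

from .nn import AvgPool1D, BiRNN, Conv1D, Dense, Dropout, Flatten, Sequential
from .nn.layers import ShapeError
from .records import TASK_NAMES, normalize_task_name

RNN_TYPES = ("lstm", "gru")
STUDY_IDS = (1, 2, 3, 4, 5, 6)


class ConstructionError(ValueError):
    """A network cannot be built for the given input length."""


class RegistryError(ValueError):
    """The shipped configuration registry is malformed."""


def normalize_rnn_type(rnn_type: str) -> str:
    key = rnn_type.strip().lower().replace("-", "")
    if key.startswith("bi"):
        key = key[2:]
    if key not in RNN_TYPES:
        raise LookupError(
            f"unknown RNN type {rnn_type!r}; expected BiLSTM or BiGRU")
    return key


@dataclass(frozen=True)
class UnitConfig:
    """One Conv1D -> Bi-RNN -> AvgPool feature-extraction unit."""

    conv_filters: int
    rnn_units: int
    kernel_size: int = 2
    rnn_type: str = "lstm"

    def __post_init__(self):
        if min(self.conv_filters, self.rnn_units, self.kernel_size) < 1:
            raise ValueError("unit sizes must be >= 1")


@dataclass(frozen=True)
class ModelConfig:
    """Full declarative description of one unit-stack network."""

    units: tuple[UnitConfig, ...]
    dense_units: tuple[int, ...]
    n_classes: int
    dropout_rate: float | None = None
    pool_size: int = 2
    conv_stride: int = 1
    conv_padding: str = "valid"
    include_conv: bool = True
    include_rnn: bool = True
    study: int | None = None
    task: str | None = None
    incomplete: tuple[str, ...] = ()

    def __post_init__(self):
        if not self.units:
            raise ConstructionError("a model needs at least one unit")
        if any(d < 1 for d in self.dense_units):
            raise ValueError("dense widths must be >= 1")
        if self.n_classes not in (2, 3, 4, 5):
            raise ValueError("n_classes must be in {2,3,4,5}")
        if self.dropout_rate is not None and not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")

    @property
    def rnn_type(self) -> str:
        return self.units[0].rnn_type

    def to_dict(self) -> dict:
        return {
            "study": self.study,
            "task": self.task,
            "rnn_type": self.rnn_type,
            "units": [[u.conv_filters, u.rnn_units] for u in self.units],
            "kernel_size": self.units[0].kernel_size,
            "pool_size": self.pool_size,
            "dropout_rate": self.dropout_rate,
            "dense_units": list(self.dense_units),
            "n_classes": self.n_classes,
            "conv_stride": self.conv_stride,
            "conv_padding": self.conv_padding,
            "include_conv": self.include_conv,
            "include_rnn": self.include_rnn,
            "incomplete": list(self.incomplete),
        }


@dataclass(frozen=True)
class TrainConfig:
    """Training protocol: softmax cross-entropy, Adam, five-fold CV."""

    epochs: int
    batch_size: int = 64
    learning_rate: float = 1e-3
    folds: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")

    def to_dict(self) -> dict:
        return {"epochs": self.epochs, "batch_size": self.batch_size,
                "learning_rate": self.learning_rate, "folds": self.folds,
                "seed": self.seed}


_ALLOWED_MISSING = {"dense", "epochs", "dropout"}


def _validate_registry(raw: dict) -> None:
    if set(raw) != {"defaults", "studies"}:
        raise RegistryError("registry must have 'defaults' and 'studies'")
    studies = raw["studies"]
    if sorted(studies) != list(STUDY_IDS):
        raise RegistryError(f"registry must define studies 1..6, got "
                            f"{sorted(studies)}")
    for sid, study in studies.items():
        tasks = study.get("tasks", {})
        if sorted(tasks) != sorted(TASK_NAMES):
            raise RegistryError(
                f"study {sid} must define tasks {TASK_NAMES}, got "
                f"{sorted(tasks)}")
        for tname, entry in tasks.items():
            units = entry.get("units")
            if (not isinstance(units, list) or not 1 <= len(units) <= 4
                    or any(len(u) != 2 or min(u) < 1 for u in units)):
                raise RegistryError(
                    f"study {sid} task {tname}: units must be 1-4 pairs of "
                    "positive integers")
            if not entry.get("dense") or min(entry["dense"]) < 1:
                raise RegistryError(
                    f"study {sid} task {tname}: dense must be positive")
            if entry.get("epochs", 0) < 1:
                raise RegistryError(
                    f"study {sid} task {tname}: epochs must be >= 1")
            extra = set(entry.get("missing", ())) - _ALLOWED_MISSING
            if extra:
                raise RegistryError(
                    f"study {sid} task {tname}: unknown missing fields {extra}")


_REGISTRY_CACHE: dict | None = None


def load_registry() -> dict:
    """Load and validate the shipped configuration registry."""
    global _REGISTRY_CACHE
    if _REGISTRY_CACHE is None:
        text = resources.files("seizurenet").joinpath(
            "data/registry.yaml").read_text()
        raw = yaml.safe_load(text)
        _validate_registry(raw)
        _REGISTRY_CACHE = raw
    return _REGISTRY_CACHE


def get_config(study: int, task: str, rnn_type: str = "lstm",
               seed: int = 0,
               overrides: dict | None = None) -> tuple[ModelConfig, TrainConfig]:
    """Resolve the published configuration for one study/task/RNN combination.

    Combinations whose source description omits a value (flagged in the
    registry) resolve with a documented fallback and emit a warning.
    ``overrides`` may replace registry fields (e.g. a dense width).
    """
    registry = load_registry()
    kind = normalize_rnn_type(rnn_type)
    if study not in registry["studies"]:
        raise LookupError(f"unknown study {study!r}; expected 1..6")
    canonical = normalize_task_name(task)
    entry = dict(registry["studies"][study]["tasks"][canonical])
    if overrides:
        unknown = set(overrides) - {"units", "kernel_size", "dense",
                                    "epochs", "dropout", "pool_size"}
        if unknown:
            raise LookupError(f"unknown override fields {sorted(unknown)}")
        missing = [m for m in entry.get("missing", ()) if m not in overrides]
        entry.update(overrides)
        entry["missing"] = missing
    defaults = registry["defaults"]
    kernel = entry.get("kernel_size", defaults["kernel_size"])
    incomplete = tuple(entry.get("missing", ()))
    if incomplete:
        warnings.warn(
            f"study {study} task {canonical}: no published value for "
            f"{', '.join(incomplete)}; using documented fallback(s)",
            stacklevel=2)
    n_classes = canonical.count("-") + 1
    model = ModelConfig(
        units=tuple(UnitConfig(conv_filters=f, rnn_units=u,
                               kernel_size=kernel, rnn_type=kind)
                    for f, u in entry["units"]),
        dense_units=tuple(entry["dense"]),
        n_classes=n_classes,
        dropout_rate=entry["dropout"],
        pool_size=defaults["pool_size"],
        study=study, task=canonical, incomplete=incomplete)
    train = TrainConfig(epochs=entry["epochs"],
                        batch_size=defaults["batch_size"],
                        learning_rate=defaults["learning_rate"],
                        folds=defaults["folds"], seed=seed)
    return model, train


def iter_combinations():
    """All 60 (study, task, rnn_type) combinations in registry order."""
    registry = load_registry()
    for study in STUDY_IDS:
        for task in registry["studies"][study]["tasks"]:
            for kind in RNN_TYPES:
                yield study, task, kind


def ablate(config: ModelConfig, drop: str) -> ModelConfig:
    """Remove every conv (``drop='conv'``) or Bi-RNN (``drop='rnn'``) stage.

    Pooling, dropout, dense stack and training settings are unchanged.
    """
    if drop == "conv":
        if not config.include_conv:
            raise ValueError("conv stages already removed")
        return replace(config, include_conv=False)
    if drop == "rnn":
        if not config.include_rnn:
            raise ValueError("RNN stages already removed")
        return replace(config, include_rnn=False)
    raise ValueError(f"unknown ablation {drop!r}; expected 'conv' or 'rnn'")


def build_model(config: ModelConfig, input_length: int,
                seed: int = 0) -> Sequential:
    """Instantiate the network for a given input length.

    The layer sequence is, per unit: Conv1D (stride 1, valid padding, ReLU)
    -> bidirectional RNN (full sequence, directions concatenated) ->
    AvgPool1D, with a Dropout stage between consecutive units when the
    config sets a rate; then Flatten, the ReLU dense stack and the
    ``n_classes``-way softmax output.  Construction fails, naming the
    stage, if the temporal axis collapses to zero anywhere.
    """
    if input_length < 1:
        raise ConstructionError("input_length must be >= 1")
    if not config.include_conv and not config.include_rnn:
        raise ConstructionError("cannot drop both conv and RNN stages")
    rng = np.random.default_rng(seed)
    layers = []
    shape = (input_length, 1)
    n_units = len(config.units)
    for i, unit in enumerate(config.units):
        stage = f"unit {i + 1}/{n_units}"
        try:
            if config.include_conv:
                conv = Conv1D(shape[1], unit.conv_filters, unit.kernel_size,
                              rng)
                shape = conv.out_shape(shape)
                layers.append(conv)
            if config.include_rnn:
                rnn = BiRNN(shape[1], unit.rnn_units, unit.rnn_type, rng)
                shape = rnn.out_shape(shape)
                layers.append(rnn)
            pool = AvgPool1D(config.pool_size)
            shape = pool.out_shape(shape)
            layers.append(pool)
        except ShapeError as exc:
            raise ConstructionError(
                f"{stage} ({exc}); input length {input_length} is too short "
                f"for this architecture") from exc
        if config.dropout_rate is not None and i < n_units - 1:
            layers.append(Dropout(config.dropout_rate, rng))
    layers.append(Flatten())
    features = shape[0] * shape[1]
    for width in config.dense_units:
        layers.append(Dense(features, width, rng, activation="relu"))
        features = width
    layers.append(Dense(features, config.n_classes, rng,
                        activation="softmax"))
    return Sequential(layers)
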