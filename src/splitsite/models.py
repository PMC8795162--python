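"""Split architectures: one hidden layer per end-system, the rest on the server.

Three built-in configurations mirror the three study setups:

- ``covid``   — custom CNN classifier, 64x64x1 input, binary cross-entropy,
  sigmoid output, 100 epochs, global batch 64; the server holds 4 hidden
  layers (three conv+pool blocks and the flatten+dense output block).
- ``mura``    — VGG19-style classifier on 224x224x1, 50 epochs, batch 128;
  the single client conv layer plus 19 server weight layers give the 20-layer
  total.
- ``cholesterol`` — small regression MLP on the 7 tabular covariates, MSE
  loss, leaky-ReLU activations, 200 epochs, batch 2048; 1 client layer + 2
  server layers.

Every end-system's hidden layer is one convolution followed by one 2x2 max
pool for image tasks (a dense layer with leaky-ReLU for the tabular task);
the transmitted feature map is post-activation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import yaml

from .nn import LayerDef, ParameterSet, Stack

__all__ = [
    "LayerDef",
    "ParameterSet",
    "ModelSpec",
    "SplitModel",
    "builtin_spec",
    "build_split_model",
    "client_output_shape",
]

BUILTIN_NAMES = ("covid", "mura", "cholesterol")

#: unstated-by-design defaults for the client hidden layer
CLIENT_CONV_FILTERS = 8
CLIENT_CONV_KERNEL = 3
CLIENT_DENSE_UNITS = 32


@dataclass(frozen=True)
class ModelSpec:
    """Hyperparameter block for one split configuration."""

    task: str  # classification | regression
    architecture: str  # custom_cnn | vgg19_split | custom_mlp
    epochs: int
    global_batch_size: int
    loss_name: str  # binary_crossentropy | mse
    activation_name: str  # sigmoid | leaky_relu
    input_shape: tuple  # (H, W, C) for images, (d,) for tabular
    n_client_layers: int = 1
    n_server_layers: int = 0
    client_filters: int = CLIENT_CONV_FILTERS
    client_kernel_size: int = CLIENT_CONV_KERNEL
    client_units: int = CLIENT_DENSE_UNITS

    def __post_init__(self) -> None:
        if self.task not in ("classification", "regression"):
            raise ValueError(f"unknown task {self.task!r}")
        if self.architecture not in ("custom_cnn", "vgg19_split", "custom_mlp"):
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if self.epochs <= 0:
            raise ValueError("epochs must be > 0")
        if self.global_batch_size <= 0:
            raise ValueError("global_batch_size must be > 0")
        if self.n_client_layers != 1:
            raise ValueError("every end-system holds exactly one hidden layer")
        if self.architecture == "custom_cnn" and self.n_server_layers != 4:
            raise ValueError("custom_cnn requires 4 server layers")
        if self.architecture == "vgg19_split" and self.n_client_layers + self.n_server_layers != 20:
            raise ValueError("vgg19_split requires 20 layers in total")
        if self.architecture == "custom_mlp" and self.n_server_layers != 2:
            raise ValueError("custom_mlp requires 2 server layers")
        if self.loss_name not in ("binary_crossentropy", "mse"):
            raise ValueError(f"unknown loss {self.loss_name!r}")
        shape = tuple(self.input_shape)
        if self.architecture in ("custom_cnn", "vgg19_split"):
            if len(shape) != 3:
                raise ValueError(f"image architectures need (H, W, C) input, got {shape}")
            if shape[0] < 8 or shape[1] < 8:
                raise ValueError("image input must be at least 8x8 for the pooling pyramid")
        else:
            if len(shape) != 1:
                raise ValueError(f"custom_mlp needs a flat (d,) input, got {shape}")
        object.__setattr__(self, "input_shape", shape)

    # -- (de)serialization -------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        return {
            "task": self.task,
            "architecture": self.architecture,
            "epochs": self.epochs,
            "global_batch_size": self.global_batch_size,
            "loss_name": self.loss_name,
            "activation_name": self.activation_name,
            "input_shape": list(self.input_shape),
            "n_client_layers": self.n_client_layers,
            "n_server_layers": self.n_server_layers,
            "client_filters": self.client_filters,
            "client_kernel_size": self.client_kernel_size,
            "client_units": self.client_units,
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ModelSpec":
        d = dict(d)
        d["input_shape"] = tuple(d["input_shape"])
        return cls(**d)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "ModelSpec":
        return cls.from_dict(yaml.safe_load(text))

    def replace(self, **kw) -> "ModelSpec":
        d = self.to_dict()
        d.update(kw)
        return ModelSpec.from_dict(d)


@dataclass
class SplitModel:
    """Client layer template plus server stack for one configuration."""

    spec: ModelSpec
    client_template: list[LayerDef]
    server_layers: list[LayerDef]

    def __post_init__(self) -> None:
        client = Stack(self.client_template)
        cut = client.output_shape(self.spec.input_shape)
        server = Stack(self.server_layers)
        out = server.output_shape(cut)
        if out != (1,):
            raise ValueError(f"server stack must end in one output unit, got shape {out}")

    @property
    def client_stack(self) -> Stack:
        return Stack(self.client_template)

    @property
    def server_stack(self) -> Stack:
        return Stack(self.server_layers)

    @property
    def cut_shape(self) -> tuple[int, ...]:
        return self.client_stack.output_shape(self.spec.input_shape)


def builtin_spec(name: str, **overrides) -> ModelSpec:
    """The three study configurations by name.

    ``overrides`` lets callers shrink a configuration for desk-scale runs
    (e.g. ``input_shape=(32, 32, 1)`` or a smaller epoch count) without
    touching the canonical values.
    """
    if name == "covid":
        spec = ModelSpec(
            task="classification",
            architecture="custom_cnn",
            epochs=100,
            global_batch_size=64,
            loss_name="binary_crossentropy",
            activation_name="sigmoid",
            input_shape=(64, 64, 1),
            n_server_layers=4,
        )
    elif name == "mura":
        spec = ModelSpec(
            task="classification",
            architecture="vgg19_split",
            epochs=50,
            global_batch_size=128,
            loss_name="binary_crossentropy",
            activation_name="sigmoid",
            input_shape=(224, 224, 1),
            n_server_layers=19,
        )
    elif name == "cholesterol":
        spec = ModelSpec(
            task="regression",
            architecture="custom_mlp",
            epochs=200,
            global_batch_size=2048,
            loss_name="mse",
            activation_name="leaky_relu",
            input_shape=(7,),
            n_server_layers=2,
        )
    else:
        raise ValueError(f"unknown builtin spec {name!r}; valid names: {BUILTIN_NAMES}")
    return spec.replace(**overrides) if overrides else spec


def _client_layers(spec: ModelSpec) -> list[LayerDef]:
    if spec.architecture in ("custom_cnn", "vgg19_split"):
        return [
            LayerDef("conv2d", kernel_size=spec.client_kernel_size, filters=spec.client_filters),
            LayerDef("activation", activation="relu"),
            LayerDef("maxpool2d"),
        ]
    return [
        LayerDef("dense", units=spec.client_units),
        LayerDef("activation", activation="leaky_relu"),
    ]


# VGG19 convolutional plan: (filters, convs-in-block); a 2x2 pool follows each block
_VGG19_BLOCKS = [(64, 2), (128, 2), (256, 4), (512, 4), (512, 4)]


def _server_layers(spec: ModelSpec) -> list[LayerDef]:
    if spec.architecture == "custom_cnn":
        layers: list[LayerDef] = []
        for f in (16, 32, 64):
            layers += [
                LayerDef("conv2d", kernel_size=3, filters=f),
                LayerDef("activation", activation="relu"),
                LayerDef("maxpool2d"),
            ]
        layers += [
            LayerDef("flatten"),
            LayerDef("dense", units=1),
            LayerDef("activation", activation="sigmoid"),
        ]
        return layers
    if spec.architecture == "vgg19_split":
        layers = []
        for f, reps in _VGG19_BLOCKS:
            for _ in range(reps):
                layers += [
                    LayerDef("conv2d", kernel_size=3, filters=f),
                    LayerDef("activation", activation="relu"),
                ]
            layers.append(LayerDef("maxpool2d"))
        layers.append(LayerDef("flatten"))
        for units in (4096, 4096):
            layers += [
                LayerDef("dense", units=units),
                LayerDef("activation", activation="relu"),
            ]
        layers += [LayerDef("dense", units=1), LayerDef("activation", activation="sigmoid")]
        return layers
    # custom_mlp: dense(16, leaky-ReLU) + dense(1, linear)
    return [
        LayerDef("dense", units=16),
        LayerDef("activation", activation="leaky_relu"),
        LayerDef("dense", units=1),
        LayerDef("activation", activation="linear"),
    ]


def client_output_shape(spec: ModelSpec) -> tuple[int, ...]:
    """Per-sample shape of the transmitted feature map.

    Same-padding convolution plus 2x2 pooling halves the spatial dimensions
    and sets the channel count to the client filter count; the tabular client
    emits its dense width.
    """
    return Stack(_client_layers(spec)).output_shape(spec.input_shape)


def build_split_model(spec: ModelSpec, seed: int) -> tuple[SplitModel, ParameterSet, ParameterSet]:
    """Build the split architecture and initialize both parameter sets.

    Deterministic: the same ``(spec, seed)`` produces bitwise-identical
    parameters.  Returns ``(model, client_params_template, server_params)``;
    each end-system receives a copy of the client template so all clients
    start identical (they diverge during training unless weight sync is on).
    """
    model = SplitModel(spec, _client_layers(spec), _server_layers(spec))
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(0xC11E,))
    client_ss, server_ss = ss.spawn(2)
    client_params = model.client_stack.init_params(
        spec.input_shape, np.random.default_rng(client_ss)
    )
    server_params = model.server_stack.init_params(model.cut_shape, np.random.default_rng(server_ss))
    client_params.validate_finite()
    server_params.validate_finite()
    return model, client_params, server_params
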