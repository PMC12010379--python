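"""Model registry: names, encoding compatibility, and construction."""

from __future__ import annotations

from dataclasses import dataclass, field

from autogs.models.classical import SkRegressor
from autogs.models.deep import DeepGSNet, DLGWASNet, DNNGPNet, SoyDNGPNet
from autogs.models.envse import EnvSENet

MODEL_NAMES = (
    "SVM", "XGBoost", "GBDT", "MLP", "RF",
    "DeepGS", "DLGWAS", "DNNGP", "SoyDNGP", "EnvSE",
)

CLASSICAL_MODELS = frozenset({"SVM", "XGBoost", "GBDT", "MLP", "RF"})
DEEP_MODELS = frozenset({"DeepGS", "DLGWAS", "DNNGP", "SoyDNGP", "EnvSE"})

_ENCODING_BY_MODEL = {
    **{m: "dosage_vector" for m in CLASSICAL_MODELS},
    "DeepGS": "dosage_vector",
    "DLGWAS": "onehot_4xL",
    "DNNGP": "pca_150",
    "SoyDNGP": "soy_3xSxS",
    "EnvSE": "dosage_vector",  # plus environment features
}

_DEEP_CLASSES = {
    "DeepGS": DeepGSNet,
    "DLGWAS": DLGWASNet,
    "DNNGP": DNNGPNet,
    "SoyDNGP": SoyDNGPNet,
    "EnvSE": EnvSENet,
}


def encoding_for_model(name: str) -> str:
    if name not in _ENCODING_BY_MODEL:
        raise ValueError(f"unknown model {name!r}; valid names: {', '.join(MODEL_NAMES)}")
    return _ENCODING_BY_MODEL[name]


@dataclass
class ModelSpec:
    """Name + encoding + hyperparameters + seed, validated for compatibility."""

    name: str
    encoding: str | None = None
    hyperparams: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in MODEL_NAMES:
            raise ValueError(
                f"unknown model {self.name!r}; valid names: {', '.join(MODEL_NAMES)}"
            )
        required = encoding_for_model(self.name)
        if self.encoding is None:
            self.encoding = required
        elif self.encoding != required:
            raise ValueError(
                f"model {self.name} requires encoding {required!r}, got {self.encoding!r}"
            )

    @property
    def is_deep(self) -> bool:
        return self.name in DEEP_MODELS

    @property
    def uses_environment(self) -> bool:
        return self.name == "EnvSE"

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "encoding": self.encoding,
            "hyperparams": dict(self.hyperparams),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(
            name=d["name"], encoding=d.get("encoding"),
            hyperparams=dict(d.get("hyperparams", {})), seed=int(d.get("seed", 0)),
        )


def build_model(spec: ModelSpec):
    """Instantiate an unfitted regressor (fit/predict/get_state/set_state)."""
    if spec.name in CLASSICAL_MODELS:
        return SkRegressor(spec.name, seed=spec.seed, hyperparams=spec.hyperparams)
    cls = _DEEP_CLASSES[spec.name]
    return cls(seed=spec.seed, **spec.hyperparams)


def prepped_input_shape(spec: ModelSpec, layout: tuple, env_dim: int | None = None):
    """Network input shape (after internal prep) for a given encoding layout.

    Needed to rebuild a convolutional model before loading saved weights.
    """
    layout = tuple(layout)
    if spec.name == "DeepGS":
        return (1, layout[0])
    if spec.name == "DLGWAS":
        return layout
    if spec.name == "DNNGP":
        return (1, layout[0])
    if spec.name == "SoyDNGP":
        return layout
    if spec.name == "EnvSE":
        if env_dim is None:
            raise ValueError("EnvSE rebuild requires the environment vector length")
        return ((1, layout[0]), (int(env_dim),))
    raise ValueError(f"{spec.name} is not a network model")
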