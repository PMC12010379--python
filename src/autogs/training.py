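"""Training protocol, evaluation metric, and the model-weights archive.

Samples are partitioned 8:1:1 (train/validation/test, remainder to train)
from a seed.  Networks train with Adam, batch size 64 (clipped to the
training-set size), mean-squared-error loss, and validation-based early
stopping; accuracy is reported as the Pearson correlation (R) on the
held-out test split.  Every artifact needed to reproduce predictions
(fitted parameters, PCA projection, environment standardization, locus
map) is serialized into a single checksummed archive.
"""

from __future__ import annotations

import hashlib
import json
import logging
import pickle
import zipfile
from dataclasses import dataclass, field

import numpy as np

from autogs.encodings import (
    PCAProjection,
    apply_pca,
    encode_dosage,
    encode_onehot_4xL,
    encode_soy,
    fit_pca,
)
from autogs.genotype_io import GenotypeMatrix
from autogs.models.environment import env_feature_matrix
from autogs.models.nn import TrainConfig
from autogs.models.pool import ModelSpec, build_model, prepped_input_shape

logger = logging.getLogger(__name__)

WEIGHTS_FORMAT_VERSION = 1

# fixed timestamp so identical fits produce byte-identical archives
_ZIP_DATE = (2020, 1, 1, 0, 0, 0)


class WeightsError(ValueError):
    """Raised on a corrupt, incompatible, or wrong-version weights archive."""


@dataclass(frozen=True)
class SplitIndex:
    train: np.ndarray
    val: np.ndarray
    test: np.ndarray

    def __post_init__(self) -> None:
        all_idx = np.concatenate([self.train, self.val, self.test])
        if len(np.unique(all_idx)) != len(all_idx):
            raise ValueError("split indices overlap")


def split_811(n: int, seed: int) -> SplitIndex:
    """Shuffled 8:1:1 partition: |val| = |test| = floor(n/10), rest train."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    k = n // 10
    return SplitIndex(train=perm[2 * k :], val=perm[k : 2 * k], test=perm[:k])


def pearson_r(pred, true) -> float:
    """Pearson correlation; rejects short or constant inputs explicitly."""
    p = np.asarray(pred, dtype=np.float64).ravel()
    t = np.asarray(true, dtype=np.float64).ravel()
    if p.shape != t.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {t.shape}")
    if len(p) < 2:
        raise ValueError("pearson_r needs at least 2 observations")
    pc = p - p.mean()
    tc = t - t.mean()
    sp = np.sqrt((pc**2).sum())
    st = np.sqrt((tc**2).sum())
    if sp == 0.0 or st == 0.0:
        raise ValueError("pearson_r undefined for a constant vector")
    return float((pc * tc).sum() / (sp * st))


@dataclass
class TrainOptions:
    """All knobs of the training protocol (networks ignore none of these;
    classical models use only the split seed and PCA rank)."""

    batch_size: int = 64
    max_epochs: int = 200
    patience: int = 20
    lr: float = 1e-3
    pca_k: int = 150
    env_mode: str = "weekly"
    env_window_days: int | None = None


@dataclass
class ModelWeights:
    spec: ModelSpec
    locus_map: list[str]
    layout: tuple
    model_kind: str  # "classical" | "deep"
    model_state: dict
    pca: PCAProjection | None = None
    env_stats: dict | None = None  # mean, std (arrays), mode, window_days, env_dim
    r_test: float = float("nan")
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (np.isnan(self.r_test) or -1.0 <= self.r_test <= 1.0):
            raise ValueError(f"r_test out of [-1, 1]: {self.r_test}")


def _encode(spec: ModelSpec, gm: GenotypeMatrix, pca: PCAProjection | None):
    if spec.encoding == "dosage_vector":
        return encode_dosage(gm).tensor
    if spec.encoding == "onehot_4xL":
        return encode_onehot_4xL(gm).tensor
    if spec.encoding == "soy_3xSxS":
        return encode_soy(gm).tensor
    if spec.encoding == "pca_150":
        if pca is None:
            raise ValueError("PCA projection required for pca_150 encoding")
        return apply_pca(gm, pca).tensor
    raise ValueError(f"unknown encoding {spec.encoding!r}")


def train(
    spec: ModelSpec,
    gm: GenotypeMatrix,
    y,
    options: TrainOptions | None = None,
    *,
    env_series: dict | None = None,
    env_ids: list[str] | None = None,
    split: SplitIndex | None = None,
) -> ModelWeights:
    """Fit a model under the standard protocol and return its weights.

    ``gm`` must be imputed and aligned with ``y``.  PCA and environment
    standardization are fit on the training split only.  For the
    environment-gated model, ``env_series`` (env id -> daily frame) and
    per-sample ``env_ids`` are required.
    """
    opts = options or TrainOptions()
    y = np.asarray(y, dtype=np.float64).ravel()
    if len(y) != gm.n_samples:
        raise ValueError("y length != number of samples")
    if split is None:
        split = split_811(gm.n_samples, seed=spec.seed)

    pca = None
    if spec.encoding == "pca_150":
        pca = fit_pca(gm.subset_samples(split.train), k=opts.pca_k)
    x = _encode(spec, gm, pca)
    layout = tuple(x.shape[1:])

    env_stats = None
    if spec.uses_environment:
        if env_series is None or env_ids is None:
            raise ValueError(
                "EnvSE requires environment data: pass env_series and env_ids"
            )
        e = env_feature_matrix(env_series, list(env_ids), mode=opts.env_mode,
                               window_days=opts.env_window_days)
        mean = e[split.train].mean(axis=0)
        std = e[split.train].std(axis=0)
        std = np.where(std == 0.0, 1.0, std)
        e = (e - mean) / std
        env_stats = {
            "mean": mean, "std": std, "mode": opts.env_mode,
            "window_days": opts.env_window_days, "env_dim": e.shape[1],
        }
        x = (x, e)

    model = build_model(spec)
    cfg = TrainConfig(batch_size=opts.batch_size, max_epochs=opts.max_epochs,
                      patience=opts.patience, lr=opts.lr)

    def _take(data, idx):
        return tuple(a[idx] for a in data) if isinstance(data, tuple) else data[idx]

    model.fit(_take(x, split.train), y[split.train],
              _take(x, split.val), y[split.val], cfg)

    r_test = float("nan")
    if len(split.test) >= 2:
        try:
            r_test = pearson_r(model.predict(_take(x, split.test)), y[split.test])
        except ValueError as exc:
            logger.warning("test R undefined: %s", exc)
    else:
        logger.warning("test split too small (%d) for an R value", len(split.test))

    metadata = {
        "seed": spec.seed,
        "n_train": int(len(split.train)),
        "n_val": int(len(split.val)),
        "n_test": int(len(split.test)),
    }
    if spec.is_deep:
        metadata.update(
            epochs_run=model.history.epochs_run,
            best_epoch=model.history.best_epoch,
            train_loss=model.history.train_loss,
            val_loss=model.history.val_loss,
        )
    return ModelWeights(
        spec=spec,
        locus_map=list(gm.loci),
        layout=layout,
        model_kind="deep" if spec.is_deep else "classical",
        model_state=model.get_state(),
        pca=pca,
        env_stats=env_stats,
        r_test=r_test,
        metadata=metadata,
    )


def predict_from_weights(
    w: ModelWeights,
    gm: GenotypeMatrix,
    *,
    env_series: dict | None = None,
    env_ids: list[str] | None = None,
) -> np.ndarray:
    """Predict trait values for ``gm`` using a trained weights object."""
    if list(gm.loci) != list(w.locus_map):
        raise WeightsError(
            f"locus map mismatch: weights were trained on {len(w.locus_map)} loci, "
            f"supplied matrix has {gm.n_loci} (or differing locus keys)"
        )
    x = _encode(w.spec, gm, w.pca)
    if w.spec.uses_environment:
        if env_series is None or env_ids is None:
            raise ValueError("EnvSE prediction requires env_series and env_ids")
        st = w.env_stats
        e = env_feature_matrix(env_series, list(env_ids), mode=st["mode"],
                               window_days=st["window_days"])
        e = (e - np.asarray(st["mean"])) / np.asarray(st["std"])
        x = (x, e)

    model = build_model(w.spec)
    if w.model_kind == "deep":
        env_dim = w.env_stats["env_dim"] if w.env_stats else None
        shape = prepped_input_shape(w.spec, w.layout, env_dim)
        model.set_state(w.model_state, shape)
    else:
        model.set_state(w.model_state)
    return model.predict(x)


# ----------------------------------------------------------------------
# weights archive: zip(meta.json, params.pkl, sha256.txt)


def save_weights(w: ModelWeights, path) -> None:
    meta = {
        "format_version": WEIGHTS_FORMAT_VERSION,
        "spec": w.spec.to_dict(),
        "locus_map": list(w.locus_map),
        "layout": list(w.layout),
        "model_kind": w.model_kind,
        "r_test": None if np.isnan(w.r_test) else w.r_test,
        "metadata": w.metadata,
        "has_pca": w.pca is not None,
        "env_stats": (
            None
            if w.env_stats is None
            else {
                **w.env_stats,
                "mean": np.asarray(w.env_stats["mean"]).tolist(),
                "std": np.asarray(w.env_stats["std"]).tolist(),
            }
        ),
    }
    meta_bytes = json.dumps(meta, indent=1, sort_keys=True).encode()
    blob = {"model_state": w.model_state}
    if w.pca is not None:
        blob["pca"] = {
            "components": w.pca.components,
            "means": w.pca.means,
            "explained_variance_ratio": w.pca.explained_variance_ratio,
            "locus_map": w.pca.locus_map,
        }
    params_bytes = pickle.dumps(blob, protocol=4)
    sums = (
        f"meta.json {hashlib.sha256(meta_bytes).hexdigest()}\n"
        f"params.pkl {hashlib.sha256(params_bytes).hexdigest()}\n"
    ).encode()
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_STORED) as zf:
        for name, data in (("meta.json", meta_bytes), ("params.pkl", params_bytes),
                           ("sha256.txt", sums)):
            zf.writestr(zipfile.ZipInfo(name, date_time=_ZIP_DATE), data)


def load_weights(path) -> ModelWeights:
    try:
        with zipfile.ZipFile(path) as zf:
            meta_bytes = zf.read("meta.json")
            params_bytes = zf.read("params.pkl")
            sums = zf.read("sha256.txt").decode()
    except (zipfile.BadZipFile, KeyError) as exc:
        raise WeightsError(f"not a valid weights archive: {path}") from exc
    expected = dict(line.split() for line in sums.strip().splitlines())
    for name, data in (("meta.json", meta_bytes), ("params.pkl", params_bytes)):
        if hashlib.sha256(data).hexdigest() != expected.get(name):
            raise WeightsError(f"checksum mismatch for {name} in {path}: archive corrupted")
    meta = json.loads(meta_bytes)
    if meta.get("format_version") != WEIGHTS_FORMAT_VERSION:
        raise WeightsError(
            f"unsupported weights format version {meta.get('format_version')}"
        )
    blob = pickle.loads(params_bytes)
    pca = None
    if meta["has_pca"]:
        p = blob["pca"]
        pca = PCAProjection(
            components=p["components"], means=p["means"],
            explained_variance_ratio=p["explained_variance_ratio"],
            locus_map=p["locus_map"],
        )
    env_stats = meta["env_stats"]
    if env_stats is not None:
        env_stats = {
            **env_stats,
            "mean": np.asarray(env_stats["mean"], dtype=np.float64),
            "std": np.asarray(env_stats["std"], dtype=np.float64),
        }
    return ModelWeights(
        spec=ModelSpec.from_dict(meta["spec"]),
        locus_map=list(meta["locus_map"]),
        layout=tuple(meta["layout"]),
        model_kind=meta["model_kind"],
        model_state=blob["model_state"],
        pca=pca,
        env_stats=env_stats,
        r_test=float("nan") if meta["r_test"] is None else float(meta["r_test"]),
        metadata=meta["metadata"],
    )
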