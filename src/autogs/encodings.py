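"""Model-specific genotype encodings.

Four representations are produced from a dosage matrix:

- ``dosage_vector``: the (n, L) float matrix itself (classical models and
  the single-branch CNN).
- ``onehot_4xL``: (n, 4, L) one-hot over genotype classes
  (hom-ref, het, hom-alt, missing).
- ``soy_3xSxS``: the first S^2 loci (S = floor(sqrt(L))) one-hot over the
  three genotype classes and reshaped row-major into a square image.
- ``pca_150``: scores on a PCA projection fit on training samples only.

All encoders are deterministic: identical input yields bit-identical output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from autogs.genotype_io import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

ENCODING_KINDS = ("dosage_vector", "onehot_4xL", "soy_3xSxS", "pca_150")


@dataclass
class EncodedInput:
    kind: str
    tensor: np.ndarray
    layout: tuple[int, ...]
    locus_map: np.ndarray  # original locus indices used, in layout order

    def __post_init__(self) -> None:
        if self.kind not in ENCODING_KINDS:
            raise ValueError(f"unknown encoding kind {self.kind!r}")
        if tuple(self.tensor.shape[1:]) != tuple(self.layout):
            raise ValueError(f"tensor shape {self.tensor.shape} != layout {self.layout}")


@dataclass
class PCAProjection:
    """Centering means and orthonormal component matrix fit on training data."""

    components: np.ndarray  # (k, L)
    means: np.ndarray  # (L,)
    explained_variance_ratio: np.ndarray
    locus_map: np.ndarray

    @property
    def k(self) -> int:
        return self.components.shape[0]


def _require_imputed(dosage: np.ndarray, op: str) -> None:
    if (dosage == MISSING).any():
        raise ValueError(f"{op}: genotype matrix contains missing entries; impute first")


def encode_dosage(gm: GenotypeMatrix) -> EncodedInput:
    """Encode as an (n, L) float matrix of alt-allele counts."""
    _require_imputed(gm.dosage, "encode_dosage")
    x = gm.dosage.astype(np.float64)
    return EncodedInput(
        kind="dosage_vector",
        tensor=x,
        layout=(gm.n_loci,),
        locus_map=np.arange(gm.n_loci),
    )


def encode_onehot_4xL(gm: GenotypeMatrix) -> EncodedInput:
    """Encode as (n, 4, L): channels (hom-ref, het, hom-alt, missing)."""
    d = gm.dosage
    x = np.zeros((gm.n_samples, 4, gm.n_loci), dtype=np.float64)
    for ch, val in enumerate((0, 1, 2, MISSING)):
        x[:, ch, :] = d == val
    return EncodedInput(
        kind="onehot_4xL",
        tensor=x,
        layout=(4, gm.n_loci),
        locus_map=np.arange(gm.n_loci),
    )


def encode_soy(gm: GenotypeMatrix) -> EncodedInput:
    """Encode as (n, 3, S, S) with S = floor(sqrt(L)).

    The first S^2 loci are one-hot over (hom-ref, het, hom-alt) and placed
    row-major into the square; trailing loci are dropped with a warning.
    """
    _require_imputed(gm.dosage, "encode_soy")
    L = gm.n_loci
    if L < 4:
        raise ValueError(f"encode_soy needs L >= 4, got {L}")
    S = int(np.floor(np.sqrt(L)))
    used = S * S
    if used < L:
        logger.warning("encode_soy: dropping %d trailing loci (L=%d, S=%d)", L - used, L, S)
    d = gm.dosage[:, :used]
    x = np.zeros((gm.n_samples, 3, used), dtype=np.float64)
    for ch, val in enumerate((0, 1, 2)):
        x[:, ch, :] = d == val
    x = x.reshape(gm.n_samples, 3, S, S)
    return EncodedInput(
        kind="soy_3xSxS", tensor=x, layout=(3, S, S), locus_map=np.arange(used)
    )


def fit_pca(gm_train: GenotypeMatrix, k: int = 150) -> PCAProjection:
    """Fit a k-component PCA on training samples only.

    k is reduced to min(n_train - 1, L) with a warning when the data cannot
    support the requested rank.  The sign of each component is fixed so its
    largest-magnitude loading is positive, making the fit deterministic.
    """
    from sklearn.decomposition import PCA

    _require_imputed(gm_train.dosage, "fit_pca")
    n, L = gm_train.dosage.shape
    k_eff = min(k, n - 1, L)
    if k_eff < k:
        logger.warning("fit_pca: reducing k from %d to %d (n=%d, L=%d)", k, k_eff, n, L)
    if k_eff < 1:
        raise ValueError(f"fit_pca: cannot fit PCA with n={n}, L={L}")
    x = gm_train.dosage.astype(np.float64)
    pca = PCA(n_components=k_eff, svd_solver="full")
    pca.fit(x)
    comps = pca.components_.copy()
    for i in range(comps.shape[0]):
        j = np.argmax(np.abs(comps[i]))
        if comps[i, j] < 0:
            comps[i] = -comps[i]
    return PCAProjection(
        components=comps,
        means=pca.mean_.copy(),
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
        locus_map=np.arange(L),
    )


def apply_pca(gm: GenotypeMatrix, proj: PCAProjection) -> EncodedInput:
    """Center by the training means and project onto the stored components."""
    _require_imputed(gm.dosage, "apply_pca")
    if gm.n_loci != proj.components.shape[1]:
        raise ValueError(
            f"apply_pca: projection built for {proj.components.shape[1]} loci, "
            f"matrix has {gm.n_loci} (locus_map mismatch)"
        )
    x = gm.dosage.astype(np.float64) - proj.means
    scores = x @ proj.components.T
    return EncodedInput(
        kind="pca_150",
        tensor=scores,
        layout=(proj.k,),
        locus_map=proj.locus_map.copy(),
    )
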