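"""Image feature extraction: basic face metrics, embedding backends, SVD reduction.

Mirrors the three nested input sets of the analysis — stated demographics,
basic face metrics computed over the face oval, and reduced image
embeddings — without requiring pretrained networks.  Embedding backends
are pluggable (pixel PCA, seeded random projection, or externally supplied
per-image vectors) and are always fitted on training rows only; the same
applies to the SVD reduction, which guards against train/test leakage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._utils import ConfigError, derive_seed
from .synthetic import AttributeTable, ImageStack

__all__ = [
    "OvalSpec",
    "FeatureMatrix",
    "basic_face_metrics",
    "register_metric",
    "make_backend",
    "extract_embedding",
    "combine_and_reduce",
    "DemographicsInput",
    "FaceMetricsInput",
    "EmbeddingInput",
    "StackedInput",
]

MAX_FACE_METRICS = 11


@dataclass(frozen=True)
class OvalSpec:
    """Face oval: center (x, y) and semi-axes (ax, ay), pixels; x = column."""

    center: tuple[float, float]
    semi_axes: tuple[float, float]

    def __post_init__(self) -> None:
        if min(self.semi_axes) <= 0:
            raise ConfigError("oval semi-axes must be positive")

    @property
    def face_width(self) -> float:
        return 2.0 * self.semi_axes[0]

    @property
    def face_height(self) -> float:
        return 2.0 * self.semi_axes[1]

    def validate_inside(self, height: int, width: int) -> None:
        cx, cy = self.center
        ax, ay = self.semi_axes
        if cx - ax < -0.5 or cx + ax > width - 0.5 or cy - ay < -0.5 or cy + ay > height - 0.5:
            raise ConfigError("face oval extends outside the image bounds")

    def mask(self, height: int, width: int) -> np.ndarray:
        self.validate_inside(height, width)
        cx, cy = self.center
        ax, ay = self.semi_axes
        rr, cc = np.meshgrid(np.arange(height), np.arange(width), indexing="ij")
        return ((cc - cx) / ax) ** 2 + ((rr - cy) / ay) ** 2 <= 1.0

    @classmethod
    def from_geometry(cls, geom: dict) -> "OvalSpec":
        return cls(center=tuple(geom["center"]), semi_axes=tuple(geom["semi_axes"]))


@dataclass
class FeatureMatrix:
    """n x d feature matrix with a provenance tag."""

    values: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ConfigError("feature matrix must be 2-D")
        if not np.isfinite(self.values).all():
            raise ConfigError(f"non-finite entries in feature matrix ({self.provenance})")

    @property
    def d(self) -> int:
        return self.values.shape[1]


# -- basic face metrics ------------------------------------------------------

_METRIC_REGISTRY: dict[str, callable] = {}


def register_metric(name: str, fn) -> None:
    """Register an extra named metric: fn(images, oval) -> (n,) vector.

    The metric set is capped at 11 per image (6 built-ins + 5 slots).
    """
    if len(_METRIC_REGISTRY) + 6 >= MAX_FACE_METRICS and name not in _METRIC_REGISTRY:
        raise ConfigError(f"metric registry full ({MAX_FACE_METRICS} metrics max)")
    _METRIC_REGISTRY[name] = fn


def basic_face_metrics(
    images: ImageStack, oval: OvalSpec, extra: list[str] | None = None
) -> pd.DataFrame:
    """Per-image face metrics: RGB means over the oval, width, height, fWHR.

    Grayscale input duplicates the single channel into R = G = B.  Width
    and height are twice the oval semi-axes; fWHR = width / height.
    """
    mask = oval.mask(images.height, images.width)
    px = images.pixels
    if px.ndim == 3:
        px = px[..., None].repeat(3, axis=3)
    elif px.shape[3] == 1:
        px = px.repeat(3, axis=3)
    elif px.shape[3] != 3:
        raise ConfigError("images must have 1 or 3 channels")
    means = px[:, mask, :].mean(axis=1)  # (n, 3)
    n = images.n
    out = pd.DataFrame(
        {
            "mean_R": means[:, 0],
            "mean_G": means[:, 1],
            "mean_B": means[:, 2],
            "face_width": np.full(n, oval.face_width),
            "face_height": np.full(n, oval.face_height),
            "fwhr": np.full(n, oval.face_width / oval.face_height),
        }
    )
    for name in extra or []:
        if name not in _METRIC_REGISTRY:
            raise ConfigError(f"unknown face metric '{name}'")
        out[name] = np.asarray(_METRIC_REGISTRY[name](images, oval), dtype=float)
    if out.shape[1] > MAX_FACE_METRICS:
        raise ConfigError(f"at most {MAX_FACE_METRICS} face metrics supported")
    return out


# -- embedding backends ------------------------------------------------------


def _flatten(images: ImageStack) -> np.ndarray:
    return images.pixels.reshape(images.n, -1)


class PixelPCABackend:
    """PCA of flattened pixels, fitted on training rows only."""

    pixel_based = True

    def __init__(self, d: int, seed: int = 0):
        self.d = d
        self.seed = seed
        self._mean = None
        self._components = None

    def fit(self, images: ImageStack, rows=None) -> "PixelPCABackend":
        X = _flatten(images if rows is None else images.subset(rows))
        self._mean = X.mean(axis=0)
        Xc = X - self._mean
        d = min(self.d, *Xc.shape)
        _, _, Vt = np.linalg.svd(Xc, full_matrices=False)
        Vt = Vt[:d]
        signs = np.sign(Vt[np.arange(d), np.abs(Vt).argmax(axis=1)])
        signs[signs == 0] = 1.0
        self._components = Vt * signs[:, None]
        return self

    def transform(self, images: ImageStack, rows=None) -> np.ndarray:
        if self._components is None:
            raise ConfigError("backend not fitted")
        X = _flatten(images if rows is None else images.subset(rows))
        return (X - self._mean) @ self._components.T


class RandomProjectionBackend:
    """Seeded Gaussian random projection of flattened pixels (no fitting)."""

    pixel_based = True

    def __init__(self, d: int, seed: int = 0):
        self.d = d
        self.seed = seed
        self._W = None

    def fit(self, images: ImageStack, rows=None) -> "RandomProjectionBackend":
        p = int(np.prod(images.pixels.shape[1:]))
        rng = np.random.default_rng(derive_seed(self.seed, "random-projection"))
        self._W = rng.normal(size=(self.d, p)) / np.sqrt(self.d)
        return self

    def transform(self, images: ImageStack, rows=None) -> np.ndarray:
        if self._W is None:
            raise ConfigError("backend not fitted")
        return _flatten(images if rows is None else images.subset(rows)) @ self._W.T


class ExternalFeaturesBackend:
    """Per-image feature vectors supplied externally (CSV or array).

    Escape hatch for users with real embeddings (e.g. CNN activations):
    rows must align with the image stack.  Not pixel-based, so it cannot
    be used where pixels are perturbed at evaluation time (occlusion).
    """

    pixel_based = False

    def __init__(self, values: np.ndarray):
        self.values = np.asarray(values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ConfigError("external features must be a 2-D matrix")

    @classmethod
    def from_csv(cls, path) -> "ExternalFeaturesBackend":
        return cls(pd.read_csv(path).to_numpy())

    def fit(self, images: ImageStack, rows=None) -> "ExternalFeaturesBackend":
        if self.values.shape[0] != images.n:
            raise ConfigError("external feature rows misaligned with images")
        return self

    def transform(self, images: ImageStack, rows=None) -> np.ndarray:
        return self.values if rows is None else self.values[rows]


_BACKENDS = {
    "pixel_pca": PixelPCABackend,
    "random_projection": RandomProjectionBackend,
}


def make_backend(name: str, d: int = 500, seed: int = 0, external_values=None):
    if name == "external":
        if external_values is None:
            raise ConfigError("external backend requires a feature matrix or CSV")
        if isinstance(external_values, (str,)) or hasattr(external_values, "__fspath__"):
            return ExternalFeaturesBackend.from_csv(external_values)
        return ExternalFeaturesBackend(external_values)
    if name not in _BACKENDS:
        raise ConfigError(
            f"unknown backend '{name}' (choose from {sorted(_BACKENDS)} or 'external')"
        )
    return _BACKENDS[name](d=d, seed=seed)


def extract_embedding(
    images: ImageStack, backend, train_rows=None
) -> FeatureMatrix:
    """Fit the backend on training rows, transform all rows."""
    backend.fit(images, rows=train_rows)
    return FeatureMatrix(
        backend.transform(images), provenance=type(backend).__name__
    )


def combine_and_reduce(
    blocks: list[FeatureMatrix], d: int, train_rows=None
) -> FeatureMatrix:
    """Concatenate feature blocks and reduce to d columns by truncated SVD.

    Columns are mean-centered on training rows, the SVD basis is fitted on
    training rows only, and all rows are projected onto the top-d right
    singular vectors (ordered by singular value).  Reduces collinearity
    between blocks.
    """
    if not blocks:
        raise ConfigError("no feature blocks to combine")
    n = blocks[0].values.shape[0]
    for b in blocks:
        if b.values.shape[0] != n:
            raise ConfigError("feature blocks are not row-aligned")
    X = np.hstack([b.values for b in blocks])
    if d > X.shape[1]:
        raise ConfigError(f"d={d} exceeds combined column count {X.shape[1]}")
    train = X if train_rows is None else X[train_rows]
    mean = train.mean(axis=0)
    _, _, Vt = np.linalg.svd(train - mean, full_matrices=False)
    Vt = Vt[:d]
    signs = np.sign(Vt[np.arange(Vt.shape[0]), np.abs(Vt).argmax(axis=1)])
    signs[signs == 0] = 1.0
    Vt = Vt * signs[:, None]
    prov = "+".join(b.provenance for b in blocks) + f"|svd{d}"
    return FeatureMatrix((X - mean) @ Vt.T, provenance=prov)


# -- nested input sets for cross-validation ----------------------------------


class DemographicsInput:
    """Selected (demographic-flagged) attribute columns as model inputs."""

    pixel_based = False

    def __init__(self, columns: list[str] | None = None):
        self.columns = columns
        self._idx = None

    def fit(self, images: ImageStack, attrs: AttributeTable, rows) -> "DemographicsInput":
        if self.columns is None:
            idx = np.flatnonzero(attrs.demographic)
            if idx.size == 0:
                raise ConfigError("no demographic-flagged attributes in the table")
        else:
            missing = [c for c in self.columns if c not in attrs.names]
            if missing:
                raise ConfigError(f"demographic columns not found: {missing}")
            idx = np.array([attrs.names.index(c) for c in self.columns])
        self._idx = idx
        return self

    def transform(self, images: ImageStack, attrs: AttributeTable, rows) -> np.ndarray:
        return attrs.y[rows][:, self._idx].astype(np.float64)

    def input_names(self, attrs: AttributeTable) -> list[str]:
        idx = (
            np.flatnonzero(attrs.demographic)
            if self.columns is None
            else [attrs.names.index(c) for c in self.columns]
        )
        return [attrs.names[i] for i in idx]


class FaceMetricsInput:
    """Basic face metrics (stateless: no training fit required)."""

    pixel_based = True

    def __init__(self, oval: OvalSpec, extra: list[str] | None = None):
        self.oval = oval
        self.extra = extra

    def fit(self, images, attrs, rows) -> "FaceMetricsInput":
        return self

    def transform(self, images: ImageStack, attrs, rows) -> np.ndarray:
        sub = images.subset(rows)
        return basic_face_metrics(sub, self.oval, extra=self.extra).to_numpy()


class EmbeddingInput:
    """Embedding backend(s) + truncated-SVD reduction, train-rows-only fit."""

    def __init__(self, backends, d_reduce: int | None = None):
        self.backends = backends if isinstance(backends, (list, tuple)) else [backends]
        self.d_reduce = d_reduce
        self._mean = None
        self._Vt = None

    @property
    def pixel_based(self) -> bool:
        return all(b.pixel_based for b in self.backends)

    def fit(self, images: ImageStack, attrs, rows) -> "EmbeddingInput":
        blocks = []
        for b in self.backends:
            b.fit(images, rows=rows)
            blocks.append(b.transform(images, rows=rows))
        X = np.hstack(blocks)
        if self.d_reduce is None or self.d_reduce >= X.shape[1]:
            self._mean, self._Vt = None, None
            return self
        self._mean = X.mean(axis=0)
        _, _, Vt = np.linalg.svd(X - self._mean, full_matrices=False)
        Vt = Vt[: self.d_reduce]
        signs = np.sign(Vt[np.arange(Vt.shape[0]), np.abs(Vt).argmax(axis=1)])
        signs[signs == 0] = 1.0
        self._Vt = Vt * signs[:, None]
        return self

    def transform(self, images: ImageStack, attrs, rows) -> np.ndarray:
        X = np.hstack([b.transform(images, rows=rows) for b in self.backends])
        if self._Vt is None:
            return X
        return (X - self._mean) @ self._Vt.T


class StackedInput:
    """Column-concatenation of several input sets (the nesting mechanism)."""

    def __init__(self, parts: list):
        if not parts:
            raise ConfigError("StackedInput needs at least one part")
        self.parts = parts

    @property
    def pixel_based(self) -> bool:
        return all(p.pixel_based for p in self.parts)

    def fit(self, images, attrs, rows) -> "StackedInput":
        for p in self.parts:
            p.fit(images, attrs, rows)
        return self

    def transform(self, images, attrs, rows) -> np.ndarray:
        return np.hstack([p.transform(images, attrs, rows) for p in self.parts])
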