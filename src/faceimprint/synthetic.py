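"""Seeded synthetic face-like datasets with planted attribute imprints.

The generator emulates the statistical structure the downstream analysis
assumes: individuals contribute several images each, binary personal
attributes are correlated across individuals through a latent-factor
model, and each image is an additive composition

    X_i = clip(P_0 + sum_j P_j * y_ij + eps_i, 0, 1)

of an intercept "face" image ``P_0``, attribute-specific imprint matrices
``P_j`` (zero for inactive attributes), and i.i.d. Gaussian pixel noise.
This is the generative inverse of the L1-regularized decomposition fitted
by :mod:`faceimprint.decompose`, so ground truth is known exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from ._utils import ConfigError, derive_seed

__all__ = [
    "SyntheticConfig",
    "AttributeTable",
    "ImageStack",
    "PrototypeSet",
    "face_oval_geometry",
    "make_prototypes",
    "make_attributes",
    "render_images",
    "make_dataset",
    "write_dataset",
    "read_dataset",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-design knobs for one synthetic dataset.

    Defaults mirror the reference study design: 969 individuals with 3
    facial images each, 224x224 pixels, 349 binary attributes.  Effect and
    noise scales are in [0,1] pixel-intensity units.
    """

    n_individuals: int = 969
    images_per_individual: int = 3
    image_size: int = 224
    m_attributes: int = 349
    n_active: int = 80
    n_demographic: int = 3
    effect_scale: float = 0.25
    noise_sigma: float = 0.05
    n_latent_factors: int = 20
    fingerprint_attribute: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_active > self.m_attributes:
            raise ConfigError(
                f"n_active={self.n_active} exceeds m_attributes={self.m_attributes}"
            )
        if self.noise_sigma < 0:
            raise ConfigError("noise_sigma must be >= 0")
        if self.image_size % 2 != 0:
            raise ConfigError("image_size must be even (horizontal symmetry pairing)")
        if self.n_individuals < 1 or self.images_per_individual < 1:
            raise ConfigError("need at least one individual and one image each")
        if self.n_latent_factors < 1:
            raise ConfigError("n_latent_factors must be >= 1")
        if self.fingerprint_attribute is not None and not (
            0 <= self.fingerprint_attribute < self.m_attributes
        ):
            raise ConfigError("fingerprint_attribute out of range")
        if self.n_demographic > self.m_attributes:
            raise ConfigError("n_demographic exceeds m_attributes")


@dataclass
class AttributeTable:
    """Binary attribute matrix with one row per image.

    All images of an individual share that individual's attribute values;
    per-image variation enters only through pixel noise at render time.
    """

    individual_id: np.ndarray  # (n,) str
    y: np.ndarray  # (n, m) uint8 in {0,1}
    names: list[str]
    demographic: np.ndarray = field(default=None)  # (m,) bool flags

    def __post_init__(self) -> None:
        self.individual_id = np.asarray(self.individual_id)
        self.y = np.asarray(self.y)
        if self.y.ndim != 2 or self.y.shape[0] != self.individual_id.shape[0]:
            raise ConfigError("attribute matrix misaligned with individual ids")
        if not np.isin(self.y, (0, 1)).all():
            raise ConfigError("attribute values must be binary")
        self.y = self.y.astype(np.uint8)
        if len(self.names) != self.y.shape[1]:
            raise ConfigError("names misaligned with attribute columns")
        if self.demographic is None:
            self.demographic = np.zeros(self.y.shape[1], dtype=bool)
        self.demographic = np.asarray(self.demographic, dtype=bool)

    @property
    def n_rows(self) -> int:
        return self.y.shape[0]

    @property
    def m(self) -> int:
        return self.y.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.y, columns=self.names)
        df.insert(0, "individual_id", self.individual_id)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, demographic=None) -> "AttributeTable":
        if df.columns[0] != "individual_id":
            raise ConfigError("first CSV column must be 'individual_id'")
        names = list(df.columns[1:])
        return cls(
            individual_id=df["individual_id"].to_numpy(),
            y=df[names].to_numpy(),
            names=names,
            demographic=demographic,
        )


@dataclass
class ImageStack:
    """n images as float arrays in [0,1], rows aligned with an AttributeTable."""

    pixels: np.ndarray  # (n, H, W) or (n, H, W, 3)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim not in (3, 4):
            raise ConfigError("pixels must be (n,H,W) or (n,H,W,C)")

    @property
    def n(self) -> int:
        return self.pixels.shape[0]

    @property
    def height(self) -> int:
        return self.pixels.shape[1]

    @property
    def width(self) -> int:
        return self.pixels.shape[2]

    @property
    def channels(self) -> int:
        return 1 if self.pixels.ndim == 3 else self.pixels.shape[3]

    def subset(self, rows) -> "ImageStack":
        return ImageStack(self.pixels[rows])


@dataclass
class PrototypeSet:
    """Intercept plus per-attribute imprint matrices P_0..P_m."""

    P: np.ndarray  # (m+1, H, W)
    symmetric: bool = True
    names: list[str] | None = None

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=np.float64)
        if self.P.ndim != 3:
            raise ConfigError("P must be (m+1, H, W)")
        if self.symmetric and not np.array_equal(self.P, self.P[:, :, ::-1]):
            raise ConfigError("symmetry flag set but prototypes are not mirror-equal")

    @property
    def m(self) -> int:
        return self.P.shape[0] - 1

    @property
    def intercept(self) -> np.ndarray:
        return self.P[0]

    @property
    def imprints(self) -> np.ndarray:
        return self.P[1:]


def face_oval_geometry(image_size: int) -> dict:
    """Ellipse used both to draw the intercept face and as the metric oval.

    Returns center (x, y) and semi-axes (ax, ay) in pixels, x = column,
    y = row.
    """
    s = image_size
    return {
        "center": (s / 2.0 - 0.5, s / 2.0 - 0.5),
        "semi_axes": (0.33 * s, 0.42 * s),
    }


def _gaussian_blur(img: np.ndarray, sigma: float) -> np.ndarray:
    from scipy.ndimage import gaussian_filter

    return gaussian_filter(img, sigma=sigma, mode="nearest")


def _symmetric_checker(size: int) -> np.ndarray:
    """High-frequency +-1 checker that is invariant to horizontal mirroring."""
    rr, cc = np.meshgrid(np.arange(size), np.arange(size), indexing="ij")
    folded = np.minimum(cc, size - 1 - cc)
    return ((rr + folded) % 2) * 2.0 - 1.0


def make_prototypes(config: SyntheticConfig) -> PrototypeSet:
    """Ground-truth intercept and imprint images.

    The intercept is a smooth face-like oval on a dark background.  The
    first ``n_active`` attributes receive localized, horizontally symmetric
    blob imprints with per-attribute amplitude drawn from
    effect_scale * U(0.25, 1) and random sign; remaining attributes have
    exactly-zero imprints.  If ``fingerprint_attribute`` is set, that
    attribute instead carries a low-amplitude high-frequency checker
    spanning the whole image (a camera-fingerprint stand-in).
    """
    rng = np.random.default_rng(derive_seed(config.seed, "prototypes"))
    s = config.image_size
    geom = face_oval_geometry(s)
    cx, cy = geom["center"]
    ax, ay = geom["semi_axes"]

    rr, cc = np.meshgrid(np.arange(s), np.arange(s), indexing="ij")
    inside = ((cc - cx) / ax) ** 2 + ((rr - cy) / ay) ** 2 <= 1.0
    intercept = np.where(inside, 0.55, 0.12)
    intercept = intercept + 0.06 * (1.0 - rr / max(s - 1, 1))  # soft top light
    intercept = _gaussian_blur(intercept, sigma=s / 40.0)
    intercept = np.clip(intercept, 0.0, 1.0)
    # enforce exact mirror symmetry of the base face
    intercept = 0.5 * (intercept + intercept[:, ::-1])

    P = np.zeros((config.m_attributes + 1, s, s))
    P[0] = intercept

    active = list(range(config.n_active))
    for j in active:
        attr_index = j + 1
        if config.fingerprint_attribute is not None and j == config.fingerprint_attribute:
            amp = 0.2 * config.effect_scale
            P[attr_index] = amp * _symmetric_checker(s)
            continue
        amp = config.effect_scale * rng.uniform(0.25, 1.0) * rng.choice((-1.0, 1.0))
        sigma = s * rng.uniform(0.04, 0.09)
        r0 = rng.uniform(0.25 * s, 0.75 * s)
        c0 = rng.uniform(0.15 * s, 0.5 * s)  # left half; mirrored below
        blob = np.exp(-(((rr - r0) ** 2) + ((cc - c0) ** 2)) / (2.0 * sigma**2))
        blob = blob + blob[:, ::-1]
        blob[np.abs(blob) < 0.02] = 0.0  # compact support for recovery checks
        P[attr_index] = amp * blob

    if (
        config.fingerprint_attribute is not None
        and config.fingerprint_attribute not in active
    ):
        amp = 0.2 * config.effect_scale
        P[config.fingerprint_attribute + 1] = amp * _symmetric_checker(s)

    names = [f"attr_{j:03d}" for j in range(config.m_attributes)]
    return PrototypeSet(P=P, symmetric=True, names=names)


def make_attributes(
    config: SyntheticConfig,
    loadings: np.ndarray | None = None,
    thresholds: np.ndarray | float | None = None,
    idio_sigma: float = 0.5,
    allow_constant: bool = False,
) -> AttributeTable:
    """Correlated binary attributes via a latent-factor probit model.

    Per individual, latent factors f ~ N(0, I) are drawn once; attribute j
    is the indicator of ``loadings_j . f + e_j > threshold_j`` with
    idiosyncratic noise e_j ~ N(0, idio_sigma^2).  Rows are repeated
    ``images_per_individual`` times.  A column that comes out constant has
    its threshold reset to the median latent score (both classes then
    occur), unless ``allow_constant`` requests the degenerate fixture.
    """
    m, L = config.m_attributes, config.n_latent_factors
    rng_load = np.random.default_rng(derive_seed(config.seed, "attr-loadings"))
    rng_thr = np.random.default_rng(derive_seed(config.seed, "attr-thresholds"))
    rng_fac = np.random.default_rng(derive_seed(config.seed, "attr-factors"))
    rng_idio = np.random.default_rng(derive_seed(config.seed, "attr-idio"))

    if loadings is None:
        loadings = rng_load.normal(size=(m, L)) / np.sqrt(L)
    loadings = np.asarray(loadings, dtype=float)
    if loadings.shape != (m, L):
        raise ConfigError(f"loadings must have shape ({m}, {L})")

    if thresholds is None:
        thresholds = rng_thr.uniform(-0.8, 0.8, size=m)
    thresholds = np.broadcast_to(np.asarray(thresholds, dtype=float), (m,)).copy()

    factors = rng_fac.normal(size=(config.n_individuals, L))
    idio = rng_idio.normal(size=(config.n_individuals, m)) * idio_sigma
    latent = factors @ loadings.T + idio

    y_ind = latent > thresholds[None, :]
    if not allow_constant and config.n_individuals > 1:
        for j in range(m):
            col = y_ind[:, j]
            if col.all() or not col.any():
                y_ind[:, j] = latent[:, j] > np.median(latent[:, j])

    reps = config.images_per_individual
    ids = np.array(
        [f"ind_{i:05d}" for i in range(config.n_individuals) for _ in range(reps)]
    )
    y = np.repeat(y_ind.astype(np.uint8), reps, axis=0)
    names = [f"attr_{j:03d}" for j in range(m)]
    demographic = np.zeros(m, dtype=bool)
    demographic[: config.n_demographic] = True
    return AttributeTable(individual_id=ids, y=y, names=names, demographic=demographic)


def render_images(
    attrs: AttributeTable,
    protos: PrototypeSet,
    noise_sigma: float,
    seed: int,
) -> ImageStack:
    """Compose images as clip(P_0 + sum_j P_j y_ij + eps, 0, 1)."""
    if attrs.m != protos.m:
        raise ConfigError(
            f"attribute columns ({attrs.m}) do not match prototypes ({protos.m})"
        )
    if noise_sigma < 0:
        raise ConfigError("noise_sigma must be >= 0")
    rng = np.random.default_rng(derive_seed(seed, "render"))
    base = protos.intercept[None, :, :] + np.einsum(
        "nm,mhw->nhw", attrs.y.astype(np.float64), protos.imprints
    )
    if noise_sigma > 0:
        base = base + rng.normal(scale=noise_sigma, size=base.shape)
    return ImageStack(np.clip(base, 0.0, 1.0))


def make_dataset(config: SyntheticConfig):
    """Full generation: (images, attrs, prototypes) from one config."""
    protos = make_prototypes(config)
    attrs = make_attributes(config)
    images = render_images(attrs, protos, config.noise_sigma, config.seed)
    return images, attrs, protos


# ---------------------------------------------------------------------------
# On-disk format: one PNG per image + attributes.csv + manifest.json
# ---------------------------------------------------------------------------


def _content_hash(images: ImageStack, attrs: AttributeTable) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(images.pixels).tobytes())
    h.update(np.ascontiguousarray(attrs.y).tobytes())
    h.update("|".join(map(str, attrs.individual_id)).encode())
    return h.hexdigest()


def write_dataset(
    path,
    images: ImageStack,
    attrs: AttributeTable,
    config: SyntheticConfig | None = None,
    bit_depth: int = 16,
) -> Path:
    """Write PNG images, an attribute CSV and a JSON manifest.

    PNGs are 8- or 16-bit; pixel round-trip error is bounded by
    1/(2^bit_depth - 1).  The manifest records the config (when the
    dataset is synthetic), the bit depth and a content hash, so a dataset
    can be regenerated and verified from the manifest alone.
    """
    if bit_depth not in (8, 16):
        raise ConfigError("bit_depth must be 8 or 16")
    if images.n != attrs.n_rows:
        raise ConfigError("image count does not match attribute rows")
    path = Path(path)
    (path / "images").mkdir(parents=True, exist_ok=True)

    scale = 2**bit_depth - 1
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    for i in range(images.n):
        arr = np.round(images.pixels[i] * scale).astype(dtype)
        iio.imwrite(path / "images" / f"img_{i:05d}.png", arr)

    attrs.to_frame().to_csv(path / "attributes.csv", index=False)
    manifest = {
        "format": "faceimprint-dataset-v1",
        "n_images": int(images.n),
        "image_shape": list(images.pixels.shape[1:]),
        "bit_depth": bit_depth,
        "names": attrs.names,
        "demographic": attrs.demographic.astype(int).tolist(),
        "oval": face_oval_geometry(images.width)
        if images.width == images.height
        else None,
        "config": dataclasses.asdict(config) if config is not None else None,
        "content_sha256": _content_hash(images, attrs),
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return path


def read_dataset(path):
    """Inverse of :func:`write_dataset`; returns (images, attrs, manifest)."""
    path = Path(path)
    manifest_path = path / "manifest.json"
    if not manifest_path.exists():
        raise ConfigError(f"no manifest.json under {path}")
    manifest = json.loads(manifest_path.read_text())
    n = manifest["n_images"]
    scale = 2 ** manifest["bit_depth"] - 1
    frames = []
    for i in range(n):
        f = path / "images" / f"img_{i:05d}.png"
        if not f.exists():
            raise ConfigError(f"missing image file {f}")
        frames.append(np.asarray(iio.imread(f), dtype=np.float64) / scale)
    shapes = {fr.shape for fr in frames}
    if len(shapes) > 1:
        raise ConfigError(f"inconsistent image shapes on disk: {sorted(shapes)}")
    images = ImageStack(np.stack(frames))
    df = pd.read_csv(path / "attributes.csv")
    demo = np.asarray(manifest.get("demographic"), dtype=bool) if manifest.get(
        "demographic"
    ) is not None else None
    attrs = AttributeTable.from_frame(df, demographic=demo)
    return images, attrs, manifest
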