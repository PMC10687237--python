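"""Occlusion-sensitivity mapping: which image areas drive a prediction.

Segments of the image are blocked one at a time on a square grid (8x8 by
default) and the resulting AUC decrease relative to the unmasked image is
averaged over images and cross-validation cells.  Models are always
trained on full images; masking is applied at evaluation time only.  Note
the inherent caveat: information stored redundantly in several areas is
not localized by this procedure, because masking one copy leaves the
others available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._utils import ConfigError
from .evaluate import CVPlan, compute_auc
from .synthetic import AttributeTable, ImageStack

__all__ = ["OcclusionMap", "mask_images", "occlusion_auc_map"]

_FILL_POLICIES = ("train_mean", "zero", "image_mean")


def _cell_slices(image_size_h: int, image_size_w: int, grid_size: int, cell):
    for size, name in ((image_size_h, "height"), (image_size_w, "width")):
        if size % grid_size != 0:
            divisors = [g for g in range(2, size + 1) if size % g == 0][:8]
            raise ConfigError(
                f"grid_size={grid_size} does not divide image {name} {size}; "
                f"try one of {divisors}"
            )
    gr, gc = cell
    if not (0 <= gr < grid_size and 0 <= gc < grid_size):
        raise ConfigError(f"cell {cell} outside {grid_size}x{grid_size} grid")
    ch, cw = image_size_h // grid_size, image_size_w // grid_size
    return slice(gr * ch, (gr + 1) * ch), slice(gc * cw, (gc + 1) * cw)


def mask_images(
    images: ImageStack,
    cell: tuple[int, int],
    grid_size: int = 8,
    fill_policy: str = "zero",
    fill_image: np.ndarray | None = None,
) -> ImageStack:
    """Copies of the images with one grid cell replaced per fill policy.

    Policies: ``zero`` (black), ``image_mean`` (each image's own mean
    intensity), ``train_mean`` (per-location mean of a reference stack,
    supplied via ``fill_image``).  All pixels outside the cell are
    untouched.
    """
    if fill_policy not in _FILL_POLICIES:
        raise ConfigError(f"fill_policy must be one of {_FILL_POLICIES}")
    rs, cs = _cell_slices(images.height, images.width, grid_size, cell)
    out = images.pixels.copy()
    if fill_policy == "zero":
        out[:, rs, cs] = 0.0
    elif fill_policy == "image_mean":
        axes = tuple(range(1, out.ndim))
        means = out.mean(axis=axes)
        out[:, rs, cs] = means.reshape((-1,) + (1,) * (out.ndim - 1))
    else:
        if fill_image is None:
            raise ConfigError("train_mean fill requires a fill_image")
        fill_image = np.asarray(fill_image, dtype=np.float64)
        if fill_image.shape != images.pixels.shape[1:]:
            raise ConfigError("fill_image shape does not match images")
        out[:, rs, cs] = fill_image[rs, cs]
    return ImageStack(out)


@dataclass
class OcclusionMap:
    """Grid of mean AUC decreases under masking, for one variable."""

    variable: str
    grid_size: int
    decrease: np.ndarray  # (grid, grid) mean baseline - masked AUC
    baseline_mean: float

    def __post_init__(self) -> None:
        self.decrease = np.asarray(self.decrease, dtype=np.float64)
        if self.decrease.shape != (self.grid_size, self.grid_size):
            raise ConfigError("decrease matrix does not match grid size")


def occlusion_auc_map(
    images: ImageStack,
    attrs: AttributeTable,
    variable: str,
    plan: CVPlan,
    input_spec,
    grid_size: int = 8,
    fill_policy: str = "train_mean",
) -> OcclusionMap:
    """Mean AUC decrease per grid cell for one variable.

    Per CV cell: the pipeline is fitted on unmasked training folds, the
    baseline AUC is computed on the held-out fold, then each grid cell is
    masked in the held-out images and the AUC recomputed; the decrease is
    averaged over all CV cells where the baseline is defined.
    """
    from .predict import fit_auto_ridge, predict_scores

    if not getattr(input_spec, "pixel_based", False):
        raise ConfigError(
            "occlusion requires a pixel-based input set (masked pixels must "
            "propagate to features)"
        )
    if variable not in attrs.names:
        raise ConfigError(f"unknown variable '{variable}'")
    _cell_slices(images.height, images.width, grid_size, (0, 0))  # validate early
    j = attrs.names.index(variable)

    sums = np.zeros((grid_size, grid_size))
    baseline_sum = 0.0
    n_cells = 0
    for repeat, fold in plan.cells():
        train, test = plan.split_rows(attrs.individual_id, repeat, fold)
        input_spec.fit(images, attrs, train)
        F_tr = input_spec.transform(images, attrs, train)
        model = fit_auto_ridge(F_tr, attrs.y[train, j])
        y_te = attrs.y[test, j]
        F_te = input_spec.transform(images, attrs, test)
        baseline = compute_auc(predict_scores(model, F_te), y_te)
        if baseline is None:
            continue
        fill = images.pixels[train].mean(axis=0) if fill_policy == "train_mean" else None
        for gr in range(grid_size):
            for gc in range(grid_size):
                masked = mask_images(
                    images, (gr, gc), grid_size, fill_policy, fill_image=fill
                )
                F_m = input_spec.transform(masked, attrs, test)
                auc = compute_auc(predict_scores(model, F_m), y_te)
                sums[gr, gc] += baseline - auc
        baseline_sum += baseline
        n_cells += 1

    if n_cells == 0:
        raise ConfigError(
            f"baseline AUC undefined in every CV cell for '{variable}'"
        )
    return OcclusionMap(
        variable=variable,
        grid_size=grid_size,
        decrease=sums / n_cells,
        baseline_mean=baseline_sum / n_cells,
    )
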