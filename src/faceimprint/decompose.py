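"""L1-regularized additive decomposition of images into attribute imprints.

A stack of n grayscale images X_i is modeled as an intercept image plus a
sum of attribute-specific imprint matrices switched on by binary
attributes y_ij:

    min over P_0..P_m of
        (1/n) sum_i || X_i - P_0 - sum_j P_j y_ij ||_F^2
        + lambda * sum_{j=0..m} 1^T |P_j| 1

Note the L1 penalty runs over all matrices including the intercept.  The
problem is convex and separable across pixel columns — each pixel is an
independent lasso on the design [1, Y] — which yields an exact
coordinate-descent oracle for small instances.  The production solvers
operate on all pixels jointly: OWL-QN (orthant-wise limited-memory
quasi-Newton) and proximal gradient (FISTA with adaptive restart), both
optionally under a horizontal symmetry reparametrization where the left
half of every coefficient matrix equals its mirrored right half, halving
the number of free parameters.

The sum of absolute entries of an estimated imprint, v_j = 1^T |P_j| 1, is
its *visual prominence score*: the total pixel-intensity mass an attribute
contributes.  An exactly-zero imprint (an attribute unrelated to image
appearance, shrunk out by the L1 penalty) has v_j = 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._utils import ConfigError
from .synthetic import AttributeTable, ImageStack, PrototypeSet

__all__ = [
    "DecompositionConfig",
    "DecompositionFit",
    "to_grayscale",
    "decomposition_loss",
    "fit_decomposition",
    "lasso_pixel_oracle",
    "prominence_scores",
    "prominence_auc_correlation",
    "normalize_prototype",
    "n_free_parameters",
]

# ITU-R BT.601 luminance weights
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class DecompositionConfig:
    """Solver settings for the imprint decomposition."""

    lambda_: float = 0.01
    symmetry: bool = True
    solver: str = "owlqn"  # or "proximal"
    stop_patience: int = 10
    max_iter: int = 2000
    tol: float = 1e-9  # pseudo-gradient / improvement tolerance
    memory: int = 10  # L-BFGS history length
    exclude_intercept_penalty: bool = False
    seed: int = 0  # reserved; both solvers start from zero

    def __post_init__(self) -> None:
        if self.lambda_ < 0:
            raise ConfigError("lambda_ must be >= 0")
        if self.stop_patience < 1:
            raise ConfigError("stop_patience must be >= 1")
        if self.solver not in ("owlqn", "proximal"):
            raise ConfigError("solver must be 'owlqn' or 'proximal'")


@dataclass
class DecompositionFit:
    """Result of the decomposition: estimated prototypes plus diagnostics."""

    prototypes: PrototypeSet
    final_loss: float
    n_iter: int
    loss_trace: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if self.loss_trace is not None:
            self.loss_trace = np.asarray(self.loss_trace, dtype=np.float64)


def to_grayscale(images: ImageStack) -> ImageStack:
    """Convert RGB to single-channel luminance; grayscale passes through."""
    if images.channels == 1:
        px = images.pixels
        return ImageStack(px if px.ndim == 3 else px[..., 0])
    if images.channels != 3:
        raise ConfigError(f"expected 1 or 3 channels, got {images.channels}")
    return ImageStack(images.pixels @ _LUMA)


def _as_pixels(X) -> np.ndarray:
    if isinstance(X, ImageStack):
        X = to_grayscale(X)
        return X.pixels
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 3:
        raise ConfigError("X must be an ImageStack or an (n,H,W) array")
    if not np.isfinite(X).all():
        raise ConfigError("non-finite pixel values")
    return X


def _as_y(Y) -> np.ndarray:
    if isinstance(Y, AttributeTable):
        return Y.y.astype(np.float64)
    Y = np.asarray(Y, dtype=np.float64)
    if Y.ndim != 2 or not np.isin(Y, (0.0, 1.0)).all():
        raise ConfigError("Y must be an (n,m) binary matrix")
    return Y


def decomposition_loss(
    X, Y, P: np.ndarray, lambda_: float, penalize_intercept: bool = True
) -> float:
    """Exact objective value; shared by both solvers, the oracle and tests."""
    Xp = _as_pixels(X)
    Yv = _as_y(Y)
    P = np.asarray(P, dtype=np.float64)
    n, h, w = Xp.shape
    if Yv.shape[0] != n or P.shape != (Yv.shape[1] + 1, h, w):
        raise ConfigError("shape mismatch between X, Y and P")
    resid = Xp - P[0][None] - np.einsum("nm,mhw->nhw", Yv, P[1:])
    fit = float((resid**2).sum() / n)
    pen = np.abs(P).sum() if penalize_intercept else np.abs(P[1:]).sum()
    return fit + lambda_ * float(pen)


def n_free_parameters(image_shape: tuple[int, int], m: int, symmetry: bool) -> int:
    """Parameter count of the decomposition; symmetry halves it exactly."""
    h, w = image_shape
    full = (m + 1) * h * w
    if not symmetry:
        return full
    if w % 2 != 0:
        raise ConfigError("symmetry requires an even image width")
    return full // 2


# ---------------------------------------------------------------------------
# Quadratic smooth part in (q x p_free) coefficient space
# ---------------------------------------------------------------------------


class _Quadratic:
    """f(C) = (a/n) tr(C' G C) - (2/n) tr(C' M) + const/n with gradient."""

    def __init__(self, Z: np.ndarray, Xf: np.ndarray, left=None, right=None):
        n = Z.shape[0]
        self.n = n
        self.G = Z.T @ Z
        if left is None:
            self.a = 1.0
            self.M = Z.T @ Xf
            self.const = float((Xf**2).sum())
        else:
            XL, XR = Xf[:, left], Xf[:, right]
            self.a = 2.0
            self.M = Z.T @ (XL + XR)
            self.const = float((XL**2).sum() + (XR**2).sum())
        self.shape = (Z.shape[1], self.M.shape[1])
        self.lipschitz = (
            2.0 * self.a / n * float(np.linalg.eigvalsh(self.G)[-1])
        )

    def value_grad(self, C: np.ndarray):
        GC = self.G @ C
        f = (
            self.a * float((C * GC).sum())
            - 2.0 * float((C * self.M).sum())
            + self.const
        ) / self.n
        g = (2.0 / self.n) * (self.a * GC - self.M)
        return f, g


def _soft_threshold(x: np.ndarray, t: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.maximum(np.abs(x) - t, 0.0)


def _check_finite(obj: float, iteration: int) -> None:
    if not np.isfinite(obj):
        raise RuntimeError(f"decomposition loss diverged (NaN/inf) at iteration {iteration}")


def _fista(quad: _Quadratic, w: np.ndarray, max_iter: int, patience: int, tol: float):
    """Proximal gradient with FISTA momentum and adaptive restart.

    Stops when `patience` successive iterations fail to improve the best
    objective by a relative `tol`.
    """
    L = quad.lipschitz
    if L == 0.0:  # no data signal at all
        C = np.zeros(quad.shape)
        f, _ = quad.value_grad(C)
        return C, [f], 0
    step = 1.0 / L
    x = np.zeros(quad.shape)
    z = x
    t = 1.0
    f, _ = quad.value_grad(x)
    best = f + float((w * np.abs(x)).sum())
    trace = [best]
    fails = 0
    n_iter = 0
    for it in range(1, max_iter + 1):
        n_iter = it
        _, g = quad.value_grad(z)
        x_new = _soft_threshold(z - step * g, step * w)
        f_new, _ = quad.value_grad(x_new)
        obj = f_new + float((w * np.abs(x_new)).sum())
        if obj > best:  # momentum overshot: restart from the last iterate
            t = 1.0
            _, g = quad.value_grad(x)
            x_new = _soft_threshold(x - step * g, step * w)
            f_new, _ = quad.value_grad(x_new)
            obj = f_new + float((w * np.abs(x_new)).sum())
        _check_finite(obj, it)
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
        z = x_new + ((t - 1.0) / t_new) * (x_new - x)
        x = x_new
        t = t_new
        trace.append(obj)
        if obj < best - tol * max(1.0, abs(best)):
            best = obj
            fails = 0
        else:
            best = min(best, obj)
            fails += 1
            if fails >= patience:
                break
    return x, trace, n_iter


def _pseudo_gradient(x: np.ndarray, g: np.ndarray, w: np.ndarray) -> np.ndarray:
    pg = np.where(x > 0, g + w, np.where(x < 0, g - w, 0.0))
    zero = x == 0
    gp = g + w
    gm = g - w
    pg = np.where(zero & (gp < 0), gp, pg)
    pg = np.where(zero & (gm > 0), gm, pg)
    return pg


def _owlqn(quad: _Quadratic, w: np.ndarray, max_iter: int, patience: int,
           tol: float, memory: int):
    """Orthant-wise limited-memory quasi-Newton for f(x) + sum w|x|.

    Standard scheme: L-BFGS direction computed from the pseudo-gradient of
    the nonsmooth objective, constrained to the orthant of the current
    iterate (sign of x, or of the steepest-descent direction at zeros),
    with a backtracking projected line search.
    """
    shape = quad.shape
    x = np.zeros(shape).ravel()
    wf = np.broadcast_to(w, shape).ravel()

    def fg(v):
        f, g = quad.value_grad(v.reshape(shape))
        return f, g.ravel()

    f, g = fg(x)
    obj = f + float((wf * np.abs(x)).sum())
    best = obj
    trace = [obj]
    s_hist: list[np.ndarray] = []
    y_hist: list[np.ndarray] = []
    rho_hist: list[float] = []
    fails = 0
    n_iter = 0

    for it in range(1, max_iter + 1):
        n_iter = it
        pg = _pseudo_gradient(x, g, wf)
        if np.abs(pg).max(initial=0.0) < tol:
            break
        # two-loop recursion on -pg
        d = -pg
        alphas = []
        for s, yv, rho in zip(reversed(s_hist), reversed(y_hist), reversed(rho_hist)):
            a = rho * (s @ d)
            alphas.append(a)
            d = d - a * yv
        if y_hist:
            gamma = (s_hist[-1] @ y_hist[-1]) / (y_hist[-1] @ y_hist[-1])
            d = gamma * d
        for (s, yv, rho), a in zip(
            zip(s_hist, y_hist, rho_hist), reversed(alphas)
        ):
            b = rho * (yv @ d)
            d = d + (a - b) * s
        # align the direction with the steepest-descent orthant
        d = np.where(d * (-pg) > 0, d, 0.0)
        if not np.any(d):
            break
        xi = np.where(x != 0, np.sign(x), np.sign(-pg))
        step = 1.0 if s_hist else min(1.0, 1.0 / (np.abs(pg).sum() + 1e-30))
        accepted = False
        for _ in range(60):
            xt = x + step * d
            xt = np.where(xt * xi > 0, xt, 0.0)
            ft, gt = fg(xt)
            objt = ft + float((wf * np.abs(xt)).sum())
            _check_finite(objt, it)
            if objt <= obj + 1e-4 * float(pg @ (xt - x)):
                accepted = True
                break
            step *= 0.5
        if not accepted:
            break  # line search exhausted: numerically converged
        s = xt - x
        yv = gt - g
        if float(s @ yv) > 1e-12:
            s_hist.append(s)
            y_hist.append(yv)
            rho_hist.append(1.0 / float(s @ yv))
            if len(s_hist) > memory:
                s_hist.pop(0)
                y_hist.pop(0)
                rho_hist.pop(0)
        x, g, obj = xt, gt, objt
        trace.append(obj)
        if obj < best - tol * max(1.0, abs(best)):
            best = obj
            fails = 0
        else:
            best = min(best, obj)
            fails += 1
            if fails >= patience:
                break
    return x.reshape(shape), trace, n_iter


def _mirror_indices(h: int, w: int):
    """Flat pixel indices of the left half and of their mirror columns."""
    rr, cc = np.meshgrid(np.arange(h), np.arange(w // 2), indexing="ij")
    left = (rr * w + cc).ravel()
    right = (rr * w + (w - 1 - cc)).ravel()
    return left, right


def fit_decomposition(X, Y, config: DecompositionConfig | None = None) -> DecompositionFit:
    """Estimate P_0..P_m by minimizing the penalized objective.

    Initialization is all-zeros (the problem is convex, so this affects
    iteration count only).  Training stops when `stop_patience` successive
    iterations fail to decrease the loss, on solver convergence, or at
    `max_iter`.
    """
    if config is None:
        config = DecompositionConfig()
    Xp = _as_pixels(X)
    Yv = _as_y(Y)
    n, h, w = Xp.shape
    if Yv.shape[0] != n:
        raise ConfigError("X and Y row counts differ")
    if config.symmetry and w % 2 != 0:
        raise ConfigError("symmetry requires an even image width")
    m = Yv.shape[1]
    q = m + 1
    Z = np.hstack([np.ones((n, 1)), Yv])
    Xf = Xp.reshape(n, h * w)

    lam_row = np.full((q, 1), config.lambda_)
    if config.exclude_intercept_penalty:
        lam_row[0] = 0.0

    if config.symmetry:
        left, right = _mirror_indices(h, w)
        quad = _Quadratic(Z, Xf, left=left, right=right)
        weights = 2.0 * lam_row  # each free entry appears in both halves
    else:
        quad = _Quadratic(Z, Xf)
        weights = lam_row

    if config.solver == "owlqn":
        C, trace, n_iter = _owlqn(
            quad, weights, config.max_iter, config.stop_patience, config.tol,
            config.memory,
        )
    else:
        C, trace, n_iter = _fista(
            quad, np.broadcast_to(weights, quad.shape).copy(),
            config.max_iter, config.stop_patience, config.tol,
        )

    if config.symmetry:
        B = np.empty((q, h * w))
        B[:, left] = C
        B[:, right] = C
    else:
        B = C
    P = B.reshape(q, h, w)
    protos = PrototypeSet(P=P, symmetric=config.symmetry, names=None)
    final = decomposition_loss(
        Xp, Yv, P, config.lambda_,
        penalize_intercept=not config.exclude_intercept_penalty,
    )
    return DecompositionFit(
        prototypes=protos, final_loss=final, n_iter=n_iter, loss_trace=trace
    )


def lasso_pixel_oracle(X, Y, lambda_: float, symmetry: bool = True) -> PrototypeSet:
    """Independent per-pixel coordinate-descent solution (small instances).

    The objective is separable across pixels: each pixel column is a lasso
    on the design [1, Y] with penalty lambda_ on every coefficient
    including the intercept.  Under symmetry, each mirrored pixel pair is
    one doubled-sample lasso.  Solves every subproblem to high precision,
    giving the global optimum to compare solvers against.
    """
    from sklearn.linear_model import Lasso

    Xp = _as_pixels(X)
    Yv = _as_y(Y)
    n, h, w = Xp.shape
    if symmetry and w % 2 != 0:
        raise ConfigError("symmetry requires an even image width")
    q = Yv.shape[1] + 1
    Z = np.hstack([np.ones((n, 1)), Yv])
    Xf = Xp.reshape(n, h * w)

    def solve_block(design, targets):
        # our (1/n')*||r||^2 + lam*|b| maps to sklearn's (1/(2n'))*||r||^2
        # + alpha*|b| with alpha = lam/2  (n' = design rows)
        if lambda_ == 0.0:
            return np.linalg.lstsq(design, targets, rcond=None)[0]
        model = Lasso(
            alpha=lambda_ / 2.0, fit_intercept=False, tol=1e-12, max_iter=200000
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # tiny-tol convergence warnings
            model.fit(design, targets)
        return model.coef_.T  # multi-output coef_ is (targets, q)

    B = np.empty((q, h * w))
    if symmetry:
        left, right = _mirror_indices(h, w)
        design = np.vstack([Z, Z])
        targets = np.vstack([Xf[:, left], Xf[:, right]])
        C = solve_block(design, targets)
        B[:, left] = C
        B[:, right] = C
    else:
        B = solve_block(Z, Xf)
    return PrototypeSet(P=B.reshape(q, h, w), symmetric=symmetry, names=None)


def prominence_scores(P) -> np.ndarray:
    """Visual prominence v_j = sum of |P_j| entries, for j = 1..m."""
    arr = P.P if isinstance(P, PrototypeSet) else np.asarray(P)
    return np.abs(arr[1:]).sum(axis=(1, 2))


def prominence_auc_correlation(v, auc_means) -> tuple[float, float] | None:
    """Pearson correlation (r, r^2) between prominence and mean hold-out AUC.

    Returns None when either vector is constant (correlation undefined).
    """
    v = np.asarray(v, dtype=np.float64)
    a = np.asarray(auc_means, dtype=np.float64)
    if v.shape != a.shape or v.size < 3:
        raise ConfigError("need aligned vectors of length >= 3")
    if np.all(v == v[0]) or np.all(a == a[0]):
        return None
    r = float(stats.pearsonr(v, a).statistic)
    return r, r * r


def normalize_prototype(P_j: np.ndarray) -> np.ndarray:
    """Scale an imprint to [-1, 1] by its max absolute entry (for display)."""
    P_j = np.asarray(P_j, dtype=np.float64)
    peak = np.abs(P_j).max()
    if peak == 0.0:
        warnings.warn("normalizing an all-zero prototype", stacklevel=2)
        return np.zeros_like(P_j)
    return P_j / peak
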