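"""Motion decoupling: local polynomial motion modeling, polar transformation
with adaptive thresholding, and dual-threshold trinary filtering.

The stage turns a pair of consecutive frames into a sparse set of
(x, y, magnitude, angle) motion features:

1. each frame is approximated pixelwise by a local quadratic model
   ``I(p) ~= 1/2 p^T A p + b^T p + c`` over an odd window;
2. per-pixel displacement is solved in closed form from the two fits
   (averaged curvature, gradient difference) with ridge stabilisation and
   optional Gauss-Newton refinement passes;
3. the displacement field is converted to polar magnitude/angle, local
   magnitude statistics give adaptive thresholds
   ``tau_low = mu + k1*sigma``, ``tau_high = mu + k2*sigma``, and each pixel
   is labelled 0 (static), 1 (uncertain) or 2 (confident motion).

Coordinates are 0-based, (x = column, y = row), pixel-centre convention.
All windowed operators use reflection padding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "ImageFrame", "PolynomialFit", "DisplacementField", "PolarMotionField",
    "ThresholdMaps", "MotionMask", "SparseMotionFeatures",
    "fit_polynomial", "estimate_displacement", "to_polar", "local_statistics",
    "adaptive_thresholds", "classify_motion", "sparse_features",
    "rasterize_motion", "decouple",
]


# ----------------------------------------------------------------------
# domain types
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class ImageFrame:
    """A single grayscale frame with intensities normalised to [0, 1]."""

    pixels: np.ndarray
    index: int = 0

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=np.float64)
        object.__setattr__(self, "pixels", px)
        if px.ndim != 2:
            raise ValueError("ImageFrame.pixels must be 2-D")
        if px.shape[0] < 8 or px.shape[1] < 8:
            raise ValueError("frames must be at least 8x8")
        if not np.all(np.isfinite(px)):
            raise ValueError("frame intensities must be finite")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class PolynomialFit:
    """Per-pixel quadratic model: A (2x2 symmetric, A_xy stored once), b, c."""

    a_xx: np.ndarray
    a_yy: np.ndarray
    a_xy: np.ndarray
    b_x: np.ndarray
    b_y: np.ndarray
    c: np.ndarray


@dataclass(frozen=True)
class DisplacementField:
    dx: np.ndarray
    dy: np.ndarray

    def __post_init__(self):
        if self.dx.shape != self.dy.shape:
            raise ValueError("dx/dy shape mismatch")


@dataclass(frozen=True)
class PolarMotionField:
    rho: np.ndarray
    theta: np.ndarray


@dataclass(frozen=True)
class ThresholdMaps:
    mu: np.ndarray
    sigma: np.ndarray
    tau_low: np.ndarray | None = None
    tau_high: np.ndarray | None = None


@dataclass(frozen=True)
class MotionMask:
    labels: np.ndarray  # values in {0, 1, 2}


@dataclass(frozen=True)
class SparseMotionFeatures:
    """Set of (x, y, rho, theta) entries for pixels with mask label > 0."""

    entries: np.ndarray = field(default_factory=lambda: np.empty((0, 4)))

    def __len__(self) -> int:
        return self.entries.shape[0]


# ----------------------------------------------------------------------
# stage 1: polynomial motion modelling
# ----------------------------------------------------------------------

def _basis_and_weights(window: int, sigma: float | None):
    r = window // 2
    off = np.arange(-r, r + 1, dtype=np.float64)
    px, py = np.meshgrid(off, off)  # px varies along columns (x), py along rows (y)
    if sigma is None:
        sigma = 0.15 * window + 0.35
    w = np.exp(-(px**2 + py**2) / (2.0 * sigma**2))
    basis = np.stack([np.ones_like(px), px, py, px**2, py**2, px * py])
    return basis, w


def fit_polynomial(frame: ImageFrame | np.ndarray, window: int = 5, *,
                   sigma: float | None = None, alpha: float = 0.0,
                   beta: float = 0.0, lam: float = 1.0) -> PolynomialFit:
    """Weighted least-squares quadratic fit around every pixel.

    ``alpha``/``beta`` add Tikhonov penalties on the curvature and gradient
    coefficients (scaled by ``lam``); with both zero the fit is exact for
    polynomial images of degree <= 2.
    """
    img = frame.pixels if isinstance(frame, ImageFrame) else np.asarray(frame, float)
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    if window > min(img.shape):
        raise ValueError("window exceeds image size")
    basis, w = _basis_and_weights(window, sigma)
    nb = basis.shape[0]
    G = np.einsum("kij,lij,ij->kl", basis, basis, w)
    # penalty on ||A||_F^2 = 4 axx^2 + 4 ayy^2 + 2 axy^2 and ||b||^2
    G = G + np.diag([0.0, lam * beta, lam * beta,
                     4.0 * lam * alpha, 4.0 * lam * alpha, 2.0 * lam * alpha])
    Ginv = np.linalg.inv(G)
    proj = np.stack([
        ndimage.correlate(img, basis[k] * w, mode="reflect") for k in range(nb)
    ])
    coeffs = np.einsum("kl,lij->kij", Ginv, proj)
    c, bx, by, axx, ayy, axy = coeffs
    # quadratic-form convention I ~= 1/2 p^T A p + b^T p + c
    return PolynomialFit(a_xx=2.0 * axx, a_yy=2.0 * ayy, a_xy=axy,
                         b_x=bx, b_y=by, c=c)


# ----------------------------------------------------------------------
# stage 1b: displacement from dual polynomial expansion
# ----------------------------------------------------------------------

def _sample_fit(fit: PolynomialFit, xs: np.ndarray, ys: np.ndarray) -> PolynomialFit:
    coords = np.stack([ys.ravel(), xs.ravel()])

    def samp(a):
        return ndimage.map_coordinates(a, coords, order=1, mode="nearest").reshape(xs.shape)

    return PolynomialFit(*(samp(getattr(fit, f)) for f in
                           ("a_xx", "a_yy", "a_xy", "b_x", "b_y", "c")))


def estimate_displacement(frame_t: ImageFrame | np.ndarray,
                          frame_next: ImageFrame | np.ndarray,
                          window: int = 5, alpha: float = 0.1,
                          beta: float = 0.01, ridge: float = 1e-6, *,
                          lam: float = 1.0, iters: int = 3,
                          agg_window: int | None = None) -> DisplacementField:
    """Closed-form per-pixel displacement between two frames.

    Both frames are fitted with the regularised quadratic model; displacement
    follows from the averaged curvature and half the gradient difference,
    aggregated over a local window and solved with ridge-stabilised 2x2
    inversion.  ``iters`` Gauss-Newton passes re-sample the second frame's
    fit at the warped positions.  Ill-conditioned pixels return (0, 0).
    """
    a = frame_t.pixels if isinstance(frame_t, ImageFrame) else np.asarray(frame_t, float)
    b = frame_next.pixels if isinstance(frame_next, ImageFrame) else np.asarray(frame_next, float)
    if a.shape != b.shape:
        raise ValueError("frames must share shape")
    fit1 = fit_polynomial(a, window, alpha=alpha, beta=beta, lam=lam)
    fit2 = fit_polynomial(b, window, alpha=alpha, beta=beta, lam=lam)
    H, W = a.shape
    ys, xs = np.mgrid[0:H, 0:W].astype(np.float64)
    dx = np.zeros_like(a)
    dy = np.zeros_like(a)
    agg = agg_window or (2 * window + 1)
    for _ in range(max(iters, 1)):
        f2 = _sample_fit(fit2, xs + dx, ys + dy)
        m11 = 0.5 * (fit1.a_xx + f2.a_xx)
        m22 = 0.5 * (fit1.a_yy + f2.a_yy)
        m12 = 0.5 * (fit1.a_xy + f2.a_xy)
        # with the 1/2 p^T A p convention, I2(x) = I1(x - d) gives A d = b1 - b2
        rx = -(f2.b_x - fit1.b_x) + m11 * dx + m12 * dy
        ry = -(f2.b_y - fit1.b_y) + m12 * dx + m22 * dy
        # aggregate normal equations M^T M d = M^T r over a local window
        def blur(z):
            return ndimage.uniform_filter(z, size=agg, mode="reflect")

        g11 = blur(m11 * m11 + m12 * m12)
        g12 = blur(m11 * m12 + m12 * m22)
        g22 = blur(m12 * m12 + m22 * m22)
        h1 = blur(m11 * rx + m12 * ry)
        h2 = blur(m12 * rx + m22 * ry)
        g11 = g11 + ridge
        g22 = g22 + ridge
        det = g11 * g22 - g12 * g12
        ok = det > 1e-30  # ridge makes the system positive definite
        inv_det = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
        dx = (g22 * h1 - g12 * h2) * inv_det
        dy = (g11 * h2 - g12 * h1) * inv_det
        dx = np.where(np.isfinite(dx), dx, 0.0)
        dy = np.where(np.isfinite(dy), dy, 0.0)
    return DisplacementField(dx=dx, dy=dy)


# ----------------------------------------------------------------------
# stage 2: polar transform and adaptive thresholds
# ----------------------------------------------------------------------

def to_polar(fld: DisplacementField) -> PolarMotionField:
    """rho = sqrt(dx^2 + dy^2), theta = atan2(dy, dx); theta := 0 where rho = 0."""
    if not (np.all(np.isfinite(fld.dx)) and np.all(np.isfinite(fld.dy))):
        raise ValueError("displacement field must be finite")
    rho = np.hypot(fld.dx, fld.dy)
    theta = np.arctan2(fld.dy, fld.dx)
    theta = np.where(rho > 0, theta, 0.0)
    return PolarMotionField(rho=rho, theta=theta)


def local_statistics(polar: PolarMotionField, stat_window: int = 15) -> ThresholdMaps:
    """Windowed mean and population standard deviation of rho (reflect padding)."""
    rho = polar.rho
    if stat_window % 2 == 0 or stat_window < 1:
        raise ValueError("stat_window must be odd")
    if stat_window > min(rho.shape):
        raise ValueError("stat_window exceeds image size")
    mu = ndimage.uniform_filter(rho, size=stat_window, mode="reflect")
    ex2 = ndimage.uniform_filter(rho * rho, size=stat_window, mode="reflect")
    sigma = np.sqrt(np.clip(ex2 - mu * mu, 0.0, None))
    return ThresholdMaps(mu=mu, sigma=sigma)


def adaptive_thresholds(maps: ThresholdMaps, k1: float = 1.0,
                        k2: float = 2.5) -> ThresholdMaps:
    """tau_low = mu + k1*sigma, tau_high = mu + k2*sigma (elementwise)."""
    if k2 < k1:
        raise ValueError("k2 must be >= k1")
    return ThresholdMaps(mu=maps.mu, sigma=maps.sigma,
                         tau_low=maps.mu + k1 * maps.sigma,
                         tau_high=maps.mu + k2 * maps.sigma)


def classify_motion(polar: PolarMotionField, maps: ThresholdMaps, *,
                    min_rho: float = 1e-6) -> MotionMask:
    """Trinary labels: 0 if rho < tau_low, 1 if tau_low <= rho <= tau_high,
    2 if rho > tau_high.  Pixels with rho < ``min_rho`` are always 0 so that
    fully static inputs (tau_low = tau_high = 0) do not flag every pixel.
    """
    if maps.tau_low is None or maps.tau_high is None:
        raise ValueError("threshold maps not filled; call adaptive_thresholds first")
    rho = polar.rho
    labels = np.ones(rho.shape, dtype=np.int8)
    labels[rho < maps.tau_low] = 0
    labels[rho > maps.tau_high] = 2
    labels[rho < min_rho] = 0
    return MotionMask(labels=labels)


# ----------------------------------------------------------------------
# stage 3: sparse features
# ----------------------------------------------------------------------

def sparse_features(polar: PolarMotionField, mask: MotionMask) -> SparseMotionFeatures:
    """Retain (x, y, rho, theta) exactly at pixels with label > 0."""
    if polar.rho.shape != mask.labels.shape:
        raise ValueError("polar/mask shape mismatch")
    ys, xs = np.nonzero(mask.labels > 0)
    entries = np.column_stack([xs.astype(np.float64), ys.astype(np.float64),
                               polar.rho[ys, xs], polar.theta[ys, xs]])
    return SparseMotionFeatures(entries=entries)


def rasterize_motion(features: SparseMotionFeatures, shape: tuple[int, int]) -> np.ndarray:
    """Densify sparse features into a 2-channel (rho, theta) image, zeros elsewhere."""
    out = np.zeros((2,) + tuple(shape), dtype=np.float64)
    if len(features) == 0:
        return out
    xs = features.entries[:, 0].astype(int)
    ys = features.entries[:, 1].astype(int)
    if (xs < 0).any() or (ys < 0).any() or (xs >= shape[1]).any() or (ys >= shape[0]).any():
        raise ValueError("sparse feature coordinates out of bounds for shape")
    out[0, ys, xs] = features.entries[:, 2]
    out[1, ys, xs] = features.entries[:, 3]
    return out


def dump_debug(polar: PolarMotionField, mask: MotionMask,
               features: SparseMotionFeatures, out_dir, prefix: str = "motion"):
    """Write mask/polar channels as 16-bit PNGs and sparse features as CSV."""
    import imageio.v3 as iio
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    iio.imwrite(out / f"{prefix}_mask.png",
                (mask.labels.astype(np.uint16) * 32767))
    rho_max = max(float(polar.rho.max()), 1e-9)
    iio.imwrite(out / f"{prefix}_rho.png",
                np.clip(polar.rho / rho_max * 65535, 0, 65535).astype(np.uint16))
    iio.imwrite(out / f"{prefix}_theta.png",
                ((polar.theta + np.pi) / (2 * np.pi) * 65535).astype(np.uint16))
    with open(out / f"{prefix}_features.csv", "w", encoding="utf-8") as fh:
        fh.write("x,y,rho,theta\n")
        for x, y, rho, theta in features.entries:
            fh.write(f"{int(x)},{int(y)},{rho:.6f},{theta:.6f}\n")
    return out


def decouple(frame_t, frame_next, cfg=None) -> tuple[np.ndarray, MotionMask, PolarMotionField]:
    """Full pipeline: frame pair -> (2-channel motion raster, mask, polar field).

    ``cfg`` is a :class:`hgtrack.config.MotionConfig`-like object; defaults are
    used when it is None.
    """
    kw = dict(ridge=1e-5)
    stat_window, k1, k2, min_rho, presmooth = 61, 1.0, 2.5, 1e-6, 1.0
    if cfg is not None:
        kw = dict(window=cfg.window, alpha=cfg.alpha, beta=cfg.beta,
                  ridge=cfg.ridge, lam=cfg.lam, iters=cfg.iters)
        stat_window, k1, k2, min_rho = cfg.stat_window, cfg.k1, cfg.k2, cfg.min_rho
        presmooth = cfg.presmooth
    a = frame_t.pixels if isinstance(frame_t, ImageFrame) else np.asarray(frame_t, float)
    b = frame_next.pixels if isinstance(frame_next, ImageFrame) else np.asarray(frame_next, float)
    if presmooth > 0:
        a = ndimage.gaussian_filter(a, presmooth)
        b = ndimage.gaussian_filter(b, presmooth)
    stat_window = min(stat_window, min(a.shape) - 1 - (min(a.shape) % 2))
    fld = estimate_displacement(a, b, **kw)
    polar = to_polar(fld)
    maps = adaptive_thresholds(local_statistics(polar, stat_window), k1, k2)
    mask = classify_motion(polar, maps, min_rho=min_rho)
    feats = sparse_features(polar, mask)
    shape = polar.rho.shape
    return rasterize_motion(feats, shape), mask, polar
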