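"""Layer-relative coordinate frame for the lobula.

The lobula is a curved, layered neuropil. To compare neurons by the layers
they innervate, all synapse positions are re-expressed in a frame derived
from the postsynapses of a reference tangential neuron whose dendrites form
a thin monostratified sheet (LT1 in the hemibrain):

1. PCA on the reference postsynapses gives two tangential axes (e1, e2) and
   a normal axis (e3).
2. A parabolic surface ``z_hat = a0 + a1*x + a2*y + a3*x^2 + a4*y^2 + a5*x*y``
   is least-squares fit to the reference cloud in that frame.
3. Each synapse's innervation depth is ``z - z_hat``: its signed offset along
   the normal from the fitted reference surface. This treats the layers as
   parallel offsets of one surface, which is accurate near the frame origin
   and degrades toward the neuropil rim.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import DegenerateGeometryError, InvalidArgumentError

__all__ = [
    "LayerFrame",
    "QuadricFit",
    "compute_pc_frame",
    "build_layer_frame",
    "fit_parabolic_surface",
    "quadric_surface",
    "relative_depth",
    "frame_points",
    "unframe_points",
]

#: Relative eigenvalue threshold below which a PC direction counts as collapsed.
_RANK_TOL = 1e-12


@dataclass(frozen=True)
class LayerFrame:
    """Origin, orthonormal axes and (optionally) the fitted layer surface.

    ``axes`` rows are e1 (long tangential), e2 (short tangential), e3
    (normal), forming a right-handed basis. ``coeffs`` are the quadric
    coefficients (a0..a5) in micrometres; ``r2`` the surface fit quality.
    """

    origin: np.ndarray
    axes: np.ndarray
    coeffs: np.ndarray | None = None
    r2: float | None = None
    eigenvalues: np.ndarray | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))
        object.__setattr__(self, "axes", np.asarray(self.axes, dtype=float))
        if self.coeffs is not None:
            object.__setattr__(self, "coeffs", np.asarray(self.coeffs, dtype=float))

    @classmethod
    def identity(cls, coeffs=None, r2=None) -> "LayerFrame":
        """Frame whose axes coincide with the native coordinate axes."""
        return cls(origin=np.zeros(3), axes=np.eye(3), coeffs=coeffs, r2=r2)

    def with_surface(self, coeffs, r2: float) -> "LayerFrame":
        return replace(self, coeffs=np.asarray(coeffs, dtype=float), r2=float(r2))

    def to_dict(self) -> dict:
        return {
            "origin": self.origin.tolist(),
            "axes": self.axes.tolist(),
            "coeffs": None if self.coeffs is None else self.coeffs.tolist(),
            "r2": self.r2,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LayerFrame":
        coeffs = d.get("coeffs")
        return cls(
            origin=np.asarray(d["origin"], dtype=float),
            axes=np.asarray(d["axes"], dtype=float),
            coeffs=None if coeffs is None else np.asarray(coeffs, dtype=float),
            r2=d.get("r2"),
        )

    def save(self, path: str | Path, **extra) -> None:
        payload = self.to_dict()
        payload.update(extra)
        Path(path).write_text(json.dumps(payload, indent=1) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "LayerFrame":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class QuadricFit:
    """Least-squares parabolic surface fit: coefficients, R^2, standard errors."""

    coeffs: np.ndarray
    r2: float
    stderr: np.ndarray

    def __iter__(self):  # allows ``coeffs, r2 = fit``-style unpacking
        return iter((self.coeffs, self.r2))


def _as_points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise InvalidArgumentError(f"expected an (n, 3) point array, got shape {pts.shape}")
    if not np.all(np.isfinite(pts)):
        raise InvalidArgumentError("points contain non-finite coordinates")
    return pts


def compute_pc_frame(reference_points) -> LayerFrame:
    """Principal-component frame of a reference synapse cloud.

    Axes are covariance eigenvectors in descending eigenvalue order. Signs:
    e1 and e2 are flipped so their largest-magnitude component is positive;
    e3 = e1 x e2, which makes the basis right-handed (e3 remains the third
    eigenvector up to sign).
    """
    pts = _as_points(reference_points)
    if pts.shape[0] < 3:
        raise InvalidArgumentError("need at least 3 reference points")
    origin = pts.mean(axis=0)
    centered = pts - origin
    cov = centered.T @ centered / max(pts.shape[0] - 1, 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if evals[1] <= _RANK_TOL * max(evals[0], 1.0):
        raise DegenerateGeometryError("reference cloud has rank < 2; cannot define tangential axes")
    e1, e2 = evecs[:, 0], evecs[:, 1]
    for v in (e1, e2):
        if v[np.argmax(np.abs(v))] < 0:
            v *= -1.0
    e3 = np.cross(e1, e2)
    return LayerFrame(origin=origin, axes=np.vstack([e1, e2, e3]), eigenvalues=evals)


def quadric_surface(coeffs, x, y):
    """Evaluate z_hat = a0 + a1*x + a2*y + a3*x^2 + a4*y^2 + a5*x*y."""
    a = np.asarray(coeffs, dtype=float)
    if a.shape != (6,):
        raise InvalidArgumentError("quadric coefficients must be a length-6 vector (a0..a5)")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return a[0] + a[1] * x + a[2] * y + a[3] * x**2 + a[4] * y**2 + a[5] * x * y


def _design(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones_like(x), x, y, x**2, y**2, x * y])


def fit_parabolic_surface(reference_points, frame: LayerFrame | None = None) -> QuadricFit:
    """Least-squares parabolic surface through a reference cloud.

    Points are first expressed in ``frame`` (pass ``None`` or an identity
    frame if they already are). Returns coefficients a0..a5 minimizing the
    squared normal residuals, the R^2 about the mean of z, and per-coefficient
    standard errors from the unbiased residual variance.
    """
    pts = _as_points(reference_points)
    if frame is not None:
        pts = (pts - frame.origin) @ frame.axes.T
    n = pts.shape[0]
    if n < 6:
        raise InvalidArgumentError("need at least 6 points to fit 6 quadric coefficients")
    x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
    X = _design(x, y)
    if np.linalg.matrix_rank(X) < 6:
        raise DegenerateGeometryError("rank-deficient quadric design (points lie on a degenerate locus)")
    coeffs, _, _, _ = np.linalg.lstsq(X, z, rcond=None)
    resid = z - X @ coeffs
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((z - z.mean()) ** 2))
    if ss_tot == 0.0:
        r2 = 1.0 if ss_res <= 1e-24 * max(n, 1) else 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    # standard errors: sigma^2 * diag((X'X)^-1), sigma^2 = SS_res / (n - 6)
    if n > 6:
        sigma2 = ss_res / (n - 6)
        xtx_inv = np.linalg.inv(X.T @ X)
        stderr = np.sqrt(sigma2 * np.diag(xtx_inv))
    else:
        stderr = np.full(6, np.nan)
    return QuadricFit(coeffs=coeffs, r2=r2, stderr=stderr)


def build_layer_frame(reference_points) -> LayerFrame:
    """Complete layer frame from a reference synapse cloud: PCA + surface fit.

    After the initial fit, the frame is oriented so the fitted surface's mean
    curvature is non-negative (a3 + a4 >= 0), i.e. the normal points toward
    the concave side of the layer. PCA alone fixes the normal only up to
    sign; without this convention the sign of every innervation depth would
    depend on the input's orientation, and the asymmetric depth range used
    downstream would silently drop synapses on flipped runs. The flip negates
    e2 and e3 together (preserving right-handedness) and the surface is refit.
    """
    frame = compute_pc_frame(reference_points)
    fit = fit_parabolic_surface(reference_points, frame)
    if fit.coeffs[3] + fit.coeffs[4] < 0:
        axes = frame.axes * np.array([[1.0], [-1.0], [-1.0]])
        frame = replace(frame, axes=axes)
        fit = fit_parabolic_surface(reference_points, frame)
    return frame.with_surface(fit.coeffs, fit.r2)


def relative_depth(x, y, z, coeffs):
    """Innervation depth ``z - z_hat(x, y)`` in micrometres (unclipped)."""
    return np.asarray(z, dtype=float) - quadric_surface(coeffs, x, y)


def frame_points(points, frame: LayerFrame) -> pd.DataFrame:
    """Express native points in the layer frame and annotate innervation depth.

    Returns a DataFrame with columns x, y (tangential), z (normal) and depth.
    Requires a complete frame (axes and fitted surface coefficients).
    """
    if frame.coeffs is None:
        raise InvalidArgumentError("frame has no fitted surface; run fit_parabolic_surface first")
    pts = _as_points(points)
    local = (pts - frame.origin) @ frame.axes.T
    depth = relative_depth(local[:, 0], local[:, 1], local[:, 2], frame.coeffs)
    return pd.DataFrame({"x": local[:, 0], "y": local[:, 1], "z": local[:, 2], "depth": depth})


def unframe_points(framed, frame: LayerFrame) -> np.ndarray:
    """Inverse of :func:`frame_points` (depth column, if any, is ignored)."""
    if isinstance(framed, pd.DataFrame):
        local = framed[["x", "y", "z"]].to_numpy(dtype=float)
    else:
        local = np.asarray(framed, dtype=float)
    return local @ frame.axes + frame.origin
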