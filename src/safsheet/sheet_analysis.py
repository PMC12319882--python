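"""Sheet characterisation of a selected SAF population.

A sheet is a thin layer of parallel fibre bundles along the grey/white
boundary: pooled streamline coordinates spread widely along two directions
(the fibre length and the sheet extent along the boundary) and narrowly
along the third (the thickness, normal to the cortex).  We quantify this by
the variance of the pooled point cloud along three orthonormal axes
("sizes", mm^2), fit a low-order 2D height surface over the two largest
axes, and classify the population as sheet vs bundle from the size ratios.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io_formats import Tractogram, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "SheetModel",
    "pooled_points",
    "sheet_frame",
    "sheet_sizes",
    "fit_sheet_surface",
    "classify_geometry",
]

# sign-fixing references: anterior (+y) first, then +x, then +z
_REFERENCE_DIRECTIONS = np.array([[0.0, 1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])


def pooled_points(t: Tractogram | np.ndarray) -> np.ndarray:
    """All streamline points pooled into one (N, 3) cloud."""
    if isinstance(t, Tractogram):
        return np.vstack(list(t))
    pts = np.asarray(t, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValidationError("expected an (N, 3) point cloud or a Tractogram")
    return pts


def _fix_signs(axes: np.ndarray) -> np.ndarray:
    """Orient each axis to have a positive dot with its reference direction."""
    out = axes.copy()
    for i in range(3):
        d = out[i] @ _REFERENCE_DIRECTIONS[0]
        if abs(d) < 1e-8:
            for ref in _REFERENCE_DIRECTIONS[1:]:
                d = out[i] @ ref
                if abs(d) >= 1e-8:
                    break
        if d < 0:
            out[i] = -out[i]
    return out


def sheet_frame(
    t: Tractogram | np.ndarray, anatomical_frame: np.ndarray | None = None
) -> np.ndarray:
    """Orthonormal frame (rows = axes) ordered by descending pooled variance.

    By default the principal axes of the centroid-centred pooled point cloud;
    a user-supplied anatomical frame is orthonormalised (QR) and used as-is.
    Signs are fixed toward +anterior (fallback +x, then +z).  A rank-deficient
    cloud is completed with an arbitrary orthogonal complement and flagged.
    """
    pts = pooled_points(t)
    if anatomical_frame is not None:
        frame = np.asarray(anatomical_frame, dtype=float)
        if frame.shape != (3, 3):
            raise ValidationError("anatomical frame must be 3x3 (rows = axes)")
        q, _ = np.linalg.qr(frame.T)
        return _fix_signs(q.T)
    if len(pts) < 2:
        raise ValidationError("need >= 2 points to define a frame")
    centred = pts - pts.mean(axis=0)
    cov = centred.T @ centred / len(centred)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    axes = evecs[:, order].T
    if evals[-1] < 1e-12 * max(evals[0], 1.0):
        logger.warning("rank-deficient point cloud: frame completed arbitrarily")
    return _fix_signs(axes)


def sheet_sizes(t: Tractogram | np.ndarray, frame: np.ndarray) -> np.ndarray:
    """Variance of pooled point coordinates along each frame axis (mm^2).

    Returned in descending order; the caller's frame is assumed sorted the
    same way (as produced by :func:`sheet_frame`).
    """
    frame = np.asarray(frame, dtype=float)
    if not np.allclose(frame @ frame.T, np.eye(3), atol=1e-8):
        raise ValidationError("frame is not orthonormal")
    pts = pooled_points(t)
    centred = pts - pts.mean(axis=0)
    coords = centred @ frame.T
    sizes = coords.var(axis=0)
    return np.sort(sizes)[::-1]


def _design_matrix(u: np.ndarray, v: np.ndarray, degree: int) -> np.ndarray:
    cols = [
        u**i * v**j
        for total in range(degree + 1)
        for i in range(total + 1)
        for j in [total - i]
    ]
    return np.column_stack(cols)


def fit_sheet_surface(
    t: Tractogram | np.ndarray, frame: np.ndarray, degree: int = 2
) -> tuple[dict[str, float], float, float]:
    """Least-squares height surface over the two largest sheet axes.

    The third-axis coordinate is modelled as a polynomial (default
    quadratic) in the first two axis coordinates.  Returns
    ``(coefficients, residual_sd, thickness_size)`` where ``thickness_size``
    is the raw variance along the third axis, independent of the fit.
    """
    if not 1 <= degree <= 3:
        raise ValidationError("surface degree must be 1, 2 or 3")
    pts = pooled_points(t)
    centred = pts - pts.mean(axis=0)
    coords = centred @ np.asarray(frame, dtype=float).T
    u, v, w = coords[:, 0], coords[:, 1], coords[:, 2]
    X = _design_matrix(u, v, degree)
    if len(pts) < X.shape[1] or np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValidationError(
            f"underdetermined surface fit: {len(pts)} points for {X.shape[1]} terms"
        )
    beta, *_ = np.linalg.lstsq(X, w, rcond=None)
    residual = w - X @ beta
    names = [
        f"u^{i}v^{j}" if (i or j) else "const"
        for total in range(degree + 1)
        for i in range(total + 1)
        for j in [total - i]
    ]
    coefficients = dict(zip(names, beta.tolist()))
    residual_sd = float(np.sqrt(np.mean(residual**2)))
    thickness_size = float(w.var())
    return coefficients, residual_sd, thickness_size


def classify_geometry(
    sizes: np.ndarray, ratio: float = 3.0, comparable: float = 3.0
) -> str:
    """Sheet vs bundle from sorted sizes (l1 >= l2 >= l3).

    sheet  iff l2/l3 >= ratio and l1/l2 < comparable  (two wide axes, one thin)
    bundle iff l1/l2 >= ratio and l2/l3 < comparable  (one long axis, thin
    comparable cross-section); anything else is indeterminate.
    """
    l1, l2, l3 = (float(x) for x in sizes)
    if not (l1 >= l2 >= l3 >= 0):
        raise ValidationError("sizes must be sorted descending and non-negative")

    def _ratio(a: float, b: float) -> float:
        return np.inf if b == 0 else a / b

    r12, r23 = _ratio(l1, l2), _ratio(l2, l3)
    if r23 >= ratio and r12 < comparable:
        return "sheet"
    if r12 >= ratio and r23 < comparable:
        return "bundle"
    return "indeterminate"


@dataclass
class SheetModel:
    """Fitted sheet description: frame, sizes, surface and classification."""

    frame: np.ndarray
    sizes: np.ndarray
    surface_coefficients: dict[str, float]
    residual_sd: float
    thickness_size: float
    classification: str
    degree: int = 2
    ratio_threshold: float = 3.0
    comparable_threshold: float = 3.0

    def __post_init__(self) -> None:
        self.frame = np.asarray(self.frame, dtype=float)
        self.sizes = np.asarray(self.sizes, dtype=float)
        if not np.allclose(self.frame @ self.frame.T, np.eye(3), atol=1e-8):
            raise ValidationError("frame is not orthonormal")
        if np.any(np.diff(self.sizes) > 1e-12) or np.any(self.sizes < 0):
            raise ValidationError("sizes must be sorted descending, non-negative")
        expect = classify_geometry(
            self.sizes, self.ratio_threshold, self.comparable_threshold
        )
        if self.classification != expect:
            raise ValidationError(
                f"classification {self.classification!r} inconsistent with sizes"
            )

    @classmethod
    def fit(
        cls,
        t: Tractogram | np.ndarray,
        anatomical_frame: np.ndarray | None = None,
        degree: int = 2,
        ratio: float = 3.0,
        comparable: float = 3.0,
    ) -> "SheetModel":
        frame = sheet_frame(t, anatomical_frame)
        sizes = sheet_sizes(t, frame)
        coeffs, residual_sd, thickness = fit_sheet_surface(t, frame, degree)
        return cls(
            frame=frame,
            sizes=sizes,
            surface_coefficients=coeffs,
            residual_sd=residual_sd,
            thickness_size=thickness,
            classification=classify_geometry(sizes, ratio, comparable),
            degree=degree,
            ratio_threshold=ratio,
            comparable_threshold=comparable,
        )

    def to_dict(self) -> dict:
        return {
            "frame": self.frame.tolist(),
            "sizes_mm2": self.sizes.tolist(),
            "surface_degree": self.degree,
            "surface_coefficients": self.surface_coefficients,
            "residual_sd_mm": self.residual_sd,
            "thickness_size_mm2": self.thickness_size,
            "classification": self.classification,
            "ratio_threshold": self.ratio_threshold,
            "comparable_threshold": self.comparable_threshold,
        }
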