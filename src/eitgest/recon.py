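"""Linearised time-difference EIT imaging with Tikhonov regularisation.

A gesture frame is differenced against a rest reference frame and the
element-wise conductivity change is recovered as the minimiser of
``||J ds - dv||^2 + alpha ||ds||^2``, i.e. the solution of the regularised
normal equations ``(J'J + alpha I) ds = J' dv``.  Images are for
visualisation; classification uses raw boundary voltages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from eitgest.forward import SensitivityMatrix
from eitgest.mesh import Mesh
from eitgest.protocol import MeasurementFrame


@dataclass
class ReconConfig:
    """Reconstruction settings.

    ``alpha`` is the Tikhonov regularisation weight; ``None`` selects the
    default ``alpha_scale * lambda_max(J'J)``.  ``reference_policy``
    selects how the reference frame is formed from a session
    (mean of rest frames, the first frame, or an explicit frame).
    """

    alpha: float | None = None
    alpha_scale: float = 1e-2
    reference_policy: str = "mean_of_rest_frames"

    def __post_init__(self):
        if self.alpha is not None and self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.reference_policy not in (
            "mean_of_rest_frames",
            "first_frame",
            "explicit_frame",
        ):
            raise ValueError(f"unknown reference policy {self.reference_policy!r}")


@dataclass
class ReconImage:
    """Element-wise conductivity change on a mesh."""

    delta_sigma: np.ndarray
    mesh: Mesh | None = None
    alpha: float = 0.0


def difference_voltages(frame, reference) -> np.ndarray:
    """Elementwise voltage difference ``frame - reference`` (canonical order)."""
    v = frame.voltages if isinstance(frame, MeasurementFrame) else np.asarray(frame, float)
    r = (
        reference.voltages
        if isinstance(reference, MeasurementFrame)
        else np.asarray(reference, float)
    )
    if v.shape != r.shape:
        raise ValueError(f"frame length {v.shape} != reference length {r.shape}")
    return v - r


def reference_from_frames(frames, policy: str = "mean_of_rest_frames") -> np.ndarray:
    """Build a reference voltage vector from a frame stream."""
    if policy == "first_frame":
        return frames[0].voltages.copy()
    if policy == "mean_of_rest_frames":
        rest = [f.voltages for f in frames if f.gesture_label in (None, "rest")]
        if not rest:
            raise ValueError("no rest frames available for the reference")
        return np.mean(rest, axis=0)
    raise ValueError(f"policy {policy!r} needs an explicit frame")


def default_alpha(J: np.ndarray, scale: float = 1e-2) -> float:
    """``scale`` times the largest eigenvalue of ``J'J`` (= squared 2-norm of J)."""
    return scale * np.linalg.norm(J, 2) ** 2


def tikhonov_reconstruct(
    J: SensitivityMatrix | np.ndarray,
    dv: np.ndarray,
    cfg: ReconConfig | None = None,
    mesh: Mesh | None = None,
) -> ReconImage:
    """Solve the regularised normal equations for the conductivity change.

    Never forms an explicit inverse; uses a symmetric positive-definite
    solve of ``(J'J + alpha I) ds = J' dv``.  With ``alpha = 0`` the
    system must be numerically well conditioned, otherwise an
    ill-conditioning error is raised.
    """
    cfg = cfg or ReconConfig()
    Jm = J.J if isinstance(J, SensitivityMatrix) else np.asarray(J, float)
    dv = np.asarray(dv, float)
    if dv.shape != (Jm.shape[0],):
        raise ValueError(f"dv length {dv.shape} does not match J rows {Jm.shape[0]}")
    alpha = cfg.alpha if cfg.alpha is not None else default_alpha(Jm, cfg.alpha_scale)
    A = Jm.T @ Jm
    if alpha == 0.0:
        cond = np.linalg.cond(A)
        if not np.isfinite(cond) or cond > 1e12:
            raise np.linalg.LinAlgError(
                f"J'J is ill-conditioned (cond={cond:.3g}); use alpha > 0"
            )
    A[np.diag_indices_from(A)] += alpha
    b = Jm.T @ dv
    ds = scipy.linalg.solve(A, b, assume_a="pos")
    return ReconImage(delta_sigma=ds, mesh=mesh, alpha=alpha)


def rasterize(image: ReconImage, n_pixels: int = 64) -> np.ndarray:
    """Nearest-element rasterisation of an image onto a square pixel grid.

    Pixels outside the disk are NaN.  Plotting plumbing only.
    """
    if image.mesh is None:
        raise ValueError("image carries no mesh")
    xs = np.linspace(-1, 1, n_pixels)
    X, Y = np.meshgrid(xs, xs)
    pts = np.column_stack([X.ravel(), Y.ravel()])
    cent = image.mesh.element_centroids()
    from scipy.spatial import cKDTree

    _, idx = cKDTree(cent).query(pts)
    img = image.delta_sigma[idx].astype(float)
    img[np.hypot(pts[:, 0], pts[:, 1]) > 1] = np.nan
    return img.reshape(n_pixels, n_pixels)
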