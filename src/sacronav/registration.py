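"""Paired-point similarity registration (absolute orientation).

The matching step of the navigation workflow: given the planned model's
landmark coordinates and the same landmarks probed on the patient, estimate
the similarity transform (rotation + translation + optional isotropic scale)
that minimises the sum of squared landmark residuals. The closed-form
solution uses the SVD of the landmark cross-covariance (Horn / Umeyama);
reflections are rejected by the standard determinant sign correction, so the
returned rotation is always proper.

The estimator follows the scikit-learn transformer protocol so it composes
with pipelines and model selection; :func:`fit_similarity` is the thin
landmark-level wrapper used by the rest of the package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .geometry import DegenerateGeometryError, LandmarkSet, SimilarityTransform

__all__ = [
    "SimilarityRegistration",
    "RegistrationResult",
    "fit_similarity",
    "target_registration_error",
]

#: Fitted scales outside this band are flagged as implausible: a probed
#: patient should not differ from their own CT model by more than 2x.
SCALE_PLAUSIBILITY_BAND = (0.5, 2.0)


@dataclass(frozen=True)
class RegistrationResult:
    """Outcome of a landmark registration.

    Attributes
    ----------
    transform : SimilarityTransform
        Maps model space into patient (probed) space.
    fre_rms : float
        Fiducial registration error: RMS of the landmark residuals, mm.
    per_landmark_residuals : numpy.ndarray
        Residual distance per landmark, in input order, mm.
    scale_warning : bool
        True if the fitted scale fell outside the plausibility band.
    """

    transform: SimilarityTransform
    fre_rms: float
    per_landmark_residuals: np.ndarray
    scale_warning: bool = False

    def to_dict(self) -> dict:
        d = self.transform.to_dict()
        d["fre_rms"] = float(self.fre_rms)
        return d


class SimilarityRegistration(BaseEstimator, TransformerMixin):
    """Least-squares similarity registration of paired 3-D points.

    ``fit(X, y)`` estimates the similarity transform minimising
    ``sum_i || s R x_i + t - y_i ||^2`` over paired points ``x_i`` (model)
    and ``y_i`` (probed); ``transform`` then maps model-space points into
    probed space.

    Parameters
    ----------
    allow_scale : bool, default True
        Estimate an isotropic scale; if False a rigid (scale = 1) fit is
        performed. The navigation workflow resizes the model to the patient,
        so scale is on by default.
    scale_band : tuple of float
        Plausibility band for the fitted scale; a fit outside it sets
        ``scale_warning_`` (the transform is still returned).

    Attributes
    ----------
    rotation_ : ndarray of shape (3, 3)
        Proper rotation matrix (det = +1, never a reflection).
    translation_ : ndarray of shape (3,)
    scale_ : float
    transform_ : SimilarityTransform
    fre_rms_ : float
        RMS landmark residual (fiducial registration error), mm.
    residuals_ : ndarray of shape (n,)
        Per-point residual distances, mm.
    scale_warning_ : bool
    """

    def __init__(self, allow_scale: bool = True, scale_band=SCALE_PLAUSIBILITY_BAND):
        self.allow_scale = allow_scale
        self.scale_band = scale_band

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[1] != 3:
            raise ValueError(f"X must have shape (n, 3), got {X.shape}")
        if y.shape != X.shape:
            raise ValueError(f"X and y must have matching shapes, got {X.shape} vs {y.shape}")
        n = X.shape[0]
        if n < 3:
            raise ValueError("at least 3 point pairs are required")

        mx = X.mean(axis=0)
        my = y.mean(axis=0)
        Xc = X - mx
        Yc = y - my
        if np.linalg.matrix_rank(Xc, tol=1e-9 * max(1.0, np.abs(Xc).max())) < 2:
            raise DegenerateGeometryError("model points are collinear; orientation unresolvable")

        # Cross-covariance; SVD gives the optimal rotation, with the sign of
        # the smallest singular vector flipped if a reflection would win.
        C = Yc.T @ Xc / n
        U, D, Vt = np.linalg.svd(C)
        sgn = np.ones(3)
        if np.linalg.det(U @ Vt) < 0:
            sgn[-1] = -1.0
        R = U @ np.diag(sgn) @ Vt

        var_x = float(np.einsum("ij,ij->", Xc, Xc)) / n
        if self.allow_scale:
            # Least-squares optimal isotropic scale (Umeyama).
            s = float(np.dot(D, sgn)) / var_x
            if s <= 0:
                raise DegenerateGeometryError("degenerate configuration: non-positive scale")
        else:
            s = 1.0
        t = my - s * R @ mx

        self.rotation_ = R
        self.translation_ = t
        self.scale_ = s
        self.transform_ = SimilarityTransform(R, t, s)
        resid = self.transform_.apply(X) - y
        self.residuals_ = np.linalg.norm(resid, axis=1)
        self.fre_rms_ = float(np.sqrt(np.mean(self.residuals_**2)))
        lo, hi = self.scale_band
        self.scale_warning_ = not (lo <= s <= hi)
        return self

    def transform(self, X):
        """Map model-space points into probed space."""
        return self.transform_.apply(np.asarray(X, dtype=float))

    def inverse_transform(self, X):
        return self.transform_.inverse().apply(np.asarray(X, dtype=float))


def fit_similarity(
    model: LandmarkSet, probed: LandmarkSet, allow_scale: bool = True
) -> RegistrationResult:
    """Register the model landmarks onto the probed landmarks.

    Correspondence is given by the landmark labels. Returns the transform
    mapping model space to probed (patient) space together with the fiducial
    registration error.
    """
    est = SimilarityRegistration(allow_scale=allow_scale)
    est.fit(model.as_array(), probed.as_array())
    return RegistrationResult(
        transform=est.transform_,
        fre_rms=est.fre_rms_,
        per_landmark_residuals=est.residuals_,
        scale_warning=est.scale_warning_,
    )


def target_registration_error(
    est: SimilarityTransform, truth: SimilarityTransform, targets
) -> np.ndarray:
    """Displacement ``||est(p) - truth(p)||`` at each target point, mm.

    Quantifies how a registration error moves points of surgical interest
    (screw entries, aim points) rather than the fiducials themselves.
    """
    pts = np.atleast_2d(np.asarray(targets, dtype=float))
    if pts.size == 0:
        raise ValueError("targets must be non-empty")
    return np.linalg.norm(est.apply(pts) - truth.apply(pts), axis=1)
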