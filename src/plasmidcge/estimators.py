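"""scikit-learn-style estimators over the lane-matrix core of the pipeline.

Lanes sharing one migration-time grid form a plain ``(n_lanes, n_times)``
matrix, so the central processing chain — baseline correction, window
integration, fraction normalization — is exposed as transformers that compose
in an :class:`sklearn.pipeline.Pipeline`, alongside a curve-fit estimator for
Gaussian band deconvolution and a regressor-shaped ladder size calibrator.
All of them delegate to the module functions in :mod:`plasmidcge.preprocess`
and :mod:`plasmidcge.quantify`.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from . import preprocess, quantify
from .errors import ValidationError
from .quantify import DEFAULT_WINDOWS, DyeCorrection, GaussianPeak, IsoformWindows
from .trace_io import LadderSpec, Trace


def _as_lane_matrix(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValidationError(f"expected a 2-D (n_lanes, n_times) matrix, got shape {X.shape}")
    if not np.all(np.isfinite(X)):
        raise ValidationError("lane matrix contains non-finite values")
    return X


def _row_trace(time: np.ndarray, row: np.ndarray, lane_id: str) -> Trace:
    return Trace(lane_id=lane_id, role="sample", time=time, signal=row)


class BaselineCorrector(TransformerMixin, BaseEstimator):
    """Per-lane linear background subtraction for a lane matrix.

    Parameters
    ----------
    time : array-like or None
        Shared migration-time grid (seconds); sample indices when None.
    exclusion_windows : sequence of (start, end)
        Intervals excluded from the baseline fit (the isoform windows).

    Fitted attributes
    -----------------
    baselines_ : ndarray of shape (n_lanes, 2)
        Per-lane (intercept, slope).
    """

    def __init__(self, time=None, exclusion_windows: Sequence = ()):
        self.time = time
        self.exclusion_windows = exclusion_windows

    def _grid(self, n: int) -> np.ndarray:
        return np.arange(n, dtype=float) if self.time is None else np.asarray(self.time, float)

    def fit(self, X, y=None):
        X = _as_lane_matrix(X)
        t = self._grid(X.shape[1])
        models = [
            preprocess.fit_linear_baseline(
                _row_trace(t, row, f"lane{i}"), self.exclusion_windows
            )
            for i, row in enumerate(X)
        ]
        self.baselines_ = np.array([[m.intercept, m.slope] for m in models])
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "baselines_")
        X = _as_lane_matrix(X)
        if X.shape != (len(self.baselines_), self.n_features_in_):
            raise ValidationError("transform input shape differs from the fitted matrix")
        t = self._grid(X.shape[1])
        return X - (self.baselines_[:, [0]] + self.baselines_[:, [1]] * t[None, :])

    def fit_transform(self, X, y=None, **kw):
        return self.fit(X, y).transform(X)


class IsoformQuantifier(TransformerMixin, BaseEstimator):
    """Window integration + fraction normalization, one fraction triple per lane.

    ``transform`` maps a background-corrected ``(n_lanes, n_times)`` matrix to
    an ``(n_lanes, 3)`` array of (f_lin, f_sc, f_oc).  Raw integrals of the
    last transform are kept in ``integrals_``.
    """

    def __init__(
        self,
        time=None,
        windows: Optional[IsoformWindows] = None,
        correction: Optional[DyeCorrection] = None,
    ):
        self.time = time
        self.windows = windows
        self.correction = correction

    def fit(self, X, y=None):
        X = _as_lane_matrix(X)
        self.windows_ = self.windows or DEFAULT_WINDOWS
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "windows_")
        X = _as_lane_matrix(X)
        t = np.arange(X.shape[1], dtype=float) if self.time is None else np.asarray(self.time, float)
        fractions, integrals = [], []
        for i, row in enumerate(X):
            ints, fr = quantify.quantify_trace(
                _row_trace(t, row, f"lane{i}"), self.windows_, self.correction
            )
            integrals.append(ints)
            fractions.append(fr.as_tuple())
        self.integrals_ = integrals
        return np.asarray(fractions)


class MultipeakGaussianFitter(RegressorMixin, BaseEstimator):
    """Curve-fit estimator for Gaussian band deconvolution of one profile.

    ``fit(x, y)`` runs bounded nonlinear least squares from ``init`` peaks;
    ``predict(x)`` evaluates the fitted band model.
    """

    def __init__(self, init: Sequence[GaussianPeak] = (), max_iter: int = 2000):
        self.init = init
        self.max_iter = max_iter

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).ravel()
        fit = quantify.fit_multipeak(
            _row_trace(x, np.asarray(y, float), "profile"), list(self.init), self.max_iter
        )
        self.peaks_ = fit.peaks
        self.converged_ = fit.converged
        self.residual_rms_ = fit.residual_rms
        self.fit_ = fit
        return self

    def predict(self, X):
        check_is_fitted(self, "peaks_")
        return self.fit_.evaluate(np.asarray(X, dtype=float).ravel())


class SizeCalibrator(RegressorMixin, BaseEstimator):
    """Ladder-based apparent-size calibration, log-linear in fragment size.

    ``fit(times, sizes_bp)`` stores the knots; ``predict(t)`` returns apparent
    sizes in bp.  ``fit_ladder(trace, spec)`` builds the knots by peak
    detection on a ladder lane instead.
    """

    def fit(self, X, y):
        times = np.asarray(X, dtype=float).ravel()
        self.size_map_ = quantify.SizeMap(times=times, sizes_bp=np.asarray(y, float))
        return self

    def fit_ladder(self, ladder_trace: Trace, spec: LadderSpec):
        self.size_map_ = quantify.calibrate_size(ladder_trace, spec)
        return self

    def predict(self, X):
        check_is_fitted(self, "size_map_")
        return np.asarray(quantify.apparent_size(self.size_map_, np.asarray(X, float).ravel()))
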