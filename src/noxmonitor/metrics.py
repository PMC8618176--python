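"""Goodness-of-fit metrics used throughout calibration and validation.

``r_squared`` is the squared Pearson correlation between observed and
predicted values.  Note this is not ``1 - SS_res/SS_tot``: it is invariant
under any affine transform of the predictions, so a model that is perfectly
anticorrelated with the observations also scores 1.  Model selection in
this package therefore uses RMSE, with R-squared reported as a descriptive
statistic.
"""

from __future__ import annotations

import warnings

import numpy as np


def r_squared(observed, predicted) -> float:
    """Squared Pearson correlation of two equal-length vectors.

    Returns NaN (with a warning) when either vector is constant, where the
    correlation is undefined.
    """
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if o.shape != p.shape or o.ndim != 1:
        raise ValueError("observed and predicted must be equal-length 1-D vectors")
    if o.size < 2:
        raise ValueError("need at least two points")
    so = o - o.mean()
    sp = p - p.mean()
    denom = np.sqrt((so**2).sum() * (sp**2).sum())
    if denom == 0.0:
        warnings.warn(
            "r_squared undefined for a constant vector; returning NaN", RuntimeWarning
        )
        return float("nan")
    r = float((so * sp).sum() / denom)
    return r * r


def rmse(observed, predicted) -> float:
    """Root mean squared error ``sqrt(mean((P - O)^2))``."""
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if o.shape != p.shape or o.ndim != 1:
        raise ValueError("observed and predicted must be equal-length 1-D vectors")
    if o.size == 0:
        raise ValueError("need at least one point")
    return float(np.sqrt(np.mean((p - o) ** 2)))
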