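"""Disorder-pathogenicity correlation via an exponential-decay fit.

Per-residue mean pathogenicity is smoothed with a moving mean (default
window 10), paired with the unsmoothed mean disorder profile, and the
relationship y = a*exp(-b*x) + c is fitted by least squares.  Goodness of
fit is the plain coefficient of determination
R^2 = 1 - SS_res / SS_tot, with no degrees-of-freedom correction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .datatypes import PerResidueTrack
from .pathogenicity import classify_score

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 10


@dataclass(frozen=True)
class FitResult:
    a: float            # amplitude, score units
    b: float            # decay rate per unit disorder, >= 0
    c: float            # offset, score units
    r_squared: float
    n: int              # residue pairs used
    converged: bool

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.a * np.exp(-self.b * np.asarray(x, dtype=float)) + self.c


def moving_mean(track: PerResidueTrack, window: int = DEFAULT_WINDOW
                ) -> PerResidueTrack:
    """Centred moving mean, truncated at the ends.

    The window at position i covers offsets -ceil(w/2)+1 .. +floor(w/2)
    (for w=10: -4..+5), clipped to the track; missing values are excluded
    from each window's mean.
    """
    n = len(track)
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > n:
        raise ValueError(f"window {window} larger than track length {n}")
    lo_off = -((window + 1) // 2 - 1)
    hi_off = window // 2
    out = np.full(n, np.nan)
    values = track.values
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for i in range(n):
            lo = max(0, i + lo_off)
            hi = min(n, i + hi_off + 1)
            out[i] = np.nanmean(values[lo:hi])
    return PerResidueTrack(track.protein_id, f"{track.name}_smoothed", out)


def r_squared(y_obs: np.ndarray, y_hat: np.ndarray) -> float:
    """1 - SS_res/SS_tot (coefficient of determination)."""
    y_obs = np.asarray(y_obs, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y_obs.shape != y_hat.shape or y_obs.size < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    ss_tot = float(np.sum((y_obs - y_obs.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("zero total variance in observations")
    ss_res = float(np.sum((y_obs - y_hat) ** 2))
    return 1.0 - ss_res / ss_tot


def fit_exponential_decay(x: PerResidueTrack | np.ndarray,
                          y: PerResidueTrack | np.ndarray,
                          with_offset: bool = True) -> FitResult:
    """Least-squares fit of y = a*exp(-b*x) + c with b >= 0.

    Initialisation is deterministic (a0 = max(y)-min(y), b0 = 1,
    c0 = min(y)); identical inputs give identical results.  A constant y
    degenerates to (a=0, b=0, c=y) with R^2 = 0 and a warning.  With
    ``with_offset=False`` the two-parameter form (c = 0) is fitted.
    """
    xv = x.values if isinstance(x, PerResidueTrack) else np.asarray(x, float)
    yv = y.values if isinstance(y, PerResidueTrack) else np.asarray(y, float)
    if xv.shape != yv.shape:
        raise ValueError("x and y must have equal length")
    keep = ~(np.isnan(xv) | np.isnan(yv))
    xv, yv = xv[keep], yv[keep]
    n = int(xv.size)
    if n < 3:
        raise ValueError("need at least 3 paired non-missing values")

    # treat a numerically constant response (e.g. a smoothed constant
    # track, which carries ~1e-17 rounding wobble) as degenerate
    if np.ptp(yv) <= 1e-12 * max(1.0, float(np.abs(yv).max())):
        logger.warning("constant response: degenerate fit a=0, b=0")
        return FitResult(0.0, 0.0, float(yv.mean()), 0.0, n, True)

    if with_offset:
        x0 = np.array([float(yv.max() - yv.min()), 1.0, float(yv.min())])
        lower = np.array([-np.inf, 0.0, -np.inf])
        upper = np.array([np.inf, np.inf, np.inf])

        def residuals(p):
            return p[0] * np.exp(-p[1] * xv) + p[2] - yv
    else:
        x0 = np.array([float(yv.max() - yv.min()), 1.0])
        lower = np.array([-np.inf, 0.0])
        upper = np.array([np.inf, np.inf])

        def residuals(p):
            return p[0] * np.exp(-p[1] * xv) - yv

    res = least_squares(residuals, x0, bounds=(lower, upper), method="trf",
                        xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=10000)
    if with_offset:
        a, b, c = (float(v) for v in res.x)
    else:
        a, b = (float(v) for v in res.x)
        c = 0.0
    y_hat = a * np.exp(-b * xv) + c
    return FitResult(a, b, c, r_squared(yv, y_hat), n, bool(res.status > 0))


def correlate_disorder_pathogenicity(mdp: PerResidueTrack,
                                     path_mean: PerResidueTrack,
                                     window: int = DEFAULT_WINDOW,
                                     smooth_x: bool = False
                                     ) -> tuple[FitResult, pd.DataFrame]:
    """Headline analysis: smoothed mean pathogenicity vs raw disorder.

    The pathogenicity track is smoothed (moving mean, default window 10);
    the mean disorder profile enters unsmoothed unless ``smooth_x`` is
    set for sensitivity analysis.  Returns the exponential-decay fit and
    the paired per-residue table (with each residue's pathogenicity class
    from the fixed cutoffs, for plotting).
    """
    if len(mdp) != len(path_mean):
        raise ValueError("tracks must have equal length")
    y = moving_mean(path_mean, window) if window > 1 else path_mean
    x = moving_mean(mdp, window) if smooth_x and window > 1 else mdp
    fit = fit_exponential_decay(x, y)
    classes = [classify_score(v) if not np.isnan(v) else None
               for v in path_mean.values]
    paired = pd.DataFrame({
        "res_index": np.arange(1, len(mdp) + 1),
        "mdp": x.values,
        "path_mean": path_mean.values,
        "path_smoothed": y.values,
        "class": classes,
    })
    return fit, paired
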