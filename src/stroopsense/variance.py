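"""Robust per-feature dispersion statistics and low-variance filtering.

Two scale-relative dispersion measures are computed per feature:

* rMAD — median absolute deviation around the median, divided by the
  magnitude of the median:  med(|f - med(f)|) / |med(f)|;
* rIQR — interquartile range divided by the magnitude of the lower
  quartile:  |p75 - p25| / |p25|, switching the denominator to p75 when
  p25 is zero.

Both are robust to outliers (breakdown through the median / quartiles) and
dimensionless, so a single pair of lower-bound thresholds can be applied
across features of different units.  Features whose natural denominator is
zero fall back to the unnormalized numerator and carry a degenerate flag.
Percentiles use linear interpolation between order statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import AllDiscardedError, InvalidParameterError

__all__ = ["VarianceStats", "FeatureMask", "rmad", "riqr", "apply_variance_thresholds"]


def _as_vector(values) -> np.ndarray:
    v = np.asarray(values, float).ravel()
    if v.size == 0:
        raise ValueError("empty input")
    return v


def rmad(values) -> float:
    """Relative median absolute deviation med(|f - med(f)|) / |med(f)|.

    A zero median makes the ratio undefined; the unnormalized MAD is
    returned in that case (see :func:`rmad_flagged` for the flag).
    """
    return rmad_flagged(values)[0]


def rmad_flagged(values) -> tuple[float, bool]:
    """rMAD plus a flag marking the degenerate zero-median fallback."""
    v = _as_vector(values)
    med = np.median(v)
    mad = float(np.median(np.abs(v - med)))
    if med == 0:
        return mad, True
    return mad / abs(med), False


def riqr(values) -> float:
    """Relative interquartile range |p75 - p25| / |p25|.

    When p25 is zero the denominator switches to p75; if both quartiles
    are zero the statistic is 0.
    """
    return riqr_flagged(values)[0]


def riqr_flagged(values) -> tuple[float, bool]:
    """rIQR plus a flag marking the degenerate both-quartiles-zero case."""
    v = _as_vector(values)
    p25, p75 = np.percentile(v, [25, 75], method="linear")
    iqr = abs(p75 - p25)
    if p25 != 0:
        return iqr / abs(p25), False
    if p75 != 0:
        return iqr / abs(p75), False
    return 0.0, True  # both quartiles zero


@dataclass
class VarianceStats:
    """Per-feature rMAD / rIQR values with degenerate-denominator flags."""

    feature_names: list[str]
    rmad: np.ndarray
    riqr: np.ndarray
    rmad_degenerate: np.ndarray  # bool: zero-median fallback used
    riqr_degenerate: np.ndarray  # bool: both quartiles zero


@dataclass
class FeatureMask:
    """Boolean retention mask under lower-bound thresholds on rMAD and rIQR."""

    mask: np.ndarray
    theta_rmad: float
    theta_riqr: float
    stats: VarianceStats

    @property
    def retained(self) -> list[str]:
        return [f for f, keep in zip(self.stats.feature_names, self.mask) if keep]


def compute_variance_stats(matrix, feature_names: list[str] | None = None) -> VarianceStats:
    """rMAD and rIQR for every column of a (rows, features) matrix."""
    m = np.asarray(matrix, float)
    if m.ndim != 2 or m.size == 0:
        raise ValueError("expected a non-empty 2-D matrix")
    names = feature_names or [f"f{j}" for j in range(m.shape[1])]
    rm, rmf = zip(*(rmad_flagged(m[:, j]) for j in range(m.shape[1])))
    ri, rif = zip(*(riqr_flagged(m[:, j]) for j in range(m.shape[1])))
    return VarianceStats(
        feature_names=list(names),
        rmad=np.array(rm),
        riqr=np.array(ri),
        rmad_degenerate=np.array(rmf, bool),
        riqr_degenerate=np.array(rif, bool),
    )


def apply_variance_thresholds(
    matrix,
    theta_rmad: float = 0.0,
    theta_riqr: float = 0.0,
    feature_names: list[str] | None = None,
) -> FeatureMask:
    """Retain features with rMAD >= theta_rmad AND rIQR >= theta_riqr.

    Statistics are computed on the rows provided — during cross-validation
    that means training rows only, so no test information leaks into the
    selection.  Raises if the mask would retain zero features.
    """
    if theta_rmad < 0 or theta_riqr < 0:
        raise InvalidParameterError("thresholds must be non-negative")
    stats = compute_variance_stats(matrix, feature_names)
    mask = (stats.rmad >= theta_rmad) & (stats.riqr >= theta_riqr)
    if not mask.any():
        raise AllDiscardedError(
            f"thresholds ({theta_rmad}, {theta_riqr}) would discard every feature"
        )
    return FeatureMask(mask=mask, theta_rmad=theta_rmad, theta_riqr=theta_riqr, stats=stats)
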