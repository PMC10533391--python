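"""Great-circle geometry, spatial autocorrelation, and buffered cross-validation.

Forest plots are point observations on a sphere; residual spatial structure
is summarized by Moran's I correlograms, absorbed into regressions through a
residual autocovariate (RAC: the inverse-distance-weighted mean of the
neighbouring residuals inside a buffer, 250 km by default), and accounted
for in accuracy assessment by spatially buffered leave-one-out
cross-validation, which withholds the focal point *and* every training
point inside its buffer before predicting it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .errors import InvalidArgumentError, UndefinedStatisticError
from .rng import stream

__all__ = [
    "EARTH_RADIUS_KM",
    "haversine_km",
    "pairwise_haversine_km",
    "SpatialIndex",
    "neighbors_within",
    "morans_i",
    "correlogram",
    "residual_autocovariate",
    "buffered_loocv",
    "CVResult",
    "auc",
    "vecv",
]

EARTH_RADIUS_KM = 6371.0


def _check_coords(lat, lon) -> None:
    lat, lon = np.asarray(lat, float), np.asarray(lon, float)
    if np.any(np.abs(lat) > 90) or np.any(np.abs(lon) > 180):
        raise InvalidArgumentError("coordinates outside [-90,90] x [-180,180]")


def haversine_km(p1, p2) -> float:
    """Great-circle distance between two (lat, lon) points in km."""
    _check_coords(*p1)
    _check_coords(*p2)
    lat1, lon1, lat2, lon2 = map(np.radians, (*p1, *p2))
    a = (
        np.sin((lat2 - lat1) / 2) ** 2
        + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2) ** 2
    )
    return float(2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1))))


def pairwise_haversine_km(lat, lon, lat2=None, lon2=None) -> np.ndarray:
    """Matrix of great-circle distances between two point sets (km)."""
    _check_coords(lat, lon)
    la1 = np.radians(np.asarray(lat, float))[:, None]
    lo1 = np.radians(np.asarray(lon, float))[:, None]
    if lat2 is None:
        la2, lo2 = la1.T, lo1.T
    else:
        _check_coords(lat2, lon2)
        la2 = np.radians(np.asarray(lat2, float))[None, :]
        lo2 = np.radians(np.asarray(lon2, float))[None, :]
    a = (
        np.sin((la2 - la1) / 2) ** 2
        + np.cos(la1) * np.cos(la2) * np.sin((lo2 - lo1) / 2) ** 2
    )
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


class SpatialIndex:
    """Pairwise great-circle geometry over a fixed set of plot coordinates."""

    def __init__(self, lat, lon):
        _check_coords(lat, lon)
        self.lat = np.asarray(lat, dtype=float)
        self.lon = np.asarray(lon, dtype=float)
        if self.lat.shape != self.lon.shape or self.lat.ndim != 1:
            raise InvalidArgumentError("lat/lon must be equal-length 1-d arrays")
        self._dist: np.ndarray | None = None

    def __len__(self) -> int:
        return self.lat.size

    @property
    def distances(self) -> np.ndarray:
        if self._dist is None:
            self._dist = pairwise_haversine_km(self.lat, self.lon)
        return self._dist

    def neighbor_mask(self, radius_km: float) -> np.ndarray:
        """Boolean matrix: within radius, self excluded."""
        mask = self.distances <= radius_km
        np.fill_diagonal(mask, False)
        return mask


def neighbors_within(index: SpatialIndex, radius_km: float):
    """Per-point neighbour ids and distances within ``radius_km``."""
    mask = index.neighbor_mask(radius_km)
    d = index.distances
    return [
        (np.flatnonzero(row), d[i, row])
        for i, row in enumerate(mask)
    ]


# --------------------------------------------------------------------------
# Moran's I
# --------------------------------------------------------------------------

def _weights(index: SpatialIndex, radius_km: float, min_dist_km: float = 1e-3):
    mask = index.neighbor_mask(radius_km)
    if not mask.any():
        raise UndefinedStatisticError("no point has a neighbour within the radius")
    w = np.where(mask, 1.0 / np.maximum(index.distances, min_dist_km), 0.0)
    return w


def morans_i(
    values,
    index: SpatialIndex,
    radius_km: float = 250.0,
    n_permutations: int = 199,
    seed: int = 0,
) -> tuple[float, float]:
    """Moran's I with inverse-distance weights plus a permutation p-value.

    The p-value is one-sided for positive autocorrelation: the proportion
    of permuted statistics >= the observed one, with the observed
    configuration counted once.
    """
    x = np.asarray(values, dtype=float)
    if x.size != len(index):
        raise InvalidArgumentError("values not aligned with the spatial index")
    if np.ptp(x) == 0:
        raise UndefinedStatisticError("Moran's I undefined for constant values")
    w = _weights(index, radius_km)

    def stat(z):
        zc = z - z.mean()
        num = zc @ w @ zc
        return (z.size / w.sum()) * num / (zc @ zc)

    observed = float(stat(x))
    if n_permutations <= 0:
        return observed, np.nan
    rng = stream(seed, "morans-i-permutation")
    count = 1
    for _ in range(n_permutations):
        if stat(rng.permutation(x)) >= observed:
            count += 1
    return observed, count / (n_permutations + 1)


def correlogram(
    values,
    index: SpatialIndex,
    bin_width_km: float = 25.0,
    max_km: float = 1000.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Moran's I per distance ring: [0, w), [w, 2w) ... up to ``max_km``."""
    x = np.asarray(values, dtype=float)
    if np.ptp(x) == 0:
        raise UndefinedStatisticError("correlogram undefined for constant values")
    d = index.distances
    xc = x - x.mean()
    denom = xc @ xc
    edges = np.arange(0.0, max_km + bin_width_km, bin_width_km)
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        mask = (d >= lo) & (d < hi)
        np.fill_diagonal(mask, False)
        n_pairs = int(mask.sum())
        if n_pairs == 0 or denom == 0:
            i_val = np.nan
        else:
            i_val = (x.size / n_pairs) * (xc @ (mask * 1.0) @ xc) / denom
        rows.append({"bin_lo_km": lo, "bin_hi_km": hi, "n_pairs": n_pairs,
                     "morans_i": i_val})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# residual autocovariate
# --------------------------------------------------------------------------

def residual_autocovariate(
    residuals,
    index: SpatialIndex,
    radius_km: float = 250.0,
    min_dist_km: float = 1e-3,
    normalize: bool = True,
) -> np.ndarray:
    """Inverse-distance-weighted neighbour residual for every point.

    ``RAC_i = sum_j w_ij r_j / sum_j w_ij`` over neighbours ``j`` within the
    radius, ``w_ij = 1/d_ij`` (distances floored at ``min_dist_km`` so
    coincident plots do not produce infinite weights).  Isolated points get
    0.  With ``normalize=False`` the raw weighted sum is returned.
    """
    r = np.asarray(residuals, dtype=float)
    if r.size != len(index):
        raise InvalidArgumentError("residuals not aligned with the spatial index")
    mask = index.neighbor_mask(radius_km)
    w = np.where(mask, 1.0 / np.maximum(index.distances, min_dist_km), 0.0)
    num = w @ r
    if not normalize:
        return num
    denom = w.sum(axis=1)
    out = np.zeros_like(num)
    has = denom > 0
    out[has] = num[has] / denom[has]
    return out


# --------------------------------------------------------------------------
# accuracy metrics
# --------------------------------------------------------------------------

def auc(labels, scores) -> float:
    """Rank-based (Mann-Whitney) ROC AUC; ties receive half credit."""
    y = np.asarray(labels)
    if np.unique(y).size < 2:
        raise UndefinedStatisticError("AUC needs both classes present")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def vecv(observed, predicted) -> float:
    """Variance explained by cross-validation against the 1:1 line.

    ``1 - sum((o-p)^2) / sum((o-mean(o))^2)``; unlike a correlation-based
    R^2 this penalizes bias and can be negative.
    """
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if o.size < 2 or np.ptp(o) == 0:
        raise UndefinedStatisticError("VEcv needs >=2 observations with variance")
    return float(1.0 - np.sum((o - p) ** 2) / np.sum((o - o.mean()) ** 2))


# --------------------------------------------------------------------------
# spatially buffered LOO-CV
# --------------------------------------------------------------------------

@dataclass
class CVResult:
    buffer_km: float
    n_repeats: int
    metric_name: str
    metric: float
    predictions: pd.DataFrame
    skipped: list[int] = field(default_factory=list)


def buffered_loocv(
    model_factory: Callable[[pd.DataFrame, pd.DataFrame], np.ndarray | float],
    data: pd.DataFrame,
    index: SpatialIndex,
    response: str,
    buffer_km: float = 250.0,
    n_repeats: int = 500,
    seed: int = 0,
    binary: bool = False,
) -> CVResult:
    """Spatially buffered leave-one-out cross-validation.

    Each repeat withholds one focal observation (sampled uniformly without
    replacement), drops every other observation within ``buffer_km`` of it,
    fits ``model_factory(train, test)`` on the remainder and records the
    prediction for the focal point.  The summary metric — AUC for binary
    outcomes, VEcv otherwise — is computed on the pooled out-of-fit
    predictions.  ``buffer_km=0`` with ``n_repeats=len(data)`` reduces to
    classical LOO.  Repeats whose training set would be empty are skipped
    and reported.
    """
    n = len(data)
    if n_repeats > n:
        raise InvalidArgumentError("n_repeats cannot exceed the number of observations")
    if len(index) != n:
        raise InvalidArgumentError("data not aligned with the spatial index")
    rng = stream(seed, "buffered-loocv-focal")
    focal_ids = rng.choice(n, size=n_repeats, replace=False)
    d = index.distances
    rows, skipped = [], []
    for focal in focal_ids:
        keep = d[focal] > buffer_km
        keep[focal] = False
        if not keep.any():
            skipped.append(int(focal))
            continue
        train = data.iloc[np.flatnonzero(keep)]
        test = data.iloc[[focal]]
        pred = float(np.asarray(model_factory(train, test)).ravel()[0])
        rows.append({"focal": int(focal), "observed": float(test[response].iloc[0]),
                     "predicted": pred})
    if not rows:
        raise UndefinedStatisticError(
            "every cross-validation repeat was skipped (buffer too large)"
        )
    preds = pd.DataFrame(rows)
    if binary:
        name, value = "auc", auc(preds["observed"], preds["predicted"])
    else:
        name, value = "vecv", vecv(preds["observed"], preds["predicted"])
    return CVResult(
        buffer_km=buffer_km,
        n_repeats=n_repeats,
        metric_name=name,
        metric=value,
        predictions=preds,
        skipped=skipped,
    )
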