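"""Convert event-level cytometry tables into per-condition percentage readouts.

The cytochrome-C channel is gated with a one-dimensional two-component
Gaussian-mixture threshold fitted on a bimodal calibration control (pooled
untreated cells with and without a PUMA-BH3 challenge, so both the retained and
the released mode are represented). Released cells are the *dim* population.
The optional membrane-potential / viability-dye channels are gated into the
standard four quadrants with negative-control tail thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm
from sklearn.mixture import GaussianMixture

from .errors import (
    ChannelAbsentError,
    InsufficientDataError,
    InvalidParameterError,
    UndefinedMeasurementError,
)
from .simulate import EventTable

MIN_THRESHOLD_EVENTS = 200
#: mixture weight below which the fit is considered degenerate and the
#: threshold falls back to the midpoint of the component means
DEGENERATE_WEIGHT = 0.02


@dataclass(frozen=True)
class ThresholdFit:
    """Release-gate threshold on the cytochrome-C channel (arbitrary units)."""

    threshold: float            # a.u., linear scale
    log10_means: tuple[float, float]   # sorted component means, log10 a.u.
    log10_sds: tuple[float, float]
    weights: tuple[float, float]
    fallback: bool              # midpoint fallback used (degenerate weights)

    def __float__(self) -> float:
        return self.threshold


@dataclass(frozen=True)
class ReleaseMeasurement:
    condition_id: str
    replicate: int
    fraction_released: float
    n_events: int
    threshold_used: float


@dataclass(frozen=True)
class QuadrantFractions:
    condition_id: str
    replicate: int
    viable: float
    dpsi_low_only: float
    dpsi_low_aad_pos: float
    aad_pos_only: float

    def as_dict(self) -> dict[str, float]:
        return {
            "viable": self.viable,
            "dpsi_low_only": self.dpsi_low_only,
            "dpsi_low_aad_pos": self.dpsi_low_aad_pos,
            "aad_pos_only": self.aad_pos_only,
        }


def _events_frame(events) -> pd.DataFrame:
    return events.data if isinstance(events, EventTable) else events


def fit_release_threshold(control_events, random_state: int = 0) -> ThresholdFit:
    """Fit the release gate on a bimodal calibration control.

    A 2-component Gaussian mixture is fitted to log10 cytochrome-C intensity;
    the threshold is the intensity of equal posterior membership between the
    dim (released) and bright (retained) components. If either mixture weight
    is degenerate (< 2%) the threshold falls back to the midpoint of the
    component means and the fit is flagged.
    """
    frame = _events_frame(control_events)
    x = np.log10(np.asarray(frame["cytc_intensity"], dtype=float))
    if x.size < MIN_THRESHOLD_EVENTS:
        raise InsufficientDataError(
            f"threshold fit needs >= {MIN_THRESHOLD_EVENTS} events, got {x.size}"
        )
    gmm = GaussianMixture(
        n_components=2, n_init=3, random_state=random_state, reg_covar=1e-6
    ).fit(x.reshape(-1, 1))
    order = np.argsort(gmm.means_.ravel())
    means = gmm.means_.ravel()[order]
    sds = np.sqrt(gmm.covariances_.ravel()[order])
    weights = gmm.weights_.ravel()[order]

    # degenerate when one component vanishes or the two components are not
    # separated relative to their widths (unimodal input split in half)
    fallback = bool(
        weights.min() < DEGENERATE_WEIGHT
        or (means[1] - means[0]) < 2.0 * float(np.mean(sds))
    )
    lo, hi = float(means[0]), float(means[1])
    if fallback or hi - lo < 1e-6:
        log10_threshold = 0.5 * (lo + hi)
        fallback = True
    else:
        def posterior_log_ratio(v: float) -> float:
            return (
                np.log(weights[0]) + norm.logpdf(v, means[0], sds[0])
                - np.log(weights[1]) - norm.logpdf(v, means[1], sds[1])
            )
        if posterior_log_ratio(lo) > 0 > posterior_log_ratio(hi):
            log10_threshold = float(brentq(posterior_log_ratio, lo, hi))
        else:  # no crossing between the means (extreme weights): midpoint
            log10_threshold = 0.5 * (lo + hi)
            fallback = True

    return ThresholdFit(
        threshold=float(10.0 ** log10_threshold),
        log10_means=(float(means[0]), float(means[1])),
        log10_sds=(float(sds[0]), float(sds[1])),
        weights=(float(weights[0]), float(weights[1])),
        fallback=fallback,
    )


def percent_release(events, threshold) -> ReleaseMeasurement:
    """Fraction of events below the release threshold (dim = released).

    Events exactly at the threshold count as retained, so the gate is
    bit-exactly reproducible.
    """
    thr = float(threshold)
    if thr <= 0:
        raise InvalidParameterError(f"threshold must be positive, got {thr}")
    frame = _events_frame(events)
    n = len(frame)
    if n == 0:
        raise UndefinedMeasurementError("percent_release undefined for 0 events")
    fraction = float(np.count_nonzero(frame["cytc_intensity"].to_numpy() < thr)) / n
    cid = events.condition_id if isinstance(events, EventTable) else ""
    rep = events.replicate if isinstance(events, EventTable) else 0
    return ReleaseMeasurement(
        condition_id=cid,
        replicate=rep,
        fraction_released=fraction,
        n_events=n,
        threshold_used=thr,
    )


def quadrant_fractions(events, dpsi_threshold: float, aad_threshold: float) -> QuadrantFractions:
    """Four-quadrant fractions on the membrane-potential / viability channels.

    Positivity conventions: dpsi < threshold is membrane-potential-low;
    aad > threshold is viability-dye-positive.
    """
    frame = _events_frame(events)
    for channel in ("dpsi_intensity", "aad_intensity"):
        if channel not in frame.columns or frame[channel].isna().all():
            raise ChannelAbsentError(f"channel {channel!r} absent from event table")
    n = len(frame)
    if n == 0:
        raise UndefinedMeasurementError("quadrant_fractions undefined for 0 events")
    dpsi_low = frame["dpsi_intensity"].to_numpy() < dpsi_threshold
    aad_pos = frame["aad_intensity"].to_numpy() > aad_threshold
    cid = events.condition_id if isinstance(events, EventTable) else ""
    rep = events.replicate if isinstance(events, EventTable) else 0
    return QuadrantFractions(
        condition_id=cid,
        replicate=rep,
        viable=float(np.count_nonzero(~dpsi_low & ~aad_pos)) / n,
        dpsi_low_only=float(np.count_nonzero(dpsi_low & ~aad_pos)) / n,
        dpsi_low_aad_pos=float(np.count_nonzero(dpsi_low & aad_pos)) / n,
        aad_pos_only=float(np.count_nonzero(~dpsi_low & aad_pos)) / n,
    )


def default_quadrant_thresholds(control_events) -> tuple[float, float]:
    """Negative-control tail gates: 0.5th percentile of the untreated control on
    the membrane-potential channel (positive = low) and 99.5th percentile on the
    viability-dye channel (positive = high)."""
    frame = _events_frame(control_events)
    for channel in ("dpsi_intensity", "aad_intensity"):
        if channel not in frame.columns or frame[channel].isna().all():
            raise ChannelAbsentError(f"channel {channel!r} absent from control table")
    dpsi_thr = float(np.percentile(frame["dpsi_intensity"].to_numpy(), 0.5))
    aad_thr = float(np.percentile(frame["aad_intensity"].to_numpy(), 99.5))
    return dpsi_thr, aad_thr
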