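"""Flow-cytometry gating and distribution summaries.

Event tables are plain DataFrames with columns ``fsc``, ``ssc`` and ``fl1``
(linear scale, as exported).  Gating keeps events with measurable — strictly
positive — forward and side scatter; summaries report the arithmetic mean and
the Robust CV of a channel.

Robust CV is the quantile-based dispersion used by cytometry software::

    100 * 0.5 * (P84.13 - P15.87) / median

For a Gaussian the 84.13/15.87 percentiles sit one standard deviation either
side of the mean, so Robust CV of N(mu, sigma) estimates 100 * sigma / mu
while remaining insensitive to outliers and heavy tails.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import (DataError, InsufficientDataError, ProtocolError,
                     UndefinedStatisticError)

logger = logging.getLogger(__name__)

#: Percentiles one sigma either side of the median of a Gaussian.
UPPER_PCT = 84.13
LOWER_PCT = 15.87


def gate_events(events: pd.DataFrame, fsc_threshold: float = 0.0,
                ssc_threshold: float = 0.0) -> pd.DataFrame:
    """Keep events with measurable (> threshold) FSC and SSC.

    The returned frame carries ``attrs['gated'] = True`` and the pre-gate
    event count in ``attrs['n_total']``; :func:`flow_summary` refuses ungated
    input unless overridden.  Idempotent: re-gating changes nothing.
    """
    if len(events) == 0:
        raise DataError("cannot gate an empty event set")
    keep = (events["fsc"].to_numpy() > fsc_threshold) & \
           (events["ssc"].to_numpy() > ssc_threshold)
    if not keep.any():
        raise DataError("gate removed every event")
    gated = events.loc[keep].reset_index(drop=True)
    gated.attrs["gated"] = True
    gated.attrs["n_total"] = int(events.attrs.get("n_total", len(events)))
    frac = keep.mean()
    logger.info("gated %d/%d events (%.1f%%)", keep.sum(), len(events), 100 * frac)
    return gated


def robust_cv(intensities) -> float:
    """Robust CV in percent: ``100 * 0.5 * (P84.13 - P15.87) / median``.

    Percentiles use linear interpolation between order statistics
    (``p * (n - 1)`` indexing, numpy's default).
    """
    x = np.asarray(intensities, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 3:
        raise InsufficientDataError("Robust CV needs at least 3 values")
    med = np.median(x)
    if med == 0:
        raise UndefinedStatisticError("Robust CV undefined for zero median")
    hi, lo = np.percentile(x, [UPPER_PCT, LOWER_PCT])
    return float(100.0 * 0.5 * (hi - lo) / med)


def flow_summary(events: pd.DataFrame, channel: str = "fl1",
                 allow_ungated: bool = False) -> dict:
    """Mean, Robust CV and event count of one channel of a gated event set."""
    if channel not in events.columns:
        raise DataError(f"channel {channel!r} not present")
    if not events.attrs.get("gated", False) and not allow_ungated:
        raise ProtocolError("events are not gated; run gate_events first "
                            "or pass allow_ungated=True")
    x = events[channel].to_numpy(dtype=float)
    return {"n": int(x.size), "mean": float(x.mean()), "robust_cv": robust_cv(x)}
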