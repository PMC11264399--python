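"""Detrending, standardization and complete-case filtering before model fitting.

Ordinal item scores are treated as continuous from here on.  Detrending
removes a pooled (fixed-effect) linear trend of score on wave index per item,
so the within-person process can be taken as stationary; standardization
z-scores each item using its mean and SD pooled across all waves jointly.
Neither operation touches the missingness pattern.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np

from .panel_data import PanelDataError, PanelDataset

logger = logging.getLogger(__name__)

__all__ = ["detrend", "standardize", "complete_cases"]


def detrend(ds: PanelDataset) -> PanelDataset:
    """Subtract a per-item OLS line of score on wave index (pooled over persons).

    The trend is a population-level fixed effect, not a per-person line: with
    few waves a per-person fit would absorb nearly all within-person variance.
    Re-fitting the trend on the output gives slope and intercept ~ 0.
    """
    scores = ds.scores.copy()
    wave_idx = np.arange(ds.n_waves, dtype=float)
    for j, item in enumerate(ds.schema.item_ids):
        obs = ~ds.missing_mask[:, :, j]
        if not obs.any():
            raise PanelDataError(f"item {item!r} entirely missing; cannot detrend")
        t = np.broadcast_to(wave_idx, obs.shape)[obs]
        y = scores[:, :, j][obs]
        if np.unique(t).size < 2:
            raise PanelDataError(f"item {item!r} observed at < 2 waves; cannot detrend")
        slope, intercept = np.polyfit(t, y, 1)
        fitted = intercept + slope * wave_idx
        scores[:, :, j] -= fitted[None, :]
    return replace(ds, scores=scores, ordinal=False)


def standardize(ds: PanelDataset) -> PanelDataset:
    """Z-score each item with mean/SD pooled across all waves jointly.

    The pooled convention (not per-wave) preserves mean differences between
    waves, which the model's wave means and detrending are responsible for.
    Sample SD uses denominator n-1.
    """
    scores = ds.scores.copy()
    for j, item in enumerate(ds.schema.item_ids):
        vals = scores[:, :, j][~ds.missing_mask[:, :, j]]
        sd = vals.std(ddof=1) if vals.size > 1 else 0.0
        if not sd > 0:
            raise PanelDataError(f"item {item!r} has zero pooled variance; screen it out first")
        scores[:, :, j] = (scores[:, :, j] - vals.mean()) / sd
    return replace(ds, scores=scores, ordinal=False)


def complete_cases(ds: PanelDataset) -> PanelDataset:
    """Keep only persons with no missing item at any wave (sensitivity analyses)."""
    keep = (~ds.missing_mask).all(axis=(1, 2))
    n_keep = int(keep.sum())
    if n_keep == 0:
        raise PanelDataError("no complete cases")
    logger.info("complete cases: retained %d, dropped %d", n_keep, ds.n_persons - n_keep)
    return ds.subset_persons(keep)
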