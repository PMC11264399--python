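"""Case-drop subsampling stability of the pruned networks.

Each replicate draws a fraction of the persons without replacement, re-runs
the whole configured pipeline (preprocessing, saturated fit, pruning and
optionally model search) on the subsample, and codes every possible edge as
present (1, free and nonzero in the final pattern) or absent (0).  A
replicate whose model does not converge contributes 0 to every edge.  The
accumulated counts mirror the "present in k out of R replications" matrices
reported for such analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import preprocess
from .estimation import fit_gvar, model_search, prune
from .panel_data import PanelDataError, PanelDataset

logger = logging.getLogger(__name__)

__all__ = ["StabilityResult", "casedrop_stability", "presence_report"]


@dataclass
class StabilityResult:
    n_replicates: int
    subsample_proportion: float
    presence_counts: dict[str, np.ndarray]  # temporal, contemporaneous, between
    n_nonconverged: int
    seed: int
    item_ids: tuple[str, ...]


def _run_replicate(sub: PanelDataset, config: dict):
    """Preprocess -> fit -> prune [-> search] on one subsample; returns the
    final FittedModel or None if any stage fails."""
    try:
        ds = sub
        if config.get("complete_cases_only", False):
            ds = preprocess.complete_cases(ds)
        if config.get("detrend", True):
            ds = preprocess.detrend(ds)
        if config.get("standardize", True):
            ds = preprocess.standardize(ds)
        model = fit_gvar(ds)
        if not model.converged:
            return None
        alpha = config.get("prune_alpha", 0.01)
        model = prune(model, ds, alpha,
                      exempt_autoregressions=config.get("exempt_autoregressions", False))
        if not model.converged:
            return None
        if config.get("search", False):
            model = model_search(model, ds, alpha)
            if not model.converged:
                return None
        return model
    except (PanelDataError, np.linalg.LinAlgError, ValueError) as e:
        logger.info("replicate failed (%s); counted non-converged", e)
        return None


def casedrop_stability(
    ds: PanelDataset,
    config: dict | None = None,
    proportion: float = 0.75,
    reps: int = 1000,
    seed: int = 0,
) -> StabilityResult:
    """Case-drop stability: rerun the pipeline on person subsamples.

    ``floor(proportion * n)`` persons are drawn without replacement per
    replicate.  Replicate r uses an independent random stream spawned from
    (seed, r), so results are reproducible and independent of execution
    order.
    """
    if not 0 < proportion <= 1:
        raise ValueError("proportion must be in (0, 1]")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    config = dict(config or {})
    p = ds.n_items
    counts = {k: np.zeros((p, p), dtype=int) for k in ("temporal", "contemporaneous", "between")}
    n_sub = int(np.floor(proportion * ds.n_persons))
    n_nonconv = 0
    root = np.random.SeedSequence(seed)
    streams = root.spawn(reps)
    for r in range(reps):
        rng = np.random.default_rng(streams[r])
        idx = rng.choice(ds.n_persons, size=n_sub, replace=False)
        idx.sort()
        model = _run_replicate(ds.subset_persons(idx), config)
        if model is None:
            n_nonconv += 1
            continue
        pat = model.pattern
        present_t = pat.temporal & (model.params.B != 0.0)
        counts["temporal"] += present_t.T.astype(int)  # source -> target orientation
        for key, patM, est in (
            ("contemporaneous", pat.contemporaneous, model.params.K_zeta),
            ("between", pat.between, model.params.K_between),
        ):
            present = patM & (est != 0.0) & ~np.eye(p, dtype=bool)
            counts[key] += present.astype(int)
    return StabilityResult(
        n_replicates=reps,
        subsample_proportion=proportion,
        presence_counts=counts,
        n_nonconverged=n_nonconv,
        seed=seed,
        item_ids=ds.schema.item_ids,
    )


def presence_report(res: StabilityResult, threshold: float = 0.10) -> pd.DataFrame:
    """Edges whose presence share across replicates falls below ``threshold``.

    Undirected networks are reported once per pair (upper triangle); the
    temporal network reports every ordered pair, self-loops included.  Shares
    are rounded to 3 decimals.
    """
    rows = []
    p = len(res.item_ids)
    R = res.n_replicates
    for i in range(p):
        for j in range(p):
            share = res.presence_counts["temporal"][i, j] / R
            if share < threshold:
                rows.append({"network": "temporal", "source": res.item_ids[i],
                             "target": res.item_ids[j],
                             "count": int(res.presence_counts["temporal"][i, j]),
                             "share": round(share, 3)})
    for name in ("contemporaneous", "between"):
        for i in range(p):
            for j in range(i + 1, p):
                share = res.presence_counts[name][i, j] / R
                if share < threshold:
                    rows.append({"network": name, "source": res.item_ids[i],
                                 "target": res.item_ids[j],
                                 "count": int(res.presence_counts[name][i, j]),
                                 "share": round(share, 3)})
    return pd.DataFrame(rows, columns=["network", "source", "target", "count", "share"])
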