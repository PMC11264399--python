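"""Panel data containers, CSV I/O, variance screening and missingness accounting.

The canonical interchange format is a long CSV with one row per (person, wave)
and one column per questionnaire item; blank cells are missing.  Scores are
small integers in ``{0..n_categories-1}`` before preprocessing and floats
afterwards.  Wave indices are 0-based internally and displayed with the
user-supplied wave labels (``T1``, ``T2``, ...).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ItemSchema",
    "PanelDataset",
    "PanelDataError",
    "read_panel",
    "write_panel",
    "screen_variance",
    "missingness_profile",
]


class PanelDataError(ValueError):
    """Malformed panel input or an operation that would leave nothing to model."""


@dataclass(frozen=True)
class ItemSchema:
    """Schema of an ordinal item battery measured repeatedly.

    Parameters
    ----------
    item_ids
        Ordered unique item labels, e.g. ``("EPDS1", ..., "EPDS10")``.
    n_categories
        Number of ordered response categories (4 for the EPDS 0-3 scale).
    wave_labels
        Ordered measurement-occasion labels, e.g. ``("T1", "T2", "T3")``.
    """

    item_ids: tuple[str, ...]
    n_categories: int
    wave_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "item_ids", tuple(self.item_ids))
        object.__setattr__(self, "wave_labels", tuple(self.wave_labels))
        if len(set(self.item_ids)) != len(self.item_ids):
            raise PanelDataError("item_ids must be unique")
        if self.n_categories < 2:
            raise PanelDataError("n_categories must be >= 2")
        if len(self.wave_labels) < 1:
            raise PanelDataError("at least one wave label required")

    @property
    def n_items(self) -> int:
        return len(self.item_ids)

    @property
    def n_waves(self) -> int:
        return len(self.wave_labels)


@dataclass
class PanelDataset:
    """Persons x waves x items score array with an explicit missingness mask.

    ``missing_mask`` is ``True`` exactly where the score is undefined; the
    score array holds NaN there.  ``ordinal`` records whether scores are raw
    category codes or continuous (post-preprocessing) values.
    """

    schema: ItemSchema
    scores: np.ndarray  # float (n_persons, n_waves, n_items)
    missing_mask: np.ndarray  # bool, same shape
    person_ids: tuple = ()
    group: str = ""
    ordinal: bool = True

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.scores.shape != self.missing_mask.shape:
            raise PanelDataError("scores and missing_mask shapes differ")
        if self.scores.ndim != 3:
            raise PanelDataError("scores must be (persons, waves, items)")
        n, w, p = self.scores.shape
        if w != self.schema.n_waves or p != self.schema.n_items:
            raise PanelDataError("scores shape inconsistent with schema")
        if not self.person_ids:
            self.person_ids = tuple(range(n))
        self.person_ids = tuple(self.person_ids)
        if len(self.person_ids) != n:
            raise PanelDataError("person_ids length mismatch")
        self.scores = self.scores.copy()
        self.scores[self.missing_mask] = np.nan
        if np.isnan(self.scores[~self.missing_mask]).any():
            raise PanelDataError("NaN score in a cell not flagged missing")

    @property
    def n_persons(self) -> int:
        return self.scores.shape[0]

    @property
    def n_waves(self) -> int:
        return self.scores.shape[1]

    @property
    def n_items(self) -> int:
        return self.scores.shape[2]

    def observed_at_wave(self, wave: int) -> np.ndarray:
        """Boolean per person: has >= 1 non-missing item at `wave`."""
        return (~self.missing_mask[:, wave, :]).any(axis=1)

    def complete_at_wave(self, wave: int) -> np.ndarray:
        """Boolean per person: all items non-missing at `wave`."""
        return (~self.missing_mask[:, wave, :]).all(axis=1)

    def stacked(self) -> tuple[np.ndarray, np.ndarray]:
        """Scores and observation mask flattened to (persons, waves*items)."""
        n = self.n_persons
        return self.scores.reshape(n, -1), (~self.missing_mask).reshape(n, -1)

    def subset_persons(self, index) -> "PanelDataset":
        idx = np.asarray(index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return PanelDataset(
            schema=self.schema,
            scores=self.scores[idx],
            missing_mask=self.missing_mask[idx],
            person_ids=tuple(self.person_ids[i] for i in idx),
            group=self.group,
            ordinal=self.ordinal,
        )


def read_panel(
    path,
    schema: ItemSchema,
    *,
    group: str = "",
    id_column: str = "person_id",
    wave_column: str = "wave",
    wide: bool = False,
    ordinal: bool = True,
) -> PanelDataset:
    """Read a long CSV (one row per person-wave) into a :class:`PanelDataset`.

    Duplicate ``(person, wave)`` rows and scores outside the schema's category
    range are rejected.  Persons with zero non-missing waves are dropped with
    a logged count.  ``wide=True`` accepts one-row-per-person files with
    columns named ``<item>_<wave_label>`` and reshapes them to long form.
    """
    df = pd.read_csv(path, dtype={id_column: str})
    if wide:
        df = _wide_to_long(df, schema, id_column, wave_column)
    missing_cols = [c for c in (id_column, wave_column, *schema.item_ids) if c not in df.columns]
    if missing_cols:
        raise PanelDataError(f"missing columns: {missing_cols}")

    wave_index = {lab: i for i, lab in enumerate(schema.wave_labels)}
    bad_waves = set(df[wave_column].astype(str)) - set(map(str, schema.wave_labels))
    if bad_waves:
        raise PanelDataError(f"malformed wave labels: {sorted(bad_waves)}")
    if df.duplicated([id_column, wave_column]).any():
        dups = df[df.duplicated([id_column, wave_column])]
        raise PanelDataError(
            f"duplicate (person, wave) rows: {dups[[id_column, wave_column]].values[:5].tolist()}"
        )

    persons = list(dict.fromkeys(df[id_column]))
    pidx = {p: i for i, p in enumerate(persons)}
    n, w, p = len(persons), schema.n_waves, schema.n_items
    scores = np.full((n, w, p), np.nan)
    for _, row in df.iterrows():
        i = pidx[row[id_column]]
        t = wave_index[str(row[wave_column])]
        vals = pd.to_numeric(row[list(schema.item_ids)], errors="coerce").to_numpy(float)
        scores[i, t, :] = vals
    if ordinal:
        obs = ~np.isnan(scores)
        v = scores[obs]
        if ((v < 0) | (v > schema.n_categories - 1) | (v != np.round(v))).any():
            raise PanelDataError(
                f"scores outside {{0..{schema.n_categories - 1}}} or non-integer present"
            )
    mask = np.isnan(scores)
    ds = PanelDataset(schema, scores, mask, tuple(persons), group, ordinal)
    keep = (~ds.missing_mask).any(axis=(1, 2))
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("dropping %d person(s) with zero non-missing waves", n_drop)
        ds = ds.subset_persons(keep)
    return ds


def _wide_to_long(df: pd.DataFrame, schema: ItemSchema, id_column: str, wave_column: str):
    rows = []
    for _, row in df.iterrows():
        for lab in schema.wave_labels:
            rec = {id_column: row[id_column], wave_column: lab}
            for item in schema.item_ids:
                rec[item] = row.get(f"{item}_{lab}", np.nan)
            rows.append(rec)
    return pd.DataFrame(rows)


def write_panel(ds: PanelDataset, path, *, id_column: str = "person_id", wave_column: str = "wave") -> None:
    """Write the long-CSV form; missing cells are left empty."""
    rows = []
    for i, pid in enumerate(ds.person_ids):
        for t, lab in enumerate(ds.schema.wave_labels):
            rec = {id_column: pid, wave_column: lab}
            for j, item in enumerate(ds.schema.item_ids):
                v = ds.scores[i, t, j]
                if ds.missing_mask[i, t, j]:
                    rec[item] = ""
                else:
                    rec[item] = int(v) if ds.ordinal else repr(float(v))
            rows.append(rec)
    pd.DataFrame(rows).to_csv(path, index=False)


def screen_variance(
    ds: PanelDataset, max_modal_share: float = 0.95
) -> tuple[PanelDataset, list[str]]:
    """Drop near-constant items (pooled modal-category share > threshold).

    Operationalizes exclusion of items "lacking variation" (e.g. a suicidal-
    ideation item endorsed by almost nobody): for each item, the share of the
    single most frequent observed value pooled over all waves is compared to
    ``max_modal_share``; items exceeding it are removed from the schema and
    score array.  Returns the reduced dataset and the excluded item ids.
    """
    if not 0 < max_modal_share <= 1:
        raise PanelDataError("max_modal_share must be in (0, 1]")
    excluded: list[str] = []
    keep_idx: list[int] = []
    for j, item in enumerate(ds.schema.item_ids):
        vals = ds.scores[:, :, j][~ds.missing_mask[:, :, j]]
        if vals.size == 0:
            excluded.append(item)
            continue
        _, counts = np.unique(vals, return_counts=True)
        if counts.max() / vals.size > max_modal_share:
            excluded.append(item)
        else:
            keep_idx.append(j)
    if not keep_idx:
        raise PanelDataError("variance screening excluded every item")
    if not excluded:
        return ds, []
    new_schema = replace(ds.schema, item_ids=tuple(ds.schema.item_ids[j] for j in keep_idx))
    out = PanelDataset(
        schema=new_schema,
        scores=ds.scores[:, :, keep_idx],
        missing_mask=ds.missing_mask[:, :, keep_idx],
        person_ids=ds.person_ids,
        group=ds.group,
        ordinal=ds.ordinal,
    )
    logger.info("variance screening excluded %s", excluded)
    return out, excluded


def missingness_profile(ds: PanelDataset) -> pd.DataFrame:
    """Per-wave participation and dropout-from-wave-1 counts and percentages.

    A person participates at a wave if they have >= 1 non-missing item there.
    Dropout at wave k is counted relative to wave-1 participants and the
    percentage (denominator = wave-1 count) is rounded to 2 decimals.
    """
    at_w1 = ds.observed_at_wave(0)
    n1 = int(at_w1.sum())
    rows = []
    for t, lab in enumerate(ds.schema.wave_labels):
        at_t = ds.observed_at_wave(t)
        nt = int(at_t.sum())
        drop = int((at_w1 & ~at_t).sum()) if t > 0 else 0
        pct = round(100.0 * drop / n1, 2) if n1 else 0.0
        rows.append({"wave": lab, "n": nt, "dropout_from_t1": drop, "dropout_pct": pct})
    return pd.DataFrame(rows)
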