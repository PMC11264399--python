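import numpy as np
import pytest

from panelgvar.panel_data import ItemSchema, PanelDataset


@pytest.fixture
def schema3():
    return ItemSchema(("A", "B", "C"), 4, ("T1", "T2", "T3"))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_dataset(scores, mask=None, n_categories=4, ordinal=None, wave_labels=None):
    """Build a PanelDataset from a (persons, waves, items) array."""
    scores = np.asarray(scores, dtype=float)
    if mask is None:
        mask = np.isnan(scores)
    n, w, p = scores.shape
    schema = ItemSchema(
        tuple(f"I{j + 1}" for j in range(p)),
        n_categories,
        tuple(wave_labels) if wave_labels else tuple(f"T{t + 1}" for t in range(w)),
    )
    if ordinal is None:
        obs = scores[~np.asarray(mask, bool)]
        ordinal = bool(obs.size == 0 or ((obs == np.round(obs)).all() and obs.min() >= 0))
    return PanelDataset(schema, scores, mask, ordinal=ordinal)


@pytest.fixture
def complete_random_ds(rng):
    """60 persons x 3 waves x 3 ordinal items, no missingness."""
    scores = rng.integers(0, 4, size=(60, 3, 3)).astype(float)
    return make_dataset(scores)
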