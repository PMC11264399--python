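"""Extract the temporal / contemporaneous / between networks and centrality.

The fitted parameters map onto three networks: the temporal network holds
directed lag-1 effects (``temporal[i, j]`` is the edge i -> j, i.e. the
standardized coefficient ``B[j, i]``); the contemporaneous and between
networks are Gaussian-graphical-model partial correlations obtained from the
respective precision matrices via ``omega_ij = -kappa_ij / sqrt(kappa_ii *
kappa_jj)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

from .estimation import FittedModel
from .gvar import GVARModelError

__all__ = ["NetworkSet", "precision_to_partial", "extract_networks", "centrality"]


def precision_to_partial(K: np.ndarray) -> np.ndarray:
    """Partial-correlation matrix of a GGM precision: -k_ij/sqrt(k_ii k_jj),
    zero diagonal."""
    K = np.asarray(K, float)
    if not np.allclose(K, K.T, atol=1e-10):
        raise GVARModelError("precision must be symmetric")
    try:
        linalg.cho_factor(K)
    except linalg.LinAlgError as e:
        raise GVARModelError("precision must be positive-definite") from e
    d = np.sqrt(np.diag(K))
    omega = -K / np.outer(d, d)
    np.fill_diagonal(omega, 0.0)
    return (omega + omega.T) / 2.0


@dataclass
class NetworkSet:
    """The three weighted networks, with edge orientation source-to-target."""

    temporal: np.ndarray  # [i, j] = directed edge i -> j (= B[j, i])
    contemporaneous: np.ndarray
    between: np.ndarray
    item_ids: tuple[str, ...]

    def edge_list(self) -> pd.DataFrame:
        """Long edge list over the three networks; zero-weight pairs omitted.
        Undirected edges are listed once with source index < target index."""
        rows = []
        p = len(self.item_ids)
        for i in range(p):
            for j in range(p):
                w = self.temporal[i, j]
                if w != 0.0:
                    rows.append({"network": "temporal", "source": self.item_ids[i],
                                 "target": self.item_ids[j], "weight": w})
        for name, M in (("contemporaneous", self.contemporaneous), ("between", self.between)):
            for i in range(p):
                for j in range(i + 1, p):
                    if M[i, j] != 0.0:
                        rows.append({"network": name, "source": self.item_ids[i],
                                     "target": self.item_ids[j], "weight": M[i, j]})
        return pd.DataFrame(rows, columns=["network", "source", "target", "weight"])


def to_graphml(nets: NetworkSet, path) -> None:
    """Export the three networks as one GraphML file for external layout
    tools; edges carry ``weight`` and ``network`` attributes, temporal edges
    are directed."""
    import networkx as nx

    G = nx.MultiDiGraph()
    G.add_nodes_from(nets.item_ids)
    for _, r in nets.edge_list().iterrows():
        G.add_edge(r.source, r.target, weight=float(r.weight), network=r.network,
                   directed=r.network == "temporal")
    nx.write_graphml(G, path)


def extract_networks(model: FittedModel) -> NetworkSet:
    """Turn fitted parameters into the three reported networks.

    ``temporal[i, j] = B[j, i]`` re-orients the coefficient matrix from
    receiver-row convention to predictor-to-receiver edges; self-loops stay
    on the diagonal.
    """
    if not model.converged:
        raise GVARModelError("cannot extract networks from a non-converged model")
    return NetworkSet(
        temporal=model.params.B.T.copy(),
        contemporaneous=precision_to_partial(model.params.K_zeta),
        between=precision_to_partial(model.params.K_between),
        item_ids=tuple(model.params.item_ids),
    )


def centrality(nets: NetworkSet) -> pd.DataFrame:
    """Strength centralities: sums of absolute edge weights, self-loops excluded.

    out_strength(i) = sum_j |temporal[i, j]| over j != i (how much i predicts
    others); in_strength(i) the column analogue; strength(i) for the two
    undirected networks.
    """
    p = len(nets.item_ids)
    A = np.abs(nets.temporal)
    off = ~np.eye(p, dtype=bool)
    out_strength = (A * off).sum(axis=1)
    in_strength = (A * off).sum(axis=0)
    strength = (np.abs(nets.contemporaneous) * off).sum(axis=1)
    strength_between = (np.abs(nets.between) * off).sum(axis=1)
    return pd.DataFrame(
        {
            "item": nets.item_ids,
            "in_strength": in_strength,
            "out_strength": out_strength,
            "strength": strength,
            "strength_between": strength_between,
        }
    )
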