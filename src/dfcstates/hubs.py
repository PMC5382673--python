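"""Hub structure of dFC state centroids.

Each state's windows are Fisher z-transformed and each edge is tested
against zero; edges failing an FDR threshold are zeroed, giving a signed
weighted graph per state.  Modules come from consensus Louvain clustering
(allegiance over repeated runs); nodes are then scored by within-module
degree z-score and participation index and classified as connector hubs,
provincial hubs or non-hubs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._louvain import louvain_signed, signed_modularity
from .simulate import derive_seed
from .stats import bh_fdr
from .windows import fisher_z


@dataclass
class StateGraph:
    """Signed weighted graph of one dFC state (FDR-thresholded mean z)."""

    adjacency: np.ndarray
    node_ids: list[str]
    subnetwork_labels: list[str]
    state: int = 0
    n_windows: int = 0

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency, dtype=float)
        n = self.adjacency.shape[0]
        if self.adjacency.shape != (n, n):
            raise ValueError("adjacency must be square")
        if not np.allclose(self.adjacency, self.adjacency.T, atol=1e-10):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(self.adjacency) != 0):
            raise ValueError("diagonal must be zero")


def _edge_pvalues_vs_zero(z_windows: np.ndarray) -> np.ndarray:
    """One-sample t-test p per edge; degenerate (constant) edges handled."""
    W = z_windows.shape[0]
    mean = z_windows.mean(axis=0)
    sd = z_windows.std(axis=0, ddof=1)
    p = np.ones(z_windows.shape[1])
    ok = sd > 0
    t = np.zeros_like(mean)
    t[ok] = mean[ok] / (sd[ok] / np.sqrt(W))
    p[ok] = 2.0 * sps.t.sf(np.abs(t[ok]), W - 1)
    # constant non-zero edge: trivially different from zero
    p[(~ok) & (mean != 0)] = 0.0
    return p


def centroid_to_graph(state_windows: np.ndarray, node_ids,
                      subnetwork_labels, alpha_fdr: float = 0.05,
                      state: int = 0, already_fisher: bool = False,
                      min_windows: int = 10) -> StateGraph:
    """Build the signed z-value graph of a state from its member windows.

    ``state_windows`` is (W, E) with E = C(C-1)/2 upper-triangle edges of
    raw correlations (or Fisher z values when ``already_fisher``).  Each
    edge's Fisher z values are tested against zero across windows; edges
    whose BH-FDR q exceeds ``alpha_fdr`` are set exactly to zero, surviving
    edges carry the mean z.
    """
    vals = np.asarray(state_windows, dtype=float)
    if vals.ndim != 2:
        raise ValueError("state_windows must be (W, E)")
    if vals.shape[0] < min_windows:
        raise ValueError(
            f"only {vals.shape[0]} windows assigned to state {state}; "
            f"need at least {min_windows} for edge statistics")
    C = len(node_ids)
    iu = np.triu_indices(C, 1)
    if vals.shape[1] != iu[0].size:
        raise ValueError("edge count does not match node count")
    z = vals if already_fisher else fisher_z(vals)
    p = _edge_pvalues_vs_zero(z)
    keep = bh_fdr(p, alpha=alpha_fdr)
    weights = np.where(keep, z.mean(axis=0), 0.0)
    adj = np.zeros((C, C))
    adj[iu] = weights
    adj += adj.T
    return StateGraph(adjacency=adj, node_ids=list(node_ids),
                      subnetwork_labels=list(subnetwork_labels),
                      state=state, n_windows=vals.shape[0])


def allegiance_matrix(partitions: list[np.ndarray]) -> np.ndarray:
    """Fraction of partitions in which each node pair shares a module."""
    if not partitions:
        raise ValueError("need at least one partition")
    n = partitions[0].size
    T = np.zeros((n, n))
    for part in partitions:
        part = np.asarray(part)
        T += part[:, None] == part[None, :]
    return T / len(partitions)


def consensus_partition(adj: np.ndarray, n_runs: int = 100,
                        gamma: float = 1.0, seed: int | None = None):
    """Consensus Louvain: allegiance over repeated runs, then re-cluster.

    ``n_runs`` Louvain partitions (different node orders) are summarized by
    their modular allegiance matrix, which is itself clustered with Louvain
    at gamma = 1 to give the consensus partition. Returns
    ``(partition, allegiance)``.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be at least 1")
    parts = [louvain_signed(adj, gamma=gamma,
                            seed=derive_seed(seed, "louvain", r))[0]
             for r in range(n_runs)]
    T = allegiance_matrix(parts)
    Tc = T.copy()
    np.fill_diagonal(Tc, 0.0)
    part, _ = louvain_signed(Tc, gamma=1.0,
                             seed=derive_seed(seed, "consensus"))
    return part, T


def module_degree_z(adj: np.ndarray, partition) -> np.ndarray:
    """Within-module degree z-score on positive strengths.

    kappa_i is node i's summed positive weight to members of its own
    module; z standardizes kappa within each module. Modules of size 1, or
    with zero strength spread, give z = 0.
    """
    part = np.asarray(partition)
    Wp = np.clip(np.asarray(adj, float), 0.0, None)
    np.fill_diagonal(Wp, 0.0)
    n = part.size
    z = np.zeros(n)
    for m in np.unique(part):
        members = np.flatnonzero(part == m)
        if members.size < 2:
            continue
        kappa = Wp[np.ix_(members, members)].sum(axis=1)
        sd = kappa.std()
        if sd > 0:
            z[members] = (kappa - kappa.mean()) / sd
    return z


def participation_index(adj: np.ndarray, partition) -> np.ndarray:
    """Participation index on positive strengths.

    P_i = 1 - sum_m (k_im / k_i)^2 over modules m, where k_im is node i's
    positive strength into module m and k_i its total positive strength;
    P_i = 0 when k_i = 0.  P is 0 for a fully intra-modular node and tends
    to 1 as strength spreads evenly over many modules.
    """
    part = np.asarray(partition)
    Wp = np.clip(np.asarray(adj, float), 0.0, None)
    np.fill_diagonal(Wp, 0.0)
    k = Wp.sum(axis=1)
    P = np.zeros(part.size)
    nz = k > 0
    for m in np.unique(part):
        members = part == m
        kim = Wp[:, members].sum(axis=1)
        P[nz] += (kim[nz] / k[nz]) ** 2
    P[nz] = 1.0 - P[nz]
    return np.clip(P, 0.0, 1.0)


def classify_hubs(z: np.ndarray, P: np.ndarray) -> list[str]:
    """Role per node: connector (z>1, P>0.3), provincial (z>1, P<=0.3),
    else non-hub.  Boundaries are strict: z = 1 is a non-hub and P = 0.3 a
    provincial hub."""
    z = np.asarray(z, float)
    P = np.asarray(P, float)
    if z.shape != P.shape:
        raise ValueError("z and P must align")
    roles = []
    for zi, pi in zip(z, P):
        if zi > 1.0:
            roles.append("connector" if pi > 0.3 else "provincial")
        else:
            roles.append("non-hub")
    return roles


def hub_table(graph: StateGraph, partition=None, n_runs: int = 100,
              gamma: float = 1.0, seed: int | None = None) -> pd.DataFrame:
    """Full hub characterization of one state graph.

    If ``partition`` is not given, consensus Louvain over ``n_runs`` runs
    determines the modules. Returns one row per node: module, z, P, role.
    """
    if partition is None:
        partition, _ = consensus_partition(graph.adjacency, n_runs=n_runs,
                                           gamma=gamma, seed=seed)
    z = module_degree_z(graph.adjacency, partition)
    P = participation_index(graph.adjacency, partition)
    return pd.DataFrame({
        "node": graph.node_ids,
        "subnetwork": graph.subnetwork_labels,
        "module": np.asarray(partition, int),
        "module_degree_z": z,
        "participation_index": P,
        "role": classify_hubs(z, P),
    })
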