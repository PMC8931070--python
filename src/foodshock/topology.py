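"""Node-level network covariates and the directed-topology summary suite.

Conventions (documented because several have competing definitions):

* clustering is the unweighted local clustering coefficient on the
  undirected projection;
* betweenness is computed on the directed unweighted graph, unnormalized
  (raw path counts; any log transform happens in the inference layer);
* the hub score is the principal HITS hub vector of the weighted adjacency,
  normalized to unit 2-norm with non-negative entries;
* PageRank uses weight-proportional transitions with damping 0.85;
* C4 is the share of a country's import calories coming from its four
  largest suppliers (0 for a country with no imports);
* the "tot" neighborhood for ANND/ANNS is the union of in- and
  out-neighbors while the total degree is k_in + k_out (the standard sum
  convention, which double-counts reciprocated partners in the degree but
  not in the neighborhood).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .network import TradeNetwork

_DIRS = ("in", "out", "tot")


def _neighbor_masks(A: np.ndarray, direction: str) -> np.ndarray:
    """Boolean n x n matrix; row i marks the direction-neighborhood of i."""
    if direction == "in":
        return A.T.copy()
    if direction == "out":
        return A.copy()
    if direction == "tot":
        return A | A.T
    raise ValueError(f"direction must be one of {_DIRS}, got {direction!r}")


def _deg(A: np.ndarray, direction: str) -> np.ndarray:
    if direction == "in":
        return A.sum(axis=0).astype(float)
    if direction == "out":
        return A.sum(axis=1).astype(float)
    return (A.sum(axis=0) + A.sum(axis=1)).astype(float)


def _strength(W: np.ndarray, direction: str) -> np.ndarray:
    if direction == "in":
        return W.sum(axis=0)
    if direction == "out":
        return W.sum(axis=1)
    return W.sum(axis=0) + W.sum(axis=1)


def annd_anns(
    network: TradeNetwork, alpha_dir: str, beta_dir: str
) -> tuple[pd.DataFrame, float, float]:
    """Average nearest-neighbor degree and strength for one direction pair.

    For each node i, ANND is the mean beta-degree over i's
    alpha-neighborhood (ANNS analogously with strengths); for the "tot"
    direction the neighborhood is the union of in- and out-neighbors, so a
    reciprocated partner is counted once.  Returns a per-node frame (NaN
    where the alpha-neighborhood is empty) plus the two assortativity
    coefficients: Pearson correlations of alpha-degree (k_in + k_out for
    "tot") with ANND and of alpha-strength with ANNS, over nodes with
    non-empty neighborhoods.  A zero-variance correlation is NaN.
    """
    W = network.weights
    A = W > 0
    nbr = _neighbor_masks(A, alpha_dir)
    nbr_size = nbr.sum(axis=1).astype(float)
    k_alpha = _deg(A, alpha_dir)
    s_alpha = _strength(W, alpha_dir)
    d_beta = _deg(A, beta_dir)
    s_beta = _strength(W, beta_dir)

    with np.errstate(invalid="ignore", divide="ignore"):
        annd = np.where(nbr_size > 0, nbr @ d_beta / nbr_size, np.nan)
        anns = np.where(nbr_size > 0, nbr @ s_beta / nbr_size, np.nan)

    df = pd.DataFrame(
        {"annd": annd, "anns": anns},
        index=pd.Index(network.codes, name="id"),
    )
    mask = k_alpha > 0
    r_deg = _pearson(k_alpha[mask], annd[mask])
    r_str = _pearson(s_alpha[mask], anns[mask])
    return df, r_deg, r_str


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if len(x) < 2 or np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def c4_concentration(network: TradeNetwork) -> np.ndarray:
    """Share of import calories from the four largest suppliers; 0 if none."""
    W = network.weights
    s_in = W.sum(axis=0)
    top4 = np.sort(W, axis=0)[-4:, :].sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        c4 = np.where(s_in > 0, top4 / s_in, 0.0)
    return np.minimum(c4, 1.0)  # guard 1-ulp overshoot of the ratio


def hub_scores(network: TradeNetwork) -> np.ndarray:
    """Principal HITS hub vector of the weighted adjacency (unit 2-norm)."""
    W = network.weights
    # hub vector: principal eigenvector of W W^T; power iteration is exact
    # enough and deterministic
    M = W @ W.T
    v = np.full(network.n, 1.0 / np.sqrt(network.n))
    for _ in range(1000):
        nv = M @ v
        norm = np.linalg.norm(nv)
        if norm == 0:
            return v * 0.0
        nv /= norm
        if np.linalg.norm(nv - v) < 1e-13:
            v = nv
            break
        v = nv
    v = np.abs(v)
    n2 = np.linalg.norm(v)
    return v / n2 if n2 > 0 else v


def node_features(network: TradeNetwork) -> pd.DataFrame:
    """All per-country covariates used by the regression analyses.

    Columns: in_degree, out_degree, in_strength, out_strength, c4,
    clustering, betweenness (raw counts), hub, pagerank, and
    annd_tot / anns_tot (the aggregated-direction nearest-neighbor values).
    """
    g = network.to_networkx()
    und = g.to_undirected()
    A = network.weights > 0

    clustering = nx.clustering(und)  # unweighted, undirected projection
    betweenness = nx.betweenness_centrality(g, normalized=False)
    pagerank = nx.pagerank(g, alpha=0.85, weight="weight")
    tot_df, _, _ = annd_anns(network, "tot", "tot")

    idx = pd.Index(network.codes, name="id")
    return pd.DataFrame(
        {
            "in_degree": A.sum(axis=0),
            "out_degree": A.sum(axis=1),
            "in_strength": network.weights.sum(axis=0),
            "out_strength": network.weights.sum(axis=1),
            "c4": c4_concentration(network),
            "clustering": [clustering[c] for c in network.codes],
            "betweenness": [betweenness[c] for c in network.codes],
            "hub": hub_scores(network),
            "pagerank": [pagerank[c] for c in network.codes],
            "annd_tot": tot_df["annd"].values,
            "anns_tot": tot_df["anns"].values,
        },
        index=idx,
    )


@dataclass(frozen=True)
class TopologySummary:
    """Whole-network summary statistics of the directed trade graph."""

    n_nodes: int
    n_edges: int
    avg_degree: float
    density: float
    avg_link_weight: float
    reciprocity: float
    n_scc: int
    n_wcc: int
    largest_scc: int
    largest_wcc: int
    avg_clustering: float
    transitivity: float
    directed_diameter: float  # NaN when not strongly connected
    avg_shortest_path: float  # directed, over reachable ordered pairs
    undirected_diameter: float  # NaN when disconnected
    undirected_avg_shortest_path: float
    assortativity: dict[str, float]  # {"annd_tot_tot": r, ..., "anns_..."}

    def to_series(self) -> pd.Series:
        d = {
            k: v
            for k, v in self.__dict__.items()
            if k != "assortativity"
        }
        for key, val in self.assortativity.items():
            d[key] = val
        return pd.Series(d, name="value")


def topology_summary(network: TradeNetwork) -> TopologySummary:
    """Compute the full summary suite for a trade network."""
    g = network.to_networkx()
    und = g.to_undirected()
    n = network.n
    m = network.n_edges
    A = network.weights > 0

    recip = float((A & A.T).sum() / m) if m else float("nan")

    sccs = list(nx.strongly_connected_components(g))
    wccs = list(nx.weakly_connected_components(g))

    if nx.is_strongly_connected(g):
        directed_diameter = float(nx.diameter(g))
    else:
        directed_diameter = float("nan")

    # directed average over reachable ordered pairs (excluding self)
    tot, cnt = 0, 0
    for _, lengths in nx.all_pairs_shortest_path_length(g):
        for dist in lengths.values():
            if dist > 0:
                tot += dist
                cnt += 1
    avg_sp = tot / cnt if cnt else float("nan")

    if nx.is_connected(und):
        und_diam = float(nx.diameter(und))
        und_avg = float(nx.average_shortest_path_length(und))
    else:
        und_diam = float("nan")
        und_avg = float("nan")

    assort: dict[str, float] = {}
    for a in _DIRS:
        for b in _DIRS:
            if a == "tot" or b == "tot":
                if not (a == "tot" and b == "tot"):
                    continue
            _, r_deg, r_str = annd_anns(network, a, b)
            assort[f"annd_{a}_{b}"] = r_deg
            assort[f"anns_{a}_{b}"] = r_str

    return TopologySummary(
        n_nodes=n,
        n_edges=m,
        avg_degree=m / n if n else float("nan"),
        density=m / (n * (n - 1)) if n > 1 else float("nan"),
        avg_link_weight=float(network.weights.sum() / m) if m else float("nan"),
        reciprocity=recip,
        n_scc=len(sccs),
        n_wcc=len(wccs),
        largest_scc=max((len(c) for c in sccs), default=0),
        largest_wcc=max((len(c) for c in wccs), default=0),
        avg_clustering=float(nx.average_clustering(und)),
        transitivity=float(nx.transitivity(und)),
        directed_diameter=directed_diameter,
        avg_shortest_path=avg_sp,
        undirected_diameter=und_diam,
        undirected_avg_shortest_path=und_avg,
        assortativity=assort,
    )
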