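"""Functional metagenomic networks (FMNs).

Merged taxon + metabolite feature matrices are correlated pairwise (Pearson),
thresholded at |r| > 0.7 into a signed co-occurrence graph, partitioned into
functional metagenomic communities (FMCs) by Louvain modularity maximization
(resolution 1, |r| edge weights, best of several seeded restarts), and
summarized into the descriptor record used to compare cohorts: node/edge
counts, synergistic (r > 0) vs competitive (r < 0) interaction counts and
ratio, density, modularity, and the top-k keystone features by (unnormalized)
betweenness centrality.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Literal

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import calinski_harabasz_score, silhouette_score

from fmnet._utils import child_seeds, write_table
from fmnet.abundance import AbundanceTable
from fmnet.nmr_preprocessing import NmrBucketMatrix


@dataclass
class MergedFeatureMatrix:
    """Column-concatenated taxon + metabolite matrix over shared samples."""

    df: pd.DataFrame
    feature_meta: pd.DataFrame  # index = feature ids; columns: kind, mean_rel_abund
    standardized: bool = False

    def __post_init__(self) -> None:
        if list(self.df.columns) != list(self.feature_meta.index):
            raise ValueError("feature_meta must be indexed by the matrix columns")
        if self.df.columns.has_duplicates:
            raise ValueError("duplicate feature ids")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.df.columns)


@dataclass
class CorrelationNetwork:
    """Thresholded signed Pearson co-occurrence graph.

    ``graph`` is an undirected :class:`networkx.Graph`; nodes carry ``kind``,
    ``mean_rel_abund``, and (after :func:`node_metrics`) ``degree`` and
    ``betweenness``; edges carry ``r``, ``sign`` (``synergistic`` for r > 0,
    ``competitive`` for r < 0) and ``cooccurrence`` (number of samples where
    both features are non-zero).
    """

    graph: nx.Graph
    threshold: float

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_signs(self) -> tuple[int, int]:
        syn = sum(1 for *_, d in self.graph.edges(data=True) if d["r"] > 0)
        return syn, self.n_edges - syn


@dataclass
class FmcPartition:
    """A community assignment with its weighted modularity."""

    community_of: dict[str, int]
    modularity: float
    resolution: float
    seed: int
    n_restarts: int

    @property
    def n_communities(self) -> int:
        return len(set(self.community_of.values()))


@dataclass
class NetworkSummary:
    """Cohort-level FMN descriptors (density, syn/com ratio, keystones, ...)."""

    n_nodes: int
    n_edges: int
    n_synergistic: int
    n_competitive: int
    pct_synergistic: float
    pct_competitive: float
    syn_com_ratio: float | None
    density: float
    modularity: float | None
    n_communities: int | None
    keystone_features: list[dict] = field(default_factory=list)
    keystone_taxa: list[dict] = field(default_factory=list)
    keystone_metabolites: list[dict] = field(default_factory=list)

    @classmethod
    def from_counts(
        cls,
        n_nodes: int,
        n_edges: int,
        n_synergistic: int,
        n_competitive: int,
        modularity: float | None = None,
        density_decimals: int = 3,
        ratio_decimals: int = 2,
    ) -> "NetworkSummary":
        """Descriptor arithmetic from raw counts (the Table-style rows)."""
        if n_nodes < 2:
            raise ValueError("need at least 2 nodes")
        if n_synergistic + n_competitive != n_edges:
            raise ValueError("edge sign counts must sum to n_edges")
        density = round(2 * n_edges / (n_nodes * (n_nodes - 1)), density_decimals)
        pct_syn = round(100 * n_synergistic / n_edges, 1) if n_edges else 0.0
        pct_com = round(100 * n_competitive / n_edges, 1) if n_edges else 0.0
        ratio = (
            round(n_synergistic / n_competitive, ratio_decimals) if n_competitive else None
        )
        return cls(
            n_nodes=n_nodes,
            n_edges=n_edges,
            n_synergistic=n_synergistic,
            n_competitive=n_competitive,
            pct_synergistic=pct_syn,
            pct_competitive=pct_com,
            syn_com_ratio=ratio,
            density=density,
            modularity=modularity,
            n_communities=None,
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    def to_table(self) -> pd.DataFrame:
        rows = {
            "Nodes": self.n_nodes,
            "Edges": self.n_edges,
            "Synergistic interactions (%)": f"{self.n_synergistic} ({self.pct_synergistic})",
            "Competitive interactions (%)": f"{self.n_competitive} ({self.pct_competitive})",
            "Syn/Com ratio": self.syn_com_ratio,
            "Density": self.density,
            "Modularity": self.modularity,
        }
        return pd.DataFrame({"value": rows})


def merge_features(
    taxa: AbundanceTable,
    metabolites: NmrBucketMatrix | pd.DataFrame,
) -> MergedFeatureMatrix:
    """Column-concatenate a relative taxa table with a metabolite matrix.

    Samples are intersected (with a warning when the sets differ); taxon
    features carry their mean relative abundance for keystone reporting.
    """
    if taxa.kind != "relative":
        raise ValueError("merge_features expects a relative taxa table")
    met_df = metabolites.df if isinstance(metabolites, NmrBucketMatrix) else metabolites
    shared = [s for s in taxa.sample_ids if s in set(met_df.index)]
    if not shared:
        raise ValueError("no shared samples between taxa and metabolite tables")
    if len(shared) < len(taxa.sample_ids) or len(shared) < len(met_df.index):
        warnings.warn(
            f"sample sets differ; keeping the {len(shared)} shared samples",
            stacklevel=2,
        )
    t, m = taxa.df.loc[shared], met_df.loc[shared]
    df = pd.concat([t, m], axis=1)
    meta = pd.DataFrame(
        {
            "kind": ["taxon"] * t.shape[1] + ["metabolite"] * m.shape[1],
            "mean_rel_abund": list(t.mean(axis=0)) + [np.nan] * m.shape[1],
        },
        index=list(t.columns) + list(m.columns),
    )
    return MergedFeatureMatrix(df, meta)


def pearson_matrix(features: MergedFeatureMatrix) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All-pairs Pearson r with two-sided t-distribution p-values (n-2 df).

    Constant features yield NaN rows/columns (flagged with a warning); the
    diagonal is r = 1, p = 0.
    """
    x = features.df.to_numpy(dtype=float)
    n, m = x.shape
    if n < 3:
        raise ValueError("need at least 3 samples for correlation")
    sd = x.std(axis=0)
    const = sd == 0
    if const.any():
        warnings.warn(
            f"constant features have undefined correlations: "
            f"{list(features.df.columns[const])}",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x, rowvar=False)
    r = np.asarray(r, dtype=float)
    r[const, :] = np.nan
    r[:, const] = np.nan
    np.fill_diagonal(r, np.where(const, np.nan, 1.0))
    rc = np.clip(r, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = rc * np.sqrt((n - 2) / (1 - rc**2))
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isclose(np.abs(rc), 1.0), 0.0, p)
    np.fill_diagonal(p, np.where(const, np.nan, 0.0))
    ids = features.feature_ids
    return (
        pd.DataFrame(r, index=ids, columns=ids),
        pd.DataFrame(p, index=ids, columns=ids),
    )


def build_network(
    R: pd.DataFrame,
    features: MergedFeatureMatrix,
    threshold: float = 0.7,
    P: pd.DataFrame | None = None,
    p_max: float | None = None,
) -> CorrelationNetwork:
    """Threshold the correlation matrix into a signed co-occurrence graph.

    An edge joins every unordered pair with r > threshold or r < -threshold
    (strict inequalities). Undefined (NaN) correlations never create edges;
    isolated nodes are retained. An optional p-value ceiling can additionally
    be applied.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    ids = list(R.index)
    vals = R.to_numpy(dtype=float)
    if vals.shape[0] != vals.shape[1] or not np.allclose(
        np.nan_to_num(vals), np.nan_to_num(vals.T), atol=1e-12
    ):
        raise ValueError("R must be symmetric")
    g = nx.Graph()
    meta = features.feature_meta
    x = features.df.to_numpy(dtype=float)
    nz = x != 0
    for f in ids:
        g.add_node(
            f,
            kind=str(meta.loc[f, "kind"]),
            mean_rel_abund=float(meta.loc[f, "mean_rel_abund"])
            if np.isfinite(meta.loc[f, "mean_rel_abund"])
            else float("nan"),
        )
    colpos = {f: i for i, f in enumerate(features.feature_ids)}
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            r = vals[i, j]
            if not np.isfinite(r) or abs(r) <= threshold:
                continue
            if p_max is not None and P is not None and not P.iloc[i, j] <= p_max:
                continue
            cooc = int(np.sum(nz[:, colpos[ids[i]]] & nz[:, colpos[ids[j]]]))
            g.add_edge(
                ids[i],
                ids[j],
                r=float(r),
                weight=float(abs(r)),
                sign="synergistic" if r > 0 else "competitive",
                cooccurrence=cooc,
            )
    return CorrelationNetwork(g, threshold)


def node_metrics(net: CorrelationNetwork) -> CorrelationNetwork:
    """Annotate nodes with degree and unnormalized Brandes betweenness.

    Betweenness is computed on the unweighted thresholded graph and counts
    unordered source-target pairs, matching the convention in which a path
    centre A-B-C scores 1 and a 4-leaf star centre scores 6.
    """
    bc = nx.betweenness_centrality(net.graph, normalized=False)
    for v in net.graph.nodes:
        net.graph.nodes[v]["degree"] = net.graph.degree[v]
        net.graph.nodes[v]["betweenness"] = float(bc[v])
    return net


def detect_fmcs(
    net: CorrelationNetwork,
    resolution: float = 1.0,
    seed: int = 0,
    n_restarts: int = 20,
) -> FmcPartition:
    """Louvain community detection with |r| weights, best of ``n_restarts``.

    Node visit order is randomized per restart from seeds derived from
    ``seed``; the partition with the highest weighted modularity
    Q = (1/2m) sum_ij [w_ij - gamma k_i k_j / 2m] delta(c_i, c_j) is kept.
    Community labels are relabelled contiguously from 0, largest first.
    """
    if net.n_edges == 0:
        raise ValueError("cannot detect communities in an edgeless network")
    g = net.graph
    best_q, best_parts = -np.inf, None
    for s in child_seeds(seed, n_restarts):
        parts = nx.community.louvain_communities(
            g, weight="weight", resolution=resolution, seed=int(s)
        )
        q = nx.community.modularity(g, parts, weight="weight", resolution=resolution)
        if q > best_q:
            best_q, best_parts = q, parts
    ordered = sorted(best_parts, key=lambda c: (-len(c), sorted(c)[0]))
    community_of = {v: i for i, comm in enumerate(ordered) for v in comm}
    return FmcPartition(
        community_of=community_of,
        modularity=float(best_q),
        resolution=resolution,
        seed=seed,
        n_restarts=n_restarts,
    )


def _keystones(nodes: list[tuple], k: int) -> list[dict]:
    ranked = sorted(
        nodes,
        key=lambda t: (
            -t[1],
            -(t[3] if np.isfinite(t[3]) else -np.inf),
            t[0],
        ),
    )
    return [
        {
            "id": f,
            "betweenness": bc,
            "community": comm,
            "mean_rel_abund": mra if np.isfinite(mra) else None,
        }
        for f, bc, comm, mra in ranked[:k]
    ]


def network_summary(
    net: CorrelationNetwork,
    partition: FmcPartition | None = None,
    keystone_k: int = 5,
    density_decimals: int = 3,
    ratio_decimals: int = 2,
    modularity_decimals: int = 3,
) -> NetworkSummary:
    """Assemble the cohort descriptor record from a metric-annotated network.

    Keystones are the top-``keystone_k`` nodes by betweenness (ties broken by
    higher mean relative abundance, then lexical id), reported jointly and
    within the taxon / metabolite pools separately.
    """
    if net.n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    syn, com = net.edge_signs()
    summary = NetworkSummary.from_counts(
        net.n_nodes,
        net.n_edges,
        syn,
        com,
        modularity=(
            round(partition.modularity, modularity_decimals) if partition else None
        ),
        density_decimals=density_decimals,
        ratio_decimals=ratio_decimals,
    )
    summary.n_communities = partition.n_communities if partition else None
    rows = []
    for v, d in net.graph.nodes(data=True):
        if "betweenness" not in d:
            raise ValueError("run node_metrics before network_summary")
        comm = partition.community_of.get(v) if partition else None
        rows.append((v, d["betweenness"], comm, d.get("mean_rel_abund", np.nan), d["kind"]))
    summary.keystone_features = _keystones([r[:4] for r in rows], keystone_k)
    summary.keystone_taxa = _keystones([r[:4] for r in rows if r[4] == "taxon"], keystone_k)
    summary.keystone_metabolites = _keystones(
        [r[:4] for r in rows if r[4] == "metabolite"], keystone_k
    )
    return summary


def validate_partition(R: pd.DataFrame, partition: FmcPartition) -> dict[str, float]:
    """Silhouette (on the 1 - r distance) and Calinski-Harabasz scores.

    Features are embedded as their correlation profiles (rows of R) for the
    variance-ratio score; the silhouette uses the correlation distance
    directly.
    """
    labels = np.asarray([partition.community_of[f] for f in R.index])
    if len(set(labels.tolist())) < 2:
        raise ValueError("validation needs at least 2 communities")
    vals = R.to_numpy(dtype=float)
    d = np.clip(1.0 - np.nan_to_num(vals, nan=0.0), 0.0, 2.0)
    np.fill_diagonal(d, 0.0)
    sil = float(silhouette_score((d + d.T) / 2, labels, metric="precomputed"))
    ch = float(calinski_harabasz_score(np.nan_to_num(vals, nan=0.0), labels))
    return {"silhouette": sil, "calinski_harabasz": ch}


ExportFormat = Literal["graphml", "gexf", "edge-tsv"]


def export_network(
    net: CorrelationNetwork,
    partition: FmcPartition | None,
    path,
    format: ExportFormat = "graphml",
) -> None:
    """Write the network with node/edge attributes; see :func:`read_network`."""
    g = net.graph.copy()
    for v in g.nodes:
        comm = partition.community_of.get(v) if partition else None
        if comm is not None:
            g.nodes[v]["community"] = int(comm)
        if not np.isfinite(g.nodes[v].get("mean_rel_abund", np.nan)):
            g.nodes[v].pop("mean_rel_abund", None)
    g.graph["threshold"] = net.threshold
    if format == "graphml":
        nx.write_graphml(g, path)
    elif format == "gexf":
        nx.write_gexf(g, path)
    elif format == "edge-tsv":
        rows = [
            {"source": u, "target": v, "r": d["r"], "sign": d["sign"],
             "cooccurrence": d["cooccurrence"]}
            for u, v, d in g.edges(data=True)
        ]
        write_table(pd.DataFrame(rows).set_index("source"), path)
    else:
        raise ValueError(f"unknown export format {format!r}")


def read_network(path, format: ExportFormat = "graphml") -> CorrelationNetwork:
    """Read a network written by :func:`export_network` (graphml/gexf only)."""
    if format == "graphml":
        g = nx.read_graphml(path)
    elif format == "gexf":
        g = nx.read_gexf(path)
    else:
        raise ValueError(f"cannot round-trip format {format!r}")
    g = nx.Graph(g)
    for _, _, d in g.edges(data=True):
        d.pop("id", None)
    return CorrelationNetwork(g, float(g.graph.get("threshold", 0.7)))
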