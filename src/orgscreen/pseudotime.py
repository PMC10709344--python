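"""Centroid-MST trajectory inference over the heterogeneity map.

Cluster centroids in the 2-D embedding are joined by a minimum spanning
tree (Euclidean edge weights). Clusters representing discrete end states
(resistant, sensitive, invasive) can be *forced* to be terminal: the MST is
built over the remaining clusters first and each terminal is then attached
as a leaf to its nearest non-terminal centroid, guaranteeing degree 1.

Each observation is mapped onto the closest MST edge (orthogonal projection
clamped to the segment; ties broken by lowest edge id). For every
root-to-leaf path — the root being the baseline-enriched cluster — the
pseudotime of an observation projecting onto a path edge is the arc
distance from the root centroid to its projection; observations on
off-path edges are undefined for that path. The *common pseudotime*
averages an observation's defined path values. Treatment-arm density along
a chosen terminal path is estimated by a Gaussian kernel with a shared
bandwidth so arms are comparable, together with each arm's mass (fraction
of its observations projecting onto the path).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .errors import DataError

logger = logging.getLogger(__name__)

__all__ = [
    "TrajectoryModel",
    "centroid_mst",
    "project_to_mst",
    "pseudotime_vectors",
    "density_along_path",
    "infer_trajectory",
]


@dataclass
class TrajectoryModel:
    """Centroid MST plus (optionally) projections and pseudotime vectors."""

    centroids: dict[int, np.ndarray]
    tree: nx.Graph  # nodes = cluster ids; edges carry 'length' and 'edge_id'
    edges: list[tuple[int, int]]  # edge_id -> (u, v)
    terminals: tuple[int, ...] = ()
    root: int | None = None
    projections: pd.DataFrame | None = None
    paths: dict[int, list[int]] = field(default_factory=dict)  # leaf -> node path
    pseudotime: pd.DataFrame | None = None  # per-path columns + 'common'


def centroid_mst(labels, coords, terminals: tuple[int, ...] = ()) -> TrajectoryModel:
    """Build the (terminal-forced) MST over cluster centroids.

    ``terminals`` are attached as leaves to their nearest non-terminal
    centroid after the MST over the non-terminal clusters is built, so each
    terminal ends a path by construction.
    """
    labels = np.asarray(labels)
    coords = np.asarray(coords, dtype=float)
    clusters = sorted(int(c) for c in np.unique(labels))
    if len(clusters) < 2:
        raise DataError("need >= 2 clusters for a trajectory")
    unknown = set(terminals) - set(clusters)
    if unknown:
        raise DataError(f"terminal cluster(s) not present: {sorted(unknown)}")
    interior = [c for c in clusters if c not in terminals]
    if not interior:
        raise DataError("all clusters designated terminal; MST needs >= 1 interior cluster")

    centroids = {c: coords[labels == c].mean(axis=0) for c in clusters}

    complete = nx.Graph()
    complete.add_nodes_from(interior)
    for i, u in enumerate(interior):
        for v in interior[i + 1:]:
            complete.add_edge(u, v, length=float(np.linalg.norm(centroids[u] - centroids[v])))
    tree = nx.minimum_spanning_tree(complete, weight="length")

    for t in terminals:
        nearest = min(interior, key=lambda c: np.linalg.norm(centroids[t] - centroids[c]))
        tree.add_edge(t, nearest, length=float(np.linalg.norm(centroids[t] - centroids[nearest])))

    edges = sorted((min(u, v), max(u, v)) for u, v in tree.edges)
    for eid, (u, v) in enumerate(edges):
        tree.edges[u, v]["edge_id"] = eid
    return TrajectoryModel(
        centroids=centroids, tree=tree, edges=edges, terminals=tuple(terminals)
    )


def project_to_mst(coords, model: TrajectoryModel) -> pd.DataFrame:
    """Map each observation to its closest MST edge.

    Returns a table with edge_id, the edge endpoints, the arc position
    ``s`` in [0, 1] from the lower-id endpoint, and the projection
    distance. Equidistant edges resolve to the lowest edge id.
    """
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    best_dist = np.full(n, np.inf)
    best_edge = np.full(n, -1, dtype=int)
    best_s = np.zeros(n)
    for eid, (u, v) in enumerate(model.edges):
        a, b = model.centroids[u], model.centroids[v]
        ab = b - a
        denom = float(ab @ ab)
        s = np.clip((coords - a) @ ab / denom, 0.0, 1.0) if denom > 0 else np.zeros(n)
        proj = a + s[:, None] * ab
        dist = np.linalg.norm(coords - proj, axis=1)
        better = dist < best_dist - 1e-12  # strict: ties keep the earlier edge id
        best_dist[better] = dist[better]
        best_edge[better] = eid
        best_s[better] = s[better]
    return pd.DataFrame({
        "edge_id": best_edge,
        "u": [model.edges[e][0] for e in best_edge],
        "v": [model.edges[e][1] for e in best_edge],
        "s": best_s,
        "proj_dist": best_dist,
    })


def pseudotime_vectors(model: TrajectoryModel, root: int) -> pd.DataFrame:
    """Per-path and common pseudotime for projected observations.

    Requires ``model.projections`` (see :func:`project_to_mst`). Returns a
    table with one ``path_to_<leaf>`` column per root→leaf path (NaN for
    observations projecting to off-path edges) and a ``common`` column
    averaging the defined values.
    """
    if model.projections is None:
        raise DataError("projections missing; call project_to_mst first")
    if root not in model.tree:
        raise DataError(f"root cluster {root} not in the tree")
    model.root = root
    leaves = [c for c in model.tree.nodes if model.tree.degree(c) == 1 and c != root]
    if not leaves:
        raise DataError("tree has no leaf distinct from the root")

    proj = model.projections
    out = {}
    model.paths = {}
    for leaf in sorted(leaves):
        path = nx.shortest_path(model.tree, root, leaf)
        model.paths[leaf] = path
        # cumulative distance from the root to each node on the path
        dist_to = {path[0]: 0.0}
        for a, b in zip(path, path[1:]):
            dist_to[b] = dist_to[a] + model.tree.edges[a, b]["length"]
        path_edges = {(min(a, b), max(a, b)) for a, b in zip(path, path[1:])}
        pt = np.full(len(proj), np.nan)
        for i, (eid, s) in enumerate(zip(proj["edge_id"], proj["s"])):
            u, v = model.edges[eid]
            if (u, v) not in path_edges:
                continue
            length = model.tree.edges[u, v]["length"]
            # s measures from u (the lower-id endpoint); orient along the path
            if dist_to[u] <= dist_to[v]:
                pt[i] = dist_to[u] + s * length
            else:
                pt[i] = dist_to[v] + (1.0 - s) * length
        out[f"path_to_{leaf}"] = pt
    table = pd.DataFrame(out)
    table["common"] = table.mean(axis=1, skipna=True)
    model.pseudotime = table
    return table


def density_along_path(
    path_pseudotime, arms, *, grid_size: int = 200, min_per_arm: int = 2
) -> pd.DataFrame:
    """Per-arm Gaussian kernel density over one path's pseudotime.

    ``path_pseudotime`` is a path column from :func:`pseudotime_vectors`
    (NaN = off-path). A single bandwidth — Scott's rule on the pooled
    on-path values — is shared across arms so densities are comparable.
    Returns a long table (arm, pseudotime grid, density, mass) where
    ``mass`` is the fraction of the arm's observations on the path; arms
    with fewer than ``min_per_arm`` on-path observations are omitted with a
    warning.
    """
    pt = np.asarray(path_pseudotime, dtype=float)
    arms = np.asarray(arms)
    if len(pt) != len(arms):
        raise DataError("pseudotime and arm labels are not aligned")
    on_path = np.isfinite(pt)
    pooled = pt[on_path]
    if len(pooled) < 2:
        raise DataError("fewer than 2 on-path observations")
    grid = np.linspace(pooled.min(), pooled.max(), grid_size)
    pooled_std = pooled.std(ddof=1)
    bandwidth = max(pooled_std, 1e-9) * len(pooled) ** (-1 / 5)  # Scott's rule

    records = []
    for arm in pd.unique(arms):
        mask = arms == arm
        values = pt[mask & on_path]
        mass = len(values) / mask.sum()
        if len(values) < min_per_arm:
            logger.warning("arm %r has %d on-path observations; omitted", arm, len(values))
            continue
        std = values.std(ddof=1)
        if std > 0:
            kde = gaussian_kde(values, bw_method=bandwidth / std)
            density = kde(grid)
        else:  # degenerate arm: all mass at one point
            density = np.zeros_like(grid)
            density[np.argmin(np.abs(grid - values[0]))] = 1.0
        records.append(pd.DataFrame({
            "arm": arm, "pseudotime": grid, "density": density, "mass": mass,
        }))
    if not records:
        raise DataError("no arm has enough on-path observations")
    return pd.concat(records, ignore_index=True)


def terminal_mass(model: TrajectoryModel, leaf: int, arms) -> pd.Series:
    """Per-arm fraction of observations projecting onto a leaf's terminal edge.

    The edge incident to a (forced) terminal leaf is unique to that leaf's
    trajectory — unlike the path's trunk, which is shared with other
    trajectories — so this mass isolates how much of each arm has moved
    into the terminal state.
    """
    if model.projections is None:
        raise DataError("projections missing; call project_to_mst first")
    if model.tree.degree(leaf) != 1:
        raise DataError(f"cluster {leaf} is not a leaf of the MST")
    neighbor = next(iter(model.tree[leaf]))
    eid = model.tree.edges[leaf, neighbor]["edge_id"]
    arms = np.asarray(arms)
    on_edge = model.projections["edge_id"].to_numpy() == eid
    return pd.Series(
        {arm: float(on_edge[arms == arm].mean()) for arm in pd.unique(arms)},
        name="terminal_mass",
    )


def infer_trajectory(
    labels, coords, root: int, terminals: tuple[int, ...] = ()
) -> TrajectoryModel:
    """Convenience: MST, projections and pseudotime in one call."""
    model = centroid_mst(labels, coords, terminals=terminals)
    model.projections = project_to_mst(coords, model)
    pseudotime_vectors(model, root)
    return model
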