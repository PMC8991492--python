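"""Outlet accessibility around schools on a road network.

Distances are shortest paths along road edges (never less than the
straight-line distance).  The per-company indicator is the proportion of
outlets within a radius of the nearest school entrance of a given level;
outlets that cannot reach any school count as beyond the radius.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "GeoScene",
    "AccessResult",
    "AccessibilityError",
    "outlets_near_schools",
    "accessibility_table",
    "load_scene",
]

SCHOOL_LEVELS = ("primary", "secondary")

#: companies with fewer outlets are flagged in the accessibility table
MIN_OUTLETS = 3


class AccessibilityError(ValueError):
    pass


@dataclass
class GeoScene:
    """Road graph plus outlet and school locations snapped to nodes."""

    graph: nx.Graph
    outlets: pd.DataFrame  # company_id, node_id
    schools: pd.DataFrame  # school_id, level, node_id

    def __post_init__(self):
        pos = {n: (d["x"], d["y"]) for n, d in self.graph.nodes(data=True)}
        for u, v, data in self.graph.edges(data=True):
            length = data.get("length")
            if length is None or length <= 0:
                raise AccessibilityError(f"edge ({u}, {v}): non-positive length")
            dx = pos[u][0] - pos[v][0]
            dy = pos[u][1] - pos[v][1]
            if length < np.hypot(dx, dy) - 1e-9:
                raise AccessibilityError(f"edge ({u}, {v}): length below Euclidean distance")
        for frame, name in ((self.outlets, "outlet"), (self.schools, "school")):
            unknown = set(frame["node_id"]) - set(self.graph.nodes)
            if unknown:
                raise AccessibilityError(f"{name} references unknown node {sorted(unknown)[0]!r}")
        bad = set(self.schools["level"].unique()) - set(SCHOOL_LEVELS)
        if bad:
            raise AccessibilityError(f"unknown school level {sorted(bad)[0]!r}")
        self.n_components = nx.number_connected_components(self.graph)


@dataclass(frozen=True)
class AccessResult:
    company_id: str
    level: str
    radius_m: float
    n_outlets: int
    n_within: int
    proportion: float
    distances: pd.DataFrame  # node_id, distance_m (inf when unreachable)


def _school_distances(scene: GeoScene, level: str) -> dict:
    sources = set(scene.schools.loc[scene.schools["level"] == level, "node_id"])
    if not sources:
        raise AccessibilityError(f"no schools of level '{level}' in scene")
    return nx.multi_source_dijkstra_path_length(scene.graph, sources, weight="length")


def outlets_near_schools(
    scene: GeoScene,
    company_id: str,
    level: str,
    radius_m: float = 500.0,
) -> AccessResult:
    """Proportion of a company's outlets within ``radius_m`` of the
    nearest school of ``level``, plus per-outlet network distances."""
    if radius_m <= 0:
        raise AccessibilityError("radius_m must be positive")
    if level not in SCHOOL_LEVELS:
        raise AccessibilityError(f"unknown school level '{level}'")
    outlets = scene.outlets[scene.outlets["company_id"] == company_id]
    if outlets.empty:
        raise AccessibilityError(f"company '{company_id}' has no outlets in scene")
    dist_map = _school_distances(scene, level)
    distances = np.array([dist_map.get(n, np.inf) for n in outlets["node_id"]], float)
    if np.isinf(distances).any():
        warnings.warn(
            f"company '{company_id}': {int(np.isinf(distances).sum())} outlet(s) cannot reach "
            f"any {level} school; counted as beyond radius",
            stacklevel=2,
        )
    within = int((distances <= radius_m).sum())
    return AccessResult(
        company_id=company_id,
        level=level,
        radius_m=float(radius_m),
        n_outlets=len(outlets),
        n_within=within,
        proportion=within / len(outlets),
        distances=pd.DataFrame(
            {"node_id": outlets["node_id"].to_numpy(), "distance_m": distances}
        ),
    )


def accessibility_table(
    scene: GeoScene,
    radius_m: float = 500.0,
    min_outlets: int = MIN_OUTLETS,
) -> pd.DataFrame:
    """Company x school-level proportions for every outlet company.

    Companies with fewer than ``min_outlets`` outlets keep their row but
    are flagged (``below_min_outlets``), mirroring exclusion from the
    reported results.
    """
    levels = [lvl for lvl in SCHOOL_LEVELS if (scene.schools["level"] == lvl).any()]
    rows = []
    for cid in sorted(scene.outlets["company_id"].astype(str).unique()):
        for level in levels:
            res = outlets_near_schools(scene, cid, level, radius_m)
            rows.append(
                dict(
                    company_id=cid,
                    level=level,
                    radius_m=res.radius_m,
                    n_outlets=res.n_outlets,
                    n_within=res.n_within,
                    proportion=res.proportion,
                    below_min_outlets=res.n_outlets < min_outlets,
                )
            )
    return pd.DataFrame(rows)


def load_scene(nodes: pd.DataFrame, edges: pd.DataFrame, points: pd.DataFrame) -> GeoScene:
    """Assemble a scene from the ``geo_nodes/geo_edges/geo_points`` frames."""
    for frame, cols, name in (
        (nodes, {"node_id", "x", "y"}, "geo_nodes"),
        (edges, {"u", "v", "length_m"}, "geo_edges"),
        (points, {"kind", "point_id", "node_id"}, "geo_points"),
    ):
        missing = cols - set(frame.columns)
        if missing:
            raise AccessibilityError(f"{name}: missing column(s) {sorted(missing)}")
    graph = nx.Graph()
    for r in nodes.itertuples():
        graph.add_node(str(r.node_id), x=float(r.x), y=float(r.y))
    for r in edges.itertuples():
        graph.add_edge(str(r.u), str(r.v), length=float(r.length_m))
    outlets = points[points["kind"] == "outlet"]
    schools = points[points["kind"] == "school"]
    return GeoScene(
        graph=graph,
        outlets=pd.DataFrame(
            {
                "company_id": outlets["company_id"].astype(str).to_numpy(),
                "node_id": outlets["node_id"].astype(str).to_numpy(),
            }
        ),
        schools=pd.DataFrame(
            {
                "school_id": schools["point_id"].astype(str).to_numpy(),
                "level": schools["level"].astype(str).to_numpy(),
                "node_id": schools["node_id"].astype(str).to_numpy(),
            }
        ),
    )
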