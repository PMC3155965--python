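"""Road-network distances to the nearest health facility.

Respondent-level geographic access is measured as the shortest-path road
distance (Dijkstra on an undirected weighted graph) from each respondent to
the nearest facility of each type: GP surgery, hospital, and hospital with an
Emergency Department (ED).  ED hospitals are a subset of hospitals, so for
every respondent ``dist_hospital <= dist_ed``.

Points are attached to the network by snapping to the nearest node
(Euclidean).  Distances are reported in kilometres with full precision
because downstream regressions interpret coefficients per extra km.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "RoadGraph",
    "FacilitySet",
    "DistanceTable",
    "build_graph",
    "snap_to_network",
    "shortest_path_distance",
    "nearest_facility_distances",
]

FACILITY_TYPES = ("GP", "hospital", "hospital_ED")


@dataclass
class RoadGraph:
    """Undirected weighted road graph.

    Wraps a :class:`networkx.Graph` whose nodes carry ``u``/``v`` coordinates
    (metres) and whose edges carry a strictly positive ``length_m``.
    """

    graph: nx.Graph

    def __post_init__(self) -> None:
        for node, data in self.graph.nodes(data=True):
            if "u" not in data or "v" not in data:
                raise ValueError(f"node {node!r} missing coordinates")
            if not (math.isfinite(data["u"]) and math.isfinite(data["v"])):
                raise ValueError(f"node {node!r} has non-finite coordinates")
        for a, b, data in self.graph.edges(data=True):
            if a == b:
                raise ValueError(f"self-loop on node {a!r}")
            length = data.get("length_m")
            if length is None or not math.isfinite(length) or length <= 0:
                raise ValueError(
                    f"edge ({a!r}, {b!r}) has invalid length {length!r}; "
                    "lengths must be finite and > 0"
                )

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def node_coordinates(self) -> tuple[list, np.ndarray]:
        """Node ids (sorted) and an (n, 2) coordinate array in the same order."""
        ids = sorted(self.graph.nodes)
        coords = np.array(
            [[self.graph.nodes[i]["u"], self.graph.nodes[i]["v"]] for i in ids],
            dtype=float,
        ).reshape(-1, 2)
        return ids, coords

    def connectivity_report(self) -> dict:
        comps = list(nx.connected_components(self.graph))
        return {
            "n_components": len(comps),
            "largest_component_size": max((len(c) for c in comps), default=0),
        }

    # -- IO -----------------------------------------------------------------

    def to_csv(self, edge_path, node_path) -> None:
        ids, coords = self.node_coordinates()
        pd.DataFrame({"node_id": ids, "u": coords[:, 0], "v": coords[:, 1]}).to_csv(
            node_path, index=False
        )
        rows = [
            {"node_a": a, "node_b": b, "length_m": d["length_m"]}
            for a, b, d in self.graph.edges(data=True)
        ]
        pd.DataFrame(rows, columns=["node_a", "node_b", "length_m"]).to_csv(
            edge_path, index=False
        )

    @classmethod
    def from_csv(cls, edge_path, node_path) -> "RoadGraph":
        edges = pd.read_csv(edge_path, dtype={"node_a": str, "node_b": str})
        nodes = pd.read_csv(node_path, dtype={"node_id": str})
        return build_graph(
            edges.to_dict("records"), nodes.to_dict("records")
        )

    def to_geojson(self, path) -> None:
        feats = []
        for a, b, d in self.graph.edges(data=True):
            na, nb = self.graph.nodes[a], self.graph.nodes[b]
            feats.append(
                {
                    "type": "Feature",
                    "geometry": {
                        "type": "LineString",
                        "coordinates": [[na["u"], na["v"]], [nb["u"], nb["v"]]],
                    },
                    "properties": {"node_a": a, "node_b": b, "length_m": d["length_m"]},
                }
            )
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": feats}, fh)

    @classmethod
    def from_geojson(cls, path) -> "RoadGraph":
        """Read LineString features; ``length_m`` is computed from the
        geometry when the property is absent.  Endpoints become nodes keyed by
        their rounded coordinates."""
        with open(path) as fh:
            fc = json.load(fh)
        nodes: dict[str, dict] = {}
        edge_records = []

        def node_id(x, y):
            key = f"{x:.3f}_{y:.3f}"
            nodes.setdefault(key, {"node_id": key, "u": x, "v": y})
            return key

        for feat in fc["features"]:
            geom = feat["geometry"]
            if geom["type"] != "LineString":
                continue
            coords = geom["coordinates"]
            props = feat.get("properties") or {}
            for (x0, y0), (x1, y1) in zip(coords[:-1], coords[1:]):
                seg_len = math.hypot(x1 - x0, y1 - y0)
                if len(coords) == 2 and props.get("length_m") is not None:
                    seg_len = float(props["length_m"])
                edge_records.append(
                    {
                        "node_a": node_id(x0, y0),
                        "node_b": node_id(x1, y1),
                        "length_m": seg_len,
                    }
                )
        return build_graph(edge_records, list(nodes.values()))


@dataclass
class FacilitySet:
    """Health facilities keyed by id.

    ``facilities`` maps id -> dict with ``u``, ``v`` (metres) and ``type`` in
    ``{"GP", "hospital", "hospital_ED"}``.  An ED hospital also counts as a
    hospital for nearest-hospital queries.
    """

    facilities: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for fid, f in self.facilities.items():
            if f["type"] not in FACILITY_TYPES:
                raise ValueError(
                    f"facility {fid!r} has unknown type {f['type']!r}; "
                    f"expected one of {FACILITY_TYPES}"
                )
            if not (math.isfinite(f["u"]) and math.isfinite(f["v"])):
                raise ValueError(f"facility {fid!r} has non-finite coordinates")

    def of_type(self, ftype: str) -> dict[str, dict]:
        """Facilities matching a queried type; hospital queries include ED
        hospitals."""
        if ftype == "hospital":
            accepted = {"hospital", "hospital_ED"}
        else:
            accepted = {ftype}
        return {
            fid: f for fid, f in self.facilities.items() if f["type"] in accepted
        }

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {"id": fid, "u": f["u"], "v": f["v"], "type": f["type"]}
            for fid, f in sorted(self.facilities.items())
        ]
        return pd.DataFrame(rows, columns=["id", "u", "v", "type"])

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FacilitySet":
        df = pd.read_csv(path, dtype={"id": str})
        return cls(
            {
                str(r.id): {"u": float(r.u), "v": float(r.v), "type": str(r.type)}
                for r in df.itertuples()
            }
        )

    def to_geojson(self, path) -> None:
        feats = [
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [f["u"], f["v"]]},
                "properties": {"id": fid, "type": f["type"]},
            }
            for fid, f in sorted(self.facilities.items())
        ]
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": feats}, fh)

    @classmethod
    def from_geojson(cls, path) -> "FacilitySet":
        with open(path) as fh:
            fc = json.load(fh)
        facilities = {}
        for feat in fc["features"]:
            props = feat["properties"]
            x, y = feat["geometry"]["coordinates"]
            facilities[str(props["id"])] = {
                "u": float(x),
                "v": float(y),
                "type": str(props["type"]),
            }
        return cls(facilities)


@dataclass
class DistanceTable:
    """Per-respondent nearest-facility road distances (km) and facility ids."""

    table: pd.DataFrame  # indexed by respondent id

    def __post_init__(self) -> None:
        t = self.table
        for col in ("dist_gp_km", "dist_hospital_km", "dist_ed_km"):
            if (t[col] < 0).any() or not np.isfinite(t[col]).all():
                raise ValueError(f"{col} contains negative or non-finite values")
        bad = t["dist_hospital_km"] > t["dist_ed_km"] + 1e-12
        if bad.any():
            raise AssertionError(
                "dist_hospital_km > dist_ed_km for respondents "
                f"{list(t.index[bad])[:5]}; ED hospitals must be a subset of hospitals"
            )

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index_label="id")


def build_graph(edge_records, node_records) -> RoadGraph:
    """Build and validate a :class:`RoadGraph` from parsed records.

    ``node_records``: dicts with ``node_id``, ``u``, ``v``.
    ``edge_records``: dicts with ``node_a``, ``node_b``, ``length_m``.

    Duplicate undirected edges (including reversed duplicates) are collapsed
    keeping the shorter length.  Dangling endpoints, non-positive lengths and
    duplicate node ids are rejected with the offending row number.
    """
    g = nx.Graph()
    seen = set()
    for i, rec in enumerate(node_records):
        nid = str(rec["node_id"])
        if nid in seen:
            raise ValueError(f"duplicate node id {nid!r} at node row {i}")
        seen.add(nid)
        g.add_node(nid, u=float(rec["u"]), v=float(rec["v"]))
    for i, rec in enumerate(edge_records):
        a, b = str(rec["node_a"]), str(rec["node_b"])
        length = float(rec["length_m"])
        for endpoint in (a, b):
            if endpoint not in seen:
                raise ValueError(
                    f"edge row {i} references unknown node {endpoint!r}"
                )
        if a == b:
            raise ValueError(f"edge row {i} is a self-loop on node {a!r}")
        if not (math.isfinite(length) and length > 0):
            raise ValueError(
                f"edge row {i} ({a!r}, {b!r}) has non-positive length {length}"
            )
        if g.has_edge(a, b):
            length = min(length, g.edges[a, b]["length_m"])
        g.add_edge(a, b, length_m=length)
    return RoadGraph(g)


def snap_to_network(point, graph: RoadGraph):
    """Nearest graph node to ``point = (u, v)``; ties go to the smallest id."""
    if graph.n_nodes == 0:
        raise ValueError("cannot snap to an empty graph")
    ids, coords = graph.node_coordinates()
    d2 = (coords[:, 0] - point[0]) ** 2 + (coords[:, 1] - point[1]) ** 2
    # ids are sorted, so the first argmin is the smallest id among ties
    return ids[int(np.argmin(d2))]


def _snap_many(points: np.ndarray, graph: RoadGraph) -> list:
    ids, coords = graph.node_coordinates()
    if len(ids) == 0:
        raise ValueError("cannot snap to an empty graph")
    d2 = (
        (points[:, None, 0] - coords[None, :, 0]) ** 2
        + (points[:, None, 1] - coords[None, :, 1]) ** 2
    )
    return [ids[j] for j in np.argmin(d2, axis=1)]


def shortest_path_distance(graph: RoadGraph, source, target) -> float:
    """Shortest-path length in metres; ``inf`` when disconnected."""
    for node in (source, target):
        if node not in graph.graph:
            raise KeyError(f"node {node!r} not in graph")
    try:
        return nx.dijkstra_path_length(graph.graph, source, target, weight="length_m")
    except nx.NetworkXNoPath:
        return math.inf


def nearest_facility_distances(dataset, facilities: FacilitySet, graph: RoadGraph):
    """Road distance (km) from every respondent to the nearest facility of
    each type.

    Respondents and facilities are snapped to their nearest network node;
    the distance is the minimum over facilities of the snapped shortest-path
    length.  Ties between equally near facilities go to the smallest facility
    id.  Returns ``(dataset_copy_with_distance_columns, DistanceTable)``.

    Raises if any respondent is unreachable from every facility of some type,
    listing the respondent ids.
    """
    type_to_col = {
        "GP": "dist_gp_km",
        "hospital": "dist_hospital_km",
        "hospital_ED": "dist_ed_km",
    }
    for ftype in type_to_col:
        if not facilities.of_type(ftype):
            raise ValueError(f"no facility of type {ftype!r}")

    df = dataset.data
    resp_points = df[["u", "v"]].to_numpy(dtype=float)
    resp_nodes = _snap_many(resp_points, graph)

    out = {}
    nearest_ids = {}
    for ftype, col in type_to_col.items():
        fac = facilities.of_type(ftype)
        best = np.full(len(df), np.inf)
        best_id = np.array([None] * len(df), dtype=object)
        for fid in sorted(fac):
            f = fac[fid]
            fnode = snap_to_network((f["u"], f["v"]), graph)
            lengths = nx.single_source_dijkstra_path_length(
                graph.graph, fnode, weight="length_m"
            )
            d = np.array([lengths.get(n, math.inf) for n in resp_nodes])
            better = d < best  # strict: ties keep the earlier (smaller) id
            best[better] = d[better]
            best_id[better] = fid
        unreachable = ~np.isfinite(best)
        if unreachable.any():
            bad_ids = list(df["id"][unreachable])
            raise ValueError(
                f"respondents unreachable from every {ftype!r} facility: {bad_ids}"
            )
        out[col] = best / 1000.0
        nearest_ids[f"nearest_{ftype.lower()}_id"] = best_id

    table = pd.DataFrame(
        {**out, **nearest_ids}, index=pd.Index(df["id"], name="id")
    )
    dist_table = DistanceTable(table)

    new_df = df.copy()
    new_df["x3_dist_gp_km"] = out["dist_gp_km"]
    new_df["dist_hospital_km"] = out["dist_hospital_km"]
    new_df["x3a_dist_ed_km"] = out["dist_ed_km"]
    new_dataset = dataset.replace_data(new_df)
    return new_dataset, dist_table
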