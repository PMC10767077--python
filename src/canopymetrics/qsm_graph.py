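"""QSM cylinder tables, tree topology graphs and fit-quality checks.

A quantitative structure model (QSM) describes a tree as a hierarchy of
fitted cylinders. The per-cylinder CSV schema carries identifiers, topology
pointers (``parentCylID``/``childCyID``), the start point, a unit axis,
length, radius, and a flag marking cylinders added after the normal fitting
pass. The topology is turned into a directed graph (one node per cylinder,
edges parent -> child) which is serialized as portable node-link JSON.

The fit-quality check labels cloud points "not fitted" when they lie
farther than a threshold from every cylinder (treated as solids), the same
diagnostic used to spot twigs missed by cylinder fitting.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .defaults import UNFITTED_THRESHOLD
from .errors import CylinderValidationError, SchemaError, TopologyError
from .geometry import Cylinder, point_to_cylinder_distance
from .pointcloud_io import PointCloud

__all__ = [
    "CYLINDER_COLUMNS",
    "CylinderRecord",
    "read_cylinders",
    "write_cylinders",
    "records_from_frame",
    "records_to_frame",
    "build_graph",
    "graph_roots",
    "total_volume",
    "FitQualityReport",
    "flag_unfitted_points",
    "write_graph",
    "read_graph",
]

#: Mandatory CSV columns, in canonical order. ``childCyID`` is the source
#: tool's spelling and is preserved verbatim.
CYLINDER_COLUMNS = [
    "date",
    "projectID",
    "treeID",
    "branchID",
    "branchOrder",
    "cylinderID",
    "posInBranch",
    "parentCylID",
    "childCyID",
    "start_x",
    "start_y",
    "start_z",
    "axis_x",
    "axis_y",
    "axis_z",
    "length",
    "radius",
    "addedVirtual",
]


@dataclass(frozen=True)
class CylinderRecord:
    """One cylinder of a QSM, i.e. one row of the cylinder CSV."""

    date: str
    project_id: str
    tree_id: str
    branch_id: int
    branch_order: int
    cylinder_id: int
    pos_in_branch: int
    parent_cyl_id: int
    child_cyl_id: int
    start: np.ndarray
    axis: np.ndarray
    length: float
    radius: float
    added_virtual: int

    def __post_init__(self):
        start = np.asarray(self.start, dtype=np.float64).reshape(3)
        axis = np.asarray(self.axis, dtype=np.float64).reshape(3)
        norm = float(np.linalg.norm(axis))
        if not np.isfinite(norm) or norm == 0.0:
            raise CylinderValidationError(
                f"cylinder {self.cylinder_id}: axis has zero/non-finite norm"
            )
        if abs(norm - 1.0) > 1e-4:
            warnings.warn(
                f"cylinder {self.cylinder_id}: axis norm {norm:.6g} deviates "
                "from 1; renormalizing",
                stacklevel=2,
            )
        if self.parent_cyl_id == self.cylinder_id:
            raise CylinderValidationError(
                f"cylinder {self.cylinder_id} is its own parent"
            )
        if not self.length > 0:
            raise CylinderValidationError(
                f"cylinder {self.cylinder_id}: length must be positive"
            )
        if not self.radius > 0:
            raise CylinderValidationError(
                f"cylinder {self.cylinder_id}: radius must be positive"
            )
        object.__setattr__(self, "start", start)
        object.__setattr__(self, "axis", axis / norm)

    def to_cylinder(self) -> Cylinder:
        return Cylinder(self.start, self.axis, self.length, self.radius)


_FIELD_TO_COLUMN = {
    "date": "date",
    "project_id": "projectID",
    "tree_id": "treeID",
    "branch_id": "branchID",
    "branch_order": "branchOrder",
    "cylinder_id": "cylinderID",
    "pos_in_branch": "posInBranch",
    "parent_cyl_id": "parentCylID",
    "child_cyl_id": "childCyID",
    "length": "length",
    "radius": "radius",
    "added_virtual": "addedVirtual",
}


def records_from_frame(frame: pd.DataFrame) -> list[CylinderRecord]:
    """Validate a cylinder table and return one record per row (order kept)."""
    for col in CYLINDER_COLUMNS:
        if col not in frame.columns:
            raise SchemaError(col)
    ids = frame["cylinderID"].to_numpy()
    if len(np.unique(ids)) != len(ids):
        dupes = pd.Series(ids)[pd.Series(ids).duplicated()].unique()
        raise CylinderValidationError(
            f"duplicate cylinderID values: {dupes.tolist()}"
        )
    records = []
    for row in frame.itertuples(index=False):
        records.append(
            CylinderRecord(
                date=str(row.date),
                project_id=str(row.projectID),
                tree_id=str(row.treeID),
                branch_id=int(row.branchID),
                branch_order=int(row.branchOrder),
                cylinder_id=int(row.cylinderID),
                pos_in_branch=int(row.posInBranch),
                parent_cyl_id=int(row.parentCylID),
                child_cyl_id=int(row.childCyID),
                start=np.array([row.start_x, row.start_y, row.start_z]),
                axis=np.array([row.axis_x, row.axis_y, row.axis_z]),
                length=float(row.length),
                radius=float(row.radius),
                added_virtual=int(row.addedVirtual),
            )
        )
    return records


def records_to_frame(records) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "date": r.date,
                "projectID": r.project_id,
                "treeID": r.tree_id,
                "branchID": r.branch_id,
                "branchOrder": r.branch_order,
                "cylinderID": r.cylinder_id,
                "posInBranch": r.pos_in_branch,
                "parentCylID": r.parent_cyl_id,
                "childCyID": r.child_cyl_id,
                "start_x": r.start[0],
                "start_y": r.start[1],
                "start_z": r.start[2],
                "axis_x": r.axis[0],
                "axis_y": r.axis[1],
                "axis_z": r.axis[2],
                "length": r.length,
                "radius": r.radius,
                "addedVirtual": r.added_virtual,
            }
        )
    return pd.DataFrame(rows, columns=CYLINDER_COLUMNS)


def read_cylinders(path) -> list[CylinderRecord]:
    """Read and validate a cylinder CSV (canonical column schema)."""
    return records_from_frame(pd.read_csv(path))


def write_cylinders(records, path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def build_graph(records) -> nx.DiGraph:
    """Build the tree graph: nodes keyed by ``cylinder_id`` carrying all
    cylinder attributes, directed edges parent -> child.

    A cylinder whose ``parent_cyl_id`` matches no cylinder id (e.g. 0 in the
    1-indexed source convention) is a root. ``child_cyl_id`` is stored as a
    node attribute but never used for edges, since a single field cannot
    encode multiple children.

    Raises
    ------
    TopologyError
        If the parent pointers contain a cycle (the cycle is listed).
    """
    graph = nx.DiGraph()
    ids = {r.cylinder_id for r in records}
    for r in records:
        graph.add_node(
            r.cylinder_id,
            date=r.date,
            projectID=r.project_id,
            treeID=r.tree_id,
            branchID=r.branch_id,
            branchOrder=r.branch_order,
            posInBranch=r.pos_in_branch,
            parentCylID=r.parent_cyl_id,
            childCyID=r.child_cyl_id,
            start_x=float(r.start[0]),
            start_y=float(r.start[1]),
            start_z=float(r.start[2]),
            axis_x=float(r.axis[0]),
            axis_y=float(r.axis[1]),
            axis_z=float(r.axis[2]),
            length=float(r.length),
            radius=float(r.radius),
            addedVirtual=r.added_virtual,
        )
    for r in records:
        if r.parent_cyl_id in ids:
            graph.add_edge(r.parent_cyl_id, r.cylinder_id)
    if not nx.is_directed_acyclic_graph(graph):
        cycle = nx.find_cycle(graph)
        raise TopologyError(
            f"cylinder parent pointers contain a cycle: {cycle}", cycle=cycle
        )
    return graph


def graph_roots(graph: nx.DiGraph) -> list:
    """Nodes with no parent, sorted."""
    return sorted(n for n, deg in graph.in_degree() if deg == 0)


def total_volume(records) -> float:
    """Total woody volume in liters: ``1000 * sum(pi * r^2 * l)``."""
    vol_m3 = sum(np.pi * r.radius**2 * r.length for r in records)
    return float(1000.0 * vol_m3)


@dataclass(frozen=True)
class FitQualityReport:
    """Per-point cylinder-fit quality labels.

    ``not_fitted`` marks points farther than ``threshold`` from every
    cylinder; ``distance`` is each point's distance to the nearest cylinder
    (solid; 0 inside).
    """

    not_fitted: np.ndarray
    distance: np.ndarray
    threshold: float

    @property
    def n_points(self) -> int:
        return int(self.not_fitted.size)

    @property
    def n_not_fitted(self) -> int:
        return int(self.not_fitted.sum())

    @property
    def fraction_not_fitted(self) -> float:
        return self.n_not_fitted / self.n_points if self.n_points else 0.0


def flag_unfitted_points(
    cloud: PointCloud, records, threshold: float = UNFITTED_THRESHOLD
) -> FitQualityReport:
    """Label each point fitted/not-fitted by distance to the nearest cylinder.

    Raises ``ValueError`` for an empty cylinder set.
    """
    records = list(records)
    if not records:
        raise ValueError("fit-quality check needs at least one cylinder")
    min_d = np.full(len(cloud), np.inf)
    for rec in records:
        d = point_to_cylinder_distance(cloud.xyz, rec.to_cylinder())
        np.minimum(min_d, d, out=min_d)
    return FitQualityReport(
        not_fitted=min_d > threshold, distance=min_d, threshold=threshold
    )


def write_graph(graph: nx.DiGraph, path) -> None:
    """Serialize a tree graph as node-link JSON (portable, diffable)."""
    data = nx.node_link_data(graph, edges="edges")
    with open(path, "w") as fh:
        json.dump(data, fh)


def read_graph(path) -> nx.DiGraph:
    """Read a node-link JSON tree graph written by :func:`write_graph`."""
    with open(path, "r") as fh:
        data = json.load(fh)
    graph = nx.node_link_graph(data, directed=True, edges="edges")
    return graph
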