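"""Reading and writing of phenotype matrices, GraphML graphs and profile tables.

Matrices travel as plain comma-separated text: the first row holds resource
names (first cell blank or arbitrary), the first column holds strain names.
Binary matrices contain only ``0``/``1`` tokens; continuous matrices hold
non-negative optical-density readings that :func:`binarize` thresholds at a
fraction of the dataset-wide maximum.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence
from xml.etree import ElementTree as ET

import numpy as np

logger = logging.getLogger("phenotier")

__all__ = [
    "MatrixParseError",
    "MatrixValidationError",
    "PhenotypeMatrix",
    "ContinuousMatrix",
    "ProfileTable",
    "read_binary_matrix",
    "read_continuous_matrix",
    "read_distance_csv",
    "write_matrix",
    "binarize",
    "write_graphml",
    "read_graphml",
    "write_profile_table",
]

GRAPHML_NS = "http://graphml.graphdrawing.org/xmlns"
YFILES_NS = "http://www.yworks.com/xml/graphml"


class MatrixParseError(ValueError):
    """A cell or row of an input table could not be parsed."""


class MatrixValidationError(ValueError):
    """A parsed matrix violates a structural invariant (duplicates, domain)."""


def _check_unique(names: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for n in names:
        if n in seen:
            raise MatrixValidationError(f"duplicate {what} name: {n!r}")
        seen.add(n)


@dataclass(frozen=True)
class PhenotypeMatrix:
    """A named binary strain x resource relation.

    ``values[i, j] == 1`` means strain ``strain_names[i]`` uses (or produces)
    resource ``resource_names[j]``.
    """

    strain_names: tuple[str, ...]
    resource_names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.int8)
        object.__setattr__(self, "values", values)
        if len(self.strain_names) == 0 or len(self.resource_names) == 0:
            raise MatrixValidationError("matrix needs at least one strain and one resource")
        _check_unique(self.strain_names, "strain")
        _check_unique(self.resource_names, "resource")
        if values.shape != (len(self.strain_names), len(self.resource_names)):
            raise MatrixValidationError(
                f"value shape {values.shape} does not match "
                f"{len(self.strain_names)} strains x {len(self.resource_names)} resources"
            )
        bad = ~np.isin(values, (0, 1))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise MatrixValidationError(
                f"cell ({self.strain_names[i]}, {self.resource_names[j]}) is not 0/1"
            )

    @property
    def n_strains(self) -> int:
        return len(self.strain_names)

    @property
    def n_resources(self) -> int:
        return len(self.resource_names)


@dataclass(frozen=True)
class ContinuousMatrix:
    """Non-negative OD measurements with the same naming rules as the binary form."""

    strain_names: tuple[str, ...]
    resource_names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if len(self.strain_names) == 0 or len(self.resource_names) == 0:
            raise MatrixValidationError("matrix needs at least one strain and one resource")
        _check_unique(self.strain_names, "strain")
        _check_unique(self.resource_names, "resource")
        if values.shape != (len(self.strain_names), len(self.resource_names)):
            raise MatrixValidationError("value shape does not match names")
        if not np.isfinite(values).all():
            raise MatrixValidationError("non-finite value in continuous matrix")
        if (values < 0).any():
            i, j = np.argwhere(values < 0)[0]
            raise MatrixValidationError(
                f"negative value at ({self.strain_names[i]}, {self.resource_names[j]})"
            )

    @property
    def n_strains(self) -> int:
        return len(self.strain_names)

    @property
    def n_resources(self) -> int:
        return len(self.resource_names)


@dataclass(frozen=True)
class ProfileTable:
    """A phenotype matrix re-ordered to mirror a tiered graph layout."""

    strain_order: tuple[str, ...]
    strain_class_of: dict[str, str]
    resource_order: tuple[str, ...]
    resource_class_of: dict[str, str]
    marks: np.ndarray  # bool, |strain_order| x |resource_order|


def _read_rows(path: str | Path, sep: str = ",") -> list[list[str]]:
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        rows = [[cell.strip() for cell in row] for row in csv.reader(fh, delimiter=sep)]
    # drop trailing blank lines
    while rows and all(c == "" for c in rows[-1]):
        rows.pop()
    if len(rows) < 2:
        raise MatrixParseError(f"{path}: no data rows")
    return rows


def _parse_table(
    rows: list[list[str]], path: str | Path
) -> tuple[tuple[str, ...], tuple[str, ...], list[list[str]]]:
    header = rows[0]
    resource_names = tuple(header[1:])
    if not resource_names:
        raise MatrixParseError(f"{path}: header row holds no resource names")
    width = len(resource_names) + 1
    strain_names: list[str] = []
    cells: list[list[str]] = []
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) != width:
            raise MatrixParseError(
                f"{path}:{lineno}: ragged row ({len(row)} fields, expected {width})"
            )
        strain_names.append(row[0])
        cells.append(row[1:])
    return tuple(strain_names), resource_names, cells


def read_binary_matrix(path: str | Path, sep: str = ",") -> PhenotypeMatrix:
    """Read a binary strain x resource matrix from comma-separated text.

    Raises :class:`MatrixParseError` for ragged rows or non-``0``/``1`` cells
    (with row/column location) and :class:`MatrixValidationError` for
    duplicate names.
    """
    strains, resources, cells = _parse_table(_read_rows(path, sep), path)
    values = np.empty((len(strains), len(resources)), dtype=np.int8)
    for i, row in enumerate(cells):
        for j, tok in enumerate(row):
            if tok == "0":
                values[i, j] = 0
            elif tok == "1":
                values[i, j] = 1
            else:
                raise MatrixParseError(
                    f"{path}: cell ({strains[i]}, {resources[j]}) = {tok!r} is not 0/1"
                )
    return PhenotypeMatrix(strains, resources, values)


def read_continuous_matrix(path: str | Path, sep: str = ",") -> ContinuousMatrix:
    """Read a non-negative OD matrix; layout as :func:`read_binary_matrix`."""
    strains, resources, cells = _parse_table(_read_rows(path, sep), path)
    values = np.empty((len(strains), len(resources)), dtype=float)
    for i, row in enumerate(cells):
        for j, tok in enumerate(row):
            try:
                v = float(tok)
            except ValueError:
                raise MatrixParseError(
                    f"{path}: cell ({strains[i]}, {resources[j]}) = {tok!r} is not numeric"
                ) from None
            if not np.isfinite(v) or v < 0:
                raise MatrixParseError(
                    f"{path}: cell ({strains[i]}, {resources[j]}) = {tok!r} "
                    "must be a finite non-negative number"
                )
            values[i, j] = v
    return ContinuousMatrix(strains, resources, values)


def read_distance_csv(path: str | Path, sep: str = ","):
    """Read a square distance matrix CSV (header row = header column names)."""
    from .ordination import DistanceMatrix

    strains, resources, cells = _parse_table(_read_rows(path, sep), path)
    if strains != resources:
        raise MatrixParseError(f"{path}: row and column names differ; not a square distance matrix")
    values = np.array([[float(tok) for tok in row] for row in cells], dtype=float)
    return DistanceMatrix(strains, values)


def write_matrix(m: PhenotypeMatrix | ContinuousMatrix, path: str | Path, sep: str = ",") -> None:
    """Write a matrix back to the CSV layout accepted by the readers."""
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter=sep)
        w.writerow([""] + list(m.resource_names))
        is_binary = isinstance(m, PhenotypeMatrix)
        for name, row in zip(m.strain_names, m.values):
            if is_binary:
                w.writerow([name] + [str(int(v)) for v in row])
            else:
                w.writerow([name] + [repr(float(v)) for v in row])


def binarize(m: ContinuousMatrix, fraction: float = 0.10) -> PhenotypeMatrix:
    """Threshold a continuous OD matrix at ``fraction`` of its global maximum.

    The threshold is ``t = fraction * max(m)``; a cell maps to 1 iff its value
    is strictly greater than ``t``.  An all-zero matrix yields an all-zero
    binary matrix with a warning (the threshold degenerates to 0).
    """
    if not (0 < fraction <= 1):
        raise ValueError(f"fraction must lie in (0, 1], got {fraction}")
    global_max = float(m.values.max())
    threshold = fraction * global_max
    if global_max == 0.0:
        warnings.warn("all-zero continuous matrix: threshold is 0, output is all zeros")
    logger.info("binarize: global max OD %.6g, threshold %.6g", global_max, threshold)
    values = (m.values > threshold).astype(np.int8)
    return PhenotypeMatrix(m.strain_names, m.resource_names, values)


# ---------------------------------------------------------------------------
# GraphML
# ---------------------------------------------------------------------------

_NODE_KEYS = (
    ("label", "string"),
    ("tier", "int"),
    ("x", "double"),
    ("y", "double"),
    ("size", "int"),
    ("degree", "int"),
)

# pixels per abstract unit when emitting yEd geometry; yEd's y axis points down
_YED_X_SCALE = 220.0
_YED_Y_SCALE = -400.0


def write_graphml(g, path: str | Path, yed_compat: bool = False) -> None:
    """Serialize a :class:`~phenotier.layout.TieredGraph` as GraphML 1.0.

    Every node carries ``label``, ``tier``, ``x``, ``y``, ``size`` and
    ``degree`` data keys; edges are directed left tier -> right tier.  With
    ``yed_compat`` the file additionally embeds yFiles geometry/label elements
    so it opens fully positioned in the yEd editor.
    """
    g.validate()

    ET.register_namespace("", GRAPHML_NS)
    root = ET.Element(f"{{{GRAPHML_NS}}}graphml")
    if yed_compat:
        ET.register_namespace("y", YFILES_NS)

    for key_name, key_type in _NODE_KEYS:
        ET.SubElement(
            root,
            f"{{{GRAPHML_NS}}}key",
            id=f"d_{key_name}",
            attrib={"for": "node", "attr.name": key_name, "attr.type": key_type},
        )
    if yed_compat:
        ET.SubElement(
            root,
            f"{{{GRAPHML_NS}}}key",
            id="d_graphics",
            attrib={"for": "node", "yfiles.type": "nodegraphics"},
        )

    graph = ET.SubElement(root, f"{{{GRAPHML_NS}}}graph", id="G", edgedefault="directed")
    for node in g.nodes:
        el = ET.SubElement(graph, f"{{{GRAPHML_NS}}}node", id=node.id)
        data = {
            "label": node.label,
            "tier": str(node.tier),
            "x": repr(float(node.x)),
            "y": repr(float(node.y)),
            "size": str(node.size),
            "degree": str(node.degree),
        }
        for key_name, _ in _NODE_KEYS:
            d = ET.SubElement(el, f"{{{GRAPHML_NS}}}data", key=f"d_{key_name}")
            d.text = data[key_name]
        if yed_compat:
            d = ET.SubElement(el, f"{{{GRAPHML_NS}}}data", key="d_graphics")
            shape = ET.SubElement(d, f"{{{YFILES_NS}}}ShapeNode")
            ET.SubElement(
                shape,
                f"{{{YFILES_NS}}}Geometry",
                x=f"{node.x * _YED_X_SCALE:.2f}",
                y=f"{node.y * _YED_Y_SCALE:.2f}",
                width="60.0",
                height="20.0",
            )
            lab = ET.SubElement(shape, f"{{{YFILES_NS}}}NodeLabel")
            lab.text = node.label
    for i, (src, dst) in enumerate(g.edges):
        ET.SubElement(graph, f"{{{GRAPHML_NS}}}edge", id=f"e{i}", source=src, target=dst)

    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(path, xml_declaration=True, encoding="UTF-8")
    logger.info("wrote GraphML with %d nodes, %d edges to %s", len(g.nodes), len(g.edges), path)


def read_graphml(path: str | Path):
    """Parse a GraphML file written by :func:`write_graphml` back to a TieredGraph."""
    from .layout import TieredGraph, TierNode

    tree = ET.parse(path)
    root = tree.getroot()
    key_names = {
        el.get("id"): el.get("attr.name")
        for el in root.findall(f"{{{GRAPHML_NS}}}key")
        if el.get("attr.name")
    }
    graph = root.find(f"{{{GRAPHML_NS}}}graph")
    if graph is None:
        raise MatrixParseError(f"{path}: no <graph> element")
    nodes = []
    for el in graph.findall(f"{{{GRAPHML_NS}}}node"):
        attrs: dict[str, str] = {}
        for d in el.findall(f"{{{GRAPHML_NS}}}data"):
            name = key_names.get(d.get("key", ""))
            if name:
                attrs[name] = d.text or ""
        nodes.append(
            TierNode(
                id=el.get("id", ""),
                label=attrs["label"],
                tier=int(attrs["tier"]),
                x=float(attrs["x"]),
                y=float(attrs["y"]),
                size=int(attrs["size"]),
                degree=int(attrs["degree"]),
            )
        )
    edges = [
        (el.get("source", ""), el.get("target", ""))
        for el in graph.findall(f"{{{GRAPHML_NS}}}edge")
    ]
    return TieredGraph(nodes=nodes, edges=edges, epsilon=0.0)


# ---------------------------------------------------------------------------
# Profile table
# ---------------------------------------------------------------------------


def build_profile_table(m: PhenotypeMatrix, g) -> ProfileTable:
    """Re-order ``m`` so rows/columns follow the vertical order of graph tiers 1/4."""
    tier1 = sorted((n for n in g.nodes if n.tier == 1), key=lambda n: -n.y)
    tier4 = sorted((n for n in g.nodes if n.tier == 4), key=lambda n: -n.y)
    strain_order = tuple(n.label for n in tier1)
    resource_order = tuple(n.label for n in tier4)
    if sorted(strain_order) != sorted(m.strain_names):
        raise MatrixValidationError("graph strain names do not match the matrix")
    if sorted(resource_order) != sorted(m.resource_names):
        raise MatrixValidationError("graph resource names do not match the matrix")

    node_by_id = {n.id: n for n in g.nodes}
    strain_class_of = {}
    resource_class_of = {}
    for src, dst in g.edges:
        s, d = node_by_id[src], node_by_id[dst]
        if s.tier == 1 and d.tier == 2:
            strain_class_of[s.label] = d.label
        elif s.tier == 3 and d.tier == 4:
            resource_class_of[d.label] = s.label

    si = {name: i for i, name in enumerate(m.strain_names)}
    ri = {name: j for j, name in enumerate(m.resource_names)}
    marks = np.array(
        [[bool(m.values[si[s], ri[r]]) for r in resource_order] for s in strain_order]
    )
    return ProfileTable(strain_order, strain_class_of, resource_order, resource_class_of, marks)


def write_profile_table(
    m: PhenotypeMatrix, g, path: str | Path, mark: str = "X", sep: str = "\t"
) -> ProfileTable:
    """Write the graph-ordered profile table as TSV and return it.

    Rows follow the vertical (top-to-bottom) order of tier-1 nodes, columns the
    order of tier-4 nodes; class columns/rows make equivalence-class
    boundaries visible.
    """
    table = build_profile_table(m, g)
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter=sep)
        w.writerow(["strain", "class"] + list(table.resource_order))
        w.writerow(["", ""] + [table.resource_class_of[r] for r in table.resource_order])
        for s, row in zip(table.strain_order, table.marks):
            w.writerow([s, table.strain_class_of[s]] + [mark if v else "" for v in row])
    return table
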