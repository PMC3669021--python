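"""Equivalence classes of identical profiles and the reduced class graph.

Strains with bitwise-identical rows share a class; resources with identical
columns likewise.  Collapsing both sides turns the strain x resource relation
into a small bipartite graph between classes, where a strain class links to a
resource class exactly when its canonical profile is 1 on that resource class.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io import PhenotypeMatrix

__all__ = [
    "EquivalenceClass",
    "Partition",
    "ClassGraph",
    "compute_strain_classes",
    "compute_resource_classes",
    "build_class_graph",
    "write_class_listing",
]


@dataclass(frozen=True)
class EquivalenceClass:
    """A maximal set of entities sharing one canonical binary profile."""

    name: str
    members: tuple[str, ...]
    profile: np.ndarray  # canonical shared profile, int8

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class Partition:
    """Ordered equivalence classes over strains or resources.

    Classes appear in first-member input order and are named ``B1..Bk``
    (strains) or ``R1..Rl`` (resources).
    """

    kind: str  # "strain" | "resource"
    classes: tuple[EquivalenceClass, ...]

    def __post_init__(self) -> None:
        if self.kind not in ("strain", "resource"):
            raise ValueError(f"kind must be 'strain' or 'resource', got {self.kind!r}")

    @property
    def member_names(self) -> tuple[str, ...]:
        return tuple(m for c in self.classes for m in c.members)

    def class_of(self) -> dict[str, str]:
        return {m: c.name for c in self.classes for m in c.members}

    def index_of(self) -> dict[str, int]:
        return {m: i for i, c in enumerate(self.classes) for m in c.members}


def _partition(names: tuple[str, ...], profiles: np.ndarray, kind: str, prefix: str) -> Partition:
    groups: dict[bytes, list[int]] = {}
    for i, row in enumerate(profiles):
        groups.setdefault(np.ascontiguousarray(row, dtype=np.int8).tobytes(), []).append(i)
    classes = tuple(
        EquivalenceClass(
            name=f"{prefix}{k}",
            members=tuple(names[i] for i in idx),
            profile=profiles[idx[0]].astype(np.int8).copy(),
        )
        for k, idx in enumerate(groups.values(), start=1)
    )
    return Partition(kind=kind, classes=classes)


def compute_strain_classes(m: PhenotypeMatrix) -> Partition:
    """Group strains with identical rows; deterministic first-member order."""
    return _partition(m.strain_names, m.values, "strain", "B")


def compute_resource_classes(m: PhenotypeMatrix) -> Partition:
    """Group resources with identical columns; deterministic first-member order."""
    return _partition(m.resource_names, m.values.T, "resource", "R")


@dataclass(frozen=True)
class ClassGraph:
    """Directed links strain class -> resource class, with per-class degrees.

    ``links`` holds index pairs into the two partitions.  A link (X, Y) means
    every strain in X has a 1 on every resource in Y; because classes collapse
    identical rows and columns this relation is all-or-none, which
    :func:`build_class_graph` asserts rather than assumes.
    """

    strain_partition: Partition
    resource_partition: Partition
    links: tuple[tuple[int, int], ...]
    out_degree: tuple[int, ...]  # per strain class
    in_degree: tuple[int, ...]  # per resource class


def _assert_consistent(p: Partition, m: PhenotypeMatrix) -> None:
    if p.kind == "strain":
        names, profiles = m.strain_names, m.values
    else:
        names, profiles = m.resource_names, m.values.T
    index = {n: i for i, n in enumerate(names)}
    if sorted(p.member_names) != sorted(names):
        raise ValueError(f"{p.kind} partition does not cover the matrix names")
    for c in p.classes:
        for member in c.members:
            if not np.array_equal(profiles[index[member]], c.profile):
                raise ValueError(
                    f"partition inconsistent with matrix: {member} does not match "
                    f"the canonical profile of {c.name}"
                )


def build_class_graph(sp: Partition, rp: Partition, m: PhenotypeMatrix) -> ClassGraph:
    """Link the two partitions over ``m`` and annotate degrees.

    Raises ``ValueError`` if either partition was not computed from ``m``.
    """
    _assert_consistent(sp, m)
    _assert_consistent(rp, m)
    ri = {n: j for j, n in enumerate(m.resource_names)}
    links: list[tuple[int, int]] = []
    for x, sc in enumerate(sp.classes):
        for y, rc in enumerate(rp.classes):
            cols = [ri[r] for r in rc.members]
            block = sc.profile[cols]
            # all-or-none by construction; verify instead of trusting it
            if block.any() and not block.all():
                raise ValueError(f"class relation not all-or-none between {sc.name} and {rc.name}")
            if block.all():
                links.append((x, y))
    out_degree = [0] * len(sp.classes)
    in_degree = [0] * len(rp.classes)
    for x, y in links:
        out_degree[x] += 1
        in_degree[y] += 1
    return ClassGraph(sp, rp, tuple(links), tuple(out_degree), tuple(in_degree))


def write_class_listing(cg: ClassGraph, path: str | Path, sep: str = "\t") -> None:
    """Export both partitions as TSV: class id, members, profile string, degree."""
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter=sep)
        w.writerow(["class", "kind", "members", "profile", "degree"])
        for c, deg in zip(cg.strain_partition.classes, cg.out_degree):
            w.writerow([c.name, "strain", ",".join(c.members), "".join(map(str, c.profile)), deg])
        for c, deg in zip(cg.resource_partition.classes, cg.in_degree):
            w.writerow([c.name, "resource", ",".join(c.members), "".join(map(str, c.profile)), deg])
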