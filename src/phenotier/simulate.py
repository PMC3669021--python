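"""Synthetic phenotype matrices with planted equivalence-class structure.

Generators plant groups of identical-row strains and identical-column
resources, optional all-one (universal) and all-zero (unused) columns, then
apply independent bit-flip noise outside the forced columns.  A continuous
variant draws bimodal OD values (no-growth noise vs. growth signal) so the
threshold binarization rule can be exercised end to end.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .io import ContinuousMatrix, PhenotypeMatrix

__all__ = ["SynthSpec", "SynthTruth", "simulate_binary", "simulate_continuous"]

_MAX_DRAW_ATTEMPTS = 1000


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of a synthetic phenotype matrix.

    ``n_strain_classes``/``n_resource_classes`` count the planted noise-free
    classes over the free columns; universal and unused columns form their
    own additional resource classes (one each, when present).
    """

    n_strains: int = 33
    n_resources: int = 95
    n_strain_classes: int = 6
    n_resource_classes: int = 8
    noise_flip_prob: float = 0.0
    n_universal_resources: int = 0
    n_unused_resources: int = 0
    od_signal_mean: float = 1.5
    od_signal_sd: float = 0.1
    od_noise_mean: float = 0.05
    od_noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_strains < 1 or self.n_resources < 1:
            raise ValueError("need at least one strain and one resource")
        if not (1 <= self.n_strain_classes <= self.n_strains):
            raise ValueError("n_strain_classes must lie in [1, n_strains]")
        if self.n_universal_resources < 0 or self.n_unused_resources < 0:
            raise ValueError("forced column counts must be non-negative")
        n_free = self.n_resources - self.n_universal_resources - self.n_unused_resources
        if n_free < 0:
            raise ValueError("universal + unused columns exceed n_resources")
        if not (0 <= self.n_resource_classes <= max(n_free, 0)) or (
            n_free > 0 and self.n_resource_classes < 1
        ):
            raise ValueError("n_resource_classes must lie in [1, free resources]")
        if not (0 <= self.noise_flip_prob < 1):
            raise ValueError("noise_flip_prob must lie in [0, 1)")
        if self.od_signal_sd < 0 or self.od_noise_sd < 0:
            raise ValueError("OD standard deviations must be non-negative")
        if self.n_strain_classes > 2**self.n_resource_classes:
            raise ValueError(
                f"cannot draw {self.n_strain_classes} distinct strain profiles "
                f"over {self.n_resource_classes} resource classes"
            )
        n_excluded = (self.n_universal_resources > 0) + (self.n_unused_resources > 0)
        if self.n_resource_classes > 2**self.n_strain_classes - n_excluded:
            raise ValueError(
                f"cannot draw {self.n_resource_classes} distinct resource-class columns "
                f"over {self.n_strain_classes} strain classes"
            )

    @property
    def n_free_resources(self) -> int:
        return self.n_resources - self.n_universal_resources - self.n_unused_resources


@dataclass(frozen=True)
class SynthTruth:
    """Planted (pre-noise) ground truth accompanying a simulated matrix."""

    strain_classes: tuple[tuple[str, ...], ...]
    resource_classes: tuple[tuple[str, ...], ...]
    universal_resources: tuple[str, ...]
    unused_resources: tuple[str, ...]
    seed: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n", encoding="utf-8")


def _draw_class_kernel(rng: np.random.Generator, spec: SynthSpec) -> np.ndarray:
    """Class-level matrix with distinct rows and distinct non-constant columns."""
    k, l = spec.n_strain_classes, spec.n_resource_classes
    exclude_all0 = spec.n_unused_resources > 0
    exclude_all1 = spec.n_universal_resources > 0
    for _ in range(_MAX_DRAW_ATTEMPTS):
        kernel = rng.integers(0, 2, size=(k, l), dtype=np.int8)
        if len({r.tobytes() for r in kernel}) != k:
            continue
        cols = [kernel[:, j] for j in range(l)]
        if len({c.tobytes() for c in cols}) != l:
            continue
        if exclude_all0 and any((c == 0).all() for c in cols):
            continue
        if exclude_all1 and any((c == 1).all() for c in cols):
            continue
        return kernel
    raise ValueError("could not draw a feasible class kernel; spec too tight")


def _assign(rng: np.random.Generator, n: int, k: int) -> np.ndarray:
    """Assign n items to k classes, each class non-empty."""
    assignment = np.concatenate([np.arange(k), rng.integers(0, k, size=n - k)])
    rng.shuffle(assignment)
    return assignment


def simulate_binary(spec: SynthSpec) -> tuple[PhenotypeMatrix, SynthTruth]:
    """Simulate a binary matrix with planted classes; returns matrix + truth.

    Noise flips are applied after the universal/unused columns are forced, so
    those columns stay clean and keep exercising the in-degree-0 and
    full-in-degree code paths.  Byte-identical output for equal specs.
    """
    rng = np.random.default_rng(spec.seed)
    strains = tuple(f"S{i + 1:03d}" for i in range(spec.n_strains))
    resources = tuple(f"C{j + 1:03d}" for j in range(spec.n_resources))

    # column roles, positions drawn once from the seeded stream
    perm = rng.permutation(spec.n_resources)
    universal_cols = np.sort(perm[: spec.n_universal_resources])
    unused_cols = np.sort(
        perm[spec.n_universal_resources : spec.n_universal_resources + spec.n_unused_resources]
    )
    free_cols = np.sort(perm[spec.n_universal_resources + spec.n_unused_resources :])

    values = np.zeros((spec.n_strains, spec.n_resources), dtype=np.int8)
    values[:, universal_cols] = 1

    resource_assignment = np.empty(0, dtype=int)
    if spec.n_free_resources > 0:
        kernel = _draw_class_kernel(rng, spec)
        strain_assignment = _assign(rng, spec.n_strains, spec.n_strain_classes)
        resource_assignment = _assign(rng, spec.n_free_resources, spec.n_resource_classes)
        values[:, free_cols] = kernel[np.ix_(strain_assignment, resource_assignment)]
    else:
        strain_assignment = np.zeros(spec.n_strains, dtype=int)
        if spec.n_strain_classes != 1:
            raise ValueError("without free resources only one strain class is expressible")

    if spec.noise_flip_prob > 0 and spec.n_free_resources > 0:
        flips = rng.random((spec.n_strains, spec.n_free_resources)) < spec.noise_flip_prob
        sub = values[:, free_cols]
        values[:, free_cols] = np.where(flips, 1 - sub, sub)

    strain_classes = tuple(
        tuple(strains[i] for i in np.flatnonzero(strain_assignment == c))
        for c in range(spec.n_strain_classes)
    )
    resource_classes = tuple(
        tuple(resources[free_cols[j]] for j in np.flatnonzero(resource_assignment == c))
        for c in range(spec.n_resource_classes if spec.n_free_resources else 0)
    )
    truth = SynthTruth(
        strain_classes=strain_classes,
        resource_classes=resource_classes,
        universal_resources=tuple(resources[j] for j in universal_cols),
        unused_resources=tuple(resources[j] for j in unused_cols),
        seed=spec.seed,
    )
    return PhenotypeMatrix(strains, resources, values), truth


def simulate_continuous(spec: SynthSpec) -> tuple[ContinuousMatrix, PhenotypeMatrix]:
    """Simulate bimodal OD measurements over a planted binary truth.

    Cells draw from N(od_signal_mean, od_signal_sd) where the binary truth is
    1 and from N(od_noise_mean, od_noise_sd) where it is 0, truncated at 0.
    With separated distributions, the 10%-of-max threshold rule recovers the
    truth.
    """
    binary, _ = simulate_binary(spec)
    rng = np.random.default_rng(spec.seed + 1)  # distinct stream from the truth draw
    signal = rng.normal(spec.od_signal_mean, spec.od_signal_sd, size=binary.values.shape)
    noise = rng.normal(spec.od_noise_mean, spec.od_noise_sd, size=binary.values.shape)
    od = np.where(binary.values == 1, signal, noise)
    od = np.clip(od, 0.0, None)
    return ContinuousMatrix(binary.strain_names, binary.resource_names, od), binary
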