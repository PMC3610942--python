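"""Genotype partitions: groupings of the four joint genotypes.

In a haploid biallelic cross two markers define four joint genotypes
{(0,0), (0,1), (1,0), (1,1)}.  A correlation model assigns each joint
genotype to a correlation class; the 15 set partitions of the four
genotypes split into one null model (a single class), two marginal
models (classes depend on one marker only), and twelve epistatic models
(every other grouping).  Model selection scans the twelve epistatic
partitions against the null.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "JOINT_GENOTYPES",
    "GenotypePartition",
    "enumerate_partitions",
    "epistatic_partitions",
    "marginal_partitions",
    "null_partition",
    "partitions_to_frame",
]

#: canonical order of the joint genotypes at two binary markers
JOINT_GENOTYPES: tuple[tuple[int, int], ...] = ((0, 0), (0, 1), (1, 0), (1, 1))


@dataclass(frozen=True)
class GenotypePartition:
    """One assignment of the four joint genotypes to correlation classes."""

    id: str
    class_of: dict[tuple[int, int], int]
    k: int
    role: str  # null | marginal_m1 | marginal_m2 | epistatic

    def __post_init__(self) -> None:
        labels = set(self.class_of.values())
        if labels != set(range(1, self.k + 1)):
            raise ValueError(f"class labels must be 1..k, got {sorted(labels)}")
        if set(self.class_of) != set(JOINT_GENOTYPES):
            raise ValueError("partition must cover all four joint genotypes")

    def classes(self) -> list[frozenset[tuple[int, int]]]:
        out: dict[int, set] = {c: set() for c in range(1, self.k + 1)}
        for g, c in self.class_of.items():
            out[c].add(g)
        return [frozenset(out[c]) for c in range(1, self.k + 1)]

    def class_labels(self) -> tuple[int, int, int, int]:
        """Class of each joint genotype in canonical genotype order."""
        return tuple(self.class_of[g] for g in JOINT_GENOTYPES)

    def refines(self, other: "GenotypePartition") -> bool:
        """True if every class of ``self`` lies inside one class of ``other``."""
        for cls in self.classes():
            targets = {other.class_of[g] for g in cls}
            if len(targets) > 1:
                return False
        return True

    def __str__(self) -> str:
        return self.id


def _assignment_id(labels: tuple[int, ...]) -> str:
    return ",".join(f"{a}{b}:{c}" for (a, b), c in zip(JOINT_GENOTYPES, labels))


def _role(labels: tuple[int, ...]) -> str:
    k = max(labels)
    if k == 1:
        return "null"
    if labels == (1, 1, 2, 2):  # split by marker 1
        return "marginal_m1"
    if labels == (1, 2, 1, 2):  # split by marker 2
        return "marginal_m2"
    return "epistatic"


def enumerate_partitions() -> list[GenotypePartition]:
    """All 15 set partitions of the four joint genotypes, canonically ordered.

    Partitions are generated as restricted-growth strings over the
    canonical genotype order and sorted by number of classes, then
    lexicographically — so the ordering (used for tie-breaking in model
    selection) is deterministic.  Exactly 1 null, 2 marginal and 12
    epistatic partitions are returned.
    """
    strings: list[tuple[int, ...]] = []

    def grow(prefix: tuple[int, ...]) -> None:
        if len(prefix) == len(JOINT_GENOTYPES):
            strings.append(prefix)
            return
        top = max(prefix) if prefix else 0
        for c in range(1, top + 2):
            grow(prefix + (c,))

    grow(())
    strings.sort(key=lambda s: (max(s), s))
    out = []
    for labels in strings:
        out.append(
            GenotypePartition(
                id=_assignment_id(labels),
                class_of=dict(zip(JOINT_GENOTYPES, labels)),
                k=max(labels),
                role=_role(labels),
            )
        )
    return out


def null_partition() -> GenotypePartition:
    return next(p for p in enumerate_partitions() if p.role == "null")


def marginal_partitions() -> list[GenotypePartition]:
    parts = enumerate_partitions()
    m1 = next(p for p in parts if p.role == "marginal_m1")
    m2 = next(p for p in parts if p.role == "marginal_m2")
    return [m1, m2]


def epistatic_partitions() -> list[GenotypePartition]:
    return [p for p in enumerate_partitions() if p.role == "epistatic"]


def partitions_to_frame():
    """Partition catalogue as a DataFrame (id, assignment, k, role)."""
    import pandas as pd

    parts = enumerate_partitions()
    return pd.DataFrame(
        {
            "id": [p.id for p in parts],
            "k": [p.k for p in parts],
            "role": [p.role for p in parts],
        }
    )
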