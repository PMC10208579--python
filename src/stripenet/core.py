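"""Genotype algebra for a three-node gene regulatory network.

The network has three nodes -- sensor, regulator and output -- in a fixed
canonical order. A genotype assigns to each node either the wild-type allele
or one of ``M`` mutant alleles (labelled 1..M; the labels carry no ordering
semantics). The *order* of a genotype is the number of mutated nodes, so
order 0 is the wild-type network, order 1 a single mutant, order 2 a pairwise
combination and order 3 a triplet.

Genotypes render to a stable string form used as the join key in every
output table: ``"WT"`` for the wild type, otherwise ``node-index`` terms
joined by ``+`` in node order, e.g. ``"sensor-3+output-7"``.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass
from enum import Enum
from typing import Iterator


class Node(str, Enum):
    """The three network nodes, in canonical order."""

    SENSOR = "sensor"
    REGULATOR = "regulator"
    OUTPUT = "output"


#: Canonical node order: sensor < regulator < output.
NODE_ORDER: tuple[Node, Node, Node] = (Node.SENSOR, Node.REGULATOR, Node.OUTPUT)

_GENOTYPE_TERM = re.compile(r"^(sensor|regulator|output)-(\d+)$")


@dataclass(frozen=True, order=True)
class Genotype:
    """Allele assignment per node; 0 means wild type, 1..M a mutant label.

    Immutable and hashable so genotypes can key dictionaries and index
    DataFrames.
    """

    sensor: int = 0
    regulator: int = 0
    output: int = 0

    def __post_init__(self) -> None:
        for node in NODE_ORDER:
            if self.allele(node) < 0:
                raise ValueError(f"allele index must be >= 0, got {self.allele(node)}")

    def allele(self, node: Node) -> int:
        return getattr(self, node.value)

    @property
    def order(self) -> int:
        """Number of mutated (non-WT) nodes, 0..3."""
        return sum(1 for n in NODE_ORDER if self.allele(n) != 0)

    @property
    def is_wt(self) -> bool:
        return self.order == 0

    def mutated_nodes(self) -> tuple[Node, ...]:
        return tuple(n for n in NODE_ORDER if self.allele(n) != 0)

    def singles(self) -> tuple["Genotype", ...]:
        """Constituent single-mutant genotypes, in node order.

        Every order-2 or order-3 genotype decomposes uniquely into these.
        """
        return tuple(
            Genotype(**{n.value: self.allele(n)}) for n in self.mutated_nodes()
        )

    def pairs(self) -> tuple["Genotype", ...]:
        """Constituent pairwise genotypes of a triplet, in node order."""
        if self.order != 3:
            raise ValueError("pairs() is defined for triplet genotypes only")
        out = []
        for a, b in itertools.combinations(NODE_ORDER, 2):
            out.append(Genotype(**{a.value: self.allele(a), b.value: self.allele(b)}))
        return tuple(out)

    def name(self) -> str:
        if self.is_wt:
            return "WT"
        return "+".join(
            f"{n.value}-{self.allele(n)}" for n in self.mutated_nodes()
        )

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.name()

    @classmethod
    def from_name(cls, name: str) -> "Genotype":
        """Parse the canonical string form (inverse of :meth:`name`)."""
        name = name.strip()
        if name == "WT":
            return cls()
        alleles: dict[str, int] = {}
        for term in name.split("+"):
            m = _GENOTYPE_TERM.match(term.strip())
            if m is None:
                raise ValueError(f"malformed genotype term {term!r} in {name!r}")
            node, idx = m.group(1), int(m.group(2))
            if node in alleles:
                raise ValueError(f"node {node!r} appears twice in {name!r}")
            if idx == 0:
                raise ValueError(f"mutant index must be >= 1 in {name!r}")
            alleles[node] = idx
        return cls(**alleles)


@dataclass(frozen=True)
class InducerLevel:
    """A named arabinose concentration (% w/v).

    The assay defaults are low = 0%, medium = 0.0002%, high = 0.2%; a
    16-point gradient uses ``gradient-<i>`` labels instead.
    """

    label: str
    concentration: float

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError("inducer concentration must be non-negative")


#: The three assay concentrations of arabinose (% w/v).
DEFAULT_LEVELS: tuple[InducerLevel, ...] = (
    InducerLevel("low", 0.0),
    InducerLevel("medium", 0.0002),
    InducerLevel("high", 0.2),
)

#: The 15 nonzero gradient concentrations plus 0% (16 points, % w/v arabinose).
GRADIENT_CONCENTRATIONS: tuple[float, ...] = (
    0.0,
    0.000012,
    0.000025,
    0.00005,
    0.0001,
    0.0002,
    0.0004,
    0.0008,
    0.0016,
    0.00313,
    0.00625,
    0.0125,
    0.025,
    0.05,
    0.1,
    0.2,
)


def gradient_levels() -> tuple[InducerLevel, ...]:
    """The 16-point inducer gradient as labelled levels."""
    return tuple(
        InducerLevel(f"gradient-{i:02d}", c)
        for i, c in enumerate(GRADIENT_CONCENTRATIONS)
    )


def _check_m(mutants_per_node: int) -> None:
    if not isinstance(mutants_per_node, (int,)) or mutants_per_node < 1:
        raise ValueError(
            f"mutants_per_node must be a positive integer, got {mutants_per_node!r}"
        )


def enumerate_genotypes(mutants_per_node: int = 10) -> list[Genotype]:
    """All genotypes up to order 3: WT, 3M singles, 3M^2 pairs, M^3 triplets.

    With M=10 this yields the full 1 + 30 + 300 + 1000 genotype panel.
    """
    _check_m(mutants_per_node)
    M = mutants_per_node
    idx = range(1, M + 1)
    out: list[Genotype] = [Genotype()]
    for node in NODE_ORDER:
        out.extend(Genotype(**{node.value: i}) for i in idx)
    for a, b in itertools.combinations(NODE_ORDER, 2):
        out.extend(
            Genotype(**{a.value: i, b.value: j})
            for i in idx
            for j in idx
        )
    out.extend(
        Genotype(sensor=i, regulator=j, output=k)
        for i in idx
        for j in idx
        for k in idx
    )
    return out


def genotypes_of_order(mutants_per_node: int, order: int) -> list[Genotype]:
    """The sub-panel at a single order (0..3)."""
    _check_m(mutants_per_node)
    if order not in (0, 1, 2, 3):
        raise ValueError(f"order must be in 0..3, got {order}")
    return [g for g in enumerate_genotypes(mutants_per_node) if g.order == order]


def combinations_containing(
    g: Genotype, order: int, mutants_per_node: int = 10
) -> list[Genotype]:
    """All order-2 or order-3 genotypes carrying ``g``'s allele at its node.

    ``g`` must be a single mutant. With M=10 a single mutant sits in 20
    pairwise and 100 triplet combinations.
    """
    _check_m(mutants_per_node)
    if g.order != 1:
        raise ValueError(f"g must be a single-mutant genotype, got order {g.order}")
    if order not in (2, 3):
        raise ValueError(f"order must be 2 or 3, got {order}")
    (node,) = g.mutated_nodes()
    allele = g.allele(node)
    return [
        cand
        for cand in genotypes_of_order(mutants_per_node, order)
        if cand.allele(node) == allele
    ]


def iter_pairs(mutants_per_node: int) -> Iterator[Genotype]:
    yield from genotypes_of_order(mutants_per_node, 2)


def iter_triplets(mutants_per_node: int) -> Iterator[Genotype]:
    yield from genotypes_of_order(mutants_per_node, 3)
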