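"""Reverse-degree transform and bond-additive topological descriptors.

A bond-additive descriptor of a molecular graph G sums a symmetric function
``TD(a, b)`` of transformed endpoint degrees over all edges.  Here the
transform is the *reverse degree with shift k*: for a vertex of degree
``d`` in a graph of maximum degree ``Δ``,

    R_k(d) = Δ - d + k            if k <= d,
    R_k(d) = (Δ - d + k) mod Δ    if k >  d.

With Δ = 4 this maps degrees (1,2,3,4) to (4,3,2,1) for k=1, (1,4,3,2) for
k=2 and (2,1,4,3) for k=3.  The wrap-around branch can in principle produce
0, for which the transform (and every descriptor built on it) is undefined;
that case raises :class:`ReverseDegreeError` rather than being remapped.

Because every edge's contribution depends only on the unordered pair of
endpoint degrees, the sum collapses onto the graph's *edge partition*: the
multiset of degree-pair classes with their edge counts.  All arithmetic is
exact (:class:`fractions.Fraction`); descriptor values are integers except
for the harmonic variants, which may be half-integral.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Callable, Iterable, Mapping, Tuple

import networkx as nx

__all__ = [
    "DESCRIPTOR_NAMES",
    "ReverseDegreeError",
    "EdgePartition",
    "DescriptorValue",
    "reverse_degree",
    "td_function",
    "descriptor_from_partition",
    "descriptor_from_graph",
    "normalize_descriptor_name",
]

#: The nine descriptor functions, in canonical enumeration order:
#: first/second Zagreb, forgotten, hyper-Zagreb, third redefined Zagreb,
#: bi-Zagreb, tri-Zagreb and the two harmonic variants.
DESCRIPTOR_NAMES: Tuple[str, ...] = (
    "M1", "M2", "F", "HZ", "ReZ3", "BM", "TM", "BMH", "TMH",
)

_TD_FUNCTIONS: Mapping[str, Callable[[Fraction, Fraction], Fraction]] = {
    "M1": lambda a, b: a + b,
    "M2": lambda a, b: a * b,
    "F": lambda a, b: a * a + b * b,
    "HZ": lambda a, b: (a + b) ** 2,
    "ReZ3": lambda a, b: (a + b) * a * b,
    "BM": lambda a, b: a + b + a * b,
    "TM": lambda a, b: a * a + b * b + a * b,
    "BMH": lambda a, b: (a + b + a * b) * (a + b) / 2,
    "TMH": lambda a, b: (a * a + b * b + a * b) * (a + b) / 2,
}


class ReverseDegreeError(ValueError):
    """The reverse-degree transform is undefined for these arguments."""


def normalize_descriptor_name(name: str) -> str:
    """Resolve a case-insensitive descriptor name to its canonical form."""
    lookup = {n.lower(): n for n in DESCRIPTOR_NAMES}
    try:
        return lookup[name.lower()]
    except KeyError:
        raise KeyError(
            f"unknown descriptor {name!r}; expected one of {DESCRIPTOR_NAMES}"
        ) from None


def reverse_degree(dv: int, delta: int, k: int) -> int:
    """Reverse degree R_k(dv) in a graph of maximum degree ``delta``.

    Raises
    ------
    ReverseDegreeError
        If the arguments are out of range or the mod branch yields 0,
        which is undefined.
    """
    if not (1 <= dv <= delta):
        raise ReverseDegreeError(f"degree {dv} outside [1, {delta}]")
    if k < 1:
        raise ReverseDegreeError(f"reverse parameter k={k} must be >= 1")
    if k <= dv:
        return delta - dv + k
    r = (delta - dv + k) % delta
    if r == 0:
        raise ReverseDegreeError(
            f"reverse degree of d={dv} with delta={delta}, k={k} wraps to 0 "
            "(undefined)"
        )
    return r


def td_function(name: str, a, b) -> Fraction:
    """Evaluate descriptor function ``name`` on a transformed degree pair.

    Symmetric in (a, b); returns an exact rational.
    """
    fn = _TD_FUNCTIONS[normalize_descriptor_name(name)]
    return fn(Fraction(a), Fraction(b))


@dataclass(frozen=True)
class EdgePartition:
    """Degree-pair edge classes of a graph.

    ``classes`` maps a canonical (du <= dv) degree pair to the number of
    edges |E_i| whose endpoints carry those degrees; ``delta`` is the
    maximum degree of the underlying graph.
    """

    classes: Mapping[Tuple[int, int], int] = field(default_factory=dict)
    delta: int = 0

    def __post_init__(self) -> None:
        canon = {}
        for (du, dv), count in self.classes.items():
            if count < 0:
                raise ValueError(f"negative class count for {(du, dv)}")
            pair = (du, dv) if du <= dv else (dv, du)
            if pair in canon:
                raise ValueError(f"duplicate degree pair {pair}")
            if self.delta and pair[1] > self.delta:
                raise ValueError(
                    f"degree {pair[1]} exceeds stated maximum {self.delta}"
                )
            canon[pair] = count
        object.__setattr__(self, "classes", canon)

    @property
    def total(self) -> int:
        """Total number of edges |E(G)|."""
        return sum(self.classes.values())

    def nonzero(self) -> "EdgePartition":
        """Copy with zero-count classes dropped."""
        return EdgePartition(
            {p: c for p, c in self.classes.items() if c > 0}, self.delta
        )

    @classmethod
    def from_graph(cls, graph: nx.Graph) -> "EdgePartition":
        deg = dict(graph.degree())
        if graph.number_of_edges() == 0:
            return cls({}, max(deg.values()) if deg else 0)
        classes: dict = {}
        for u, v in graph.edges():
            pair = tuple(sorted((deg[u], deg[v])))
            classes[pair] = classes.get(pair, 0) + 1
        return cls(classes, max(deg.values()))


@dataclass(frozen=True)
class DescriptorValue:
    """A descriptor evaluation: name, reverse parameter and exact value."""

    name: str
    k: int
    value: Fraction

    def __float__(self) -> float:
        return float(self.value)


def descriptor_from_partition(
    partition: EdgePartition, name: str, k: int
) -> DescriptorValue:
    """Sum |E_i| * TD(R_k(du), R_k(dv)) over the partition's classes."""
    name = normalize_descriptor_name(name)
    total = Fraction(0)
    for (du, dv), count in partition.classes.items():
        if count == 0:
            continue
        a = reverse_degree(du, partition.delta, k)
        b = reverse_degree(dv, partition.delta, k)
        total += count * td_function(name, a, b)
    return DescriptorValue(name, k, total)


def descriptor_from_graph(graph: nx.Graph, name: str, k: int) -> DescriptorValue:
    """Brute-force per-edge evaluation over an explicit graph.

    Serves as the independent oracle for the partition pathway: the two
    agree on every simple undirected graph.
    """
    name = normalize_descriptor_name(name)
    deg = dict(graph.degree())
    if graph.number_of_edges() == 0:
        return DescriptorValue(name, k, Fraction(0))
    delta = max(deg.values())
    total = Fraction(0)
    for u, v in graph.edges():
        a = reverse_degree(deg[u], delta, k)
        b = reverse_degree(deg[v], delta, k)
        total += td_function(name, a, b)
    return DescriptorValue(name, k, total)


def modified_pair(du: int, dv: int, delta: int, k: int) -> Tuple[int, int]:
    """The reverse-degree image of an (unordered) degree pair."""
    return reverse_degree(du, delta, k), reverse_degree(dv, delta, k)
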