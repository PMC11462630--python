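"""Edge-class graph entropy under descriptor weightings.

For an edge partition {E_1, ..., E_n} and a positive weight f_i per class
(here a descriptor function of the reverse-transformed degree pair), with
T = sum_i |E_i| f_i, the *modified* entropy used throughout this package is

    I_f = log T - (1/T) * sum_i [ log|E_i| + f_i log f_i ],

i.e. the Shannon-type form in which the per-class product |E_i| * f_i^f_i
replaces the classical per-edge product f_i^(f_i |E_i|).  The classical form

    I_f^cl = log T - (1/T) * sum_i |E_i| f_i log f_i

is provided for comparison; the two coincide exactly when every class is a
singleton.  Logs are base 10 by default (the base the reference tables
use); both quantities are computed entirely in log space.

The bond-wise entropy BI = I_f / |E(G)| normalises by edge count so that
frameworks of different sizes can be compared per bond.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from .descriptors import (
    EdgePartition,
    normalize_descriptor_name,
    reverse_degree,
    td_function,
)
from .families import edge_partition as family_edge_partition

__all__ = [
    "WeightedClass",
    "WeightedPartition",
    "EntropyResult",
    "weighted_partition",
    "modified_entropy",
    "classical_entropy",
    "bondwise_entropy",
    "entropy_result",
    "entropy_table",
]


@dataclass(frozen=True)
class WeightedClass:
    pair: Tuple[int, int]
    count: int
    weight: Fraction  # descriptor value of the transformed degree pair


@dataclass(frozen=True)
class WeightedPartition:
    classes: Tuple[WeightedClass, ...]

    def __post_init__(self) -> None:
        for c in self.classes:
            if c.weight <= 0:
                raise ValueError(f"non-positive weight for class {c.pair}")
            if c.count < 0:
                raise ValueError(f"negative count for class {c.pair}")

    @property
    def total(self) -> Fraction:
        """T = sum_i |E_i| * f_i (the descriptor value of the graph)."""
        return sum((c.count * c.weight for c in self.classes), Fraction(0))

    @property
    def edge_count(self) -> int:
        return sum(c.count for c in self.classes)


def weighted_partition(
    partition: EdgePartition, name: str, k: int
) -> WeightedPartition:
    """Attach reverse-degree descriptor weights to an edge partition.

    Zero-count classes are dropped (they contribute no edges and would be
    undefined under log).
    """
    name = normalize_descriptor_name(name)
    classes = []
    for (du, dv), count in partition.classes.items():
        if count == 0:
            continue
        a = reverse_degree(du, partition.delta, k)
        b = reverse_degree(dv, partition.delta, k)
        classes.append(WeightedClass((du, dv), count, td_function(name, a, b)))
    return WeightedPartition(tuple(classes))


def _log(x: float, base: float) -> float:
    return math.log(x) / math.log(base)


def modified_entropy(wp: WeightedPartition, log_base: float = 10.0) -> float:
    """I_f = log T - (1/T) sum_i [log|E_i| + f_i log f_i]."""
    if not wp.classes:
        raise ValueError("entropy of an empty partition is undefined")
    total = float(wp.total)
    corr = 0.0
    for c in wp.classes:
        f = float(c.weight)
        corr += _log(c.count, log_base) + f * _log(f, log_base)
    return _log(total, log_base) - corr / total


def classical_entropy(wp: WeightedPartition, log_base: float = 10.0) -> float:
    """Shannon form: log T - (1/T) sum_i |E_i| f_i log f_i."""
    if not wp.classes:
        raise ValueError("entropy of an empty partition is undefined")
    total = float(wp.total)
    corr = 0.0
    for c in wp.classes:
        f = float(c.weight)
        corr += c.count * f * _log(f, log_base)
    return _log(total, log_base) - corr / total


def bondwise_entropy(entropy: float, edge_count: int) -> float:
    """BI = I_f / |E(G)|."""
    if edge_count <= 0:
        raise ValueError("edge count must be positive")
    return entropy / edge_count


@dataclass(frozen=True)
class EntropyResult:
    family: str
    m: int
    n: int
    k: int
    descriptor: str
    total: Fraction
    entropy: float
    bondwise: float
    edge_count: int
    log_base: float


def entropy_result(
    family: str,
    m: int,
    n: int,
    k: int,
    descriptor: str,
    log_base: float = 10.0,
    classical: bool = False,
) -> EntropyResult:
    """Entropy of a family lattice from its partition closed forms."""
    part = family_edge_partition(family, m, n)
    wp = weighted_partition(part, descriptor, k)
    fn = classical_entropy if classical else modified_entropy
    I = fn(wp, log_base)
    ec = wp.edge_count
    return EntropyResult(
        family=family,
        m=m,
        n=n,
        k=k,
        descriptor=normalize_descriptor_name(descriptor),
        total=wp.total,
        entropy=I,
        bondwise=bondwise_entropy(I, ec),
        edge_count=ec,
        log_base=log_base,
    )


def entropy_table(
    family: str,
    k: int,
    names: Optional[Sequence[str]] = None,
    dims: Optional[Sequence[Tuple[int, int]]] = None,
    log_base: float = 10.0,
) -> pd.DataFrame:
    """Entropy values for a grid of lattice dimensions.

    One row per descriptor, one column per (m, n); full precision is
    retained (round for display as needed).
    """
    from .descriptors import DESCRIPTOR_NAMES

    names = list(names) if names else list(DESCRIPTOR_NAMES)
    dims = list(dims) if dims else [(m, m) for m in (1, 2, 3, 4)]
    data = {}
    for m, n in dims:
        col = []
        for name in names:
            col.append(entropy_result(family, m, n, k, name, log_base).entropy)
        data[(m, n)] = col
    return pd.DataFrame(data, index=[normalize_descriptor_name(n) for n in names])
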