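"""Closed-form specifications of the four 2D MOF lattice families.

Each family — TM-Pc (transition-metal phthalocyanine), MOAPc (metal
octa-amino phthalocyanine), MBHT (metal butylated hydroxytoluene) and
NHC-TM (NH-substituted coronene transition metal) — is a 2D lattice
parameterised by void dimensions (m, n), with maximum degree 4.  A family
carries three kinds of closed forms, all bivariate polynomials in (m, n)
with monomials {mn, m, n, 1}:

* vertex and edge counts,
* the degree-pair edge-partition class sizes, and
* the tabulated descriptor polynomials, indexed by (descriptor, k).

The partition and descriptor polynomials are two independent computation
pathways for the same quantities.  For TM-Pc they agree everywhere; for the
other three families they disagree (the partitions, not the descriptor
polynomials, are consistent with the explicitly reconstructed lattices —
see :mod:`moftopo.builder`).  :func:`consistency_report` makes the
comparison explicit instead of silently preferring one side.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache
from importlib import resources
from typing import Dict, List, Mapping, Tuple

from .descriptors import (
    DESCRIPTOR_NAMES,
    DescriptorValue,
    EdgePartition,
    descriptor_from_partition,
    normalize_descriptor_name,
)

__all__ = [
    "FAMILY_NAMES",
    "FamilySpec",
    "ConsistencyReport",
    "get_family",
    "normalize_family_name",
    "vertex_count",
    "edge_count",
    "edge_partition",
    "published_descriptor",
    "consistency_report",
]

FAMILY_NAMES: Tuple[str, ...] = ("TM-Pc", "MOAPc", "MBHT", "NHC-TM")

Poly = Mapping[str, int]  # monomial key ("mn", "m", "n", "1") -> coefficient


def eval_poly(poly: Poly, m: int, n: int) -> int:
    return (
        poly.get("mn", 0) * m * n
        + poly.get("m", 0) * m
        + poly.get("n", 0) * n
        + poly.get("1", 0)
    )


@dataclass(frozen=True)
class FamilySpec:
    name: str
    delta: int
    vcount: Poly
    ecount: Poly
    partition_formulas: Mapping[Tuple[int, int], Poly]
    published_polys: Mapping[Tuple[str, int], Poly]


@dataclass(frozen=True)
class ConsistencyReport:
    """Partition-pathway vs published-polynomial value for one descriptor."""

    family: str
    k: int
    descriptor: str
    m: int
    n: int
    partition_value: Fraction
    published_value: Fraction
    agree: bool


def normalize_family_name(name: str) -> str:
    lookup = {f.lower().replace("-", ""): f for f in FAMILY_NAMES}
    key = name.lower().replace("-", "").replace("_", "")
    try:
        return lookup[key]
    except KeyError:
        raise KeyError(
            f"unknown family {name!r}; expected one of {FAMILY_NAMES}"
        ) from None


@lru_cache(maxsize=1)
def _load_specs() -> Dict[str, FamilySpec]:
    raw = json.loads(
        resources.files("moftopo.data").joinpath("families.json").read_text()
    )
    specs = {}
    for fam, doc in raw["families"].items():
        partition = {
            tuple(int(x) for x in key.split(",")): poly
            for key, poly in doc["partition"].items()
        }
        published = {}
        for key, poly in doc["published"].items():
            name, ktag = key.split(",")
            published[(name, int(ktag[1:]))] = poly
        specs[fam] = FamilySpec(
            name=fam,
            delta=doc["delta"],
            vcount=doc["vcount"],
            ecount=doc["ecount"],
            partition_formulas=partition,
            published_polys=published,
        )
    return specs


def get_family(name: str) -> FamilySpec:
    return _load_specs()[normalize_family_name(name)]


def _check_dims(m: int, n: int) -> None:
    if m < 1 or n < 1:
        raise ValueError(f"lattice dimensions must be positive, got ({m}, {n})")


def vertex_count(family: str, m: int, n: int) -> int:
    _check_dims(m, n)
    return eval_poly(get_family(family).vcount, m, n)


def edge_count(family: str, m: int, n: int) -> int:
    _check_dims(m, n)
    return eval_poly(get_family(family).ecount, m, n)


def edge_partition(family: str, m: int, n: int) -> EdgePartition:
    """Evaluate the family's partition polynomials at (m, n).

    Classes that evaluate to zero are omitted.
    """
    _check_dims(m, n)
    spec = get_family(family)
    classes = {}
    for pair, poly in spec.partition_formulas.items():
        count = eval_poly(poly, m, n)
        if count < 0:
            raise ValueError(
                f"{spec.name} partition class {pair} negative at ({m}, {n})"
            )
        if count:
            classes[pair] = count
    return EdgePartition(classes, spec.delta)


def published_descriptor(family: str, name: str, k: int, m: int, n: int) -> int:
    """Evaluate the tabulated closed-form descriptor polynomial as printed."""
    _check_dims(m, n)
    spec = get_family(family)
    name = normalize_descriptor_name(name)
    try:
        poly = spec.published_polys[(name, k)]
    except KeyError:
        raise KeyError(
            f"no tabulated polynomial for {spec.name} descriptor {name} at k={k}"
        ) from None
    return eval_poly(poly, m, n)


def consistency_report(
    family: str, k: int, m: int, n: int
) -> List[ConsistencyReport]:
    """Compare the partition pathway against the tabulated polynomials.

    The disagreement pattern is a stable property of the source tables:
    TM-Pc agrees for every descriptor and k; the other three families do
    not (e.g. MOAPc at (1,1), k=1, M1: 1232 from the partition vs 1280
    from the polynomial).
    """
    part = edge_partition(family, m, n)
    reports = []
    for name in DESCRIPTOR_NAMES:
        pv = descriptor_from_partition(part, name, k).value
        try:
            pub = Fraction(published_descriptor(family, name, k, m, n))
        except KeyError:
            continue
        reports.append(
            ConsistencyReport(
                family=normalize_family_name(family),
                k=k,
                descriptor=name,
                m=m,
                n=n,
                partition_value=pv,
                published_value=pub,
                agree=pv == pub,
            )
        )
    return reports


def descriptor_value(family: str, name: str, k: int, m: int, n: int) -> DescriptorValue:
    """Partition-pathway descriptor value for a family lattice."""
    return descriptor_from_partition(edge_partition(family, m, n), name, k)
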