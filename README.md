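# moftopo

Reverse-degree topological descriptors, edge-class graph entropy and
adjacency-spectrum graph energy for two-dimensional metal-organic-framework
(MOF) lattices, with a QSPR linear-regression stage that predicts graph
energy from descriptors.

## The problem

Degree-based topological indices summarise a molecular graph G by a
bond-additive sum over its edges.  This package implements the *modified
reverse degree* variant: with Δ = Δ(G) the maximum degree and a shift
parameter k ≥ 1, each vertex degree d is replaced by

```
R_k(d) = Δ − d + k            if k ≤ d
R_k(d) = (Δ − d + k) mod Δ    if k > d
```

and a descriptor is `TD_k(G) = Σ_{uv ∈ E(G)} TD(R_k(d_u), R_k(d_v))` for one
of nine symmetric functions TD — first/second Zagreb (a+b, ab), forgotten
(a²+b²), hyper-Zagreb ((a+b)²), third redefined Zagreb ((a+b)ab), bi-Zagreb
(a+b+ab), tri-Zagreb (a²+b²+ab) and the harmonic variants
((a+b+ab)(a+b)/2, (a²+b²+ab)(a+b)/2).  Because the summand depends only on
the endpoint degree pair, the sum collapses onto the graph's *edge
partition* {E_i} (edges classed by degree pair), and for the lattice
families supported here every class size is a closed-form polynomial in
the lattice dimensions (m, n).

Four MOF families are built in, all with Δ = 4:

* **TM-Pc** — transition-metal phthalocyanine sheets (macrocycles fused
  through shared benzene rings),
* **MOAPc** — metal octa-amino phthalocyanine (macrocycles bridged by
  square-planar metal nodes chelated by amino N),
* **MBHT** — metal benzene-ring/S₆ units on a brick-wall lattice joined by
  square-planar metals,
* **NHC-TM** — NH-substituted coronene units complexed with transition
  metals.

On top of the descriptors the package computes the edge-class entropy

```
I_f = log₁₀ T − (1/T) Σ_i [ log₁₀|E_i| + f_i log₁₀ f_i ],   T = Σ_i |E_i| f_i
```

(with the classical Shannon form available for comparison), the bond-wise
entropy `BI = I_f / |E(G)|`, the graph energy `E_π = Σ_i |λ_i|` of the
adjacency spectrum, and per-family ordinary-least-squares models
`E_π = a·TD + b` with r, r², adjusted r², residual standard error and F.

The lattice graphs themselves can be constructed explicitly
(`moftopo.build`), validated against the closed-form vertex/edge counts and
partitions, and exported as plain-text edge lists; arbitrary graphs can be
read back in for brute-force descriptor, entropy and spectral work.

## Worked example

```python
>>> import moftopo as mt
>>> part = mt.edge_partition("TM-Pc", 1, 1)       # closed-form partition
>>> part.classes
{(2, 2): 16, (2, 3): 48, (3, 3): 40, (3, 4): 16}
>>> mt.descriptor_from_partition(part, "M1", 1).value
Fraction(544, 1)
>>> round(mt.modified_entropy(mt.weighted_partition(part, "M1", 1)), 5)
2.70307
>>> g = mt.build("TM-Pc", 1, 1)                   # explicit lattice graph
>>> g.number_of_nodes(), g.number_of_edges()
(92, 120)
>>> mt.round_half_up(mt.graph_energy(g), 3)
133.489
```

The unit TM-Pc cell has 92 atoms and 120 bonds; its k=1 first-Zagreb
descriptor is exactly 544, the base-10 edge-class entropy of that weighting
is 2.703, and the sum of absolute adjacency eigenvalues — the graph energy —
is 133.489.  The regression stage then links descriptor to energy across
lattice sizes:

```python
>>> fit = mt.family_fits(mt.property_table(), "TM-Pc", 3)["M1"]
>>> mt.round_half_up(fit.slope, 3), mt.round_half_up(fit.intercept, 3)
(0.168, 17.263)
>>> mt.predict(fit, mt.published_descriptor("TM-Pc", "M1", 3, 4, 4), 3)
988.303...
```

i.e. a TM-Pc(4,4) sheet's energy is predicted as 988.3 from its k=3
first-Zagreb value (5780) without forming the 2281-atom adjacency matrix.

The same operations are available from the shell:

```
$ moftopo energy --family TM-Pc -m 1 -n 1
{"graph": "TM-Pc(1,1)", "vertices": 92, "edges": 120, "energy": 133.489}
$ moftopo entropy TM-Pc -m 1 -n 3 -k 3 --name TMH --bondwise
family,m,n,k,descriptor,entropy,bondwise
TM-Pc,1,3,3,TMH,4.432466,0.017048
```

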