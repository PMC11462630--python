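# Methods

## Reverse-degree descriptors

The reverse-degree transform `R_k(d) = Δ−d+k` (with a mod-Δ wrap when
k > d) is applied to vertex degrees before evaluating any of the nine
bond-additive descriptor functions.  The wrap branch can produce 0 for
some (Δ, d, k) combinations — e.g. Δ=3, d=2, k=5 — for which neither the
transform nor the descriptors are meaningfully defined; `moftopo` raises
`ReverseDegreeError` there rather than remapping.  In the Δ=4, k ≤ 3
regime of the built-in families the wrap never reaches 0.  k is accepted
for any k ≥ 1, not just 1–3, since the definition is general.

All descriptor arithmetic is exact (`fractions.Fraction`): seven of the
nine functions are integer-valued on integer arguments, and the two
harmonic variants are at worst half-integral.  Floats appear only at
presentation (entropy, spectra, regression).

Two computation pathways exist for the built-in families and are kept
strictly separate:

* the **partition pathway** — evaluate the degree-pair class-size
  polynomials at (m, n) and sum class contributions, and
* the **published-polynomial pathway** — evaluate the tabulated
  closed-form descriptor polynomials directly.

For TM-Pc they agree identically.  For MOAPc, MBHT and NHC-TM they
disagree (e.g. MOAPc(1,1), k=1, first Zagreb: 1232 vs 1280).  The explicit
lattice reconstructions (below) side with the partition pathway: the built
graphs match the partition class counts *and* reproduce the tabulated
spectral energies, so the closed-form descriptor polynomials for those
three families are internally inconsistent with the structures.
`consistency_report` surfaces the comparison instead of silently
preferring either side; the regression stage deliberately consumes the
tabulated values (see below).

### Known inconsistencies in the shipped reference tables

The shipped `descriptor_values.csv` transcribes the tabulated reference
values verbatim, including five rows that contradict the closed forms:
the TM-Pc(3,3) k=2 row, the MOAPc(2,3) k=1 row, and three MOAPc k=2 rows
that are verbatim duplicates of the corresponding k=3 rows.  Tests pin
these mismatches as stable properties of the source data.  The entropy
reference block inherits the TM-Pc(3,3) k=2 corruption in its k=2, m=3
column.

## Lattice reconstructions

No coordinates or connection tables are published for the four families;
the unit cells were reverse-engineered from the depicted structures under
the closed-form count and partition constraints, which act as the
acceptance oracle for the builder.  The reconstructions are:

* **TM-Pc(m,n)** — phthalocyanine cores (metal + 4 isoindole N + 4 aza N +
  8 α-C; 17 atoms, 20 bonds) on an (m+1)×(n+1) grid; adjacent cores share
  a benzene ring (6 C, 10 bonds including the four fusion bonds), two of
  whose carbons close each neighbour's pyrrole ring.  Boundary pyrroles
  stay open.
* **MOAPc(m,n)** — the same core with four unshared fused benzenes
  carrying two amino N each; neighbouring macrocycles are bridged by a
  shared square-planar metal bonded to two amino N per side.  Boundary
  bridge metals keep one chelating pair (degree 2).
* **NHC-TM(m,n)** — coronene units (hub hexagon, 6 junctions, 12 rim C);
  8 rim positions carry N, in four chelating pairs toward shared bridge
  metals, and the 4 bare rim carbons are pairwise non-adjacent (the
  placement is forced by the partition constraints up to symmetry).
* **MBHT(m,n)** — an m×n brick-wall patch of hexagons whose vertices are
  benzene C₆S₆ units, whose edges are square-planar metals bonded to one
  S–S chelate pair from each adjacent unit, and whose boundary valence
  deficiencies are capped by degree-2 metals.

Validation is three-fold: vertex count, edge count and degree-pair
partition all match the closed forms for every family (tested on the full
reference grid).  The decisive corroboration is spectral: the graph energy
of every reconstructed lattice reproduces the tabulated reference energies
at all six reference dimensions per family — 24 of 24 cells — to the
printed 3 d.p. (one cell, MBHT(3,3), computes 584.5833 against a printed
584.584, a last-digit rounding artifact).  Graph energy is an extremely
sharp structural fingerprint, so agreement across 24 independent spectra
leaves essentially no freedom in the connectivity.

`build` is deterministic: vertex ids are contiguous integers assigned in a
fixed construction order, so the same (family, m, n) always yields the
same edge set — a requirement for reproducible edge-list files.
Graphs are abstract (no element labels or coordinates); every computation
here uses connectivity only.

## Entropy

The edge-class entropy uses the *modified* product Π |E_i|·f_i^{f_i}
(one log|E_i| term per class) rather than the classical Shannon product
Π f_i^{f_i|E_i|} (one per edge); both are computed entirely in log space,
base 10 by default (the base of the reference tables), with the base
exposed as a parameter and an exact change-of-base identity tested.  The
two forms coincide exactly when every class is a singleton.  They are not
ordered in general: on the lattice partitions, where classes hold dozens
of edges, the modified correction is far smaller, so the modified entropy
*exceeds* the classical one — and can exceed the log|E| Shannon bound,
which applies only to the classical form.  Zero-count classes are dropped
before evaluation (they contribute no edges and would be undefined under
log).

Bond-wise entropy divides by the edge count, making frameworks of
different sizes comparable per bond.  Display rounding for comparisons
against reference values is half-up (3 d.p. for the entropy block,
6 d.p. for bond-wise values); full precision is retained internally.

## Spectra

The adjacency matrix of an undirected simple graph is real symmetric, so
eigenvalues are computed with `numpy.linalg.eigvalsh` (guaranteed real
spectrum).  Invariants tested on every computed spectrum: Σλ = 0,
Σλ² = 2|E|, the McClelland bound E_π ≤ √(2|E||V|), spectral symmetry for
bipartite graphs and the closed form E_π(K_n) = 2(n−1).  Reported energies
are rounded half-up to 3 d.p. to match the reference presentation.  The
largest built-in reference lattice (MOAPc(3,3), 824 vertices) decomposes
in well under a second on one CPU.

## Regression

Each family is fitted separately over its six reference dimensions:
energy against one descriptor column, by ordinary least squares
(`scipy.stats.linregress` core; r², adjusted r², residual standard error
√(SSE/(n−2)) and F = SSR/(SSE/(n−2)) derived from the residuals and
cross-checked against statsmodels in the tests).  A perfect fit reports
se = 0 and F = ∞, flagged via `RegressionFit.exact` rather than raised —
exact collinearity is legitimate in synthetic data.  Model selection is
max-F with min-se then enumeration order as tie-breaks, deterministic.

The default inputs are the *tabulated* descriptor values joined with the
tabulated energies, not recomputed descriptors: the reference regressions
demonstrably used the printed tables, and recomputed values differ for
three families (see above).  `predict` optionally rounds the fitted
coefficients half-up to a fixed number of decimals first; this replicates
predictions made from regression equations quoted at printed precision.
Quoted reference equations carry last-digit rounding noise in a few
intercepts (and one decimal-shift misprint in a quoted k=2 intercept,
−4.33 for a fitted −0.433), so exact replication of the printed
predictions requires the quoted coefficients; predictions from this
package's own 3-d.p.-rounded fits agree within 0.002.  Printed F-values
run 0.01–0.06% below the exact OLS F — F is sensitive to the sixth digit
of r² when r² ≈ 0.999998 — and are compared at 0.1% relative tolerance.

Quadratic models are out of scope: no quadratic coefficients are
tabulated anywhere, leaving nothing to verify.

## Numerical and design choices

* Exact rational arithmetic for everything the tables print exactly;
  half-up decimal rounding (`round_half_up`) for every printed-precision
  comparison, since Python's banker's rounding disagrees on ties.
* `random_test_graph` (the fixture generator for oracle and property
  tests) draws a vertex count and an edge budget from a seeded generator
  and inserts shuffled candidate edges subject to the degree cap —
  reproducible for a fixed seed, always at least one edge.
* Problem sizes in the test suite: descriptor oracle equivalence uses 200
  seeded random graphs of up to 30 vertices with degree cap 6; spectral
  property checks run on the (1,1)–(2,3) built lattices plus random and
  complete graphs.  These sizes exercise every code path while keeping
  the whole suite a few seconds long.
* The synthetic regression check generates y = 0.2x + 7 + N(0,1) at the
  reference design size n = 6 (matching the slope/noise scale of the
  energy fits) and verifies 3-SE parameter coverage over 40 seeds.

## Limitations

* The lattice reconstructions, however strongly corroborated by the
  24/24 energy agreement, remain reverse-engineered; any structural
  feature invisible to both the degree partition and the adjacency
  spectrum is unconstrained.
* Entropy reference values for the MOAPc/MBHT/NHC-TM families match
  neither computation pathway in spot checks and are not reproduction
  targets; the TM-Pc block is the anchor.
* Distance-based indices, vertex-partition descriptor variants,
  Laplacian/distance energies and crystallographic file formats are out
  of scope.
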