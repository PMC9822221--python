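# Methods

This note documents the models, algorithms, numerical choices and known
limitations behind `wnrtools`.  Energies are in units of the Hückel
resonance integral β (β > 0); all structural quantities refer to the
hydrogen-suppressed carbon skeleton.

## 1. Graph construction

### Lattice representation

Carbons live on the honeycomb lattice with exact integer coordinates
`(x, y)`; the Cartesian position is `(√3/2·x·L, y/2·L)` with `L = 1.42 Å`,
so lattice bonds are the displacements `(0, ±2)` and `(±1, ±1)`.
Hexagon centres sit at `(2b + a, 3a)`.  Vertices are deduplicated by
exact integer coordinate — never by floating-point comparison — and are
numbered in lexicographic coordinate order, which makes every downstream
report byte-reproducible.

The r×c **parallelogram benzenoid** `M(r,c)` is the union of hexagons
`(i, j) → centre (2j + i, 3i)`, `0 ≤ i < r`, `0 ≤ j < c`.  It has
`2(rc + r + c)` carbons, `3rc + 2r + 2c − 1` bonds, `2(r + c + 1)` of its
carbons have degree 2, and its Kekulé count is `C(r+c, r)`.

### The ZNR/WNR junction

The zigzag-edged unit **ZNR(r,c)** couples `M(r,c)` to a second,
mirror-image parallelogram through `r` parallel single bonds attached at
the right-hand zigzag teeth `R_i = (2c − 1 + i, 3i − 1)`, `i = 0..r−1`.
The second copy is the image of the first under the glide reflection

    f(x, y) = ((x − y)/2 + 2c + r,  −(3x + y)/2 + 3r − 6),

and the bonds are the diagonal lattice edges `R_i → R_i + (1, −1)`.  The
wave-like ribbon **WNR(r,c,n)** is the glide orbit: parallelogram k is
`f^k(M(r,c))` for `k = 0..2n−1`, with the coupling bonds carried along by
`f`.  Successive parallelograms alternate between the two mirror-image
slants, which is precisely the trans/wave geometry; `n = 1` reduces to
ZNR(r,c).  The counts follow: `4n(cr + c + r)` carbons and
`n(2c(3r + 2) + 5r − 2) + r(n − 1)` bonds, checked at build time.

**How the junction was certified.**  Vertex/edge counts and the bond
degree partition do not pin the junction (several couplings produce the
same local structure but different global distances).  The construction
above was selected by exhaustive search over all honeycomb congruences of
the second parallelogram and all candidate bridge sets between degree-2
sites, with three independent structural certificates that only the
intended geometry satisfies simultaneously:

1. the published HOMO–LUMO gaps of ZNR(3,3), ZNR(3,4) and ZNR(4,3)
   (0.132706/0.07387/0.048414 β) — the search produced a *unique* junction
   up to congruence;
2. the distance-descriptor table of WNR(n,n,n) (W, We, Wev, Szv, Sze,
   Szev, PI, S, Gut exact for n = 1..10);
3. the bond degree partition formulas for 1 ≤ r, c, n ≤ 6.

A plain "staircase" chain (all couplings on the same side), by contrast,
reproduces the degree partition but gives W(WNR(2,2,2)) = 17012 instead
of 16988 and a ZNR(3,3) gap of 0.143 β.

### Hydrogens

Hydrogens are never materialized.  Every degree-2 carbon bears one
implicit H, so the skeleton's C–H bond count is `4cn + 4n + 2r`.  The
family's published closed form `2(2cn + r)` differs from this by `4n`;
both numbers are exposed (`ch_bond_count` vs `degree_two_count`) and the
difference is reported, not reconciled.

## 2. Cut-method distance descriptors

Two bonds are Θ-related when `d(r1,r2) + d(s1,s2) ≠ d(r1,s2) + d(s1,r2)`.
The engine computes BFS distances (`scipy.sparse.csgraph`, int16 storage:
WNR(10,10,10) with 4800 carbons needs ~46 MB), then closes the pairwise
relation transitively with a union–find — a no-op on genuine partial
cubes, where Θ is already transitive, but taken defensively.  Each class
is certified by deletion: exactly two components must remain, else the
input is rejected as not a partial cube (`K4`, for instance, is refused
rather than silently mis-scored).  The per-class parameters
`(|B|, n1, n2, m1, m2)` are assembled into the eleven descriptors with
exact integer arithmetic; the ½ factors of Wev/Szev are applied after an
evenness assertion.  The pairwise scan is O(|E|²) with vectorized
distance lookups — about 5 s for WNR(10,10,10)'s 6970 bonds.

W, S and Gut are additionally checked against direct degree-weighted
distance sums (independent oracles) on every tested ribbon.

## 3. Degree and degree-sum descriptors

Bond partitions by endpoint degree `(d_u, d_v)` or neighbourhood degree
sum `(s_u, s_v)` (both on the carbon skeleton; pairs stored sorted), and
the eleven bond-additive functionals ψ(s,t) (M1, M2, SO, SC, GA, AZ, ISI,
ABC, F, SDD, H).  Closed-form partitions for the family:

* degree mode, valid for all r, c, n ≥ 1:
  `d22 = 4(n+1)`, `d23 = 4(2cn + r − 2)`,
  `d33 = 6cnr + 6nr − 4cn − 5r − 6n + 4`;
* degree-sum mode, ten classes, valid for r, c, n ≥ 2 only.  At n = 1
  several closed-form counts are negative and the closed form disagrees
  with the skeleton (direct M2s of WNR(1,1,1) is 333, the closed form
  gives 297); validation therefore starts at n = 2 and the n = 1 column
  is flagged, not patched.

The closed-form descriptor values ("theorem3/4") are computed by weighting
these partitions with ψ — mathematically identical to the published
expanded polynomials, which were verified against the readable rational
items (M1, M2, F, ISI, H, SDD, AZ).

## 4. Closed-form distance polynomials

The wide family (`r ≤ c`, `r ≥ 2`, empirically also valid at `c = r − 1`)
and the narrow family (`c = r − 2`, `r ≥ 3`) are transcribed into exact
`Fraction` arithmetic; the Mostar items carry `(−1)^n` parity terms with
absolute values.  Every closed form is regression-locked against the
direct engines:

* wide family: exact equality on the full grid r ≤ c ≤ 5, n ≤ 4
  (including c = r − 1), all eleven descriptors *including* the Mostar
  parity terms;
* narrow family: exact equality for r ≤ 7, n ≤ 4, **except** the n = 1
  boundary for wide-narrow ribbons (Moe from r = 5, Mov from r = 6), where
  the published closed forms assume an |m1 − m2| sign pattern that only
  holds once inter-unit cuts exist.  The discrepancy reporter surfaces
  these; direct computation is authoritative.

## 5. Reference-table discrepancies

Validating against the published family tables exposed several cells that
are internally inconsistent with the same source's own formulas.  They are
kept in `reference_values.py`, asserted as printed (failing honestly), and
catalogued in `KNOWN_DISCREPANT`:

* **Mostar rows of the distance table** equal the closed-form polynomials
  *without* their parity-correction terms.  No graph can reproduce them:
  W and Szv fix the multiset {(|B|, n1, n2)}, which then forces
  Mov = Σ|B||n1−n2|.  The true values are the full closed forms (e.g.
  Mov(WNR(2,2,2)) = 2516, printed 2476; the difference is exactly
  `4(r+c+1)|r² − 2c − 2|`).
* **Degree-table H row** is not the harmonic index: it contradicts the
  source's own closed form `(30cnr + 28cn + 30nr − r + 2)/15`, which our
  direct computation matches exactly.  Isolated typos: degree-table SC at
  n = 2 (34.824 for 35.824) and degree-sum SC at n = 5 (244.874 for
  244.8715).
* **Spectral table**: ZNR(5,3) gap prints 0.0184152 vs computed 0.0181517,
  and WNR(3,4,5) prints 0.00074 vs computed 0.0000732 (the printed value
  also breaks the monotone gap decrease with n that the computed series
  obeys).  All other gaps and every π-energy match to the last printed
  digit.
* **Resonance-energy column**: the exact Kekulé count of the units is
  `K(ZNR(r,c)) = C(r+c, r)²` — the r coupling bonds all leave the same
  bipartition colour class of each parallelogram, so no Kekulé structure
  can use them; determinant route, matching DP and the closed form agree.
  The printed RE values imply non-integer K (e.g. 295.3 for ZNR(3,3),
  where K = 400 and RE = 1.185·ln 400/60 = 0.1183314 β vs printed
  0.1123377), and distinct rows with identical (K, N) print different RE.
  The column is treated as unverifiable.

Elsewhere the printed tables mix truncation and nearest-rounding in the
last digit, so float comparisons use a tolerance of one unit in the last
printed digit.

## 6. Spectral analysis

Dense symmetric eigendecomposition (`numpy.linalg.eigvalsh`; the largest
case used anywhere is 4800×4800, the spectral table needs ≤ 460×460).
Gap = difference of the two middle eigenvalues of the descending spectrum
(reported non-negative; equals twice the smallest non-negative eigenvalue
for alternants).  E_π = 2·Σ positive eigenvalues; "per site" means per
carbon, which at half filling equals per π-electron — the delocalization
column of the reference equals E_π/N − 1 exactly, which fixes that
normalization.  E_deloc/site = E_π/site − 1.

Kekulé counts: primary route `K = round(√|det A|)` (valid for benzenoid
alternants; `slogdet` keeps large cases finite), mandatorily cross-checked
on graphs ≤ 40 vertices against an exact boundary dynamic program that
eliminates vertices in lexicographic coordinate order and tracks the set
of forward-matched boundary vertices.  Disagreement raises.  Herndon
resonance energy RE/site = 1.185·ln K/N, undefined (error, not −∞) at
K = 0.

## 7. DDSV equivalence, NMR and ESR

DDSVs are computed from the BFS distance matrix and compared after
zero-padding to the graph diameter.  Class count = predicted ¹³C signal
count; class sizes give the intensity pattern.  For every family member
tested the classes all have size 2 (N/2 signals), consistent with the
fixed-point-free C2 symmetry of the units; small biphenyl-like cases have
larger orbits (2+2+4+4 for WNR(1,1,1)).  An independent automorphism-orbit
oracle (VF2 self-isomorphism enumeration with the DDSV as pruning
invariant) must refine-or-equal the DDSV partition; this is asserted on
fixtures.  DDSV equivalence is a necessary, not sufficient, criterion for
automorphic equivalence — on these ribbons the two coincide wherever we
enumerate orbits, but that is checked, not assumed.

ESR: classes of k equivalent spin-½ nuclei contribute binomial
multiplets; the composed pattern assumes pairwise-distinct couplings
(coupling magnitudes are outside the model), composes classes in
(size, smallest-member) order, and is expanded only below a configurable
line cap (default 10⁶); above it the structured lazy form (class sizes,
multiplets, exact line count as a big integer) is returned.  Intensity
conservation Σ = 2^(#spins) is asserted on expanded cases.

## 8. Problem sizes and determinism

The validation suite covers the parameter box 1 ≤ r, c, n ≤ 6 for counts
and partitions, r, c ≤ 5 with n ≤ 4 for closed-form/direct equivalence,
n = 1..10 for the WNR(n,n,n) tables (largest graph: 4800 carbons), and
the eleven spectral-table rows (≤ 460 carbons).  Everything in the
package is deterministic; there is no random number generation anywhere
in the computational path (the acceptance script accepts a seed argument
for interface uniformity only).

## 9. Limitations

* 2-D topology only: no 3-D geometry, curvature, or DFT-level energetics;
  β is not assigned an eV value.
* The cut engine requires partial-cube inputs (all benzenoid-type
  skeletons qualify) and O(N²) distance storage; ~7000 bonds is the
  comfortable range for the Θ scan.
* The determinant Kekulé route assumes a benzenoid alternant; for other
  graphs use the DP explicitly.
* Open-shell electronic structure is out of scope: near-zero gaps are
  reported as computed, without spin-state modelling.
* The ESR pattern is combinatorial; real spectra collapse lines with
  equal or near-equal couplings.
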