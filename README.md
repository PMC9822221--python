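# wnrtools

Topological, spectral and spectroscopic analysis of **wavy zigzag
graphene nanoribbons** — the molecular graphs WNR(r,c,n) obtained by
trans-coupling n zigzag-edged nanographene units ZNR(r,c), each unit
being two r×c parallelogram benzenoids joined by r single bonds.

The package is aimed at mathematical chemists and nanomaterials
researchers who need exact, reproducible structure descriptors for
QSPR/QSAR work and quick Hückel-level stability estimates:

* **Builders** for M(r,c) parallelogram benzenoids, ZNR(r,c) units and
  WNR(r,c,n) ribbons on an exact integer honeycomb lattice, with
  GraphML/edge-list/XYZ/SDF export and readers for external skeletons.
* **Cut-method distance descriptors.** The Djoković–Winkler relation
  partitions the bonds of a partial cube into Θ*-classes B₁…B_k; deleting
  a class leaves two components with n₁, n₂ vertices and m₁, m₂ edges,
  and the engine assembles
  W = Σ n₁n₂, We = Σ m₁m₂, Wev = ½Σ(n₁m₂ + n₂m₁),
  Szv = Σ|B|n₁n₂, Sze = Σ|B|m₁m₂, Szev = ½Σ|B|(n₁m₂ + n₂m₁),
  PI = |E|² − Σ|B|², S = 2Σ(n₁m₂ + n₂m₁) + |E||V|,
  Gut = Σ(4m₁m₂ − |B|²) + 2|E|², Mov = Σ|B||n₁ − n₂|,
  Moe = Σ|B||m₁ − m₂| — in exact integer arithmetic, with independent
  distance-sum oracles for W, S, Gut.
* **Degree descriptors.** Degree and neighbourhood-degree-sum edge
  partitions and the eleven bond-additive functionals ψ(s,t) (Zagreb,
  Sombor, ABC, GA, augmented Zagreb, ISI, sum-connectivity, forgotten,
  SDD, harmonic).
* **Closed forms.** Exact polynomial values of all of the above for the
  ribbon family (wide r ≤ c and narrow c = r − 2 regimes), cross-checked
  descriptor-by-descriptor against the direct engines with a discrepancy
  report.
* **Hückel spectra**: HOMO–LUMO gaps, π-energies and delocalization
  energies per site (in β), exact Kekulé counts (determinant route with
  a matching-DP cross-check) and Herndon resonance energies.
* **NMR/ESR machinery**: distance-degree-sequence (DDSV) vertex
  equivalence classes → ¹³C signal counts and intensity patterns, an
  automorphism-orbit oracle, and ESR hyperfine generating-function
  patterns with exact big-integer line counts.

## Worked example

```python
from wnrtools import (build_znr, build_wnr, RibbonSpec, distance_indices,
                      spectral_summary, nmr_partition)

ribbon = build_wnr(RibbonSpec(r=2, c=2, n=2))
print(ribbon.n_vertices, ribbon.n_edges)   # 64 82

idx = distance_indices(ribbon)
print(idx["W"], idx["Sze"], idx["PI"])     # 16988 81660 6428

unit = build_znr(3, 3)                     # 60-carbon ZNR(3,3)
s = spectral_summary(unit)
print(round(s.homo_lumo_gap, 6))           # 0.132705  (beta units)
print(round(s.e_pi_per_site, 8))           # 1.46369662
print(s.kekule_count)                      # 400
print(round(s.re_per_site, 7))             # 0.1183314

print(nmr_partition(unit).n_classes)       # 30  (13C NMR signals, all 1:1)
```

The Wiener index 16988 says the 64 carbons of WNR(2,2,2) are separated
by 16988 bond-steps summed over all pairs; the 0.1327 β gap of ZNR(3,3)
marks it as a small-gap (kinetically reactive) unit, and its 400 Kekulé
structures give a Herndon resonance energy of 0.118 β per carbon.

The same analyses are available from the shell:

```bash
wnr distance --r 2 --c 2 --n 2 --out out/          # CSV of all 11 indices
wnr spectral --r 3 --c 3 --n 1 --out out/          # gap, energies, K, RE
wnr nmr --r 3 --c 3 --n 1 --out out/               # DDSV classes
wnr closed-forms --r 2 --c 2 --n 2 --out out/      # closed vs direct + flags
wnr tables --max-n 10 --out tables/                # regenerate family tables
wnr build --r 3 --c 4 --n 5 --graph-format xyz --out out/
```

`wnr tables` regenerates the WNR(n,n,n) distance/degree/degree-sum tables
and the spectral summary table, diffing every cell against frozen
published reference values; a handful of reference cells are known to be
internally inconsistent and are flagged rather than matched (see
`docs/methods.md` for the full analysis).

## Layout

```
src/wnrtools/
  ribbon_graphs.py        lattice builders + io
  cut_descriptors.py      Theta*-classes and distance descriptors
  degree_descriptors.py   degree / degree-sum partitions and functionals
  closed_forms.py         family polynomials + discrepancy reporting
  pi_spectral.py          spectra, gaps, energies, Kekulé counts, RE
  spectro_equivalence.py  DDSV classes, NMR patterns, ESR generating fns
  reference_values.py     frozen published table values (regression data)
  cli.py                  the `wnr` command
```
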