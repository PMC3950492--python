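# Methods

## The model

`lipidenum` treats a glycerophospholipid as a composition of independent
building blocks on the *sn*-glycero-3-phosphate scaffold (C3H9O6P):

```
species = core + headgroup delta + sn-1 substituent delta + sn-2 substituent delta
```

Each delta is a condensation delta (the free component minus water), so the
arithmetic is plain element-wise integer addition and every species
composition is recomputable from its shorthand name.  The sixteen headgroup
variants cover twelve LIPID MAPS glycerophospholipid subclasses:

| id | LM code | delta vs core | note |
|----|---------|---------------|------|
| PA | GP10 | — | the bare phosphate |
| PPA | GP11 | +HPO3 | pyrophosphate monoester |
| PC | GP01 | +C5H11N | choline; neutral zwitterion-summed formula |
| PE | GP02 | +C2H5N | ethanolamine |
| PS | GP03 | +C3H5NO2 | serine |
| PG | GP04 | +C3H6O2 | glycerol |
| PGP | GP05 | +C3H6O2+HPO3 | glycerol 3-phosphate |
| CDP-DG | GP13 | +C9H12N3O7P | cytidine 5'-monophosphate, pyrophosphate-bridged |
| PI | GP06 | +C6H10O5 | myo-inositol |
| PI[x]P, PI[x,y]P2, PI[3,4,5]P3 | GP07–GP09 | +C6H10O5 + n·HPO3 | phosphates on inositol C3/C4/C5 |

An *sn* substituent is a free hydroxyl (lyso, `0:0`) or a chain
`(linkage, c, u)` with `c` carbons and `u` double bonds:

* acyl (ester): `C_c H_(2c-2u-2) O`
* alkyl (`O-`, ether/plasmanyl): `C_c H_(2c-2u)`
* alkenyl (`P-`, vinyl ether/plasmenyl): `C_c H_(2c-2u-2)`

For alkenyl chains `u` counts only the double bonds beyond the vinyl-ether
bond at position 1 (standard plasmalogen shorthand, so `P-18:0` carries one
C=C and alkenyl(c, u) is an isomer of alkyl(c, u+1)).  This convention is
not forced by the shorthand itself; it is a design choice, applied
consistently in composition, naming, and structure generation.

## Masses and ion modes

Monoisotopic ("exact") and average masses are linear functionals of the
composition; the element masses (principal-isotope masses from the AME
evaluation, IUPAC 2021 conventional atomic weights, CODATA electron mass)
are pinned in `data/atomic_masses.txt` with provenance, so results are
bit-for-bit reproducible.  Six singly-charged-or-neutral ion modes are
supported: [M+H]+, [M+K]+, [M+Li]+, [M+Na]+, [M−H]−, and neutral.  A
charged adduct's m/z includes the electron-mass correction (a cation is one
electron lighter than the sum of its atoms); [M+H]+ is therefore proton
arithmetic, +1.0072765 Da.  The correction (0.00055 Da) matters only at the
tightest supported tolerance but is physically correct; hydrogen-atom
arithmetic is available via `adduct_mz(..., electron_correction=False)`.

## The chain rule and the database census

The enumerated space is the cartesian product of the two per-position chain
spaces for each headgroup, with `sn-1/sn-2` inversions as distinct species
(they are distinct identities with equal mass, and both are reported by the
search engine).  The shipped default `ChainRule` is:

* carbons 0–30 (`0` only as the lyso hydroxyl), up to 6 unsaturations;
* acyl, alkyl and alkenyl allowed at both positions; lyso allowed at both;
  the di-lyso species included;
* a `(c, u)` pair is admissible only if at least one double-bond placement
  exists under the drawing constraints: first bond start at carbon ≥ 2
  (acyl/alkyl; the acyl C1 is the carbonyl) or ≥ 3 for additional alkenyl
  bonds (the vinyl ether occupies carbons 1–2), with consecutive bond
  starts ≥ d = 2 carbons apart.

"Separated by a minimum of two carbons" is implemented as start-to-start
spacing `d = 2`, which forbids cumulated dienes but allows conjugated
dienes.  Stricter readings (`d = 3` or `4`) would make the benchmark
10:4 chain of the worked example undrawable; `d` is configurable.

This default yields 498 chains per position, hence 498² = 248,004 species
per class, 1,984,032 for the eight-member PI superfamily and 3,968,064 in
total.  The published census these tables are calibrated against is 92,073
species per class.  That figure is **not reproducible** inside this rule
family: every family member's per-class count is a product of two
chain-space sizes (minus one without di-lyso), 92,073 = 3 × 47 × 653 admits
no such factorization within the achievable space sizes, and broad sweeps
over extended families (joint caps on total carbons or total unsaturations,
per-linkage loop-bound variants) produce only matches that contradict the
stated chain space (e.g. no alkenyl linkage, or at most five
unsaturations).  `calibrate_chain_rule` therefore searches the documented
family and reports its honest result — for 92,073 an empty match list, with
`nearest_rules` reporting the closest configurations (the nearest is
92,099, off by 26).  The default rule is the chemically conventional family
member, deliberately not adjusted to chase the published figure; all
structural identities that do not depend on the absolute census (identical
counts across all sixteen classes, PI-superfamily total = 8 × per-class,
grand total = 16 × per-class, count = |sn1 space| × |sn2 space|) are
enforced by tests.

## Search

The index stores neutral exact and average masses sorted; a query is
answered by inverting the adduct transform on the query m/z and taking a
binary-search window, then applying class, parity and common-chain filters.
Tolerances are absolute Da, symmetric, inclusive at both edges, and
restricted to 0.0001–2 Da (out-of-range values are rejected, not clamped).
Hits are ordered by |delta|, ties by canonical name, and indexed search is
tested for exact agreement with an independent linear scan on randomized
queries.  The "best prediction" filter keeps species whose non-lyso chains
all belong to an editable common-chain list; the shipped default is the
eight prevalent mammalian acyl chains 16:0, 16:1, 18:0, 18:1, 18:2, 18:3,
20:4, 22:6 (the historical curation behind this filter is not public, so
the list is a configurable stand-in).

## Structures

Double-bond patterns are strictly increasing start positions
`s_1 < s_2 < …` with `s_1 ≥ s_min`, `s_{k+1} − s_k ≥ d`, `s_u + 1 ≤ c`; the
number of patterns is the stars-and-bars closed form
`C((c − s_min) − (d−1)(u−1), u)`, verified against exhaustive generation.
Structures are assembled as SMILES (glycerol sn-2 stereocentre explicit in
the *sn*-glycero-3-phosphate configuration; PC emitted as the net-neutral
zwitterion) and validated through RDKit: every emitted structure must parse
and its toolkit-derived molecular formula must equal the assembled
composition.  All placed chain double bonds, including the vinyl-ether
bond, are flagged cis (Z); a terminal `=CH2` bond carries no stereo sense.
The inositol ring is emitted without ring stereo by default, since the 2D
skeletal drawing style the output mirrors does not encode it; an opt-in
flag emits a fixed stereo template intended as 1D-myo-inositol (validated
for formula and parseability, not against a stereo reference).  The
"canonical" structure is the earliest-position ("sequential") pattern on
both chains; `all_structures` emits the cartesian product of per-chain
patterns.

## Problem sizes in tests

Unit and acceptance tests that need exhaustive oracles use a reduced chain
space (carbons ≤ 8, unsaturations ≤ 2: 2,704 species per class, 43,264
total), chosen so brute-force scans, 1000-query search comparisons and
500-structure formula checks are exact rather than sampled approximations
of the oracle.  Census, worked-example and index tests run on the full
default space (3.97 M species), which builds vectorized in a few seconds.

## Known limitations

* The published per-class census (92,073) is not reproduced, for the
  structural reasons above; the package reports its own census openly.
* No isotope fine structure, isotopic distributions, multiply charged
  ions, ppm tolerances, or MS/MS fragment matching.
* No sphingolipids, sterols, oxidized or branched chains, chains beyond
  30 carbons or 6 unsaturations.
* Structure output is connectivity + double-bond geometry + glycerol
  stereo; no 2D/3D coordinates or rendering.
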