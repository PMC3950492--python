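# lipidenum

Combinatorial glycerophospholipid enumeration, exact/average mass search,
and structure generation for lipidomic m/z annotation.

Assigning molecular identities to peaks in ESI/MALDI-MS lipidomic datasets
requires knowing, for any observed m/z, *every* theoretically possible
glycerophospholipid that could produce it under the experiment's ion mode
and mass tolerance — including *sn*-1/*sn*-2 chain inversions, acyl vs
ether (O-) vs vinyl-ether (P-) linkage variants, and, for the
phosphoinositides, the position of headgroup phosphorylation (PI[3]P …
PI[3,4,5]P3).  `lipidenum` builds that search space in silico and answers
such queries for sixteen polar-headgroup variants spanning twelve LIPID
MAPS glycerophospholipid subclasses, with machine-readable structures
(SMILES/SDF) for every species including all cis double-bond positional
isomers.

## The model

Every species is a composition sum on the *sn*-glycero-3-phosphate core:

```
M(species) = M(C3H9O6P) + Δ(headgroup) + Δ(sn-1 chain) + Δ(sn-2 chain)
```

with chain deltas `acyl(c,u) = C_cH_{2c−2u−2}O`, `alkyl(c,u) = C_cH_{2c−2u}`,
`alkenyl(c,u) = C_cH_{2c−2u−2}` (the vinyl-ether bond is not counted in
`u`), and a lyso position contributing nothing.  Masses are computed from
pinned monoisotopic or standard-atomic-weight tables; adduct m/z for
[M+H]+, [M+K]+, [M+Li]+, [M+Na]+ and [M−H]− includes the electron-mass
correction.  Chains run over 0–30 carbons and 0–6 double bonds under a
configurable admissibility rule (see `docs/methods.md`); the default space
holds 498 chains per position, 248,004 species per headgroup class and
3,968,064 species in total.

## Worked example

The [M+H]+ ion of the doubly phosphorylated, tetra-unsaturated lyso
species PI[4,5]P2(10:4/0:0) (C19H31O18P3, monoisotopic 640.0723 Da) has
m/z 641.0796, so a search at m/z 642 ± 1 amu must return it:

```
$ lipidenum search --mz 642 --tol 1 --mode M+H --mass-type exact \
      --class pi+pipx --parity even --out hits.csv --verbose
indexing classes: PI, PI3P, PI4P, PI5P, PI34P2, PI35P2, PI45P2, PI345P3
index size: 1984032 species
268 hit(s) across 1 query m/z value(s)
```

`hits.csv` lists every phosphoinositide with an even-carbon chain
combination within the window, one row per species with its theoretical
m/z and signed error; the target species and its chain inversion appear
with a −0.92 Da delta:

```
query_mz,tolerance,ion_mode,mass_type,name,lipidmaps_code,formula,theoretical_mz,delta_da
642.0,1.0,M+H,exact,"PI[4,5]P2(0:0/10:4)",GP08,C19H31O18P3,641.0796,-0.9204
642.0,1.0,M+H,exact,"PI[4,5]P2(10:4/0:0)",GP08,C19H31O18P3,641.0796,-0.9204
```

The same species has C(5,4) = 5 cis double-bond positional isomers, which
can be exported for any structure viewer:

```
$ lipidenum draw "PI[4,5]P2(10:4/0:0)" --all-isomers --out isomers.smi
5 structure(s) written to isomers.smi
$ head -1 isomers.smi
C/C=C\C=C/C=C\C=C/C(=O)OC[C@@H](O)COP(=O)(O)OC1C(O)C(O)C(OP(=O)(O)O)C(OP(=O)(O)O)C1O	PI[4,5]P2(10:4/0:0)
```

Other commands: `lipidenum build` exports the full database as CSV with a
per-class census, and `lipidenum calibrate --target N` searches the
chain-rule family for configurations with a given per-class count,
reporting the nearest configurations when none matches exactly.

The library mirrors the CLI: `parse_name`, `species_composition`,
`exact_mass`/`average_mass`/`adduct_mz`, `enumerate_class`,
`build_database_index(...).search(Query(...))`, `all_structures`.

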