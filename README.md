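# ribotrace

In-cell polysome tracing and ribosome heterogeneity analysis from
subtomogram particle tables, plus quantification of dual protein binding
sites in atomic models.

## The problem

Cellular cryo-electron tomography resolves individual ribosomes — their
positions, orientations and (via focused classification) compositional
classes — but not the mRNA threading through them. Whether two adjacent
ribosomes share one mRNA must therefore be inferred from their relative
poses: on a polysome, the mRNA **exit** site of the leading ribosome faces
the mRNA **entry** site of the trailing one at short range, while ribosomes
on different mRNAs meet in unconstrained orientations.

`ribotrace` implements this inference and the statistics built on it, for
questions like: do ribosomes that carry an extra copy of a protein (e.g. a
second bS20 on the large subunit, present in ~2/3 of ribosomes in
*Psychrobacter urativorans*) segregate onto their own mRNAs, translate at
different speeds, or mix freely with canonical ribosomes?

It is aimed at structural biologists with RELION-style particle STAR files
(per-particle coordinates, ZYZ Euler angles, class labels) from
subtomogram averaging.

## The method

For each particle *i* with position **p**ᵢ and orientation **R**ᵢ, marker
offsets **v**entry, **v**exit defined in the subtomogram-average frame map
into the tomogram as **p**ᵢ + **A**ᵢ**v**, with **A**ᵢ = **R**ᵢ or
**R**ᵢᵀ (an explicit convention switch — see `docs/methods.md`). Tracing
then proceeds per cell:

1. **link** — each particle gets at most one directed link to the
   neighbour *j* minimising |exit(*i*) − entry(*j*)|, kept if below the
   cut-off (25 nm for tracing);
2. **resolve** — if several particles share a neighbour, only the
   shortest incoming link survives;
3. **decycle** — any closed circle loses its longest link;
4. **chain** — maximal directed paths become polysomes, ordered from the
   particle with no incoming link.

Downstream statistics: per-polysome class fractions (mean ± SD across
chains), per-cell occupancies (mean ± SD across cells), exit→entry
distance distributions at a looser 50 nm cut-off stratified by the
(leader, trailer) class pair, with 5–95% cell-to-cell percentile bands
and pairwise two-sample Kolmogorov–Smirnov tests (Holm-corrected).

A synthetic scene generator plants polysome chains with geometrically
exact marker relations, isolated monosomes, and i.i.d. class labels, so
every stage is validated against known ground truth. A structural module
quantifies dual binding sites in deposited models: Kabsch Cα superposition
RMSD between the two copies, Shrake–Rupley buried areas
(SASA(A) + SASA(B) − SASA(AB)) with a per-partner-chain split, and
heavy-atom contact-residue classification into site-specific and shared
binders.

## Worked example

```sh
ribotrace all --seed 0 --out run_all
```

simulates the 28-cell study-scale scene (2xbS20 occupancy 0.67,
Trigger-Factor binding 0.88), traces it and prints:

```
{"occupancy": {"mean_across_cells": 0.6653, "sd_across_cells": 0.0234,
               "pooled_fraction": 0.6654, "n_cells": 28}, "n_chains": 560}
```

i.e. the per-cell occupancy recovers the planted 67% with ~2% cell-to-cell
SD, and all 560 planted polysomes are recovered. The same flow is broken
into narrative steps under `analysis/` (01 simulate → 02 trace → 03
composition/occupancy → 04 distance strata → 05 interface), each writing
its tables under `results/`. Running them prints, among others, a
per-polysome 2xbS20 fraction of 66.7% ± 22.1% SD across 560 chains —
matching the per-cell occupancy, the signature of classes mixing freely on
shared mRNAs — and 0 of 6 stratum KS tests significant, as expected when
both classes step identically.

For a deposited model (e.g. PDB 9HC4, with the two bS20 copies in chains
*a* and *b*):

```sh
ribotrace interface --structure 9hc4.cif --chain-a a --chain-b b --report rep.json
```

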