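# Methods

## Pose model and marker mapping

Particles carry ZYZ Euler angles (rot, tilt, psi), composed as
R = Rz(rot)·Ry(tilt)·Rz(psi) (intrinsic). Angles are normalised at load to
tilt ∈ [0°, 180°], rot/psi ∈ [−180°, 180°] using the identity
Rz(a)Ry(b)Rz(c) = Rz(a+180°)Ry(−b)Rz(c+180°), which leaves the rotation
matrix unchanged.

Alignment packages disagree on whether the stored angles rotate the
reference into the particle or vice versa, and the error is silent: both
conventions produce plausible-looking marker clouds. We therefore expose
`map_direction` in `MarkerConfig`:

* `inverse` (default): markers map as p + Rᵀv — the stored angles are
  taken as the rotation that aligns the particle onto the reference, the
  common subtomogram-averaging convention;
* `forward`: p + Rv.

`export_marker_clouds` writes both candidate clouds as CSV so users can
overlay them on a tomogram and pick the one matching their software. The
synthetic generator emits angles consistent with the configured
convention, so round-trip recovery tests hold under either choice.

Positions are in Å everywhere. STAR coordinates are converted at load
(coordinate × pixel size, minus refined origin; both the pixel-unit
`_rlnOriginX` and the Å-unit `_rlnOriginXAngst` conventions are
accepted). We use shift-corrected coordinates; published tracing scripts
do not state which convention they used, so this choice is fixed here and
flagged.

## Tracing rules

Per tomogram (= cell; mRNAs cannot span cells):

1. For each particle, the nearest entry site among all other particles;
   a directed link is kept if the distance is strictly below the cut-off
   (250 Å for tracing).
2. Targets with several incoming links keep only the shortest.
3. The resulting graph has in/out degree ≤ 1, so every component is a
   path or a simple cycle; each cycle loses its longest link (removal
   cannot create new cycles in a functional graph, so one pass suffices).
4. Maximal paths become chains, ordered from the node with no incoming
   link. A link i→j means j trails i on the inferred mRNA; the chain
   start is the most-upstream ribosome of the traced graph.

All ties break on particle id (smaller id wins a nearest-neighbour or
shortest-link tie; the larger source id loses a longest-in-cycle tie).
Ties have measure zero in real data; fixing them makes the pipeline
bit-reproducible. The spatial search uses a k-d tree above 2048 particles
per tomogram and an exhaustive scan below; both paths are exactly
equivalent (tested against a brute-force oracle).

## Statistics

* **Per-polysome composition**: fraction of chain members carrying a label
  value; the headline mean/SD weight chains equally, and the
  ribosome-weighted pooled fraction is reported alongside, since "average
  ratio per polysome" is ambiguous between the two.
* **Per-cell occupancy**: cells weighted equally; the pooled per-ribosome
  fraction is also reported.
* **SD convention**: population SD (ddof = 0) by default, `ddof=1`
  available. The convention matters at 28 cells and must be explicit.
* **Distance table**: each particle's single nearest entry neighbour at
  the looser 500 Å cut-off, *before* shared-link/cycle resolution by
  default (`resolved=True` restricts to surviving polysome links). The
  looser cut-off and pre-resolution choice match the separate
  "elongation-rate" analysis cut-off named alongside the 25 nm tracing
  cut-off.
* **Cell-to-cell band**: per-cell histograms normalised to unit sum; the
  band is the empirical 5th/95th percentile per bin across cells. Fewer
  than 3 cells degrade to a point estimate with a warning.
* **Stratum comparison**: pairwise two-sample Kolmogorov–Smirnov between
  the four (leader, trailer) class pairs with Holm correction; the test
  choice is recorded in the output metadata because no specific test is
  canonical for this comparison. Empty strata are reported as
  not-testable rather than raising.
* **State-by-class tables**: chi-square test of homogeneity with an
  expected-count (≥5) validity flag; degenerate tables skip the test with
  a notice.

## Synthetic scenes

The generator emulates the statistical structure the analysis consumes,
with defaults set to the study conditions:

| parameter | default | rationale |
|---|---|---|
| n_cells | 28 | number of analysed cells |
| particles/cell | ~500 (20 chains of mean 5 + 400 monosomes) | per-cell sample size used for occupancy statistics |
| occupancy_p | 0.67 | 2xbS20 prevalence |
| tf_bound_p | 0.88 | Trigger-Factor bound fraction |
| chain length | 2 + Poisson(3) | mean ~5; gives an across-chain binomial SD of the per-polysome fraction of ~0.21–0.22, the observed scale |
| step distance | 70 ± 15 Å (truncated > 0) | exit→entry gaps well under the 250 Å cut-off |
| max turn / jitter | 60° / 15° per step | compact, curling polysome paths |
| monosome clearance | 600 Å (> 2 × cut-off) | guarantees monosomes never link |
| cell box | 12 000 × 12 000 × 5 000 Å | bacterial-cell scale; large enough to place ~1000 markers at 600 Å clearance |
| position noise | 5 Å SD | residual localisation error |
| marker offsets | entry (55, 0, 0), exit (−55, 0, 20) Å | entry and exit on opposite sides of the small subunit, ~11 nm apart; the numeric offsets used on real data are user configuration |

Chain members are placed by solving the pose directly: a member's
orientation aligns its exit−entry axis with the (jittered) local path
direction with a uniform free spin, and its position puts the mapped
entry marker exactly at the drawn step distance from the predecessor's
mapped exit. Positional noise is applied **before** the self-consistency
and clearance checks, so the planted-recovery guarantee (precision =
recall = 1 when steps < cut-off/2 and clearances > 2 × cut-off) holds on
the geometry tracing actually sees. Placement uses rejection sampling
with a capped attempt budget; an overfull box raises a capacity error.

The generator does **not** emulate tomographic image formation,
missing-wedge anisotropy, classification error (labels are exact and
i.i.d., independent of geometry), membrane-associated ribosome ordering,
or crowding below the clearance floor. Passing tests therefore show the
*rules* are implemented exactly and the estimators are calibrated — not
that tracing is robust to the dense, noisy neighbourhoods of real
cytosol, where the cut-off and marker choices dominate performance.

## Structural interface module

* **SASA**: Shrake–Rupley with a deterministic golden-section spiral
  (default 960 points, probe 1.4 Å); the point set is fixed, so results
  are exactly reproducible. Isolated-sphere and two-sphere cap closed
  forms agree to <1% / <2% at the default density.
* **Radii**: Bondi-style heavy-atom values (C 1.70, N 1.55, O 1.52,
  S 1.80, P 1.80 Å …), shipped in code and echoed in every report.
  Deposited ribosome models carry no hydrogens; unknown elements get
  1.70 Å with a warning.
* **Buried area**: SASA(A) + SASA(B) − SASA(AB); per-partner splits
  repeat the computation with each partner chain alone, so splits need
  not sum exactly to the total when partners also touch each other near
  the query. `neighborhood()` restricts a large assembly to whole
  residues within a margin of the query; with margin ≥ ~13 Å (twice the
  largest inflated-atom diameter) buried areas and contacts are exactly
  unchanged, making ribosome-scale models tractable.
* **Superposition**: Kabsch via SVD with the proper-rotation sign fix;
  collinear or n < 3 inputs are rejected. Copies are paired by residue
  number over the range modelled in both chains (the 50S copy's
  N-terminus, residues 1–18, is disordered and drops out of the pairing
  automatically).
* **Contacts**: a query residue contacts the ribosome if any heavy atom
  lies within 4.0 Å (configurable — no standard value exists) of a
  non-query heavy atom; the two sites' sets are classified into
  site-only and shared binders by residue number.
* Alternate locations resolve to the highest-occupancy copy; waters and
  monoatomic ions are excluded by default.

Exact reproduction of published interface areas carries method-dependent
tolerance (probe, radii, point density and contact cut-off are rarely
stated); reports therefore always echo their parameters.

## Problem sizes and determinism

The test suite and `scripts/acceptance.py` use: 1000 (tests) / 300
(script) random ≤10-particle scenes for brute-force equivalence; 100 / 30
seeds for planted recovery; one 28-cell, ~14 000-particle mimic for
parameter recovery; 100 replicates × 500 samples per stratum for KS
calibration. These sizes make every check a few seconds while keeping
standard errors far below the tested tolerances. All randomness flows
from explicit seeds; identical seeds give byte-identical STAR output.

## Known limitations

* Tracing is purely geometric: no probabilistic assignment, no modelling
  of the mRNA path between ribosomes, no use of membrane or cell-boundary
  segmentation.
* The upstream/downstream naming of chain ends follows the link
  direction defined here (exit feeds entry); the biological wording is
  ambiguous, the geometric rule is not.
* Label noise (classification error) is not modelled; a mislabelled
  particle propagates into composition statistics unchanged.
* The distance-stratification test detects distributional differences
  only as well as two-sample KS does; subtle queueing signatures
  (multi-modality at fixed offsets) may need tailored statistics.
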