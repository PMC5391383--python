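# Methods

This note documents the models, conventions and numerical choices behind
each module, what the synthetic generators do and do not emulate, and the
known limitations.

## Secondary-structure assignment (`secstruct`)

Hydrogen bonds between backbone amides and carbonyls are scored with the
Kabsch–Sander electrostatic model,

    E = q1·q2 · f · (1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN),

with q1·q2 = 0.084 e², f = 332 kcal·Å/(mol·e²), and a bond declared when
E < −0.5 kcal/mol. Pairs closer than two residues apart are excluded, and
proline contributes no donor. When the input lacks amide hydrogens (typical
for heavy-atom ensembles) the H is rebuilt at 1.01 Å from N along the
reversed C(prev)→O(prev) direction, i.e. anti to the preceding carbonyl —
the standard reconstruction for this energy model.

From the bond pattern, six classes are assigned with priority
H > G > E > B > T > C:

* **H** — runs of ≥ 2 consecutive i→i+4 turns mark residues i..i+3;
* **G** — likewise with i→i+3 turns (3 residues);
* **E/B** — parallel/antiparallel bridge patterns between residues ≥ 3
  apart; bridges with a neighbouring bridge form ladders (E), isolated ones
  stay B;
* **T** — interior residues of any 3-, 4- or 5-turn not otherwise assigned;
* **C** — everything else. π-helices get no class of their own (their turns
  surface as T).

Chain termini can never be H (no flanking turn pair); this is documented
behaviour, not an error. The vectorised implementation is tested against a
literal nested-loop reimplementation of both the energy and the pattern
rules on small peptides.

Per-residue occupancy is the fraction of frames in each class; rows sum to
one by construction.

## Superposition and clustering (`confcluster`)

RMSD is always computed after optimal rigid superposition (Kabsch SVD with
the reflection guard); translation and rotation of a free peptide carry no
information, so unfitted RMSD is not offered. Degenerate point sets (< 3
points, collinear) produce a warning, not an error. The implementation is
cross-checked against a coarse-to-fine rotation-space search and against
MDAnalysis.

Single-linkage clustering at cutoff c is computed as the connected
components of the graph with edges where RMSD ≤ c — exactly the merge
structure single linkage produces at a fixed threshold. Clusters are ordered
by descending population with ties broken by the lowest member frame index.
The "median" representative of a cluster is its **medoid** (member with
minimal summed RMSD to the rest, ties again to the lowest frame index);
coordinate averaging of divergent conformers is deliberately avoided. The
default cutoff is 13 Å on all tail Cα atoms; tip re-clustering uses the
first 15 N-terminal Cα only (`selection=(1, 15)`).

## Tail reach (`reach`)

The reach of a frame is the maximum over residues i < anchor of
|Cα_i − Cα_anchor|,
anchored at P43 by default; the anchor itself and residues C-terminal of it
are excluded. Quantiles use linear interpolation between order statistics
(numpy's default); this convention is fixed here because the chromatin
shells inherit Q1/Q3 as radii. Box whiskers follow Tukey's 1.5·IQR rule by
default, with a min/max option.

Isoform comparison uses the unpaired two-sided Welch t-test
(scipy, `equal_var=False`) with the Welch–Satterthwaite degrees of freedom
and a 95% CI of the mean difference. Two all-constant samples with equal
means return p = 1 by convention; with unequal means the statistic is
undefined and an error is raised. No multiple-testing correction is applied
(a single planned comparison).

## Docking-pose analysis (`dockstats`)

The docking search itself is out of scope; the module consumes pose tables
from any engine. Energies follow the "energy obtained from binding"
convention (larger = more favorable); a `negate_energies` switch adapts
engines that report released energy as negative. Best-pose ties break on
grid-label order A1..C3, making ranking deterministic.

The grid is rows × cols axis-aligned cells over the receptor's xy bounding
box (z spans the box); each interior edge is expanded by `overlap_frac`
(default 0.25) of the base cell width, so neighbouring cells overlap and
every receptor atom falls in at least one cell for any overlap ≥ 0.

Contact classification between a docked tip and the receptor, all within a
single cutoff (default 5 Å):

* **total** — every inter-structure atom pair within the cutoff;
* **hydrogen bond** — N/O–N/O pairs ≤ 3.5 Å; when a hydrogen is resolved on
  either partner the X–H…Y angle must be ≥ 135°, otherwise the distance
  rule alone decides (heavy-atom inputs);
* **hydrophobic** — carbon–carbon pairs where neither carbon has a
  covalently bonded N/O (≤ 1.7 Å), the simplest reproducible
  operationalisation of "apolar".

Both special classes are subsets of the total set. Receptor atoms are
tagged DNA (nucleotide residue names) or `chain_<id>`.

A reference pose-energy table for six tail-tip structures (three unmodified
tip clusters, hyperacetylated, active, inactive) over the nine 3×3 cells
ships with the package (`data/tip_pose_energies.csv`) and drives the ranking
stage and its tests.

## Chromatin reach model (`chromatin`)

Each H3 anchor (P43 Cα) carries a spherical annulus with r_inner = Q1 and
r_outer = Q3 of that tail's reach distribution — the band holding the middle
half of the per-frame tail lengths. A site is reachable when its **nearest**
point to the anchor lies inside the band (a tail tip need only touch part of
a surface); a stricter all-points mode is available. Reachable sites are
classified against explicit stack metadata (never inferred from geometry) as
intranucleosomal, internucleosomal within the same stack, or on the adjacent
stack. Site transplantation between nucleosomes goes through the Kabsch
superposition of their shared core atoms, so it commutes with rigid motions
of the target by construction.

The absolute Q1/Q3 radii are inputs everywhere: measured values from real
trajectories can be substituted for the synthetic ones without code changes.

## Synthetic data (`synthdata`)

All generators are pure functions of spec + seed (numpy `default_rng`;
derived seeds via `SeedSequence`), so every downstream artifact is
bit-reproducible.

**Peptide ensembles.** Backbones are built frame-by-frame from ideal
internal coordinates (N–Cα 1.458 Å, Cα–C 1.525 Å, C–N 1.329 Å, C=O 1.231 Å;
angles 111.2°/117.2°/121.7°; ω = 180°) via NeRF placement, vectorised across
frames. Helical segments use canonical dihedrals (α: −57°/−47°; 3₁₀:
−49°/−26°) and are switched on per frame by independent Bernoulli draws at
the segment's persistence; all other residues draw jittered coil dihedrals
(defaults −120°/130° ± 25°). Side chains stop at a Cβ stub (1.53 Å,
tetrahedral branch) — enough to exercise hydrophobic contact detection; no
other side-chain atoms are needed by any in-scope analysis. The default
43-mer carries the H3 sequence and two planted helices: the "tip" helix
T3–G12 at persistence 0.8 and the less stable "middle" helix L20–A29 at
0.4.

Frames are i.i.d. conformers, not dynamics: there is no force field, no
solvent, no temporal correlation, and no coupling between segments. Tests
that pass on these ensembles therefore validate the *analysis* operations
and their statistical behaviour at planted effect sizes — they say nothing
about the conformational thermodynamics of real tails.

**Active/inactive pair.** Each frame draws a global extension weight w
interpolating the coil means between a compact curl (−70°/−35°) and an
extended chain (−135°/145°), with 10° per-residue jitter: the compact
"active-like" tail draws w ~ U(0, 0.55), the extended "inactive-like" tail
w ~ U(0.35, 1) and additionally plants an α-helix at L20–K27 with
persistence 0.7 (the helix the heterochromatin-type PTM pattern stabilises).
These defaults were chosen once so that the two reach distributions are
broad and overlapping — as real isoform ensembles are — while the inactive
mean is larger by a clearly detectable margin.

**Toy nucleosomes.** A nucleosome is a pseudo-atom disc: a DNA superhelix
path (radius 42 Å, 1.65 turns, pitch 25.9 Å; one P and one phosphate O per
wrapped base pair, 147 points) plus an octamer shell of 80 carbon
pseudo-atoms assigned to chains A–H, two labelled H3 P43 anchor atoms, and
annotated sites (a tip binding site and an acidic patch). The
tetranucleosome stacks two columns of two discs, populating anchors and
sites on each copy through the same core-superposition transplant used for
real structures. The geometry is schematic — correct in topology, scale
and labelling, not in atomic detail.

**Pose tables.** One energy per (structure, cell), Gaussian noise around
zero except the planted winner, which strictly exceeds its row by a fixed
margin (default 2 kcal/mol).

## Pipeline and problem sizes

`run_all` executes extract → secondary structure → clustering (full + tip) →
reach → pose ranking → contacts → chromatin, each stage into its own
directory, with a summary JSON recording seed, parameters and a SHA-256 per
output file (no timestamps, so identical configs produce byte-identical
bundles). Stage failures abort the run with the stage name and leave a
`FAILED` marker beside any partial outputs.

The chromatin stage builds the toy stack to the measured reach scale: the
parental tip site is placed at the midpoint of the overlap between the
active and inactive Q1..Q3 bands, the stack rise is chosen so the
same-stack site lands between the two outer radii, the acidic patch sits at
half the smaller Q1 (inside both inner spheres), and the lateral stack
spacing clears the largest outer radius for every cross-stack anchor/site
pair. If the two bands do not overlap the stage stops with an explanatory
error rather than fabricating a geometry.

Default problem sizes are chosen for interactive turnaround: analysis
scripts use 2,000-frame ensembles (quartiles stable to ~1 Å, occupancy to
~±0.02); the end-to-end pipeline defaults to 300 frames and subsamples to
≤ 60 frames before the O(n²) RMSD matrix. All sizes are config parameters.

## Limitations

* Secondary-structure classes omit π-helix, bend and PP-II; assignments on
  real ensembles will differ in detail from tools with richer rule sets.
* The clustering cutoff semantics (fitted RMSD) is a convention choice;
  results at a fixed cutoff are not comparable to unfitted-RMSD pipelines.
* The hydrogen-bond and hydrophobic definitions are deliberately minimal;
  they are stable for ranking and counting, not for publication-grade
  interaction analysis.
* Synthetic ensembles cannot reproduce any absolute quantity of real tails
  (helix boundaries, reach in Å, cluster counts); only planted,
  construction-level truths are asserted anywhere.
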