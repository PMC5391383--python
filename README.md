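# tailscope

Analysis pipeline for conformational ensembles of the histone H3 N-terminal
tail, their docking poses on the nucleosome core particle (NCP), and the
geometric consequences for compact chromatin.

The N-terminal tail of histone H3 (residues 1–43, ending at P43 where the
tail joins the nucleosome core) is intrinsically disordered but transiently
structured, and its post-translational modifications (PTMs) — lysine
acetylation/methylation, serine phosphorylation — shift which structures it
samples. This package implements, as a tested and reusable library, the
analyses needed to characterise such ensembles and their consequences:

* **Secondary structure** — Kabsch–Sander electrostatic hydrogen-bond
  detection (`E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) <
  −0.5 kcal/mol`) and a six-class assignment (α-helix H, 3₁₀ G, strand E,
  bridge B, turn T, coil C), reduced to per-residue occupancy over a
  trajectory.
* **Conformational clustering** — all-vs-all Cα RMSD after optimal (Kabsch)
  superposition, single-linkage clustering at a 13 Å cutoff (connected
  components of the threshold graph), medoid representatives, and
  re-clustering on the first 15 N-terminal α-carbons to get tail-tip
  structures for docking.
* **Tail reach** — the per-frame maximum distance from the P43 Cα to any
  N-terminal Cα, its quartile summary, and Welch's unequal-variance t-test
  between isoform ensembles.
* **Docking-pose bookkeeping** — an overlapping 3×3 grid over the NCP
  (9 cells × 400 poses = 3,600 poses per structure), best-pose selection per
  tip structure (larger binding energy = more favorable), and contact
  classification (total / hydrogen bond / hydrophobic within 5 Å, tagged by
  DNA vs histone chain).
* **Chromatin reach model** — a spherical annulus per H3 anchor whose radii
  are the Q1 and Q3 of the reach distribution, queried against annotated
  binding sites on a stacked tetranucleosome and classified as intra- or
  internucleosomal (same stack / adjacent stack).

Because real 500-ns MD ensembles and docking engines are out of scope, a
first-class synthetic-data module supplies every input: seeded peptide
backbone generators with planted helical segments of tunable per-frame
persistence, toy nucleosome discs with labelled anchors and sites, stacked
tetranucleosomes, and pose tables with planted best cells. Every planted
quantity is a testable ground truth.

## Worked example

The numbered scripts under `analysis/` run the full analysis on synthetic
ensembles (2,000 frames each by default) and write tables under `results/`:

```sh
python analysis/01_simulate_ensembles.py   --seed 20000
python analysis/02_secondary_structure.py  --seed 20000
python analysis/04_tail_reach.py           --seed 20000
python analysis/06_tetranucleosome_reach.py --seed 20000
```

Script 02 measures the planted structure of the unmodified-tail analogue
(tip helix T3–G12 planted at persistence 0.8, middle helix L20–A29 at 0.4):

```
unmodified tail: tip-helix H occupancy 0.81, middle 0.40
tip helix more persistent than middle helix: True
```

Script 04 compares the compact ("active-like") and extended
("inactive-like") ensembles:

```
active:   Q1 73.5  median 87.1  Q3 100.0 Å
inactive: Q1 89.8  median 98.4  Q3 109.3 Å
Welch inactive vs active: t = 28.3, df = 3996, p = 3.27e-161;
mean difference 14.5 Å (95% CI 13.5..15.5)
```

i.e. the heterochromatin-associated analogue reaches significantly farther.
Script 06 feeds those quartiles into the tetranucleosome shells:

```
active tail (band 74.2..100.4 Å) reaches: ['intranucleosomal']
inactive tail (band 89.9..108.7 Å) reaches: ['internucleosomal_same_stack', 'intranucleosomal']
adjacent-stack contact for either tail: False
```

— the short-reach tail touches only its parental nucleosome's binding site,
the long-reach tail also the site one nucleosome up/down the same stack, and
neither crosses to the adjacent stack or reaches the H2A/H2B acidic patch.

A `tailscope` console command exposes each stage (`tailscope ss`,
`tailscope cluster`, `tailscope reach`, `tailscope dock-rank`,
`tailscope contacts`, `tailscope chromatin`, `tailscope synth …`), and
`tailscope run` executes every stage end-to-end into a reproducible,
content-hashed report bundle.

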