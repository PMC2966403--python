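# phylogeocat

Comparative mitochondrial phylogeography for co-distributed small cats,
plus a presence-only climatic envelope model of range limits.

The package addresses a recurring question in comparative phylogeography:
when two similar, co-occurring species are sampled over the same landscape,
do they carry congruent signatures of history in their mtDNA — and if not,
can an ecological variable (here, a summer-temperature ceiling) explain the
difference? It implements, as a tested library with a pipeline and CLI,
the full analysis chain used in mtDNA studies of this kind:

* **Sequence handling** — aligned FASTA I/O, per-gene fragment
  concatenation, haplotype collapsing, segregating-site census with
  transition/transversion classification (`seqio`).
* **Diversity and neutrality** — gene diversity *h* = n/(n−1)·(1−Σp²),
  nucleotide diversity π, mean pairwise differences θπ, Watterson's
  θs = S/a₁; Tajima's D = (θπ−θs)/√V̂ and Fu's Fs = ln(S′/(1−S′)) with
  S′ = Pr(K ≥ k_obs | θ=θπ) under the Ewens sampling formula, both with
  coalescent-simulated p-values (`popgen`).
* **Demographic history** — mismatch distributions; the sudden-expansion
  model F_j(τ, θ₀, θ₁) fitted by least squares with parametric-bootstrap
  confidence intervals and Harpending's raggedness; expansion dating
  t = τ/(2µ) (`mismatch`).
* **Population structure** — one-level AMOVA ΦST on pairwise sequence
  differences with permutation tests, pairwise-population ΦST matrices,
  haversine geographic distances, Mantel isolation-by-distance with exact
  enumeration for small instances (`structure`).
* **Genealogy** — median-joining haplotype networks with quasi-median
  vectors (`network`); Jukes–Cantor distances, neighbor-joining trees,
  site-resampling bootstrap and reciprocal-monophyly checks (`phylo`).
* **Niche modelling** — BIOCLIM percentile envelopes (0.025 tail) with a
  tent percentile score and min-over-variables suitability, Pearson
  correlation variable filtering (|r| ≤ 0.7), pseudo-absence sampling and
  rank-based (Mann–Whitney) AUC over replicate 75/25 splits; ESRI ASCII
  grid rasters (`niche`).
* **Simulators** — coalescent alignments (constant size, sudden
  expansion, two islands; finite-sites HKY or infinite-sites mutation) and
  gradient climate rasters with threshold-governed presences, so every
  stage runs without any download (`synthetic_data`).

## Worked example

Generate a synthetic two-species bundle and run the full pipeline:

```bash
python analysis/01_simulate_inputs.py --seed 1
python analysis/02_phylogeography.py
python analysis/03_niche_model.py
```

The second step prints, for the expansion-simulated species A and the
two-island species B:

```
speciesA: n=30, K=26, h=0.989, theta_pi=4.278, theta_s=10.097
  Tajima's D=-2.123 (p=0.005); Fu's Fs=-25.204 (p=0.0)
  mismatch tau=4.472, theta0=0.0, theta1=99999.0, raggedness=0.021
  AMOVA [biogeographic]: Phi_ST=-0.0036 (p=0.55)

speciesB: n=24, K=10, h=0.848, theta_pi=15.779, theta_s=9.373
  Tajima's D=2.603 (p=0.005); Fu's Fs=4.846 (p=0.955)
  AMOVA [biogeographic]: Phi_ST=0.963 (p=0.005)
```

Species A shows the classic expansion signature — strongly negative D and
Fs, a smooth unimodal mismatch distribution fitted by a θ₀≈0 → θ₁ at the
upper bound expansion, and no spatial structure. Species B shows the
opposite: positive D/Fs (two deep clades inflate θπ over θs) and a ΦST
near 1 between the islands. The niche step reports the replicate AUC of
the envelope model and confirms that no presence point exceeds the
simulated bio5 occupancy ceiling:

```
AUC over 10 replicates: mean=0.621 (range 0.544-0.679)
bio5 at presences: mean=25.285 (95% CI 24.587-25.983), max=31.742, 0/140 exceed 32.0
```

The same pipeline runs on real data: aligned per-gene FASTA files, a
metadata CSV (`sample_id,population,biogeographic,taxonomic,latitudinal,
latitude,longitude`), presence CSVs and `.asc` climate rasters, wired
together by a YAML config (see `results/bundle/config.yaml` after step 01,
or `phylogeocat --help`).

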