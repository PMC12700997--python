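# caulotraits

Comparative-genomics and single-cell lifecycle analytics for
*Caulobacterales*-style datasets.

Model bacteria like *Caulobacter crescentus* divide asymmetrically: the
sessile stalked cell reproduces, and each division releases a motile
swarmer daughter that must differentiate before it can divide. Comparative
surveys of the order ask three recurring quantitative questions that this
package turns into a reusable, tested pipeline:

1. **How asymmetric is reproduction?** From tracked timelapse lineages,
   for each mother whose daughters divide after times t₁ ≤ t₂, the
   *degree of asymmetry* is Δt/t₂ with Δt = t₂ − t₁ — how much extra time
   the late daughter needs, as a fraction of its generation time. The
   package pairs daughters (with explicit censoring/exclusion accounting),
   builds the standard overflow histograms, classifies generation-time
   distributions as unimodal or bimodal (EM mixtures selected by ICL,
   reporting the peak separation), and summarizes division-site positions
   against the mid-cell ±5% convention.
2. **Which gene modules were lost convergently?** Given a rooted species
   tree and a genome × gene-family presence/absence matrix (built from
   KEGG-ortholog and reciprocal-best-hit evidence), the screen finds
   families that are conserved in the background, absent from every genome
   of two or more independent lineages, and lost independently under Dollo
   parsimony (single gain at the MRCA of present tips, minimal loss edges
   below it) — the pattern left behind when unrelated clades abandon
   flagellar motility and the dimorphic developmental program.
3. **Who can run photosynthesis?** Rule-based calling of type II
   anoxygenic phototrophy (pufL+pufM reaction-center core plus
   bacteriochlorophyll genes) and photoautotrophic potential (complete
   Calvin–Benson–Bassham cycle including RuBisCO), with photosynthesis
   gene cluster detection in gene-order space, contig-edge truncation
   flags, and cluster synteny scores.

Every method is exercised on synthetic data with planted ground truth —
simulated dimorphic/monomorphic lineages, trees with planted convergent
loss modules, and annotated genomes with planted (optionally
contig-split or scattered) photosynthesis gene clusters — so the whole
pipeline is testable without any external download.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data (each is a thin driver over the library; outputs land in
`results/`):

```sh
python analysis/01_simulate_inputs.py --seed 1
python analysis/02_lifecycle_asymmetry.py --seed 1
python analysis/03_convergent_loss.py
python analysis/04_phototrophy.py
```

which prints:

```
lineages: 9212 dimorphic / 48144 monomorphic cells
matrix: 200 genomes x 2026 families, module of 26 planted in 2 clades
annotations: 20 genomes (2 PGC+CBB, 1 contig-edge PGC, 17 background)
dimorphic: 1977 pairs, median degree 0.333, median Δt 30.0 min, bimodal generation times (peaks 29.6 min apart), mid-cell fraction 0.15
monomorphic: 11510 pairs, median degree 0.083, median Δt 5.0 min, unimodal generation times, mid-cell fraction 0.99
discovered 2 marker-free clades of sizes [6, 7]
screen returned 26 families; vs planted module of 26: precision 1.00, recall 1.00
20 genomes screened: phototrophic fraction 0.15 (2 with photoautotrophic potential)
4 PGC regions detected; edge-flagged fragments in ['EDGE00'] (the split-contig genome)
synteny: 6 region pairs, 5 with fully conserved adjacencies
```

Reading the output: the dimorphic strain's median degree 0.333 matches the
closed form D/(T+D) = 30/90 for a 30-min differentiation delay on a 60-min
stalked generation time, and its generation times are bimodal with peaks
≈30 min apart; the monomorphic strain is unimodal with small degrees and
divides mid-cell (fraction 0.99 vs 0.15 for the off-center divider). The
loss screen recovers the planted 26-family module exactly from the two
marker-free clades it discovers itself. In the genome cohort, 3/20 genomes
(15%) carry phototrophy genes — the two photoautotroph-potential genomes
plus the genome whose cluster is split across a contig edge, which the
detector reports as two edge-flagged fragments.

The same operations are available as a CLI
(`caulotraits simulate|asymmetry|convergent-loss|phototrophy|pgc-cluster|run|validate`)
and as plain library functions (`import caulotraits`).

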