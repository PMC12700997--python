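# Methods

`caulotraits` re-implements, as a tested library, three strands of
comparative analysis for *Caulobacterales*-style datasets: (1) replicative
asymmetry statistics from tracked single-cell division tables, (2)
phylogeny-aware screening of gene presence/absence matrices for modules
convergently lost in independent lineages, and (3) calling of
phototrophic/photoautotrophic genetic potential with photosynthesis gene
cluster (PGC) detection. Because the original datasets (hundreds of
genomes, manually tracked timelapses) are external, every method is
validated against a synthetic-data module that plants known ground truth.

## Replicative asymmetry

For a mother cell whose two daughters divide after generation times
t₁ ≤ t₂, the *degree of asymmetry* is

    degree = Δt / t₂,  Δt = t₂ − t₁,

i.e. the extra time the late daughter needs as a fraction of its own
generation time. Degrees lie in [0, 1); 0 means simultaneous division.
Pairs are formed only for mothers with exactly two daughters whose
division times are both observed; mothers with a censored daughter are
counted as exclusions, and mothers with a different daughter count are
counted as malformed input — neither is an error. Because both daughters
share the mother's division time as their birth time, Δt equals the
difference of the daughters' division times.

Histograms follow the display conventions of timelapse studies: half-open
bins with an explicit overflow bucket (degrees at or above 50%; generation
times at or above 150 min, or 20 h for slow growers), so
counts + overflow + exclusions always reconstruct the input size.

**Generation-time modality.** One- and two-component Gaussian mixtures are
fitted by EM (scikit-learn, multiple seeded restarts) and compared by ICL
— BIC plus twice the assignment entropy. Plain BIC will happily spend a
second component on the mild right skew of single-population generation
times; the entropy term penalizes such heavily overlapping solutions, so a
skewed unimodal sample (gamma, CV ≲ 0.3) is reliably called unimodal while
two populations separated by ~4σ are called bimodal with the peak
separation read off the component means. A zero-variance sample is
unimodal by definition; fewer than `min_n = 50` observations raises an
error rather than risking a silent call.

**Constriction positions.** Division-site positions are displayed
pole-unoriented: each value x is replaced by x or 1−x with equal
(seeded) probability, making the display's null symmetric about 0.5; the
symmetry p-value comes from a two-sample KS test of {x} against {1−x}.
The mid-cell fraction uses the raw orientation-free statistic
min(x, 1−x) ≥ 0.5 − halfwidth (halfwidth 0.05, matching a ±5% band),
binned into 100 bins for display.

## Lineage simulator

The generator emulates agar-pad timelapses of a dimorphic strain. Each
division produces one stalked-like daughter, whose next generation time is
drawn from a gamma distribution with mean `stalked_gen_mean` and CV
`stalked_gen_cv`, and one swarmer-like daughter, whose generation time
adds an independent gamma differentiation delay (`swarmer_delay_mean`,
`swarmer_delay_cv`). Gamma was chosen for its strictly positive support —
a normal would need truncation; a CV of 0 degenerates to the deterministic
mean, and `swarmer_delay_mean = 0` gives monomorphic timing. In the
noise-free limit every complete pair has degree D/(T+D), e.g. 1/3 for a
30-min delay on a 60-min stalked time.

Each cell records which pole is new (formed at its birth division); the
division site is displaced by `division_offset` toward that pole — the
swarmer pole of the coming division — plus Gaussian noise, recorded in the
cell's own unoriented frame. The parameter constraint
`division_offset + 3·position_noise_sd < 0.5` keeps positions inside
(0, 1) up to clamping of rare tails.

All event times are quantized to the imaging interval as the first frame
at or after the event; `imaging_interval = 0` or `None` means continuous
recording (the quantization-free limit). Quantized times are used as-is
downstream, as manual tracking would observe them. Cells not divided by
`duration` are emitted with a missing division time and a censored flag so
pairing code must handle censoring. Defaults (stalked 60 min CV 0.1, delay
30 min CV 0.1, offset 0.07, position noise 0.02, 5-min imaging) are one
fixed choice of realistic magnitudes for a fast-growing dimorphic strain;
they are study conditions, not tuning knobs.

A note on what the monomorphic limit can show: with independent daughter
draws at CV c, the median degree concentrates near Φ⁻¹(0.75)·√2·c (≈0.095
at c = 0.1), not near zero — a delay-free strain is distinguished from a
dimorphic one by the *location* of its degree distribution and its
unimodal generation times, not by degrees vanishing. Real sibling pairs
share microenvironment and inherited factors, which correlates their
generation times and pushes observed degrees lower than this independence
model predicts; the simulator deliberately does not model that
correlation.

## Presence/absence matrices

Presence evidence comes from two channels: KEGG-ortholog annotations and
reciprocal best hits (RBH) against a reference proteome. Each matrix cell
stores an evidence code (absent / KO only / RBH only / both); presence is
the union, mirroring displays that overlay both annotation sources, and
multi-copy genes collapse to presence. Family definitions (KO ids plus
reference locus ids per family, with a category label) are configuration —
a JSON shipped with defaults covering flagellum, chemotaxis, T4P,
holdfast, developmental regulators, crescentin, S-layer, photosynthesis,
carotenoid and CBB families — not code.

RBH selection filters both directional hit tables to e-value ≤ 1e-3, takes
each query's best hit (maximal bitscore; ties broken by minimal e-value,
then lexicographic subject id, for determinism), and keeps mutual pairs.
The output is a partial matching by construction.

Clade aggregation is the per-clade mean of binary presence (a fraction in
[0, 1]); estimated genome size is assembly size divided by completeness,
with percent-style completeness values (1, 100] auto-detected and
normalized under a warning. Environment summaries tally a controlled
category vocabulary, mapping unknown labels to "unclassified" so fractions
sum to one.

## Convergent-loss screening

`fitch_score` is unrestricted binary parsimony computed by a min-cost
dynamic program (Sankoff-style), which is exact on multifurcating trees;
it returns one optimal ancestral labeling (ties resolved toward the
parent's state, deterministically). `dollo_losses` is Dollo parsimony: the
gene is gained once, at the MRCA of the present tips (the root if all tips
are present; a family absent everywhere has no inferable gain and returns
empty). Losses are the maximal edges inside the gain subtree whose entire
tip set is absent — a unique, pairwise-incomparable set. Absences outside
the gain subtree need no loss: they predate the gain. Dollo is the default
loss counter because the screened scenario argues ancestral presence;
Fitch remains available as a diagnostic. Independent-loss counting
collapses ancestor–descendant event pairs; for Dollo output this is a
no-op, which the screen asserts.

The co-loss screen takes ≥2 disjoint focal genome sets and returns the
families that are (a) present in at least `conservation_min` of the
background (default 0.75 — a module choice for "largely conserved", not an
external constant), (b) absent from every focal genome, and (c) lost
independently at least as many times as there are focal sets. Focal sets
can be discovered from the data as maximal clades in which every genome
lacks every marker family. Absence patterns are further classified as
`focal_only` (relatives retain the gene) versus `focal_and_relatives`,
with "close relatives" supplied explicitly or defaulting to same-genus
non-focal genomes.

## Planted-matrix generator

Random rooted binary trees come from seeded uniform random pair joins
(coalescent-style); the screens are topology-agnostic, so the topology
distribution is immaterial. Focal clades are drawn among clades of 3 to
n/8 tips (a generator choice keeping lineages small relative to the
background), subject to three exclusions: overlap/nesting (disjointness),
sister pairs, and children of the root. The last two matter for truth
integrity: losses planted in sister clades collapse into a single stem
loss under parsimony, and a "lost" root-child clade is indistinguishable
from a later gain — in either case the planted claim of k independent
losses would be false by construction.

Background families are present per tip with probability
`background_conservation`, then flipped absent with `sporadic_loss_rate`;
module families are absent in exactly the focal tips. Sporadic noise never
touches the module (keeping the truth exact) unless `noise_on_module` is
set for robustness experiments.

## Phototrophy and gene clusters

Pathway completeness is step-based: a pathway is an ordered set of named
steps, each satisfied by any of its alternative gene combinations, where a
combination may require several subunits (so cbbL + cbbS count once,
avoiding subunit double-counting). Completeness is satisfied steps over
total steps and is monotone under gene-set union.

The phototroph call requires the reaction-center core (pufL AND pufM) plus
at least 4 of 16 bacteriochlorophyll-synthesis families;
photoautotrophic potential additionally requires a complete CBB cycle
including the required RuBisCO step. A genome complete except for RuBisCO
keeps the phototroph level and raises `near_complete_cbb_missing_rubisco`
— the signature of a cluster truncated by assembly. LH2 (pucAB) and
carotenoid (crtCDF) families are recorded as evidence only. These numeric
gates are a shipped, editable rule set validated on synthetic truth; no
external standard fixes them.

Cluster detection works in gene-index space — distance is the number of
intervening genes, robust to intergenic length variation. A cluster is a
maximal run of category genes with at most `max_gap` (default 5)
non-category genes between consecutive members, reported at
`min_members` ≥ 5; a run whose first/last member lies within `max_gap`
genes of a contig end is edge-flagged as potentially truncated. Synteny
between two clusters reports shared families, the fraction of adjacent
shared pairs in one cluster that are adjacent (either orientation) in the
other, and strand agreement relative to each cluster's majority frame.

The genome generator plants a canonical crt/bch/puf cluster layout
(optionally with CBB genes inside the cluster, as observed for
photoautotrophic members) in background genomes of ~2000 genes —
a typical bacterial gene count; `split_at` breaks the cluster across two
contigs with both fragments abutting contig ends, and `scatter` destroys
clustering while keeping gene content. No sequences are generated —
annotations are the unit of analysis.

## Pipeline, formats, determinism

All tables are TSV (UTF-8, headers mandatory, 0-based half-open
coordinates); trees are Newick (dendropy-parsed, deterministic post-order
internal ids, duplicate tips rejected, multifurcating roots accepted with
a warning). File writes are atomic (temp-file-then-rename), so partial
files never parse as complete. The pipeline runner executes stages in
dependency order from a JSON config; each stochastic stage consumes
exactly one child seed derived as
`SeedSequence([root_seed, stage_index])`, and the run manifest records the
tool version, config hash, input checksums, stage seeds, row counts and
output checksums. Two runs with the same config and seed produce
byte-identical outputs.

## Problem sizes and what passing shows

The validation suite runs at desk scale: exhaustive parsimony checks on
100 random trees of ≤8 tips (every tip pattern against enumeration over
all ancestral labelings), planted-module recovery on 200-tip trees with
2026 families (noise-free, and 20 seeds at 95% conservation / 1% sporadic
loss), ~2000 daughter pairs per simulated strain, 100 modality replicates
per scenario, 50 random RBH tables against a double-loop oracle, and 100
scatter shuffles for the cluster null. These sizes were chosen to make the
checks sharp (exact where exactness is claimed, tight rates elsewhere)
while keeping the whole suite under a minute of CPU.

Passing demonstrates internal correctness on data whose generating process
matches the model's assumptions: independent gamma generation times, a
single planted loss module over i.i.d. background noise, exactly annotated
gene orders. Real data violate all of these in places — correlated sibling
physiology, lineage-specific annotation biases, fragmented assemblies,
mis-binned MAGs — so synthetic recall/precision figures bound what the
methods can do, not what any particular dataset will yield.

## Known limitations

- Dollo parsimony is unweighted and rate-free; it cannot distinguish loss
  from undetected presence (incomplete genomes) and offers no uncertainty.
- The screen's background/focal dichotomy assumes focal lineages are known
  or discoverable from markers; partial losses inside a focal clade are
  not modeled.
- The modality classifier fits location mixtures only; strongly skewed
  bimodal mixtures with coincident means are out of scope.
- Phototrophy rules are genetic potential, not expression or activity.
- The simulator does not model growth-rate inheritance, sibling
  correlation, cell-size control, or imaging segmentation error.
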