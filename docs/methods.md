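# Methods

## The paired-consensus model

The analysis treats each patient as their own control. All quantities flow
from one primitive: the within-patient fold change of per-million-normalized
H3K27ac fragment density, CAF over paired NF. A region (or gene) is called
reprogrammed only when the per-patient criterion holds in at least
`min_pairs` patients. The default `min_pairs` is the strict majority,
⌊n/2⌋ + 1 (4 for a 6-pair histone cohort and for a 7-pair RNA cohort),
which both encodes "in more than 3 pairs" and guarantees the activated and
repressed sets are disjoint whenever the up- and down-thresholds are on
opposite sides of 1. No variance model is fitted across patients: the
consensus count *is* the heterogeneity model, which is the point of the
design — an effect absent in a minority of patients does not block a call,
and an effect present in only a minority does not create one.

### Region algebra

Coordinates are 0-based half-open throughout (BED native). Peak merging
follows center distance: two peaks on one chromosome belong to the same
merged group when their centers are ≤ `merge_d` (default 200 bp) apart,
taken to transitive closure, so chains longer than `merge_d` are allowed.
On a line this closure equals chaining center-sorted neighbours. The merged
span is the union span (min start, max end) of the group — the span rule of
the original merging tool is not documented anywhere we could rely on, so
union-span is this package's documented choice; it is idempotent because a
merged center never leaves the interval spanned by its members' centers.

Fragments are assigned to regions by midpoint containment rather than
any-overlap. An any-overlap rule lets one fragment inflate two abutting
regions; the midpoint rule gives each fragment at most one vote per
disjoint tiling. Counts are normalized as
`(count + 1) × 10⁶ / total_unique` — the one-fragment pseudocount exists
solely to keep every fold change finite, and `total_unique` is taken from
sample metadata rather than the fragment file so that down-sampled files
keep honest scaling.

Promoters are TSS ± 1 kb, strand-symmetric. Nearest-gene assignment
minimizes |TSS − region center| among genes on the region's chromosome,
with deterministic tie-breaks (smaller TSS, then lexicographic gene id).

### Enhancer calls

Per sample, active enhancers are H3K27ac peaks overlapping an H3K4me1 peak
of the same sample by ≥ `min_overlap_bp` (default 1 bp). The cohort union
concatenates all samples' active enhancers and center-merges once; H3K27ac
fragments of all samples are then re-counted on the union. Activated:
FC ≥ `fc_up` (default 2) in ≥ `min_pairs` patients; repressed: FC ≤
`fc_down` (default ½). With `fc_down = 1/fc_up`, relabelling NF↔CAF in the
design exchanges the two sets exactly; this symmetry is asserted in the
test suite. Whether the original analysis applied any cross-sample scaling
beyond per-sample depth normalization is unstated; this implementation
uses per-sample RPM only.

TOP-k ranking sums the per-patient fold changes within a promoter or
non-promoter stratum and takes the k highest (default k = 2,000), ties
broken by coordinate.

### Expression

Signature genes use the same consensus rule on FPKM-like values with a
pseudocount of ε = 0.1 FPKM (expression of zero is common; the threshold is
applied to the raw pseudocounted ratio, not its log). The signature score
of an independent sample is the unweighted mean of the signature genes
detected in that dataset; "undetected" means absent from the platform,
flagged absent in a supplied detection column, or — failing both — zero in
every sample. The same gene set is dropped for all samples, so scores stay
comparable, and the score scales linearly with global rescaling of the
matrix.

IHC composite scores multiply the percentage-positive bin (0–25, 26–50,
51–75, 76–100 → 1–4) by the staining-intensity bin (negative, weak,
moderate, strong → 1–4); the 1–4 numeric coding of the printed categories
is implied rather than stated by the scoring scheme and is fixed here in
listed order.

### Central motif enrichment

This is deliberately a simplified centrality statistic, not a port of
CentriMo or HOMER. Per PWM (probabilities floored at 10⁻³ per cell and
renormalized; JASPAR count matrices read with +0.25 pseudocount) each
±300 bp center-anchored sequence contributes its single best log-odds site
over both strands (ZOOPS; N bases score 0; ties resolve to the smallest
position, then the + strand). Sequences whose best score falls below
`score_min` (default 60% of the PWM's maximum log-odds) are ignored. Among
passing sequences, a hit is a best site *fully contained* in the central
±100 bp window, so the uniform-null success probability is exactly

    p0 = (2·central_half − W + 1) / (L − W + 1)

and the reported p-value is the one-sided binomial tail. Containment (vs
"midpoint within the window") was chosen to make the hit rule and p0
identical, keeping the test calibrated: under uniformly placed best sites
the p-values are uniform-to-conservative, which the suite verifies by
simulation. Motifs are ranked by p-value, ties by central hit fraction,
then motif id. No multiple-testing correction is applied across the
library; ranking, not inference, is the goal.

### Sample structure

PCA and average-linkage hierarchical clustering (Euclidean metric) operate
on log2(RPM + 1), region-centered signal at a chosen region subset
(typically the activated enhancers). The transform is recorded in the
embedding. PCA signs follow a fixed convention (largest-magnitude loading
positive); clustering cuts the dendrogram at k clusters with ties resolved
by sample order. Linkage and metric are exposed as arguments since no
single choice is canonical.

## The synthetic cohort

`CohortSpec` defaults define the study conditions end to end: 6 NF/CAF
pairs, a 2 × 5 Mb uniform-random genome, 2,000 enhancer loci (≈1 kb wide,
≥1.5 kb apart), 300 activated at fold 4 and 150 repressed at fold 0.25,
per-(locus, patient) effect dropout 1/6, 2×10⁵ fragments per sample per
mark, 800 genes, AP-1 consensus (TGACTCA/TGAGTCA, 20% with one mismatch,
random strand) planted within ±50 bp of 70% of activated-locus centers,
expression coupling of +1.5 log2 in CAF columns for nearest genes of
realized activated loci, and a separate 7-pair RNA design with 100
signature genes planted at fold 3 in exactly 5 of 7 pairs.

Fragments are per-locus Poisson signal over a uniform background; 75% of
the expected depth sits at loci (λ ≈ 75 per locus per sample) and 25% is
background. H3K4me1 rates are condition-independent and its peaks (and
even its spurious peak calls) are identical within a pair, encoding the
preset-and-maintained behaviour of the priming mark. An H3K27ac peak is
emitted where the expected local rate is at least half the base rate, so
realized repressed loci lose their CAF peak but stay in the union through
the NF samples. `total_unique` always equals the number of fragments
written. All randomness flows from one `numpy` generator seeded by
`CohortSpec.seed`; identical seeds give byte-identical files.

Expression noise is decomposed as lognormal patient-level biological
variation (σ = 0.4 natural-log units per gene per patient, shared by the
NF and CAF of a pair) plus a small per-sample technical term (σ = 0.1 log2
units). Placing the dominant term at the patient level is the generator's
model of why the paired design works: within-pair ratios cancel the
biological term, while unpaired comparisons see the full σ = 0.4 spread.
The two-group "invasive vs normal stroma" matrix uses the same machinery
with every column its own "patient", so group comparisons there do face
the full biological variance.

What the generator does **not** emulate: GC and mappability bias, duplicate
reads, fragment-length/peak-shape realism, copy-number artifacts,
non-uniform genomic background, correlated gene programs, or platform
detection limits. Passing tests therefore demonstrate that the algorithms
recover what they are specified to recover under clean planted structure —
not that the thresholds are optimal for any particular real cohort.

## Numerical and design choices

* Fold changes are always finite by construction (pseudocounted RPM /
  FPKM); no special-casing of zeros anywhere downstream.
* Expected recovery on the default cohort is bounded by dropout, not by
  noise: a planted effect needs ≥ 4 realized pairs out of 6, which happens
  with probability ≈ 0.94 at dropout 1/6 — observed recall ≈ 0.93–0.97 with
  precision ≈ 1.0 is the anticipated operating point, comfortably above the
  0.90 the suite requires but visibly below 1.
* Column-shuffled PWMs serve as ranking decoys; shuffles equal to the
  original matrix are rejected (a near-palindromic motif has column
  permutations that reproduce it exactly).
* Problem sizes in the tests: the full default cohort is generated once per
  session and reused; repeated-generation tests (determinism, null cohorts)
  use a reduced spec (1 × 0.4 Mb genome, 80 loci, 4 pairs, 4×10⁴ fragments)
  — small enough to regenerate in about a second while exercising every
  code path.
* Brute-force oracles (union-find merging, quadratic overlap/counting
  scans, per-region double-loop consensus, exhaustive PWM scans, exact
  binomial-tail enumeration) live in the tests and are kept independent of
  the library code paths they check.

## Known limitations

* The consensus caller assumes one NF and one CAF sample per patient;
  replicates must be merged upstream.
* `nearest_gene` requires at least one gene on the region's chromosome and
  uses TSS-to-center distance only (no gene-body distance).
* The centrality statistic evaluates a single fixed central window; it does
  not optimize window width and reports no e-values, so p-values across
  motifs of very different widths are comparable only through p0.
* Counts reported for real cohorts depend on upstream peak calling and
  sequencing depth; the synthetic cohort reproduces the structure of such
  results, not their absolute numbers.
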