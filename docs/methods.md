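# Methods

## Data model

A **methylation matrix** is a set of CpG site records over an ordered
sample list. Each site carries a host-gene symbol, a site identity
(Illumina probe id `cg…`, a genomic position `chrom:pos`, or a synthetic
id), optional position and Annovar-style location category, and a beta
vector in [0, 1] with missing values allowed. Beta values are taken as
given (array or bisulfite pipeline output); no intensity-level
normalization is attempted. An **expression matrix** maps gene symbols to
FPKM vectors ≥ 0. Row keys of methylation matrices are underscore-annotated
gene names (`GENE_cg123_chr1:100_UTR5` in the fixed order gene, site id,
position, location); the parser is total — tokens that are not a probe id,
position, or known location fold back into the gene symbol, so gene names
containing underscores survive.

Pathways are parsed from KGML. Graphics x/y are interpreted as box centers
(the KGML convention) and converted to corners at draw time. A gene entry's
display label is the first comma-separated token of the KGML graphics name
(trailing "…" stripped); all tokens are kept as aliases, and site-to-gene
matching is case-insensitive against any alias, because public metadata
mixes symbol casings. Relations with unrecognized subtype names are kept
with subtype `unknown` and rendered in the explicit "unknown" style rather
than dropped.

## Site filtering

A site passes a filter specification iff every active criterion holds:

* **SD filter** — sample standard deviation over non-missing betas,
  denominator n − 1, strictly greater than the threshold. Sample SD is the
  conventional estimator; sites with fewer than two observed betas fail any
  SD criterion. The working default threshold in examples is 0.2, a value
  at which a two-group flip of Δβ ≈ 0.5 passes (pooled SD ≈ 0.25) while
  technical noise of σ ≈ 0.05 does not.
* **Beta range** — by default *all* non-missing betas must lie inside
  [low, high] (the strict reading of a user-defined range); an "any sample
  in range" mode is available where the permissive reading is wanted.
* **Location** — membership of the site's category in a chosen subset of
  the Annovar vocabulary {upstream, downstream, exonic, intronic, UTR5,
  UTR3, splicing, intergenic, ncRNA}.
* **Site list** — the site's probe id or position key appears in an
  explicit list (e.g. the output of an external feature-selection method).

Filtering partitions the input (passing ∪ excluded, disjoint, order
preserved) and is idempotent.

## Display values

Per-sample gene value = mean beta over the gene's passing sites, skipping
missing entries. Group-wise value = aggregator over member samples'
values; the default is **mean for methylation** and **median for
expression** (both overridable) — the two conventions coexist in practice
and the choice is visible in the config echo of every run. Sites whose
betas are all missing can never pass a filter and never contribute.

Expression display value: `f = log2((x + ε)/(median + ε))` clipped to
[−s, +s], default scale s = 4 and pseudocount ε = 0.01 FPKM (keeps zero
expression finite while shifting a median-sized signal by < 0.1%). Group
boxes take the median of member samples' raw FPKM first, then the same
transform, so a group box equals the fold of a "typical" member rather than
a mean of clipped folds.

## Similar-pattern mining

The target profile is the per-sample mean over the target's sites. For
every candidate site in the loaded matrix (not restricted to the current
pathway, so results can seed a gene-grid view), the distance is the
root-mean-square difference over pairwise-complete samples:
`d = sqrt(Σ_shared (t_s − c_s)² / n_shared)`. Normalizing by the shared
count makes sites with different missingness comparable; the plain
unnormalized Euclidean norm is available as an option. Candidates sharing
fewer than 2 samples with the target are skipped. Per gene only the
minimum-distance site is kept; ranking is ascending (similar) or descending
(dissimilar), ties broken lexicographically by gene symbol so output is
deterministic; the target's own gene is excluded.

## Methylation–expression correlation

Spearman rank correlation (mean ranks for ties, p-value from the
t-distribution approximation with n − 2 df, via `scipy.stats.spearmanr`)
between a site's beta vector and the host gene's FPKM vector, over
pairwise-complete observations (≥ 3 required). A constant vector makes ρ
undefined; it is reported as such and never counted as passing a threshold.
The screening helper keeps genes whose most negative site satisfies
ρ < −0.7 — a plain threshold, matching how such screens are typically
applied; Benjamini–Hochberg FDR control over the best-site p-values is
available behind a flag for analysts who want it.

## Rendering

Colors interpolate linearly in 8-bit RGB (simplicity and byte-determinism
over perceptual uniformity): methylation dark blue `#00008B` → white →
dark red `#8B0000` with white exactly at β = 0.5; expression red (−s) →
white (0) → blue (+s), inverted from expression-centric conventions so a
methylation-silenced gene trends the same color in both data types. Status
colors: light green `#CCFFCC` = no data matched, gray `#BEBEBE` = sites
existed but none passed the filter; a green border `#008000` marks genes
averaging more than one site. Non-gene entries (maps, compounds, groups)
render neutrally and never receive overlay colors.

SVG is assembled by plain string concatenation with fixed numeric
formatting — no timestamps, random ids, or dict-order dependence — so a
fixed plan renders byte-identically, which the test-suite asserts for every
renderer. Relation edges use a fixed per-subtype style table (activation:
solid + arrowhead; inhibition: bar end; repression: dashed + bar;
methylation: distinct dash; unknown: dotted). Matplotlib figures (bar
plot/histogram) pin `svg.hashsalt` and strip the date so they are
reproducible too, and every figure's numbers are exported as TSV beside it.
Playback emits one single-sample frame per sample in a caller-supplied
order; with expression loaded, each gene shows its methylation and
expression boxes side by side (a static-frame adaptation of a stacked
interactive view).

## Synthetic data generator

The generator emulates a two-group tumor-cohort contrast: two groups of 20
samples; per gene, 3 CpG sites; in 4 "planted" genes the first site draws
group means 0.15 vs 0.65 (Δβ = 0.5, the magnitude of a strong
hypermethylation event) with truncated-Gaussian noise σ = 0.05; background
sites share one mean (0.35) across groups. Two planted genes are
"coupled": FPKM = 50 · 2^(−4·β) times log-normal noise (sd 0.1), a strictly
decreasing map from methylation to expression, so with zero noise Spearman
ρ is exactly −1. Noise models match the supports (truncated Gaussian on
[0, 1] betas, multiplicative log-normal on positive FPKM). A truth table
(planted site ids, coupled genes) ships beside the matrices, making
recovery tests self-describing. Output is byte-reproducible under a fixed
seed.

What it does **not** emulate: probe-level array chemistry and bias,
co-methylation/LD structure between neighboring sites, batch effects,
realistic FPKM dynamic range, or many-to-many probe/gene annotation.
Passing the planted-recovery tests therefore demonstrates that the
filtering/correlation machinery is arithmetically correct and wired
end-to-end, not that the thresholds are optimal on real cohorts.

## Problem sizes and numerical choices

The default test/acceptance conditions (12 genes × 3 sites × 40 samples;
100 random graphs for round-trips; 200 random filter cases; 5 random
20 × 15 similarity matrices) keep the whole suite within seconds while
leaving no filter branch or ordering contract unexercised. Bismark
percentages are cross-checked against count ratios and discrepancies
beyond 0.005 logged, not fatal (truncated-file detection). Ties in sample
ordering preserve input order (stable sort); undefined (all-missing)
samples sort last. KEGG access goes through an injectable transport with a
byte-identical local cache, so parses are reproducible and tests never
touch the network.

## Known limitations

* Annotation is table-driven; the package does not compute genomic-region
  assignments itself, and conflicting duplicate probe annotations are
  rejected rather than merged.
* Only KGML is supported as a pathway source.
* The gene grid and playback are static artifacts; there is no interactive
  navigation, and frames are not encoded to video.
* Expression "sites" are whole-gene vectors; transcript-level resolution is
  out of scope.
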