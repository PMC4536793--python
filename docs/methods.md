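# Methods

`pombechip` re-implements, as a tested pipeline, the computational
analyses of a fission-yeast study of the Ccr4-Not complex: identifying
the RNAs bound by complex subunits (RIP-chip), calling expression
changes in deadenylase mutants, quantifying the overlap between gene
sets, and measuring heterochromatin integrity as H3-normalized
H3K9me2 ChIP-seq occupancy over annotated chromatin domains. This note
records the models, the parameters that matter, the numerical choices,
and what the synthetic-data generator does and does not emulate.

## RIP-chip target calling (`ripchip`)

Input is a gene x replicate matrix of log2(IP/total) enrichments. Per
array (column) the values are mean-centred and converted to z-scores
using the sample (n−1) standard deviation; a transcript is called a
target when z > 2.5 (strict) in at least k of n biological replicates,
with k = 2 for both the duplicated (2-of-2) and triplicated (2-of-3)
designs. Choices worth recording:

* Centring, the SD and the z-score are per array, not pooled across
  arrays: each hybridization carries its own scale, and cross-array
  reproducibility is enforced by the k-of-n rule instead. Pooled
  variants would change z by a near-constant factor and are not
  implemented.
* A zero-variance array yields all-zero z-scores rather than a
  division error; ties exactly at the threshold are not called. Both
  conventions only matter on degenerate inputs.
* A gene missing in some replicate is evaluated on its remaining
  replicates against the same k — an undetected probe cannot veto a
  call, but it also cannot support one.
* The upstream "detected RNA" filter is not a fixed rule;
  `detected_filter` exposes a maximum-missing-fraction and a
  minimum-intensity knob and applies no filtering by default.

`relative_enrichment` expresses per-target enrichments relative to a
reference transcript (e.g. actin) and reports the per-replicate median
over the queried set, matching how per-target panels are usually drawn.

## Differential expression (`diffexpr`)

Each array is already a mutant-vs-wild-type log2 ratio, so the design
is one-class: per gene, is the mean log-ratio non-zero? The moderated
statistic is

    d_g = mean_g / (se_g + s0)

with `se_g` the standard error of the replicate log-ratios and `s0` a
fudge constant that keeps low-variance genes from dominating. `s0` is
chosen by the standard tuning search: candidates are percentiles of
the gene-wise standard errors; for each candidate, genes are binned by
standard error and the candidate minimizing the coefficient of
variation of the within-bin MAD of d is selected. A fixed-percentile
shortcut (`percentile_s0`) is available, but with 2–3 replicates the
standard-error distribution is heavy-tailed and small fixed
percentiles systematically under-damp d (near-zero-variance genes
produce extreme null statistics), which destroys the separation
between planted and null genes; the tuned value is therefore the
default.

The false-discovery rate is estimated by permutation. Exchangeability
under the null (symmetric ratio noise) justifies sign flips; one
random ±1 per replicate *column* per permutation, shared by all genes,
is used — the scheme of the cited microarray-significance method.
Column-wise flips matter when many genes carry true signal: they
concentrate the sign patterns that regenerate the signal into a
minority of permutations, which the median-based FDR estimate then
ignores, whereas independent per-cell flips would regenerate a
constant fraction of the signal in *every* permutation and inflate
every q-value. Per gene,

    q_g = median_b #{ |d_null^(b)| >= |d_g| } / #{ |d_obs| >= |d_g| },

capped at 1; genes with q below the configured FDR (default 0.005) are
called and split by sign into up- and down-regulated lists. The
procedure is bit-reproducible given a seed, and the seed is mandatory.

Arrays with intensity-dependent dye bias are corrected by Loess:
per array, a locally weighted regression (span 0.3) of log-ratio on
mean log-intensity is subtracted. Ratio tables destined for stability
comparisons are median-centred instead, as is conventional for that
analysis. Fold-changes are reported as 2^(mean log2 ratio).

## Set overlaps (`overlap`)

For gene lists A and B in an explicit universe of N genes, the
expected overlap of random lists is the hypergeometric mean |A||B|/N
and significance is the one-sided (enrichment) Fisher exact test,
i.e. the hypergeometric upper tail P(X ≥ observed) (delegated to
`scipy.stats.hypergeom`; an exhaustive enumeration oracle in the test
suite checks every instance with N ≤ 12 exactly). The universe is a
mandatory argument — detected-on-array versus whole-annotation
universes change both numbers materially, so no default exists. No
multiple-testing correction is applied across panels; p-values are
reported raw, one per comparison.

## ChIP-seq occupancy (`occupancy`)

Reads arrive aligned (SAM primary alignments or BED; the generator
emits aligned coordinates directly) and trimmed to a fixed length
(default 50 bp). Quantification:

1. **Counting.** A read is assigned to every feature whose half-open
   interval contains its leftmost position (midpoint assignment is a
   config alternative). The single-point rule makes counts additive
   and boundary behaviour exact; overlapping features (islands overlap
   genes) each receive the read.
2. **RPKM** = count / (feature kb) / (library millions), with the
   library defined as all aligned reads of the sample, not only
   in-feature reads.
3. **H3 normalization.** Per condition and replicate, the H3K9me2
   RPKM is divided by the H3 RPKM of the matching sample; features
   with zero H3 signal are flagged undefined rather than set to zero.

Calls on the normalized ratios:

* **Background** is the per-replicate median ratio over features not
  annotated as heterochromatin. A *candidate* domain is flagged
  enriched when its ratio is at least `enrichment_factor` (default 2)
  times background in every replicate. Candidates default to the
  annotated heterochromatin features: the question asked is which
  *reported* domains show enrichment, not de-novo discovery.
* **Condition comparison.** Ratios of each condition are first divided
  by that condition's own background. This matters because per-million
  normalization is composition-sensitive: a mutant that loses domain
  methylation redistributes those reads genome-wide, which inflates
  every other ratio by the change in total enrichment mass (at the
  generator's defaults, a true 0.3 density fold measures as ~0.39 raw,
  and untouched domains as ~1.3). Background rescaling restores folds
  centred on the density change. A feature is called reduced when the
  mutant/WT fold is ≤ 1/`reduction_factor` (default 2) in every
  replicate pairing; increases are symmetric; undefined ratios yield
  `not_evaluable`, never a silent drop. The H3 RPKM fold is reported
  in parallel so methylation losses can be distinguished from histone
  losses.
* Thresholds are deliberately configuration, echoed into output
  headers: the underlying calls ("clear and reproducible") are not
  defined numerically in the source analysis, so no claim of numeric
  identity with it is made. "Reproducible" is operationalized as
  "in every replicate (pairing)"; a k-of-n relaxation is exposed.

`class_summary` groups per-feature rows by class (islands,
subtelomeres, centromere, transposons, HOODs, genes) with ratios,
folds and calls, mirroring the per-class supplementary-table layout.
A binned me2/H3 bedGraph track per condition supports browser-style
inspection.

## qPCR (`qpcr`)

The comparative Ct method on a target/reference x IP/input quartet:

    ddCt = (Ct_target_IP − Ct_ref_IP) − (Ct_target_INPUT − Ct_ref_INPUT)
    ratio = 2^(−ddCt)

PCR efficiency is fixed at 2, as the formula assumes. Because
published renderings of the exponent sometimes typeset the two deltas
summed rather than differenced while still labelling the quantity
2^−ddCt, the standard difference-of-differences is the default and the
summed-sign literal reading is available behind `literal_sign=True`.
Replicate ratios are aggregated by geometric mean (ratios are
log-scale quantities) with the SD reported on the log2 scale.

## Synthetic data (`synthetic`)

All pipeline inputs are generated from a single seed through labelled
substreams (`SeedSequence([seed, crc32(label)])`), so each generator is
bit-reproducible independently of call order. Defaults are the study's
conditions at desk scale:

| parameter | default | rationale |
|---|---|---|
| genes on array | 5,000 | order of the fission-yeast gene count |
| RIP targets / effect / noise | 50 / +3.0 log2 / 0.5 log2, 2 replicates | tens of bound RNAs, strong IP enrichment |
| DE genes / effect / noise | 80 / ±1.5 log2 / 0.3 log2, 3 replicates | tens of changed RNAs in the mutants |
| candidate islands / methylated / lost | 21 / 6 / 5 | island census and the subset with detectable/lost signal |
| me2 enrichment / mutant retention | 8× / 0.2 | strong heterochromatin mark, partial mutant loss |
| genome / reads per channel / read length | 1.5 Mb over 3 chromosomes / 100,000 / 50 bp | ~1,000 expected reads per island (well above the ~200 needed for stable ratios) at second-scale runtimes; reads are pre-trimmed to 50 bp |
| qPCR true ratio / Ct noise | 8 / 0.1 cycles | typical ChIP enrichment and machine noise |

The genome places four subtelomeric blocks (chrI/chrII ends) each with
a distal 5-kb "nucleation" sub-block that never loses methylation in
mutants, one centromere, two transposon and two HOOD blocks, and lays
candidate islands over runs of genes so that islands overlap genes as
in the real annotation. The H3 channel is uniform by default, giving
the normalization a known flat denominator; `h3_domain_factor` < 1
simulates nucleosome depletion inside domains to exercise the
normalization's purpose. The expression generator can add a smooth
cosine-shaped intensity-dependent dye bias to exercise Loess.

What the generator does **not** emulate — and hence what passing tests
do not demonstrate about real data: probe-level effects
(cross-hybridization, spot quality, saturation), correlated or
heavy-tailed array noise, PCR amplification and GC bias in libraries,
multi-mapping and duplicate reads, nucleosome positioning, partial or
spreading methylation boundaries within a domain, and biological
replicate-to-replicate variance beyond resampling noise. Recovery
rates measured here are therefore upper bounds on real-data
performance of the same procedures.

## Problem sizes and determinism

Tests and the acceptance script run the generators at the default
sizes above (5,000 genes; 100,000 reads per channel per sample;
10–20 seeds per calibration claim; 100 permutations and 10,000
Monte-Carlo draws where applicable), sizes chosen so the whole suite
completes in about a minute while every planted effect remains
comfortably resolvable. Every stochastic step takes an explicit seed;
re-running any stage on unchanged inputs reproduces outputs
byte-identically.

## Known limitations

* The SAM q-value estimator omits the π0 (true-null fraction)
  correction, making it mildly conservative when many genes are truly
  changed; at FDR 0.005 this does not affect the calls on the
  generator's defaults.
* `detect_enriched` scores annotated candidates; it is not a peak
  caller and will not find unannotated domains.
* Ingestion counts SAM primary alignments only and ignores CIGAR
  detail beyond the alignment start; spliced or clipped alignments are
  treated by their leftmost position.
* The Loess correction assumes a single smooth trend per array; it
  will not remove spatial (print-tip) artefacts.
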