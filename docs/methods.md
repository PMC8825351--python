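# Methods

This note documents the models, estimators, defaults, and design choices
behind `rmtcr`, and what the synthetic-data validation does and does not
establish about real data.

## V(D)J reference QC

A usable rhesus TCR reference is assembled from IMGT V/D/J segments plus
TRAC/TRBC constant-region alleles taken from IMGT and Ensembl CDS models;
the package bundles the nine RM constant-region alleles used for this
purpose (`rmtcr/data/rm_tcr_cregions.fasta`) in the pipe-delimited header
dialect (`record_id|allele note|gene|region|group|chain|...`).

Each segment is screened for:

* **premature stops** — any in-frame TAA/TAG/TGA, reading from a
  configurable frame offset, excluding a terminal stop codon (CDS-derived
  constant regions legitimately end in one);
* **frame-length defects** — a C-region whose length minus the frame
  offset is not a codon multiple, the symptom of a single-base deletion;
* **ambiguous bases** (warning only) and **truncations** (< 30 nt by
  default).

Records are removed when flagged for stops or frame length; ambiguous
bases only warn. The reading frame of a constant region is implied by the
upstream J junction and is not recorded in the FASTA, so the default frame
is 0 with a per-allele override. This matters: among the bundled alleles,
TRAC*02–06 are stop-free in frame 0 while TRAC*01 and TRBC1*01 are
stop-free only in frame 2, and TRBC1*02/TRBC2*03 have no stop-free frame
at all — as printed they carry single-base deletions relative to TRBC1*01
(e.g. `CCACAGCTTCTAC` vs `CCACAGGCTTCTAC`), and whether those are true
alleles or transcription artifacts cannot be decided from sequence alone.
The filter reports them; it does not adjudicate.

Primer auditing uses a Hamming (substitution-only) match model on both
strands. An indel-tolerant model was rejected deliberately: with exact
Hamming scanning the independent brute-force oracle in the tests is exact,
and enrichment primers are short enough that indel annealing is not the
failure mode of interest. Primer Tm is the Wallace rule, 2(A+T) + 4(G+C)
°C, matching how short-primer kits quote annealing temperatures; a
nearest-neighbor model is out of scope. Nested inner/outer spacing is
reported as the distance between primer 3′-end template positions within
the segment; published amplicon spacings can span exon junctions or UTR
and need not equal the within-segment distance, so no particular value is
assumed.

## Contig tables and chain summaries

`filtered_contig_annotations.csv` tables are grouped per barcode. The
per-sample chain summary reports the percentage of cells with a
CDR3-annotated alpha contig, with a beta contig, and with a full-length
productive alpha+beta pair. CDR3 presence alone (not `full_length`) is the
criterion for the single-chain rates, because that is what "reconstructed
CDR3-annotated chain" means operationally; the pair rate additionally
requires `productive` and `full_length` on both chains. Droplets whose
chains all failed reconstruction have no contig rows at all; when the full
droplet list is known (from the matched GEX library or a simulation),
`pad_cells` restores them so denominators count every cell. Barcode
matching between VDJ and GEX libraries strips a single trailing `-<digit>`
GEM-well suffix by default.

## Clonotyping and MLR tagging

A clonotype key is the CDR3 nucleotide sequence of the alpha chain, beta
chain, or both. When a cell has multiple contigs of a required chain the
highest-UMI contig is used (ties broken by contig id), and the cell is
counted in a doublet-warning tally. Tagging uses paired keys by default —
the stricter match for linking tissue cells to MLR clonotypes — with
single-chain modes available for cross-sample tracking where alpha-only
grouping is the norm.

The allo-proliferating set is defined as every clonotype observed at least
`min_cells = 2` times in the CTV-Low (highly proliferated) fraction. No
published threshold exists for this; it is config-exposed and logged. Note
an inherent limitation of count-threshold derivation under the
multiplicative expansion model used here (below): multi-cell *background*
clonotypes also pass any small threshold purely by sampling collisions, so
the derived set is a superset of the planted set. In the wet-lab assay the
CTV sort physically excludes undivided cells, which is what makes CTV-Low
clonotypes alloreactive by construction; clone-size alone cannot reproduce
that separation, because an expanded small clone and an unexpanded large
clone are indistinguishable in a single sample. Exactness claims in the
tests therefore use the planted key set (tagging mechanics), while the
threshold rule is validated for sensitivity.

## Diversity and overlap statistics

Shannon entropy is the plug-in estimator in nats with the analytic
variance used by the Hutcheson test (delta-method term plus the
(S−1)/(2N²) correction). Nats were chosen because the R packages standard
in this niche default to natural logs and because observed per-sample
values at thousands of clonotypes (≈ 7.5–9.1) are consistent with nats.
The plug-in estimator is biased low by unseen clonotypes — roughly
−(S/2N) nats; at N = S = 5,000 this is ≈ 0.4 nats — so absolute H values
should only be compared between samples of similar depth, which is how
they are used here. Rarefaction/extrapolation corrections are out of
scope.

The Hutcheson test uses a two-sided t-distribution tail at Welch-style
degrees of freedom, floored at 1. Identical inputs return t = 0, p = 1
rather than an error.

The Morisita index defaults to the classical integer-count estimator,
with the Morisita–Horn variant as an option (the R `vegan` package offers
both; tests pin agreement with both to 1e-9). When both samples are
all-singletons the classical denominator vanishes and the Horn form is
substituted, flagged in the result. Counts are raw cell counts, not
UMI-weighted.

## Expression pipeline

QC applies the gene filter first (genes in < 5 cells removed), recomputes
per-cell metrics on the reduced gene set, then applies cell filters:
500–6,000 genes detected and 1,800–40,000 transcripts (closed intervals),
mitochondrial fraction strictly < 5%. Because removing cells can push a
gene below the 5-cell floor, one more application may drop genes; the
operation is idempotent from the second application onward.

Normalization is log-CP10K by default. A variance-stabilizing
regression-based normalization in the style of scTransform is not
re-implemented; since the downstream tests (rank-sum DE, signature-score
rank-sum) are rank-based within genes, they are insensitive to the choice
within this family. An analytic Pearson-residual option (NB null, fixed
dispersion θ = 100, clipped at √n) is provided and recorded in the output
metadata.

Differential expression is a per-gene two-sided Wilcoxon rank-sum test
(normal approximation, tie-corrected); all-tied genes get p = 1. The
log₂ fold change is computed on de-logged group means with ε = 1e-9.
Adjustment defaults to Bonferroni — the default adjusted p of the
toolchain this pipeline mirrors — with Benjamini–Hochberg available;
adjusted p < 0.05 is called significant.

Signature scores are per-cell signed z-score averages: genes are z-scored
across the compared cells, summed with +1/−1 signs for the
positive/negative set, and divided by the number of signature genes
present in the matrix (absent genes are dropped and counted; SD-0 genes
contribute 0). This is a deliberate simplification of latent-space
signature autocorrelation frameworks: for two-group comparisons of score
distributions, the signed z-average carries the relevant information.
Group comparison is again a two-sided rank-sum test.

## Synthetic data: what it emulates

The generator emulates the study design end-to-end with known ground
truth:

* **Repertoire** — lognormal clone frequencies (default; Dirichlet
  available), n_clones = 30,000, σ = 1.0. These defaults were set so that
  a 5,000-cell draw of an unstimulated fraction lands at H ≈ 8.2–8.3,
  inside the observed per-sample range for non-proliferating sorted RM
  T cells (7.94–9.09), which also implies the observed near-singleton
  structure (most sampled clonotypes seen once). Each clone gets unique
  alpha and beta CDR3 junctions (stop-free, C…F frame); uniqueness is
  enforced by construction because the exact-recovery tests require it —
  no biological junction model (no TdT) is attempted.
* **MLR fractions** — alloreactive clones (a random 1% of clones by
  default) have their frequencies multiplied by a per-fraction expansion
  factor (CTV-Low 50 ≫ CTV-Mid 5 > CTV-High 1), renormalized, and cells
  drawn multinomially, 5,000 per fraction. This keeps shared clones
  between blood and all fractions. It also means CTV-Low retains
  non-proliferated background mass — a known divergence from a physical
  CTV sort, discussed above.
* **Contig tables** — per cell, the alpha contig is emitted with
  probability 0.60 and beta with 0.90, independently (within the observed
  per-chain reconstruction ranges of 50–67% and 83–94%); a configurable
  fraction of contigs is marked non-productive/non-full-length. Dropout
  correlation between chains is deferred.
* **Expression** — counts are NB(μ_g · s_c, θ = 10) with lognormal gene
  means around 15 (≈ 3,000 counts/cell at the default 200-gene panel) and
  mild cell size factors; planted genes (a *GZMB*-like cytotoxic marker by
  default) have their means multiplied by 2.5 in MLR+ cells;
  mitochondrial genes run at half mean (baseline mito fraction ≈ 1–2%);
  optional outlier cells (100 total counts, 20% mitochondrial) exercise
  the QC filters. No transcriptome-wide co-expression structure is
  simulated, so passing DE tests demonstrate calibration and power under
  independence, not robustness to correlated backgrounds.

All outputs are deterministic given the config seed (one seeded
generator per stream, stable across platforms), and a run manifest records
the config and file checksums.

## Validation scales and known limitations

The test suite and the acceptance script run at desk scale: 20-seed
panels at 5,000 cells/fraction for diversity ordering and significance,
two simulated donors for overlap specificity, 500-vs-500 cells for DE
power, 20 null runs for type-I control, and a 1,000-cell fixture with 100
planted single-violation outliers for QC. These sizes were chosen as the
smallest at which the statistical claims are stable.

One statistical margin is worth stating plainly: with a ×5 Mid expansion
moving only ~4% of repertoire mass, the population Shannon gap between
CTV-Mid and CTV-High (~0.04 nats) is comparable to the sampling noise of
the estimator at 5,000 cells, so the strict three-way per-seed ordering
Low < Mid < High holds in roughly 85% of seeds rather than always; the
Low-vs-High ordering and its Hutcheson significance are robust (20/20 in
the panels run here). Conclusions about weakly expanded fractions should
rest on the test statistic, not on point-estimate ordering.

Other limitations: no rarefaction or Hill-number diversity; no
CDR3 amino-acid motif clustering or germline allele correction; no
doublet deconvolution beyond highest-UMI selection; human→macaque
ortholog mapping for signature gene sets is the caller's responsibility
(signatures are matched to the matrix namespace as given); and bulk
TCR-seq inputs are not supported.
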