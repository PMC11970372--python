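# Methods

This note documents the models and procedures implemented in `haplotax`,
the defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical conventions.

## Coordinates and rounding

All in-memory coordinates are 0-based half-open (BED/PAF convention);
human-readable reports are 1-based inclusive, converted only by
`io_formats.to_report_coords` / `from_report_coords`. Reported percentages
and ratios are rounded half-away-from-zero at the printed precision
(`_util.round_half_up`); full precision is kept internally.

## Assembly accounting

- **Gaps.** A gap is a maximal run of N of length ≥ `min_n_run`. There is
  no universal definition of an assembly gap; the default of 10 avoids
  counting isolated ambiguous bases while catching any deliberate
  gap-filling placeholder. Correctness is checked against a per-base
  brute-force scanner on random strings.
- **Telomeres.** An end is telomeric when the motif TTTAGGG *or* its
  reverse complement occurs ≥ `min_copies` (default 10) times,
  non-overlapping, in the terminal `terminal_window` (default 10 kb).
  TTTAGGG is the canonical plant telomere repeat; counting both strands
  makes the scan orientation-agnostic. The detection parameters are
  package decisions — real telomere annotation pipelines vary, and these
  defaults favour specificity (10 tandem copies almost never occur by
  chance) over sensitivity to degenerate arrays.
- **T2T status** = both telomeres present ∧ zero gaps.
- **NX curve** uses the "first cumulative sum ≥ X% of total" convention of
  common assembly-stats tools; it is permutation-invariant and
  non-increasing in X.
- **QV.** `errors/Mbp = 10^(−QV/10) × 1e6`. QV estimation itself (k-mer
  based) is out of scope; QV is an input.

## Collapse calling

Input is a pre-windowed depth track (BED4). Read mapping and per-base depth
are out of scope: the statistic of interest is window-level, and windowing
is what any mapper + `samtools`/`mosdepth` step produces.

- **Baseline** is the histogram mode of window depths (Freedman–Diaconis
  bins, midpoint of the tallest bin). The mode, unlike the mean, is robust
  to the high-depth tail that collapsed regions create.
- **Threshold** is 1.75 × baseline, inclusive. A fully collapsed two-copy
  region maps at ~2× the baseline; 1.75 sits 2.5 standard deviations below
  2× at 10% depth noise while staying far above the haploid band. At 10%
  noise this still misses a 2-copy window with probability
  Φ((1.75 − 2)/(√2 · 0.1)) ≈ 4%, which bounds the achievable window-level
  sensitivity near 0.96; the acceptance battery therefore measures pooled
  sensitivity/precision over 100 replicate worlds rather than per-replicate.
- **Copy number** `round(depth/baseline)` clamped to ≥ 2 (below 1.5× cannot
  be flagged given the threshold). Adjacent flagged windows merge; the
  merged call's copy number uses the size-weighted mean depth.
- **Corrected length** = assembled + Σ window × (copies − 1). The
  percentage difference of a homologous pair is computed against each
  haplotype's own corrected length (the two percentages differ when the
  corrected lengths do).
- **Sex ranking.** Pairs carrying interchromosomal translocations (from the
  SV stage) are excluded — their length difference reflects the
  rearrangement. Remaining pairs sort by descending percentage difference,
  ties broken by chromosome id. In a female sample of a ZW system the
  longer haplotype of the top pair is labelled W, the shorter Z. This is a
  ranking heuristic, not a test: it nominates a candidate pair, and
  corroboration (e.g. sex-biased expression in the nonhomologous region)
  is expected.

## SV classification

The classifier consumes alignment blocks; whole-genome alignment itself
(minimap2-class) is out of scope. The syntenic backbone is the
length-weighted longest increasing subsequence (in both coordinates) of
+ strand blocks per chromosome pair; each query chromosome's partner is the
target chromosome with the highest chained coverage. Classification rules
are in the README; numerical choices:

- `min_sv_len` = 50 bp, **inclusive** (the usual ">50 bp" phrasing is
  implemented as ≥ 50).
- DUP requires the off-backbone block's target interval to overlap
  backbone-covered target by ≥ 50% (tunable `dup_overlap`); no published
  criterion exists, and 50% separates re-covering blocks from blocks
  aligning into genuinely novel target sequence.
- Overlap resolution: candidates sort by precedence INV > TRANS > DUP >
  INS/DEL, then longest first; a candidate is dropped when ≥ 50% of its
  length is covered by an already-kept call on either coordinate system.
  This deterministically suppresses the INS/DEL shadows that every
  translocation and duplication casts on the backbone gaps.
- The novel W-specific segment of the sex pair appears as an INS call at
  the head of the W chromosome — that is correct behaviour, and recovery
  metrics treat it as expected rather than a false positive.

Interval unions use a sorted sweep, verified against a per-base bitmap
oracle.

## Synthetic worlds

The generator's default world is a scaled-down phased conifer assembly:
4 chromosome pairs × 2 Mb (real chromosomes are ~420 Mb), depth windows of
10 kb (scaled from the 100 kb used at full size), mean HiFi depth 30×
(scaled from ~72×), telomere arrays of 100 × TTTAGGG, a handful of planted
N-gaps (chr2 left gapless as the planted T2T case), 3 inversions +
2 duplications + 1 chr1→chr3 translocation, three collapsed intervals
(visible only in the depth track — the FASTA holds one copy, which is what
"collapse" means), and a sex pair (chr4) whose haplotype 2 is 1.7% longer
via a novel segment just inside the left telomere — the magnitude observed
on a real candidate ZW pair. The expression panel is 500 genes × 40
samples with a planted module of 16 known-pathway + 70 family genes
(one-factor model `x_g = a·f + ε`, loading set so the within-module
correlation is `module_corr` = 0.8, noise SD 1) among 158 family genes
total; 7 sex-biased genes (5 female-, 2 male-biased) are planted in the
nonhomologous W region alongside 50 unbiased genes.

What the generator does **not** emulate: read-level sequencing error,
repeat-induced mis-alignment (alignment blocks are a deterministic
projection of the planted truth), Hi-C scaffolding, nested/overlapping SVs
(the generator refuses ambiguous truth), gene-length or GC biases in
expression, and replicate structure in the tissue × sex panel. A green
recovery test therefore establishes that each procedure inverts its own
generative model at realistic noise levels — not that it is robust to real
aligner artefacts.

Determinism: every generator takes a seed and is bit-reproducible;
`pipeline.run_all` derives stage seeds as fixed offsets of the master seed,
so the whole report is byte-identical for a fixed seed.

## Coexpression mining

Pearson on log2(TPM+1) is the default correlation (standard for TPM
panels); Spearman is available. Constant genes get r = 0 against all
others. Clustering is average-linkage agglomerative on distance 1 − r, cut
into k clusters; k defaults to the silhouette-optimal cut in [2, 20]. The
candidate module is the cluster with the most known pathway genes, ties
broken by the higher mean family–known correlation. Both the clustering
algorithm and k are package decisions (the source procedure states only
"clustering"); everything is deterministic and row-order invariant (genes
are sorted internally).

At 40 samples, a background gene's chance correlation with the module's
latent factor has SD ≈ 0.16, so a tail of background family genes always
attaches to the module cluster under average linkage: single-panel
candidate precision fluctuates roughly between 0.81 and 1.0 around a mean
of ~0.91, with recall 1.0. The acceptance battery asserts the 20-seed mean;
`run_all`'s per-run module check keeps the 0.9 threshold and can
legitimately fail on some seeds by this sampling noise alone.

The 11-gene shortlist formalises a qualitative expert judgement (span
evolutionary clades and chromosomal locations): clades are visited by
descending size and each round picks the member maximising the minimum
genomic distance to genes already picked (different chromosomes count as
infinitely far; ties by gene id). It is a reproducible stand-in for a
judgement call, not a published rule.

## Sex-biased expression

Thresholds `tau_on` = 1 TPM / `tau_off` = 0.1 TPM define "expressed" vs
"not expressed" in a single-tissue contrast (default flower). With no
replicates there is no test statistic; the filter is exact on noise-free
planted truth and should be read as a screen, not an inference.

## Docking-pose filter

Distance ≤ 5 Å (inclusive, "within") from the substrate's reactive atom to
the FeO centre plus a strictly negative docking score. Which atom is the
reactive site (e.g. C11 vs a centroid) is ambiguous in practice and is
therefore the caller's input, not a package decision.

## Known limitations

- The SV classifier is matched to the generator's SV taxonomy; it does not
  handle nested events, breakpoint uncertainty, or alignment noise.
- Collapse copy-number estimates are point estimates from window means; no
  CNV genotype likelihoods.
- `choose_k` is O(k · n²) on the correlation matrix; fine for
  hundreds of labelled genes, not for whole-transcriptome matrices.
- The pipeline's per-run module-recovery check is seed-sensitive (see
  above); batteries of seeds are the meaningful quantity.
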