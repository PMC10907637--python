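# Methods

## Clonotype definition and input handling

The unit of analysis is the CDR3β amino-acid clonotype: all rearrangements
sharing one productive CDR3β amino-acid sequence are aggregated into a
single clone, summing their template counts. V/J gene labels are parsed and
carried as metadata but never enter clonal identity, and there is no
nucleotide-level clonotyping or sequencing-error collapsing.

A rearrangement row is *productive* when its frame column flags it in-frame
(immunoSEQ `frame_type == In`, AIRR `productive == T`); when the file has no
frame column the filter falls back to "CDR3 amino-acid sequence non-empty
and free of the stop character `*`". Sequences are uppercased on read, and
productive rows containing residues outside the 20-letter alphabet are
dropped with a logged count. Counts are template counts; when a file offers
only a read-count column it is used with a logged warning, and a row with a
missing count value stands for one observed molecule (count 1). Rows with an
explicit count of zero are ignored: the repertoire records observed
molecules only.

## Diversity statistics

All logarithms are base 2. With `p_i = templates_i / N` over `n` unique
clonotypes:

- Shannon entropy `H = −Σ p_i log2 p_i` (bits);
- clonality `1 − H / log2 n`, clipped to [0, 1] against ~1e-16 floating
  excursions. Clonality is dimensionless (a normalized-entropy ratio) even
  though the underlying entropy is in bits. For `n = 1` the formula divides
  by `log2 1 = 0`; we define clonality of a single-clone repertoire as 1,
  the monoclonal extreme.
- Simpson's index `D = Σ p_i²`.

Weighting is by template count throughout — `p_i` is the fraction of
*templates*, not of unique rearrangements. This is the convention for
template-resolved assays; an unweighted variant would discard the abundance
information MOI depends on.

Statistics are computed on full repertoires by default. Down-sampling is a
display/comparability device and is applied only where requested
(clone-size spectra by default at k = 20,000).

## Clonotype down-sampling

`downsample_clonotypes(r, k)` samples exactly `k` clonotypes uniformly
without replacement and keeps their original template counts (frequencies
renormalize implicitly); repertoires at or below `k` pass through
unchanged. Sampling clonotypes — not templates — is what fixes the *unique
clonotype count*, and unweighted selection preserves the clone-size
distribution shape in expectation. The draw is reproducible from a seed.

## Clone-size spectrum

Clonotypes are ranked by descending template count with lexicographic
tie-breaks, and binned into size classes defined by strictly increasing
edges; the top class is open-ended (default edges (1, 10, 100) give classes
1–9, 10–99, ≥100). The power-law shape is generated and displayed, never
fitted — no abundance-model estimation is attempted.

## Morisita's overlap index

For repertoires X and Y with counts `x_i`, `y_i` over the union of their
clonotype keys:

    MOI = 2 Σ x_i y_i / ((D_X + D_Y) N_X N_Y)

with `D` each sample's Simpson index and `N` its **total template count**
(the standard Morisita–Horn convention). The alternative reading of N as
the number of unique clonotypes fails the boundary requirement that two
identical repertoires score 1, so it is not used. The denominator is
evaluated as `Σx²·(N_Y/N_X) + Σy²·(N_X/N_Y)`, which is algebraically equal
and makes the identical-repertoire case return exactly 1.0 in floating
point. MOI is symmetric, bounded in [0, 1] (Cauchy–Schwarz), and invariant
to uniform scaling of all counts in one repertoire. Overlap is computed on
full repertoires by default (no down-sampling), configurable.

## Paired and cohort comparisons

- **Paired clonality (tumor vs NTL).** Per subject, the difference
  NTL-clonality − tumor-clonality enters a two-sided paired t-test; the
  report also counts subjects with NTL above tumor. An all-equal difference
  vector has an undefined t statistic and is returned as a flagged
  *degenerate* result (statistic 0 and p 1 when all differences are zero,
  NaN otherwise) rather than ±∞.
- **Within-cohort sharing.** Pairwise MOI is computed within the tumor
  group and within the NTL group. Pairing pairwise quantities for a paired
  test is genuinely ambiguous; we reduce each subject to the mean MOI of
  its sample against all *other* subjects' samples in the same tissue,
  giving one number per subject per tissue, and run a paired two-sided
  t-test on those. This is one defensible choice, stated rather than
  hidden.
- **Cross-cohort comparison.** One-way ANOVA across cohorts, on per-sample
  clonality for the clonality contrast and on within-cohort pairwise MOI
  values for the overlap contrast (per-pair values are the default unit;
  per-cohort means can be passed instead). Cohort means are reported ranked.
- **Clonality–density regression.** Ordinary least squares of cell density
  (cells/mm²) on clonality: slope, intercept, Pearson r and the two-sided
  slope p-value. Constant clonality is an error (undefined slope).

t-tests and ANOVA assume approximate normality; nonparametric alternatives
are out of scope. All p-values are raw two-sided values — no
multiple-testing adjustment is applied, and reports label them as such.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis is built to
detect, with paired tumor/NTL samples per subject:

- **Clone sizes.** `zipf_counts(u, t, α)` gives every clonotype one
  guaranteed template and allocates the residual `t − u` multinomially with
  rank-r probability ∝ r^(−α). α = 0 yields near-uniform counts (clonality
  < 0.01 at u ≥ 1000); larger α yields heavier tails and higher clonality.
- **Sharing.** One *public pool* of P CDR3β sequences is drawn once per
  cohort; each sample takes round(f·U) of its U clonotypes uniformly from
  the pool, with a tissue-specific fraction f. Template counts for public
  clonotypes are drawn independently per sample: sharing is of identity,
  not abundance. Tumor and NTL of one subject additionally share a small
  within-subject pool (fraction 0.05 of U) so paired samples are not
  artificially disjoint. All remaining clonotypes are private sequences
  guaranteed unique across the cohort, so f = 0 gives exactly zero
  cross-individual overlap.
- **Sequences.** CDR3β-like strings start with C, end with F, with a
  uniform interior over the 20-letter alphabet and lengths uniform on 9–18.

Defaults: 6 subjects, U = 20,000 unique clonotypes and T = 200,000
templates per sample (≈10 templates per clonotype, inside the realistic
5,000–150,000 productive-rearrangement range for solid-tissue samples),
tumor α = 1.0 / NTL α = 1.5 (NTL more expanded), tumor f = 0.30 / NTL
f = 0.02 (tumors far more conserved across individuals), pool P = 30,000.
The sharing fractions are chosen for qualitative pattern reproduction —
tumor repertoires score lower clonality and higher cross-individual MOI
than NTL, with a sign stable across seeds — not as estimates of any real
tissue's public-clonotype rate. The generator is a modeling device: it has
no V(D)J recombination model, no generation-probability realism, no
sequencing error, and clone sizes are exactly Zipf-shaped rather than fit
to data. Passing tests therefore demonstrate correctness of the *analysis
machinery* and recoverability of the generator's parameters, not claims
about real repertoires.

## Numerical and design notes

- Reductions use float64 throughout; formula implementations agree with
  independent brute-force loop evaluations to 1e-12 on repertoires up to
  n = 50.
- Ranking ties (equal template counts) break lexicographically by sequence,
  making tables and spectra byte-reproducible.
- Down-sampling, the generator, and the pipeline derive all randomness from
  `numpy.random.default_rng(seed)`; identical seeds give byte-identical
  outputs.
- A documented subtlety of entropy-normalized clonality: shifting one
  template from the smallest to the largest clone always increases (or
  preserves) clonality and Simpson while the clone count n is unchanged,
  but *eliminating* the smallest clone shrinks the log2 n normalizer and
  can lower clonality. The property tests assert the n-preserving version.
- Test-suite and script problem sizes (e.g. 1,000-repertoire oracle sweeps,
  20-seed parameter-recovery scans at a few hundred clonotypes per sample)
  are chosen to keep the full verification cycle to a couple of minutes on
  a single core while leaving every statistical sign test comfortably
  powered.

## Known limitations

- CDR3β amino-acid identity only; no nucleotide clonotypes, V/J allele
  resolution, or error correction.
- No Hill-number diversity family, rarefaction curves, or abundance-model
  fitting; no Jaccard/Sørensen overlap variants; no permutation-based
  significance for overlap.
- The paired-t pairing scheme for pairwise MOI values is one defensible
  reduction among several.
- No plotting beyond the exported TSV tables.
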