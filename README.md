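# tcrep

Diversity and overlap analysis for T-cell receptor β-chain (TCR-β)
repertoires, built around CDR3β amino-acid clonotypes.

High-throughput TCR-β sequencing of paired tumor and adjacent normal tissue
asks two questions of each sample set: *how clonally expanded* is each
repertoire, and *how much of it is shared* between individuals? `tcrep`
implements the standard answers for immunoSEQ-style rearrangement exports —
entropy-based clonality, Simpson's index, clone-size spectra with fixed-size
clonotype down-sampling, and pairwise Morisita overlap — together with a
synthetic paired-cohort generator so the whole pipeline can be exercised and
verified end to end without access to patient data. It is aimed at tumor
immunologists comparing tumor-infiltrating lymphocyte repertoires against
matched control tissue or between cancer cohorts.

## The statistics

A *clonotype* is one productive (in-frame, stop-free) CDR3β amino-acid
sequence; its abundance is its template count. With clonotype probabilities
p<sub>i</sub> = templates<sub>i</sub>/N over n unique clonotypes:

- **Shannon entropy** (bits): H = −Σ p<sub>i</sub> log₂ p<sub>i</sub>
- **Clonality**: 1 + (Σ p<sub>i</sub> log₂ p<sub>i</sub>)/log₂ n = 1 − H/log₂ n,
  ranging from 0 (perfectly even, maximally diverse) to 1 (monoclonal).
  A single-clone repertoire is defined as clonality 1.
- **Simpson's index**: D = Σ p<sub>i</sub>² — the probability two randomly
  drawn templates are the same clonotype.
- **Morisita's overlap index** between repertoires X and Y, over the union
  of their clonotype keys with absent counts 0:

  MOI = 2 Σ x<sub>i</sub> y<sub>i</sub> / ((D_X + D_Y) N_X N_Y)

  where N is each sample's total template count. MOI is 0 when no sequence
  is shared and 1 when both samples have identical composition.

## Worked example

Generate a small synthetic cohort of 3 subjects (paired tumor + adjacent
non-tumor liver, "NTL", per subject), then summarize and compare:

```bash
tcrep simulate --out demo/cohort --subjects 3 --unique 2000 --templates 20000 --seed 7
tcrep summarize demo/cohort/*.tsv
```

```
sample_id   n_unique  total_templates  shannon_entropy_bits  clonality       simpson
S01-ntl     2000      20000            5.29241481091         0.517370151234  0.145960975
S01-tumor   2000      20000            8.46962023391         0.227632058589  0.02024216
S02-ntl     2000      20000            5.32003294146         0.514851578021  0.14636093
S02-tumor   2000      20000            8.50745363466         0.224181926818  0.019826985
S03-ntl     2000      20000            5.27240175373         0.519195196908  0.148958005
S03-tumor   2000      20000            8.51290044927         0.223685216827  0.0199376
```

Every sample holds 2,000 clonotypes over 20,000 templates. The generator's
default clone-size skew is stronger in NTL (Zipf exponent 1.5) than in tumor
(1.0), so NTL repertoires are more expanded: clonality ≈ 0.52 vs ≈ 0.22,
Simpson ≈ 0.15 vs ≈ 0.02. Pairwise sharing:

```bash
tcrep overlap demo/cohort/*tumor*.tsv demo/cohort/*ntl*.tsv --long
```

```
sample_a    sample_b    moi
S01-tumor   S02-tumor   0.000185179893407
S01-tumor   S03-tumor   2.05327259297e-05
...
S01-ntl     S02-ntl     0
S02-ntl     S03-ntl     0
```

Cross-individual MOI is small but consistently positive among tumors (30%
of each tumor's clonotypes come from a shared public pool) and essentially
zero among NTL samples (2% public) — the conserved-repertoire signature the
pipeline is designed to detect. `tcrep pipeline --simulate --out report`
runs the whole analysis (summaries, overlap matrices, paired tumor-vs-NTL
clonality t-test, within-cohort MOI comparison, clone-size spectra) and
writes a report bundle; `tcrep pipeline --config manifest.yaml` does the
same for real rearrangement TSVs listed in a manifest.

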