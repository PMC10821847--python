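# neoprior

Expression-aware identification and prioritization of tumor neoantigens
from somatic missense mutations, with downstream immunogenicity
selection and single-cell read-outs of vaccine-target expression.

## Who this is for

Groups building personalized cancer-vaccine candidate lists from
matched tumor/normal sequencing: the package takes a somatic missense
variant table with RNA evidence, a protein FASTA and a gene-expression
table, and produces a ranked short-list of candidate neoantigen
mutations, the peptides to synthesize, and — once ELISPOT and
single-cell data exist — the immunogenicity selection and per-cell
mutant-allele quantification. Everything is also runnable end-to-end on
a built-in synthetic study with planted ground truth, so every stage is
testable without any sequencing data.

## The method

1. **Expression filter.** A variant is retained when
   VAF ≥ 10%, depth ≥ 20 and TPM(gene) ≥ 1 (all inclusive). Absence of
   the gene from the expression table counts as failing the TPM rule.
2. **Peptide design.** Per mutation: a 17-aa mutation-centered long
   peptide (flank (17−1)/2 = 8 on each side, truncated asymmetrically
   at protein termini) plus every 8–9-mer window of the mutant protein
   covering the mutated residue (H-2Kb presents 8–9-mers; lengths are
   configurable in [8, 11]). Positions are 1-based, intervals closed —
   e.g. the validated Mapkbp1_W204C epitope RHIKFCYL spans 199–206 with
   the mutant residue at offset 6.
3. **Binding consensus.** Each short peptide is scored by an ensemble
   of predictors reporting percentile ranks in [0, 100] (lower =
   stronger). The consensus statistic per peptide is the **median rank
   across predictors**; per mutation, the minimum median over its
   windows (best-epitope convention). A mutation passes at median rank
   ≤ 2%. Real predictor output enters as a (peptide, predictor, rank)
   TSV; for self-contained runs eight mock PSSM predictors calibrate
   raw scores against a proteome background:
   `rank = 100 · #{background ≥ score} / B`.
4. **Prioritization.** Passing mutations sorted by ascending best
   median rank (ties: descending TPM, then VAF), top 20 kept for
   synthesis.
5. **ELISPOT selection.** A peptide is immunogenic when its mean
   IFN-γ spot count across replicates is **strictly greater than 100**;
   cross-reactivity versus the wild-type peptide combines an absolute
   guard (wild-type arm above the selection threshold) with a Welch
   t-test and a negative-control guard (mean + 3·SD).
6. **Single-cell read-outs.** A binned-control signature score for the
   parent genes of the vaccine mutations (signature mean minus
   expression-matched control mean per cell; Wilcoxon rank-sum between
   treatment groups), and the per-group proportion of covered tumor
   cells with ≥ 1 mutant-supporting read at any queried site (Fisher's
   exact test vs the reference group).

## Worked example

```python
from neoprior import SimConfig, simulate_study, run_all

bundle = simulate_study(SimConfig(seed=1), "study")       # synthetic inputs
manifest = run_all(bundle.run_config, "study/out")        # all stages
print(manifest.funnel)
```

prints

```
{'input_variants': 762, 'expressed': 224, 'consensus_pass': 60,
 'top': 20, 'synthesized': 16, 'selected': 7}
```

i.e. of 762 simulated somatic mutations, 224 survive the expression
filter, 60 produce a short peptide with consensus median rank ≤ 2%, the
top 20 are carried to synthesis, 16 synthesized peptides enter the
ELISPOT screen and 7 clear the 100-spot selection — each stage exactly
recovering the generator's planted truth (recorded in
`study/truth.json`). `study/out/` holds the per-stage TSV/JSON outputs
and a `manifest.json` with input checksums and the funnel; re-running
with the same seed reproduces byte-identical files.

The same run from the shell:

```sh
neoprior simulate --outdir study --seed 1
neoprior run --config study/run_config.yaml --outdir study/out
```

Individual stages (`neoprior filter`, `peptides`, `mock-rank`,
`consensus`, `elispot`, `sc-score`, `sc-mutprop`) operate on the
documented file formats, so any stage can be swapped for real tool
output — e.g. genuine NetMHCpan ranks in place of the mock ensemble.

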