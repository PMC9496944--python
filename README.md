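# ptmb — pathway-derived tumor mutation burden

Tumor mutation burden (TMB, nonsynonymous somatic mutations per megabase of
coding sequence) is a widely used biomarker for response to immune
checkpoint blockade (ICB), but in several melanoma and NSCLC cohorts it
separates responders from non-responders poorly: per-patient burdens span
orders of magnitude and most of that variation is unrelated to response.
`ptmb` implements a pathway-restricted alternative.  From per-sample
somatic mutation tables it

1. builds a per-cohort mutation-frequency matrix *M* (samples × mutated
   genes, per-Mb gene burden by default),
2. scores every pathway in every sample with a GSVA-style weighted
   Kolmogorov–Smirnov random walk over the within-sample gene ranking,
3. compares the enrichment scores of responders (R) and non-responders
   (NR) per cohort with a Mann–Whitney U test, and labels pathways
   consistently R-enriched across cohorts as *positive pathways* (PP) and
   consistently NR-enriched ones as *negative pathways* (NP),
4. contrasts the burden inside the two gene unions:

   P-TMB = ( Σ<sub>g∈PP</sub> P<sub>g</sub> / Σ<sub>g∈PP</sub> L<sub>g</sub> −
   Σ<sub>g∈NP</sub> N<sub>g</sub> / Σ<sub>g∈NP</sub> L<sub>g</sub> ) × 10⁶

   where P<sub>g</sub>/N<sub>g</sub> are a sample's nonsynonymous mutation
   counts in gene *g* and L<sub>g</sub> its coding length in bp, and
5. evaluates the score against response by ROC/AUC, picks a Youden-index
   cutoff per cohort, and averages the cutoffs into one global threshold
   (classification rule: score > threshold ⇒ predicted responder).

The package also covers the companion single-gene analyses: Fisher-exact +
fold-change response-gene selection, recurrent-mutation R/NR exclusivity,
"A|B" gene-pair survival features with log-rank tests, and multivariate Cox
fits.  Because the original patient-level WES cohorts are controlled-access,
a fully parameterized synthetic multi-cohort generator with planted pathway
effects and planted survival effects makes every stage testable and
reproducible offline.

## Worked example

Run the whole workflow on the default synthetic study (6 cohorts × 60
samples, 2000 genes, 60 pathways of which 10 carry a 3× mutation-rate
effect in responders):

```python
from ptmb import SimulationConfig, PipelineConfig, run_full_pipeline

cfg = PipelineConfig(outdir="demo", simulate=SimulationConfig(seed=42), seed=42)
result = run_full_pipeline(cfg)
print(open(result.report_path).read())
```

which prints (abridged):

```
positive pathways (PP): PW01, PW02, PW03, PW04, PW05, PW06, PW07, PW08, PW09, PW10
negative pathways (NP): -
PP genes: 250  NP genes: 0
global P-TMB threshold: 21.4658
cohort1: AUC(P-TMB)=0.7911 AUC(TMB)=0.5644 cutoff=25.3049 tp=21 fp=6 tn=24 fn=9
cohort2: AUC(P-TMB)=0.7639 AUC(TMB)=0.4967 cutoff=27.9334 tp=18 fp=9 tn=21 fn=12
cohort3: AUC(P-TMB)=0.8372 AUC(TMB)=0.5933 cutoff=20.9041 tp=23 fp=6 tn=24 fn=7
...
```

All ten planted pathways are recovered as PP with no false positives; the
per-cohort AUCs are *held-out* (with the default `leave_one_out=True`,
pathways scored on a cohort are selected from the other cohorts only).
P-TMB separates responders (AUC ≈ 0.68–0.87 here) while whole-exome TMB
stays near chance — the pathway-restricted burden isolates the
response-relevant signal that global TMB dilutes.  The global threshold is
the average of the six Youden cutoffs; `tp/fp/tn/fn` are the confusion
counts at that shared threshold.

The same workflow is available from the shell:

```sh
ptmb simulate --seed 42 -o fixtures/
ptmb pathways --cohort c1=fixtures/cohort1_mutations.tsv:fixtures/cohort1_clinical.tsv \
    ... --lengths fixtures/lengths.tsv --gmt fixtures/pathways.gmt -o out/
ptmb burden --mutations fixtures/cohort1_mutations.tsv --clinical fixtures/cohort1_clinical.tsv \
    --lengths fixtures/lengths.tsv --pp out/pp_genes.txt --np out/np_genes.txt \
    --allow-empty-np -o out/burden1.tsv
ptmb evaluate --scores out/burden1.tsv --clinical fixtures/cohort1_clinical.tsv -o out/eval1/
ptmb run --config pipeline.yaml     # everything in one step
```

## Layout

- `src/ptmb/io_formats.py` — MAF-like mutation TSV, clinical TSV,
  gene-length TSV, GMT readers/writers and the core containers
- `src/ptmb/burden.py` — nonsynonymous classification, TMB, P-TMB
- `src/ptmb/association.py` — response genes, exclusivity, gene pairs,
  log-rank, Cox
- `src/ptmb/pathway_scoring.py` — frequency matrix, GSVA-style enrichment,
  Mann–Whitney tests, PP/NP selection
- `src/ptmb/evaluation.py` — ROC/AUC, Youden cutpoints, global threshold
- `src/ptmb/synthetic_data.py` — the multi-cohort generator
- `src/ptmb/pipeline.py`, `src/ptmb/cli.py` — orchestration and the `ptmb`
  command

See `docs/methods.md` for the model, parameter choices, and limitations.
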