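# prognet

Causal-network discovery of "master" prognosis-impacting genes in tumor
expression data, and derivation/validation of expression subtypes.

The pipeline chains:

1. **screen** — per-gene univariate Cox proportional-hazards screening
   (Efron tie handling, Wald p), favourable/unfavourable calls, zero-heavy
   gene filtering; network genes selected at p < 0.01 and |coef| > 0.2.
2. **network** — biweight midcorrelation matrix → stable-PC CPDAG estimation
   (Fisher-z partial-correlation tests, v-structures, Meek rules R1–R4) →
   summarized degree (out − in) → master-gene selection at |degree| > threshold.
3. **subtype** — per-gene z-scaling, consensus clustering (subsampled PAM on
   1 − Pearson sample distance, k = 2), C1 = worse-prognosis cluster,
   Kaplan-Meier/log-rank comparison, and a random-gene-set null distribution
   of the log-rank statistic.
4. **characterize** — random-forest (OOB permutation) gene importance,
   hypergeometric pathway enrichment of the top-50 genes (GMT input),
   mutated-vs-wild differential expression per SMG (t or Wilcoxon, BH FDR),
   Fisher-exact SMG×cluster enrichment.
5. **predict** — elastic-net logistic subtype predictor on the top-10
   important genes, leave-one-out accuracy, transfer to an external cohort
   with survival validation.

A first-class **synthetic-data module** plants a known causal DAG (hub
"masters" with orientable out-edges), latent subtypes with survival effects,
and subtype-enriched mutations, so every stage is verifiable against ground
truth without any external download.

## CLI

```sh
prognet demo --out-dir demo_run --seed 0 [--quick]   # end-to-end synthetic demo + self-checks
prognet simulate --out-dir data --seed 1             # synthetic dataset with ground truth
prognet screen --expr E.tsv --clin C.tsv --out R.tsv [--standardize]
prognet network --expr E.tsv --genes network_genes.txt --alpha 0.01 --hub-threshold 5 --out-dir out
prognet subtype --expr E.tsv --genes masters.txt --clin C.tsv --null-reps 100 --seed 1 --out-dir out
prognet characterize --expr E.tsv --genes masters.txt --labels labels.tsv \
    [--mutations M.tsv] [--pathways sets.gmt] --out-dir out
prognet predict --model predictor.json --expr EXT.tsv [--clin EXT_clin.tsv] --out pred.tsv
prognet run --config pipeline.json [--seed 7]        # full pipeline from a JSON config
```

Formats are plain TSV (expression: `gene` column + sample columns; clinical:
`sample`, `time`, `event`), GMT for gene sets, JSON for configs/manifests/
models. Pipeline outputs are stamped with the config hash and summarized in
`manifest.json`.

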