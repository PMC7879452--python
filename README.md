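# lncrecur

Recurrence-based discovery of tumor-specific long non-coding RNAs
(lncRNAs) from matched tumor–normal RNA-seq cohorts, with cis/trans
target-gene prediction.

## The problem

Cohort studies of aggressive tumors (the motivating design is a
triple-negative breast cancer cohort with ~19 patient-matched
tumor–normal pairs) look for lncRNAs that are *recurrently* and
*direction-consistently* dysregulated across patients. Each patient
contributes one tumor and one normal library — no replicates — so the
per-patient comparison needs a variance model borrowed from the data
itself. `lncrecur` implements that screen end to end:

1. **Identification** — transcripts longer than 200 nt, expressed in at
   least one sample, either matching a known-lncRNA catalog or called
   non-coding by a consensus of three external coding-potential callers.
2. **Per-pair differential expression** — a local pooled error (LPE)
   test on log2(CPM+1): transcripts are binned by average abundance,
   the scale of the tumor−normal difference is estimated per bin by the
   MAD, and each transcript is scored as
   `z = (d − median_bin) / σ̂_bin`, with Benjamini–Hochberg correction
   within each pair. DE calls require `q < 0.05` and `|log2FC| > 1`
   (strict).
3. **Recurrence prioritization** — *occurrence* = number of pairs in
   which a lncRNA is DE; candidates need occurrence > 10 and a single
   direction across all DE pairs, and are ranked by a rank-sum of
   occurrence and |median log2FC|.
4. **Target prediction** — *cis*: protein-coding genes within 100 kb of
   the lncRNA locus (strand-agnostic, boundary inclusive); *trans*:
   genes with |Pearson r| > 0.95 across all samples; plus hypergeometric
   over-representation of predicted targets against user gene sets.

A negative-binomial cohort simulator with planted ground truth (DE
lncRNAs, direction consistency, cis neighbors and decoys, correlated
trans targets) backs the test suite and lets the operating
characteristics of the screen be measured exactly.

## Worked example

```python
from lncrecur import RecurrenceModel, SimulationConfig, simulate_cohort

cohort, truth = simulate_cohort(SimulationConfig(seed=7, log2fc_mean=4.0))
results = RecurrenceModel(cohort).fit()
print(results.summary())
```

```
Recurrence screen for tumor-specific lncRNAs
============================================
Matched pairs:                19
Samples:                      38
Transcripts in cohort:        810
lncRNAs prioritized:          310
Per-pair DE calls (q<0.05, |log2FC|>1): 819
Recurrent (occurrence > 10):  7
  consistent up:              1
  consistent down:            4
  inconsistent:               2
Top candidates:
   1. LNC_0031  occurrence=14  median_log2FC=-6.73  (consistent_down)
   2. LNC_0073  occurrence=11  median_log2FC=-5.53  (consistent_down)
   3. LNC_0119  occurrence=12  median_log2FC=-5.21  (consistent_down)
   4. LNC_0163  occurrence=11  median_log2FC=-5.37  (consistent_down)
   5. LNC_0065  occurrence=11  median_log2FC=+1.90  (consistent_up)
```

The funnel reads: 819 per-pair DE calls collapse to 7 recurrent
lncRNAs, of which 5 are direction-consistent candidates. The top-ranked
candidates here are all planted in the simulation's ground truth.
Target prediction hangs off the results object:

```python
top = results.top(3)
results.predict_trans_targets(candidates=top["transcript_id"])
```

```
  lnc_id  gene_id  mode  distance_bp         r     r_pvalue  passes
LNC_0031 PCT_0023 trans          NaN  0.993622 1.003243e-35    True
LNC_0031 PCT_0072 trans          NaN -0.980745 3.921431e-27    True
LNC_0073 PCT_0011 trans          NaN  0.992665 1.233523e-34    True
...
```

Each row is one lncRNA→gene link passing the strict |r| > 0.95 rule;
p-values come from the t-transform of r and are reported, never
filtered on.

## Command line

Every stage is exposed as a subcommand (`lncrecur simulate / identify /
de / prioritize / targets / enrich`), and `lncrecur run-all --config
run.yaml` executes the whole pipeline into a run directory with a
`manifest.json` recording the resolved configuration, seed and
per-stage row counts. Re-running with the same config and seed
reproduces every output byte for byte.

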