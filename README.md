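# hubdrs

Interictal MEG network hubs and their surgical removal: functional
connectivity networks from source-space region-of-interest (ROI) time
series, the **D_RS** removed-vs-spared distinguishability statistic, and
group-level surgical-outcome and epilepsy-duration inference — with a
synthetic-cohort generator for end-to-end validation.

## The problem

In drug-refractory focal epilepsy, surgery aims to remove the
epileptogenic zone. High-connectivity network "hubs" in interictal
(between-seizure) MEG recordings are candidate epileptogenic tissue: if
removing hubs matters, patients whose resections cover the hubs should
more often become seizure-free. `hubdrs` quantifies that idea for cohorts
of pre-surgical recordings with known resections and post-surgical
outcomes (ILAE class 1 = seizure-free vs ILAE > 1).

## The method

Per subject and one-minute analysis epoch:

1. **Networks.** A 2-s sliding window with 50% overlap runs over the ROI
   time series; each window yields a Pearson correlation matrix; windows
   are averaged element-wise into one epoch matrix. Inter-hemispheric
   entries are then masked (resections are unilateral; contralateral
   coupling carries little discriminative signal).
2. **Node strength.** strength(i) = mean correlation of region *i* with
   all other regions of its own hemisphere.
3. **D_RS.** With removed set *R* and spared set *S* from the resection,

   D_RS = [ #{(r,s) ∈ R×S : strength(s) > strength(r)} + ½·#ties ] / (|R|·|S|),

   the normalized Mann–Whitney U of the spared sample: 0 means every
   removed node was stronger than every spared node (the resection took
   the hubs), 0.5 means no difference, 1 the reverse.

Across subjects:

* **Outcome.** AUC for separating outcome groups by D_RS (AUC > 0.5 ⇔
  seizure-free patients have lower D_RS), a confidence interval from the
  Hanley–McNeil standard error mapped through the logit, and a one-tailed
  Mann–Whitney rank-sum test.
* **Duration.** Mean FC (mean of *all* connections of the unmasked epoch
  matrix) regressed on log10 epilepsy duration with a Tukey-bisquare
  robust fit per segment, and a linear mixed model
  `mean_FC ~ 1 + log10(duration) + (1 | segment)` across segments, both
  with likelihood-ratio p-values.

Resections are specified either as an explicit removed-region list or as
a parcellation label volume plus a binary resection mask (NIfTI): a
region is *removed* if any of its voxels overlaps the mask.

## Worked example

Simulate and analyze a default synthetic cohort (31 subjects, 12
seizure-free, 32 regions, 10 s of 600 Hz signal each, strong planted
hub-removal effect):

```python
import hubdrs as h

cfg = h.RunConfig(
    cohort=h.CohortConfig(record_minutes=10 / 60),
    epochs=h.EpochSpec(n_epochs=1, epoch_seconds=10.0, min_gap_seconds=0.0),
).with_seed(7)
out = h.run_pipeline(cfg, "demo")
s = out["group_stats"]["segments"]["1"]
print(f"AUC={s['auc']:.3f} CI=[{s['ci_low']:.2f}, {s['ci_high']:.2f}] "
      f"p={s['p_one_tailed']:.2e}")
```

prints

```
AUC=0.965 CI=[0.74, 1.00] p=9.40e-06
```

i.e. on this cohort a randomly chosen not-seizure-free subject has a
higher D_RS than a randomly chosen seizure-free subject 96.5% of the
time — the planted effect (seizure-free subjects had ~90% of their hubs
resected, others ~10%) is recovered with high confidence. The cohort
table written to `demo/cohort.tsv` starts

```
subject_id  segment      drs  mean_fc  outcome   duration_years
sub001            1 0.967949 0.126780  ILAE_gt1        4.134979
sub002            1 0.256410 0.131794  ILAE1           7.125755
```

— the seizure-free subject's low D_RS (0.26) says the removed regions
ranked among the strongest nodes. The same run reports the duration
model (`duration_robust` block): slope 0.0080 mean-FC units per decade
of duration with LRT p = 6.7e-11, recovering the planted positive
duration–connectivity association.

The same pipeline runs from the shell:

```sh
hubdrs run --config run.yaml --out demo --seed 7
hubdrs simulate --config cohort.yaml --out cohort_dir --seed 1
hubdrs connectivity --ts sub-sub001_ts.csv --atlas atlas.tsv --fs 600 --out conn
hubdrs label-regions --parcellation parc.nii.gz --mask resection.nii.gz \
    --atlas atlas.tsv --out removed.json
hubdrs drs --fc conn/epoch-1_fc.csv --atlas atlas.tsv --removed removed.json \
    --out drs.json
hubdrs group --cohort cohort.tsv --out group_stats.json
```

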