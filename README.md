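# eegnetdyn

Dynamic functional-network analysis of multichannel EEG: quasi-stable
network detection by edit distance against surrogate null models.

Scalp EEG records fast-changing electrical activity at dozens of sensors.
A long-standing observation is that the brain's sensor-level functional
network — which channel pairs co-fluctuate — does not drift continuously
but lingers in quasi-stable configurations that are revisited over time,
and that the dwell-time and topology of those configurations differ between
clinical populations (for example between typically developing youths and
youths on the autism spectrum, at rest versus under task load). This
package implements that analysis end to end for researchers working with
sensor-space EEG who want a reproducible, testable pipeline: it combines a
microstate-style stability segmentation with weighted graph analysis, and
ships a synthetic-data generator with planted ground truth so every stage
can be validated without access to clinical recordings.

## The method

1. **Networks per epoch.** Each recording is epoched (resting: a 30 s
   window as 16 consecutive 1.875 s epochs; event-related: 500 ms epochs
   from 100 ms pre-stimulus, baseline-corrected, artifact/incorrect trials
   rejected at |x| > 150 µV). For every channel pair (i, j) the Pearson
   correlation γ̂_ij(h) is evaluated on overlapping samples at every lag
   h ∈ [−max_lag, max_lag] (default 100 ms) and the signed correlation at
   the |r|-maximizing lag becomes the edge weight — one weighted undirected
   network S per epoch.

2. **Stability by edit distance.** Network change between consecutive
   epochs is the entrywise L1 (edit) distance

       dist(S1, S2) = Σᵢ Σⱼ |S1,ij − S2,ij|

   (L2 and cosine variants are available). A transition is *stable* when
   its distance falls more than two standard deviations below the mean of
   a null distribution pooled per condition, built from either
   degree/strength-preserving matrix randomization or per-channel
   temporal-shift surrogates (delete a random 0–5 s prefix per channel,
   trim to 30 s). Maximal runs of stable transitions become quasi-stable
   periods; each period's averaged network is the mean of its epochs'
   matrices.

3. **Graph measures.** Averaged stable networks are summarized by
   diameter, radius, characteristic path length, transitivity, maximum
   modularity (seeded Louvain restarts) and global efficiency, over
   connection lengths 1/w.

4. **Group statistics.** Subject-level summaries (stable-network counts,
   mean durations, per-measure means) enter mixed two-way ANOVAs
   (within-subject condition × between-subject group) with step-down
   Welch t tests.

See `docs/methods.md` for assumptions, parameter defaults, null-model
details and limitations.

## Worked example

Run a small synthetic cohort (two groups × four subjects, resting
condition, 8 channels) through the full pipeline:

```python
from eegnetdyn import RunConfig
from eegnetdyn.pipeline import run_pipeline

cfg = RunConfig(n_channels=8, n_subjects_per_group=4, conditions=["rest"],
                n_null_replicates=20, n_modularity_restarts=20, seed=7,
                out_dir="runs/example")
res = run_pipeline(cfg)
null = res.nulls["rest"]
print(f"null: mean={null.mean:.2f} sd={null.sd:.2f} "
      f"-> threshold={res.thresholds['rest']:.2f}")
tab = res.cohort_table
for meas in ("n_stable", "mean_duration", "diameter"):
    m = tab[tab.measure == meas].groupby("group").value.mean()
    print(f"{meas}: ASD_like={m['ASD_like']:.3f}  TD_like={m['TD_like']:.3f}")
```

prints

```
null: mean=8.70 sd=1.81 -> threshold=5.07
n_stable: ASD_like=3.250  TD_like=3.000
mean_duration: ASD_like=7.461  TD_like=5.031
diameter: ASD_like=13.179  TD_like=10.733
```

The randomized-matrix null puts typical between-epoch change at 8.7 ± 1.8,
so transitions with edit distance below 5.07 are flagged stable. The
ASD-like group — planted with longer regimes and weaker couplings — shows
longer mean stable durations (7.5 s vs 5.0 s) and a larger network
diameter (13.2 vs 10.7), the two directional group effects the generator
encodes. The run directory (`runs/example`) contains the per-epoch
matrices, distance vectors, null summaries, stable-period and metric
tables, the ANOVA report and a provenance manifest; re-running the same
config bit-reproduces all outputs.

The same pipeline is available from the shell:

```bash
eegnetdyn run --simulate --seed 7 --out runs/example
eegnetdyn simulate --seed 1 --out cohort/          # recordings + ground truth
eegnetdyn connect cohort/TD_like__TD_like_s00__rest.tsv --out conn/
```

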