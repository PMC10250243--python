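# mitodwell

Quantitative analysis of how transcription factors (TFs) engage chromatin
through mitosis, for researchers doing single-molecule live-cell imaging and
spike-in normalized CUT&Tag in cultured cells. The package implements three
measurements end to end, together with a synthetic-data generator that makes
every stage testable by parameter recovery:

1. **Single-molecule residence times (slow tracking).** In long-exposure
   (200 ms, 5 Hz) movies, diffusing molecules blur out while DNA-bound
   molecules appear as diffraction-limited spots. Spots are detected with a
   per-pixel generalized likelihood-ratio test (false-alarm probability
   10⁻⁶·²⁵, three deflation loops to recover overlapping spots), localized
   sub-pixel by Gaussian fitting, and linked into tracks with one-frame gap
   closing under a diffusion-limited search radius (D_max = 0.5 µm²/s, at
   most 5 competitors per assignment). Each track contributes a dwell time;
   pooled dwells give the survival curve S(t) = P(dwell ≥ t), which is fitted
   with a two-component exponential decay

   S(t) = f·e^(−k_fast·(t−t₀)) + (1−f)·e^(−k_slow·(t−t₀)),

   where the slow component is the apparent dissociation rate k_off of the
   specific bound state and the fast component absorbs transient,
   non-specific binding. The apparent rate is corrected for photobleaching by
   subtracting the apparent rate of an H2B-Halo control measured identically:
   k_corr = k_app − k_H2B, residence time = 1/k_corr. The time at which the
   fitted model reaches 1% bound is also reported.

2. **Mitotic chromatin-enrichment score.** From a two-channel image of a
   mitotic cell (H2B marker + HaloTag-TF), the score is
   log₂(mean TF intensity over chromatin / mean over the whole cell):
   positive for TFs that coat mitotic chromosomes, zero for uniform, negative
   for excluded. Masks come from automatic Otsu-based segmentation of the H2B
   channel (or hand-drawn ROIs imported from CSV); constructs are compared by
   a two-tailed t-test on biological-replicate means.

3. **Spike-in scaling of CUT&Tag counts.** Samples carry a known fraction of
   Drosophila S2 spike-in cells; each sample's scaling is an arbitrary
   constant (100 000 at 10% spike-in, 200 000 at 20%) divided by its
   fly-aligned read count, normalized so the asynchronous reference equals 1.
   Scaled per-site count matrices and paired asynchronous-vs-mitotic scatter
   data are produced.

## Worked example

```bash
python examples/residence_time_recovery.py
```

```
interphase: true k_off 0.059/s -> recovered 0.0580/s (residence 17.2 s, 4347 dwells)
mitosis: true k_off 0.138/s -> recovered 0.1397/s (residence 7.2 s, 4244 dwells)
mitosis/interphase residence ratio: true 42.8% -> recovered 40.2% (p = 3.1e-05)
A ratio below 100% means the TF dissociates faster from mitotic chromatin.
```

This simulates 5000 dwell times per condition and replicate under the
two-component bleaching model (30% transient binders at 1 s⁻¹, bleach rate
0.05 s⁻¹, 5 Hz frame discretization), runs the full survival → fit →
correction pipeline including an independently simulated H2B control, and
recovers the generating dissociation rates within a few percent. The ratio
line runs three replicates per condition and compares them the way the
experiments are analyzed: fits per replicate, statistics across replicates.

Other examples: `spot_detection_and_tracking.py` (movie → spots → tracks →
dwells), `chromatin_enrichment.py` (synthetic mitotic cells → scores),
`spikein_scaling.py` (counts → scaling → normalized matrix).

There is also a thin CLI over the same stages:

```bash
mitodwell all --out run1 --seed 1          # end-to-end synthetic run
mitodwell localize movie.tif --out run1    # stage by stage
mitodwell track run1/localizations.csv --out run1
```

Every run writes its parameters, seed and per-stage record counts to a JSON
run log, and reruns with the same config and seed are byte-identical.

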