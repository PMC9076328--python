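# elindex

Hemispheric asymmetry analysis of two-channel sleep EEG with the
**enhanced laterality index (ELI)**.

During sleep the two cerebral hemispheres are not equally active, and
disorders such as obstructive sleep apnea (OSA) perturb that balance.  The
classical laterality index summarizes the contrast of one representative
quantity *Q* measured over the left (C3) and right (C4) central derivations,

```
LI = (Q_LH − Q_RH) / (Q_LH + Q_RH)  ∈ [−1, 1],
```

with +1 pure left dominance and −1 pure right dominance.  A single quantity
can miss asymmetries that only show in another: signal *complexity* and
signal *strength* concentrate in different frequency bands.  The ELI fuses N
quantities with convex weights λᵢ (Σλᵢ = 1):

```
ELI = Σᵢ λᵢ · (Q_LH^i − Q_RH^i) / (Q_LH^i + Q_RH^i).
```

`elindex` implements the two-quantity instantiation used in sleep studies —
complexity via **fuzzy entropy** (FuzzyEn, m = 2, n = 2, r = 0.2·SD) and
strength via **epoch energy** (sum of squared samples) — so that

```
ELI(λ) = λ·LI_FE + (1−λ)·LI_E,   λ ∈ {0, 0.1, …, 1}.
```

The pipeline: annotated C3/C4 recordings → event-locked 20-s segments →
order-8 Butterworth low-pass at 50 Hz (zero-phase) → wavelet-packet
decomposition into δ (1–3 Hz), θ (4–7), α (8–13), β (14–30) → twenty 1-s
epochs per segment → per-epoch FuzzyEn and energy → 20-epoch means →
laterality indices and the λ-sweep → mean±SD tables and subject-paired
t tests across bands, hemispheres and conditions.

Because clinical polysomnography recordings are access-restricted, the
package ships a first-class synthetic-cohort generator with analytic
ground-truth asymmetries (`elindex.synthdata`), so every stage — and the
ELI's discriminative claim — is testable end to end.

Intended users: sleep/EEG researchers who want a reproducible laterality
pipeline, and methodologists studying multi-feature index fusion.

## Worked example

```python
from elindex import PipelineConfig, run_pipeline, synth_cohort
from elindex.synthdata import make_eli_separation_scenario

# 5 subjects; OSA segments carry a left-dominant asymmetry in both
# strength (all bands) and complexity (beta band); normal sleep symmetric.
spec = make_eli_separation_scenario(n_subjects=5, seed=7)
recordings, truth = synth_cohort(spec)
result = run_pipeline(recordings, PipelineConfig())

lat = result.laterality
beta = lat[lat["band"] == "beta"]
print(beta.groupby("condition")[["li_fe", "li_e", "eli_0.5"]].mean().round(3))
```

prints

```
           li_fe   li_e  eli_0.5
condition
OSA        0.026  0.261    0.143
normal     0.003  0.000    0.002
```

Reading the numbers: in apnea segments the left hemisphere carries ~26%
relatively more beta-band energy (`li_e = 0.261 ≈ (1.3²−1)/(1.3²+1)`, the
analytic value for the injected 1.3× amplitude ratio) and slightly higher
complexity (`li_fe = 0.026`), while normal sleep shows no laterality.  The
balanced index `eli_0.5` separates the two conditions at every λ, which
neither single-quantity LI does at its opposing endpoint.

The same analysis from the shell:

```bash
elindex synth --spec spec.yaml --out-dir cohort/
elindex features --input-dir cohort/ --out features.csv
elindex laterality --features features_agg.csv --grid 0:0.1:1 --out laterality.csv
elindex report --features features_agg.csv --out report.csv
# or all at once on a synthetic cohort:
elindex run --seed 0 --out-dir out/
```

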