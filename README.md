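# octflush

Pixel-based paired analysis of intravascular optical coherence tomography
(OCT) pullbacks.

## The problem

Intracoronary OCT needs the blood column displaced during acquisition —
red cells scatter the near-infrared beam — and the standard flushing
medium is iodine contrast, which adds nephrotoxic load on top of the
angiographic dose. Evaluating an alternative flushing medium (e.g. a
pentastarch / hydroxyethyl-starch solution) requires comparing *paired*
pullbacks of the same vessel segment, one per medium, on three axes:

1. **Blood-flushing capability** — a per-cross-section pixel statistic:

   ```
   flushing capability = 1 − (bright pixels within the vessel lumen)
                             ───────────────────────────────────────
                             (lumen area − catheter and guidewire area)
   ```

   where a pixel is "bright" (residual blood) if its normalized intensity
   exceeds a predetermined background threshold, and the denominator is
   the *effective lumen*: lumen interior minus the catheter sheath and the
   guidewire artifact.

2. **Image quality** — the clear-image-segment (CIS) convention: a frame
   is *clear* when arterial structure is visualized along a continuous arc
   > 270°; a 1-mm longitudinal segment is a *CIS* when ≥ 50% of its frames
   are clear; a pullback is a *clear run* when ≥ 90% of its segments are
   CIS.

3. **Morphometry** — per-frame lumen/stent areas from the segmented
   contours (`A = ½ Σ rᵢ² Δθ`), minimal lumen/stent area (MLA/MSA),
   per-1-mm segment lumen/stent volumes (SLV/SSV), with refractive-index
   correction `value × (n_ref / n_actual)^d` (d = 1, 2, 3) when the medium
   used differs from the index assumed by the console — for pentastarch
   vs. contrast, n = 1.3433 vs. 1.4421, a linear factor of ≈ 1.0735.

The agreement layer reports paired t / Wilcoxon tests, Pearson r/R²,
ICC(2,1) (two-way random effects, absolute agreement, single measure,
with F-based CI), Bland–Altman limits of agreement, and the paired-t
sample size by exact noncentral-t power (d = 0.50, α = 0.05, power 0.90
→ 44 pairs).

Because clinical pullbacks cannot ship with a package, `octflush`
includes a **synthetic polar phantom generator** that renders pullbacks —
catheter sheath, speckled attenuating vessel wall, stent struts with
radial shadows, a guidewire shadow sector, Bernoulli residual-blood
pixels at a known density — together with exhaustive ground truth, so
every stage of the chain is verifiable end to end.

Who is this for: imaging-core-lab and research engineers building or
validating quantitative OCT comparisons, and anyone needing a tested
reference implementation of the flushing/CIS/morphometry/agreement stack.

## Worked example

```python
from octflush import (AcquisitionMeta, LumenModel, StentSpec, GuidewireSpec,
                      PhantomSpec, PairConfig, paired_sample_size)
from octflush.pipeline import PipelineConfig, run_pipeline

meta = AcquisitionMeta(n_alines=300, n_depth=620, pullback_length_mm=6.0)
spec = PhantomSpec(
    lumen=LumenModel(base_radius_mm=1.6, slope_mm_per_mm=0.08,
                     center_offset_mm=0.25, ovality=0.04),
    stent=StentSpec(n_struts=8),
    guidewire=GuidewireSpec(center_deg=200.0, width_deg=28.0),
    landmark_frames=(5, 20),
)
cfg = PipelineConfig(
    meta=meta, spec=spec,
    pair=PairConfig(density_a=0.03, density_b=0.03,     # 3% residual blood
                    index_a=1.4421, index_b=1.3433),    # contrast vs. starch
    n_frames=25, seed=11,
)
res = run_pipeline(cfg)
print(res.agreement_table[["endpoint", "n", "mean_a", "mean_b",
                           "t_pvalue", "r2", "icc"]].round(4).to_string(index=False))
print("clear run (contrast arm):", res.analysis_a.quality.clear_run)
print("flushing median (IQR):",
      round(res.analysis_a.quality.flushing_median, 3),
      tuple(round(q, 3) for q in res.analysis_a.quality.flushing_iqr))
print("pairs needed for 90% power at d=0.5:", paired_sample_size(0.5, 0.05, 0.90))
```

prints

```
       endpoint  n  mean_a  mean_b  t_pvalue  r2  icc
 lumen_area_mm2 25 10.1881 10.1798    0.0000 1.0  1.0
        slv_mm3  5 10.1881 10.1798    0.0309 1.0  1.0
flushing_median 25  0.9729  0.9729       NaN NaN  NaN
clear run (contrast arm): True
flushing median (IQR): 0.973 (0.972, 0.973)
pairs needed for 90% power at d=0.5: 44
```

Member B was rendered under the lower-index medium (its radii shrink by
1.3433/1.4421) and corrected back; per-frame lumen areas agree to < 0.1%
(mean 10.188 vs 10.180 mm², R² and ICC ≈ 1.0). The residual ~0.008 mm²
bias is the sub-pixel remnant of the contour detector and is resolvable
only because the phantom's noise floor is far below clinical variability.
With 3% seeded residual blood the flushing median is 0.973, and all 1-mm
segments are CIS, so the pullback is a clear run.

The same chain is available from the shell:

```bash
octflush simulate --config phantom.json --seed 1 --out pb/
octflush segment  --in pb/ --out seg/
octflush quality  --in pb/ --out q/
octflush morph    --in pb/ --correct 1.4421,1.3433 --out m/
octflush compare  --a mla_a.csv --b mla_b.csv --out agreement.csv
octflush power    --d 0.5 --alpha 0.05 --power 0.9
octflush run      --config pair.json --seed 1 --out results/
```

## Layout

| module | contents |
| --- | --- |
| `octflush.core` | geometry conventions, `AcquisitionMeta`, `PolarPullback` |
| `octflush.phantom` | synthetic pullback generator + `GroundTruth` |
| `octflush.segmentation` | catheter mask, lumen contour, guidewire, struts, stent spline, scan conversion |
| `octflush.quality` | flushing capability, clear frame / CIS / clear run |
| `octflush.morphometry` | areas, MLA/MSA, SLV/SSV, refractive correction |
| `octflush.paired_stats` | matching, paired tests, ICC, Bland–Altman, power, CIN rule |
| `octflush.io` / `pipeline` / `cli` | TIFF+JSON interchange, end-to-end runner, `octflush` CLI |

See `docs/methods.md` for the model assumptions, parameter defaults, and
known limitations.
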