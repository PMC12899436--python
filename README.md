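# fishstack

Multilayer FISH z-stack analysis: nuclear segmentation, cross-plane
nucleus registration, gene-spot detection, and break-apart / dual-fusion
genotype classification, with the evaluation statistics used to compare
segmentation methods and a synthetic-data generator with exact ground
truth.

## The problem

Interphase FISH detects gene rearrangements — e.g. the t(14;18)(q32;q21)
BCL2–IGH translocation of follicular lymphoma — as the geometry of green
(FITC) and red (TRITC) probe signals inside individual DAPI-stained
nuclei.  In lymphoid tissue the nuclei are densely packed and overlap, so
whole-slide scanners acquire short z-stacks (typically 7 planes, 0.4 µm
apart) around a best-focus plane.  Reading such stacks automatically
requires solving, in order:

1. **Extended focus** — collapse each channel to a 2-D composite by
   per-pixel maximum over planes.
2. **Nuclear segmentation** — binarise DAPI against a Gaussian-weighted
   local mean (foreground iff `I(p) > m_w(p) + offset`), clean the mask,
   and split touching nuclei with a distance-transform-seeded watershed;
   or ingest instance masks from external segmenters (StarDist,
   NucleAIzer, Cellpose, …).
3. **Cross-plane registration** — accumulate per-plane contours into a
   non-redundant nucleus-ID dictionary (focal plane first), so a nucleus
   visible in several planes is counted once.
4. **Spot detection** — seed spots at prominent intensity peaks inside
   registered contours, grow each seed into its connected
   super-threshold region (clipped to the ≤ 0.5 µm physical spot size),
   and keep a per-nucleus spot dictionary that is non-overlapping across
   planes.
5. **Classification** — pair green and red spots by 3-D distance: pairs
   within the colocalization radius are fused, pairs beyond three spot
   diameters (3 × 0.5 µm) are separated.  Break-apart probes call
   *aberrant* on a separated pair; dual-fusion probes on a colocalized
   pair.
6. **Evaluation** — recall, precision, F-measure (= Dice on TP/FP/FN),
   accuracy (= Jaccard = TP/(TP+FP+FN)), sample/population variance
   (VP/VS = (n−1)/n), Pearson correlation and Cohen's kappa.

See `docs/methods.md` for the full model description, parameter defaults
and design rationale.

## Worked example

Simulate a field of 200 partially overlapping nuclei with planted
genotypes, run the whole pipeline, and compare against the ground truth:

```python
from fishstack.synthetic_fishgen import SimulationConfig, simulate
from fishstack.pipeline import analyze_stack, synthetic_analysis_configs

cfg = SimulationConfig(seed=1)              # 200 nuclei, 20% overlap, 7 planes
stack, truth = simulate(cfg)
seg, spot, cls = synthetic_analysis_configs()
result = analyze_stack(stack, seg, spot, cls)

print(len(result.registry), "nuclei registered of", len(truth.nuclei))
print("mean spots/nucleus:", result.summary["mean_spots_per_nucleus"])
print("fraction aberrant:", round(result.summary["fraction_aberrant"], 3))
print("planted:", truth.genotype_fractions())
```

Output:

```
199 nuclei registered of 200
mean spots/nucleus: {'FITC': 2.0100502512562812, 'TRITC': 2.0100502512562812}
fraction aberrant: 0.613
planted: {'fusion': 0.2650000000000001, 'break_apart': 0.3450000000000002, 'normal': 0.39000000000000024}
```

199 of 200 nuclei are recovered (one overlapping pair merges), the mean
of 2.01 spots per nucleus per channel matches the planted 2 + 2 pattern,
and the recovered aberrant fraction 0.613 sits within 0.003 of the
planted fusion + break-apart share (0.265 + 0.345 = 0.610) — the
generator plants exactly two green and two red spots per nucleus, with
fused pairs only in aberrant genotypes.

The same workflow is available from the shell:

```bash
fishstack simulate --seed 1 --out case/
fishstack run --config cfg.yaml --out results/
fishstack project --channel DAPI --in case/dapi.tif --out dapi_efi.tif
```

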