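# redoxcell

Single-cell optical metabolic imaging analysis: per-cell optical redox
ratio, TMRE-based mitochondrial membrane potential, extracellular-flux
(mito stress test) metrics, plate-assay reductions, and
treatment-versus-control statistics — with synthetic ground-truth
generators that let every stage be validated by parameter recovery.

## Who this is for

Labs quantifying drug-induced metabolic shifts in cultured cells from
label-free autofluorescence (NAD(P)H, FAD) and TMRE fluorescence
microscopy, alongside standard orthogonal assays (Seahorse flux, WST-1
viability, CytoID autophagy, Ki67/CC3 immunofluorescence, X-gal
senescence). The package turns raw images and plate tables into
per-cell and per-condition metrics and runs the matching statistics.

## The quantities at its core

**Optical redox ratio.** For each pixel (and each cell cytoplasm),

    ORR = I_NAD(P)H / I_FAD

the ratio of the NAD(P)H autofluorescence intensity to the FAD
intensity. The two cofactors are, respectively, the cell's main
electron donor and acceptor, so their intensity ratio reports the
cellular oxidation–reduction state. Photon-counting acquisitions are
first collapsed to intensities by integrating each pixel's decay curve
over a sliding 3×3 spatial bin.

**Mitochondrial membrane potential.** TMRE is a cationic dye whose
accumulation across the inner mitochondrial membrane follows the
Nernst relation (non-quenching mode). With the mean mitochondrial and
nuclear TMRE intensities FI_m and FI_n of a cell,

    ΔΨ = −RT · log10(FI_m / FI_n),   RT = 61.5 mV at 37 °C

The nucleus stands in for the cytosolic reference because TMRE
equilibrates similarly in nucleus and cytosol while the cytoplasmic
signal proper is contaminated by mitochondria.

**Segmentation.** Cells are grown outward from nucleus seed masks by
intensity-guided geodesic propagation (step cost
sqrt(λ² + ΔI²), ties to the lower label); cytoplasm = cell minus
nucleus; mitochondria = cytoplasm gated by a global minimum
cross-entropy (Li) TMRE threshold with a correction factor of 2.

**Flux metrics.** Basal respiration = mean baseline OCR − mean OCR
after rotenone/antimycin A; OCR:ECAR ratio at baseline; energy
phenotype quadrant (aerobic / quiescent / energetic / glycolytic)
relative to the control's baseline means. Rates are normalized to DNA
per well via crystal-violet absorbance.

**Statistics.** One-way ANOVA, then Dunnett's many-to-one comparison
with a single pooled variance (two-sided, α = 0.01; adjusted p from a
seeded Monte-Carlo sample of the joint max-|t| null), and
control-referenced z-scores z = (μ_treatment − μ_control)/σ_control.

## Worked example

Generate a synthetic field of view with a known membrane potential,
run the full pipeline, and recover it:

```python
import numpy as np
from redoxcell import (
    SimConfig, generate_cell_scene, integrate_decay,
    segment_cells, potential_table, per_cell_redox,
)

cfg = SimConfig(seed=1, image_size=352, n_cells=120, delta_psi_mv=-61.5)
scene = generate_cell_scene(cfg)

guide = integrate_decay(scene.decays["NADPH"], 1)      # 3x3-binned intensity
seg, empty = segment_cells(scene.nuclei, guide, scene.images["TMRE"])

records, excluded = potential_table(seg, scene.images["TMRE"])
dp = np.array([r.delta_psi for r in records])
print(f"cells analyzed: {len(records)} (excluded: {len(excluded)})")
print(f"median delta-psi: {np.median(dp):.1f} mV (target -61.5)")

nadph = integrate_decay(scene.decays["NADPH"], 1)
fad = integrate_decay(scene.decays["FAD"], 1)
recs, _ = per_cell_redox(seg.cytoplasm, nadph, fad)
print(f"mean cytoplasmic ORR: {np.mean([r.orr for r in recs]):.3f}")
```

Output:

```
cells analyzed: 120 (excluded: 0)
median delta-psi: -62.3 mV (target -61.5)
mean cytoplasmic ORR: 1.200
```

The 120 cells were segmented from their nucleus seeds, the global
corrected TMRE threshold isolated the mitochondrial puncta, and the
median Nernst potential lands within 1 mV of the generator's target;
the mean cytoplasmic ORR equals the configured 30/25 photon-rate
ratio.

The same stages are scriptable from the shell:

```bash
redoxcell simulate --config sim.yaml --out run/
redoxcell segment  --config seg.yaml --out run/seg
redoxcell orr      --config orr.yaml --out run/orr
redoxcell stats    --config stats.yaml --out run/stats --seed 1
```

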