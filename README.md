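# retflim

Phasor-FLIM metabolic and structural analysis of retina sections, with a
built-in synthetic TCSPC simulator.

## The problem

Multiphoton fluorescence lifetime imaging (FLIM) of retina cross-sections
can read out the tissue's metabolic state label-free: free NAD(P)H decays
fast (τ ≈ 0.4 ns) and marks glycolysis, protein-bound NAD(P)H decays
slowly and marks oxidative phosphorylation. The same acquisition also
carries structural channels — melanin (RPE/choroid), hemoglobin (retinal
vessels and two RPE bands), and the effectively instantaneous
second-harmonic signal of fibrillar collagen (sclera) — each with a
distinct phasor signature.

`retflim` implements the full analysis chain for such data, plus a
simulator of labeled retina-section phantoms and per-pixel TCSPC decay
cubes, so every stage can be validated against known ground truth.

## The method

Each pixel's photon-arrival histogram `I(t)` is mapped to first-harmonic
phasor coordinates

    g = Σ I(t)·cos(nωt) / Σ I(t),   s = Σ I(t)·sin(nωt) / Σ I(t),

with ω = 2π/T the laser repetition angular frequency. A mono-exponential
lifetime τ sits on the universal circle (center (½, 0), radius ½) at
g = 1/(1+(ωτ)²), s = ωτ/(1+(ωτ)²); mixtures combine linearly by
fractional intensity. After calibration against a reference decay of known
lifetime, a *metabolic trajectory* is drawn from the free-NAD(P)H anchor
(0.4 ns) through an ROI's photon-weighted phasor center of mass to its
second intersection with the circle (100 % bound). The bound-NAD(P)H
percentage is the center of mass's relative position along that chord,
×100. The FAD channel uses the same geometry anchored at free FAD
(2.6 ns) and reports the free percentage.

Sections are zoned by eccentricity along the retinal midline
(peripapillary 200 µm, central 400 µm, paracentral 600 µm from the optic
disc, mid periphery at half the disc-to-ora arc, far periphery at the ora
serrata), split into outer (OS+IS+ONL) and inner (OPL…RNFL) regions, and
analyzed in 150 µm-wide ROIs. Per-image region means are compared with
two-tailed paired t-tests.

## Worked example

```python
import retflim as rf

inst = rf.InstrumentModel()                     # 12.5 ns period, 256 bins
phantom = rf.make_phantom(1600, 300, 2.0, seed=0)
truth = rf.layer_metabolic_profile(phantom, 58.9, 60.9)   # bound % ground truth
cube = rf.simulate_decay_cube(phantom, inst, "nadph", 1e5,
                              ground_truth_pct=truth, seed=0)
ref = rf.simulate_reference_cube(inst, 1.0, poisson=False)
field = rf.calibrate(rf.phasor_transform(cube), ref, 1.0)
zones = rf.build_zones(phantom)
rois = rf.make_rois(zones)
for r in rf.analyze_rois(field, rois, free_tau_ns=0.4)[:3]:
    print(f"{r.roi_id}: {r.bound_pct:.2f} % bound, {r.n_pixels} px")
```

prints

```
central_inferior_outer: 58.90 % bound, 3525 px
central_inferior_inner: 60.90 % bound, 4003 px
central_superior_outer: 58.90 % bound, 3525 px
```

i.e. the outer-retina ROIs recover the simulated 58.9 % bound NAD(P)H and
the inner-retina ROIs the simulated 60.9 %, to about 0.01 percentage
points at this photon budget. The full pipeline (simulate → phasor →
calibrate → zones → ROIs → structural channels → paired statistics) runs
from one seeded config:

```sh
retflim run --seed 1 --out results/run1      # or: --config my.yaml
```

and writes ROI/aggregate CSV tables, a comparison report, structural
masks, a bound-fraction rainbow map, and a provenance JSON.

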