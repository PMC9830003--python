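# cario — caries lesion-activity assessment from multimodal imaging

`cario` is a Python library for quantifying the **activity of dental caries
lesions** — whether a lesion is still progressing (active, porous, permeable)
or has remineralised and arrested — from four kinds of images of the same
tooth surface:

* **SWIR reflectance dehydration series** (shortwave infrared, ~1950 nm): a
  wet tooth is dried with forced air for 60 s at one frame per second.  Water
  in the pores of an active lesion absorbs SWIR light; as it evaporates, the
  lesion brightens sigmoidally at a rate set by its permeability.
* **Thermal dehydration series**: evaporative cooling dips the surface
  temperature below ambient before it recovers; the enclosed area measures
  the water lost.
* **OCT B-scans**: demineralised enamel scatters strongly (bright body); a
  remineralised **transparent surface layer (TSL)** appears as a dark band
  capping the lesion and is the structural hallmark of arrest.
* **MicroCT slices**: mineral-density profiles give lesion depth and the
  (near-universal) high-mineral **surface layer (SL)** on a true 10 μm scale.

The per-ROI dehydration statistics are

```
ΔI = Σ_t (I_t − I_min)          (SWIR intensity gain, a.u.·s)
ΔQ = Σ_t (T_max − T_t)          (evaporative heat-loss area, K·s)
```

each contrasted against a sound control ROI on the same tooth as a
difference `L−C` and a ratio `L/C`.  OCT lesion depth and TSL thickness are
optical path lengths divided by **1.6**, the refractive index of enamel;
MicroCT lengths are never corrected.  A lesion with no detectable TSL is
classified *active*, with a TSL under 70 μm *partially arrested*, and at or
above **70 μm** *arrested* — past that thickness the layer blocks fluid
exchange almost completely and dehydration statistics stop responding.

Because no public dataset of extracted teeth with secondary caries exists,
the package ships a first-class synthetic cohort generator (`cario.synth`)
that renders all four modalities from ground-truth lesion parameters, so
every analysis stage is tested by parameter recovery and by reproduction of
the expected cohort-level sign structure.

## Worked example

`python examples/04_cohort_statistics.py` analyses a 100-lesion synthetic
cohort end to end and prints:

```
100 lesions, 76 with a detected TSL
  ld_oct_um vs delta_R   r=-0.13 p=0.2 n=100
    delta_R vs dQ_ratio  r=+0.10 p=0.33 n=100
     tsl_um vs dI_diff   r=-0.76 p=1.6e-15 n=76 *
     tsl_um vs dI_ratio  r=-0.63 p=1.3e-09 n=76 *
     tsl_um vs dQ_diff   r=-0.43 p=0.00012 n=76 *
     tsl_um vs dQ_ratio  r=-0.42 p=0.00014 n=76 *
     tsl_um vs sl_um     r=+0.56 p=1.1e-07 n=76 *
TSL<70um band:  r=-0.73 p=2.9e-10 (n=55)
TSL>=70um band: r=-0.09 p=0.7 (n=21)
between-band dI L-C t-test: t=7.24 p=9.4e-10
```

Read: the thicker the transparent surface layer, the smaller the dehydration
contrasts (strongly for SWIR `ΔI_{L−C}`, more weakly for the noisier thermal
`ΔQ`), the correlation lives entirely in the sub-70-μm band and vanishes in
the arrest band, and OCT TSL agrees positively with the MicroCT surface
layer.  The other examples demonstrate single-lesion dehydration analysis
(`01`), OCT morphometry with the ÷1.6 optical-to-tissue conversion (`02`),
MicroCT line profiles (`03`) and the deterministic end-to-end pipeline
(`05`).

A thin CLI wraps the same functions:

```bash
cario run --seed 7 --out report/           # end-to-end synthetic pipeline
cario synth --out cohort/ --seed 7         # render a cohort to TIFF/CSV
cario oct --bscan b.tif --pitch 5 --cols 16:48 --out oct.csv
```

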