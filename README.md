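# sporesalt

Tools for quantifying how much of the sodium-salt aerosol in the Amazon
basin comes from fungal spores rather than sea salt.

Single-particle electron microscopy of coarse-mode particles (1–3.2 µm)
collected in the central Amazon shows that nearly half are sodium-rich,
and that many of them are fungal spores: carbonaceous particles with
spherical, rod-like or spheroidal morphology, 1–6 µm area-equivalent
diameter, detectable phosphorus, and often ≥3 wt% sodium. `sporesalt`
implements the desk-scale computations behind that finding as a tested
pipeline:

- **`sporesalt.classify`** — rule-based particle typing from CC-SEM/EDX
  composition (atomic→weight fraction conversion, a configurable decision
  list over Na/crustal/S/CNO thresholds, fungal-spore and
  sodium-containing flags, group number fractions with binomial standard
  errors, size distributions).
- **`sporesalt.sodium`** — per-spore sodium mass: w_Na = w_C / r with
  w_C = 0.51 and C:Na mass ratio r = 4 gives the 13% spore sodium
  dry-mass content; spore mass m = (π/6) d³ ρ at ρ = 1 g cm⁻³
  (1 µm³ = 1 pg); size dependence of the Na fraction via Spearman rank
  correlation.
- **`sporesalt.hygro`** — hygroscopic growth factors from hydration
  microscopy: area growth factor as the wet/dry ratio of area-equivalent
  diameters d = 2√(A/π) from segmented ESEM frames, and mass growth
  factor as the wet/dry ratio of integrated optical density
  OD = −ln(I/I₀) (Beer–Lambert) from STXM transmission maps at the oxygen
  edge.
- **`sporesalt.budget`** — apportionment of particulate sodium between
  spores and sea salt on concentration time series:

      f = p·w_s·C_spore / (p·w_s·C_spore + w_ss·C_seasalt)

  with w_s = 0.13, w_ss = 0.30, and p the assumed sodium-rich spore
  fraction (0.70; 0.30/0.50 as sensitivity cases). Seasonal means,
  ×10 spore / ×2 sea-salt uncertainty bounds, percentage of days with
  f ≥ 50%, day/night (06:00–18:00 / 18:00–06:00) distribution splits,
  and per-grid-cell maps.
- **`sporesalt.synthetic`** — generators for every input: particle
  tables with calibrated per-class composition profiles, dry/wet ESEM
  frame pairs and STXM map pairs with known growth factors, and
  lognormal spore/sea-salt concentration series with a diurnal spore
  cycle and wet-season sea-salt scavenging.

## Worked example

```sh
sporesalt simulate particles --n 2000 --seed 11 --out demo/particles.csv
sporesalt classify --particles demo/particles.csv --out demo/results.csv
sporesalt fractions --particles demo/particles.csv --results demo/results.csv
```

```
composition_class  fraction  standard_error    n
          na_rich  0.471820        0.011566 1863
             dust  0.256575        0.010119 1863
            other  0.199678        0.009262 1863
          sulfate  0.041331        0.004612 1863
     carbonaceous  0.030596        0.003990 1863
```

2000 particles were drawn from the default coarse-mode mixture (48%
sodium-rich); 137 grid-edge particles were excluded before
classification, and the classifier recovers the sodium-rich fraction as
47.2% ± 1.2% — within binomial sampling error of the configured value.
The `other` class is mostly fungal spores whose sodium content stays
below dominance (spores are flagged separately via `is_fungal_spore`).

```sh
sporesalt simulate series --n-days 180 --hourly --seed 1 --out demo/series.csv
sporesalt budget --series demo/series.csv
```

```
mean sodium fraction: 72.4% (20-97%)
  p_rich=0.3: 57.5%
  p_rich=0.5: 66.8%
  p_rich=0.7: 72.4%
days with fraction >= 50%: 84.4%
window   median      q25      q75      min      max    n
 night 0.827297 0.687144 0.914961 0.089525 0.993377 2160
   day 0.705462 0.523397 0.843252 0.046860 0.986841 2160
```

On this synthetic wet season, spores supply 72% of sodium on average
(bounds from ÷10/×10 spore and ×2/÷2 sea-salt mass scalings), the mean
fraction rises monotonically with the assumed sodium-rich spore
fraction, f ≥ 50% on 84% of days, and the nighttime spore enhancement
pushes the night median fraction above the daytime one.

Growth factors from imagery:

```sh
sporesalt simulate hydration --gf 2.4 --out demo/pair
sporesalt hygro area --dry demo/pair/dry.tif --wet demo/pair/wet.tif
# gf_area=2.3918 (area ratio 5.7207) at RH 30->94%
```

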