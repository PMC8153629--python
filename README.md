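# nemri

Quantitative analysis of SPIO-loaded nano-emulsion (NE) contrast agents:
dynamic-MRI pharmacokinetics, T2\* relaxometry of targeted plaque, ESR spin
quantification, and hemolysis-based antioxidant metrics — validated
end-to-end on synthetic phantoms with known ground truth.

## The problem

Oil-in-water nano-emulsions loaded with superparamagnetic iron oxide
(SPIO) act as T2\*-shortening MRI contrast agents. Because the oil core
keeps water away from the iron, the agent's longitudinal relaxivity is
almost zero (r1 ≈ 0) while its transverse relaxivity is large
(r2\* ≈ 45 mM⁻¹·s⁻¹), so tissue accumulation changes only R2\*. This makes
the liver signal of a dynamic spoiled-GRE (FLASH) acquisition a clean
readout of blood clearance:

    S(t)      = M0 · sin α · exp(−TE · (R2*(0) + r2*·C(t)))
    S_norm(t) = S(t) / S(0) = exp(−TE · r2*·C(t))
    C(t)      = −ln S_norm(t) / (TE · r2*)
    C(t)      = Cmax (1 − e^(−τt))        →   t1/2 = ln 2 / τ

The pipeline implements that chain — including optical-flow tracking of
the liver ROI through respiratory motion, session fusion around the
injection gap, and a Levenberg–Marquardt fit of the first-order
accumulation model — plus three companion analyses:

* **T2\* mapping** of atheromatous plaque from multi-echo GRE magnitude
  data: SNR gate (threshold 4), through-slice field-gradient (sinc)
  correction, mono-exponential voxel fits, exclusion of T2\* > 30 ms, and
  slice means.
* **ESR spin quantification**: double integration of first-derivative
  spectra against a through-origin calibration (5×10⁻¹⁰–10⁻⁷ mol/g), and
  resonance arithmetic g = hν/(μ_B·B).
* **KRL hemolysis reduction**: T50% extraction, percent change versus
  control, Trolox equivalents.

No in-vivo data are shipped; the `nemri.phantom` module generates every
input (with Rician noise, smooth respiratory deformation, through-slice
gradients, derivative lineshapes, logistic hemolysis kinetics) alongside
its ground truth, so every stage is tested quantitatively.

## Worked example

```sh
python analysis/01_simulate_phantoms.py   # writes results/simulated/
python analysis/02_halflife_recovery.py
```

The second script runs 20 motion-corrupted, noisy (liver SNR 30) dynamic
series with true half-lives from 5 to 140 min through the full tracked
pipeline and prints:

```
20 series -> results/halflife_recovery.csv
median |t1/2 error|: 0.57%
  true t1/2      5 min: median error 0.32%
  true t1/2     15 min: median error 0.39%
  true t1/2     60 min: median error 1.57%
  true t1/2    140 min: median error 0.85%
noiseless pipeline error: 4.74e-15 (relative)
```

i.e. the blood half-life of a formulation observed for ~50 min
post-injection is recovered with sub-percent median error; a noiseless,
motion-free series round-trips to machine precision. The remaining
drivers (`03`–`05`) report T2\* map accuracy (RMSE ≈ 2% of truth at SNR
50; the sinc correction cuts the RMSE under a 2 µT/mm gradient by 86%),
ESR recovery of a 1.7×10⁻⁸ mol/g sample (exact noiseless, ±uncertainty at
5% spectral noise), and the KRL metrics (+104.63% / −10.95% T50 changes,
44.62 mg/g Trolox equivalent recovered).

The same stages are available as a CLI:

```sh
nemri simulate --seed 1 --out sim/
nemri fit-halflife --series sim/dynamic.nii.gz --roi sim/liver.nii.gz --out fit.json
nemri t2star-map --vol sim/multiecho.nii.gz --out t2.nii.gz --stats stats.csv
nemri esr-quant --sample sample.csv --refs refs/ --out esr.json
nemri krl --sample s.csv --control c.csv --out krl.json
nemri run-all --seed 1 --out results/run
```

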