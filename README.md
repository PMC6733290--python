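# lyoglass

Analysis toolkit for the molecular mobility and structure of **lyophilised
(freeze-dried) protein formulations** — the amorphous protein/sugar solids
used to stabilise biologics such as BSA- or monoclonal-antibody-based
products.  It is written for formulation scientists who characterise these
solids with variable-temperature terahertz time-domain spectroscopy
(THz-TDS), FTIR, CD and solid-state NMR, and who want the data-analysis
chain — not the instruments — in reproducible, tested code.

## What it computes

**Glass-transition analysis from THz-TDS.**  The absorption coefficient of
an amorphous solid at 1 THz grows linearly with temperature, with slope
changes at the onset of local (Johari–Goldstein β-relaxation) and
cooperative (α-relaxation) mobility.  From a reference/sample waveform pair
the package extracts the optical constants of a pellet of thickness *d*
via the thick-slab transfer-function inversion

    n(ω) = 1 + c·|φ(ω)| / (ω·d)
    α(ω) = −(2/d) · ln[ |H(ω)| (n+1)² / (4n) ]

and fits α(1 THz) vs *T* with an exhaustive three-segment least-squares
segmentation.  The transition temperatures are line intersections:
**T<sub>g,β</sub>** (regions 1/2) and **T<sub>g,α</sub>** (regions 2/3).
A region-3 slope significantly below region 2 is classified as
**confinement** — the protein trapped in its excipient matrix above
T<sub>g,α</sub> — and two heating cycles can be compared for hysteresis.

**Secondary structure from FTIR.**  The amide-I band (1600–1700 cm⁻¹) is
processed by excipient subtraction anchored at 851 cm⁻¹, area
normalisation, a Savitzky–Golay second derivative over 14 cm⁻¹, a
ten-Gaussian band fit and centre-based class assignment; the per-class area
shares give % α-helix, β-sheet, turn and random coil.

**CD mean residue ellipticity.**  [θ] = θ_obs / (l·c·n) with the path
length *l* in mm, molar concentration *c* and residue count *n*
(583 for BSA, 1330 for the IgG1 antibody), plus a qualitative
helix-rich / sheet-rich signature classifier.

**ssNMR phase homogeneity.**  Inversion-recovery
M(t) = M₀(1 − 2A·e^(−t/T₁)) and spin-lock decay
M(t_SL) = M₀·e^(−t_SL/T₁ρ) fits for the protein (165–185 ppm) and sugar
(67–102 ppm) signals; equal relaxation times indicate a homogeneous mixture
on ~20–50 nm (T₁) and ~2–5 nm (T₁ρ) length scales.

**Synthetic data.**  Every modality has a generator with known ground truth
(`lyoglass.synthetic`), including a slab-transmission forward model that is
the exact inverse of the THz extraction — so the whole chain is testable
without instrument data.

## Worked example

Simulate a noisy absorption–temperature series for the F2-like formulation
(1.1 mM BSA, 25 mM histidine-HCl, 265 mM sucrose; generator truth
m = 0.021/0.054/0.023 cm⁻¹ K⁻¹, transitions 219 K and 339 K) and refit it:

```sh
lyoglass simulate temperature-series --label F2 --noise-sd 0.05 --seed 3 --out demo
lyoglass transitions --in demo/temperature_series.tsv
```

```json
{
  "slopes": [0.02108, 0.05434, 0.02256],
  "tg_beta_k": 219.36,
  "tg_alpha_k": 339.91,
  "mobility_class": "confined",
  "weighted": true
}
```

The three fitted slopes match the generator truth to the third decimal,
both transition temperatures are recovered within 1 K despite the noise
(SD 0.05 cm⁻¹, three replicates), and the flat region-3 slope relative to
region 2 produces the *confined* call — the high-temperature absorption
plateau that distinguishes protein formulations trapped in a rigid
excipient scaffold from those whose mobility keeps increasing.

The same library surface is available in Python (`lyoglass.transitions`,
`lyoglass.thz`, `lyoglass.ftir`, `lyoglass.cd`, `lyoglass.nmr`), and
`lyoglass run` orchestrates all stages for one formulation behind a
residual-moisture QC gate (< 2.5 % w/w) into a JSON report.

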