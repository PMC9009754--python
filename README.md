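# thzshrink

Wavelet shrinkage for recovering the resonant absorption fingerprints of
molecular crystals from rough-surface-scattered terahertz reflectivity.

## The problem

Reflection-mode THz time-domain spectroscopy is the natural choice for
stand-off chemical identification, but two effects routinely bury the
characteristic low-frequency vibrational resonances of crystalline
solids (e.g. α-lactose monohydrate at 0.53, 1.2, 1.38 THz;
4-aminobenzoic acid, PABA, at 0.6, 0.8, 1.29, 1.54 THz):

* **rough-surface scattering** — for a surface with RMS height σ
  illuminated at incidence angle θᵢ, the Kirchhoff approximation
  predicts the specular power reflectivity decays from its Fresnel
  baseline |r|² by the Rayleigh factor,

      |ρ(f)|² = |r|² · exp(−4k²σ²cos²θᵢ),   k = 2πf/c,

  wiping out the high-frequency end of the band; the Fraunhofer
  criterion σ ≥ λ/(32 cos θᵢ) marks the wavelengths significantly
  distorted;
* **phase ambiguity** — without a reliable reflection phase, the
  extinction spectrum is unavailable and one works instead with the
  negative derivative −d|ρ(f)|²/df, in which each absorption dip
  appears as a localized antisymmetric swing — but differentiation
  amplifies noise and scattering artifacts.

`thzshrink` implements a wavelet-shrinkage pipeline that retrieves the
resonance positions from that derivative:

1. **MODWT pyramid** — a maximal overlap (undecimated, shift-equivariant)
   discrete wavelet transform with least-asymmetric LA(8)/`sym4` filters,
   J = 6 levels, circular boundaries;
2. **zero-phase alignment** — level-j wavelet coefficients are circularly
   advanced by |2^{j−1}(L−1) + ν| (ν the LA phase parameter, −3 for
   LA(8)) so wavelet-domain features sit at the frequencies they belong
   to;
3. **level selection by second-order total variation** — levels whose
   TV₂ fraction exceeds 25% (noise/artifact-dominated fine scales) or
   falls below 0.2% (baseline-only coarse scales) are excluded;
4. **interval thresholds + hard shrinkage** — per kept level, the
   threshold τⱼ is the largest coefficient magnitude inside two 200-GHz
   "noise and scattering" windows centered at 0.3 and 1.7 THz, where no
   resonances live; coefficients below τⱼ are zeroed (Donoho-style hard
   thresholding with an interval-derived, level-wise threshold);
5. **reconstruction + peak calling** — advances are reversed, the
   inverse pyramid is applied, and strict local maxima above a 5%
   prominence floor are reported as resonance candidates.

The package also contains the Kirchhoff scattering model (`scatter`):
RMS-height estimation by a log-domain linear fit of ln|ρ|² against k²,
and the Fraunhofer threshold — plus a seeded synthetic-spectrum
generator (`synth`) that emulates the measurement: Fresnel baseline ×
Rayleigh roll-off × Lorentzian absorption dips × sharp water-vapor
lines × an off-specular loss lobe, with additive white noise.

## Worked example

Simulate a PABA pellet pressed against grit-220 sandpaper (σ = 15 µm,
θᵢ = 35°, 30 dB SNR, water vapor on) and run the identification
pipeline:

```
$ thzshrink simulate --preset paba:grit220 --seed 7 --out paba.csv
wrote 321 samples (0.2-1.8 THz) to paba.csv
$ thzshrink identify --input paba.csv --out run/
peak 0.545 THz  amplitude 2.507
peak 0.585 THz  amplitude 4.548
...
peak 1.275 THz  amplitude 2.747
...
peak 1.525 THz  amplitude 1.652
13 peak(s); artifacts in run
```

All four PABA modes are recovered: the maxima at 0.585, 0.785, 1.275
and 1.525 THz sit within 0.02 THz of the true centers 0.6, 0.8, 1.29
and 1.54 THz (a derivative-based locator peaks slightly below the line
center, by about 0.3 of the linewidth). The 1.29 and 1.54 THz modes are
invisible in the raw derivative — they are the ones the shrinkage
recovers from under the scattering roll-off. Remaining small maxima
(0.545, 0.74, 1.085, 1.15, 1.395 THz) are residues of the sharp
atmospheric water-vapor lines the generator injects.

The same spectrum also yields the surface roughness:

```
$ thzshrink roughness --input paba.csv
sigma_um: 14.94
...
fraunhofer_freq_GHz: 765.5
```

i.e. the log-domain Kirchhoff fit recovers the generating σ = 15 µm to
within the noise, and flags frequencies above ~0.77 THz as
scattering-distorted.

From Python, the same run is:

```python
from thzshrink import run_identify, preset

result = run_identify(preset("paba", 220, seed=7))
print(result.peaks.to_frame())
```

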