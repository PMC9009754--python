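# Methods

This note records the models implemented in `thzshrink`, the defaults
and why they were chosen, the numerical decisions that were genuinely
open, and what the synthetic fixture does and does not establish.

## Signal model

The observable is the power reflectivity |ρ(f)|² of a pressed
molecular-crystal pellet, sampled uniformly (step δf) over an analysis
band (f₁, f₂). Phase ambiguity in reflection geometry rules out
extinction retrieval, so resonance positions are read from the negative
derivative V₀(f) = −d|ρ(f)|²/df, computed by central differences in the
interior and one-sided differences at the ends (the lowest-order
unbiased interior estimate; forward differences are reserved for the
TV₂ statistic, which is defined through them). Each absorption dip
produces an antisymmetric swing in V₀ whose positive lobe peaks
*below* the line center by ≈ 0.29 × FWHM for a Lorentzian profile —
for linewidths of 25–40 GHz this bias is 7–12 GHz, inside the 0.02 THz
accuracy conventionally quoted for derivative-based THz peak location.
Sub-bin (5 GHz) localization is therefore not attainable by any
derivative-based locator; the pipeline's matching tolerance is
0.02 THz throughout.

## MODWT pyramid

The maximal overlap DWT is used rather than the decimated DWT because
shift equivariance is essential: thresholds are read from fixed
frequency intervals, so wavelet-domain features must not move with the
sampling phase. Forward and inverse pyramids use circular convolution
exactly as written in the signal model above (`mod N` boundaries). An
optional mirror-extension pre-pad is available to suppress wrap-around
artifacts on non-periodic spectra but is **off** by default; the
default analysis is the plain circular transform.

Filters are the least-asymmetric (symlet) family LA(L),
L ∈ {8, …, 20}, defaulting to LA(8) = `sym4` (four vanishing moments:
polynomials up to cubic order pass losslessly into the scaling band).
Coefficients come from PyWavelets' orthonormal tables, rescaled by
1/√2 to MODWT normalization, with the wavelet filter derived from the
scaling filter by the quadrature-mirror relation; the pair is validated
at load time against Σh = 0, Σg = 1, Σh² = Σg² = ½ and even-shift
orthogonality (tolerance 1e−10) rather than trusted.

Depth J = 6: at δf = 5 GHz, level j responds to structure at scale
2^{j−1}·δf, so levels 3–5 (20–80 GHz) straddle typical crystalline
linewidths while level 6 carries only baseline; deeper levels add
nothing for resonance retrieval. A finer δf requires a deeper J for the
same physical scales — J is configurable for that reason.

### Zero-phase alignment

LA filters are nearly linear-phase. The level-j wavelet coefficients
are circularly advanced by

    |2^{j−1}(L−1) + ν|,   ν(LA8/12/16/20) = −L/2+1,
                          ν(LA10/18) = −L/2,  ν(LA14) = −L/2+2,

which for LA(8) gives 4, 11, 25, 53, 109 at levels 1–5. This amount
equals the energy centroid of the effective level-j wavelet filter to
within one sample (verified numerically in the test suite: an isolated
bump's aligned coefficients peak within two samples of the bump at
every usable level). The sign of ν matters: the variant
2^{j−1}(L−1) − ν (advances 10, 17, … for LA(8)) cannot align level 1
under *any* length-8 filter, since an advance of 10 exceeds the
filter's 8-sample support; some published statements of the rule differ
in this sign convention. Scaling coefficients are never advanced — they
are consumed only by the inverse transform, after the advances have
been reversed. Alignment and its reversal are exact circular shifts,
hence bit-identical mutual inverses.

## Level selection by second-order total variation

For aligned level-j coefficients restricted to the band, with first
differences D₁ and second differences D₂ (unit step),
TV₂,ⱼ = Σ|D₂| summed over f ∈ [f₁, f₂ − 2δf]. Levels are kept when
their share of the total TV₂ lies within [0.2%, 25%], inclusive on both
ends (the bounds are stated as open elsewhere; inclusive keeps the
measure-zero edge case and is configurable). Rationale: sharp
scattering artifacts and water-vapor lines concentrate curvature at
fine scales (fraction > 25%), the smooth baseline at the coarsest
(< 0.2%); per-level *energy* does not separate the levels this way —
a qualitative contrast the test suite asserts on all four roughness
presets. The level-J scaling band is outside the rule: it carries the
baseline and is never excluded. TV₂ is computed band-restricted (the
band endpoints define the sum); whether one normalizes over the full or
cropped axis is immaterial to the kept set when the band covers the
axis, and band-restricted is what is implemented. A fully featureless
(all-zero) band yields uniform fractions so a null input flows through
to an empty peak list instead of an error.

## Interval thresholds and hard shrinkage

For each kept level, τⱼ is the largest |coefficient| inside two 200-GHz
windows centered at 0.3 THz and 1.7 THz — band regions that contain no
resonances of the target materials, so whatever lives there at a given
scale is noise or scattering artifact. Alignment is a precondition:
without it the windows would address coefficients belonging to shifted
frequencies. Windows are clipped to the band with a logged warning;
only if every window vanishes is the run aborted. Shrinkage is hard:
kept-level coefficients survive verbatim iff |W| ≥ τⱼ (so the
window-maximum coefficient itself always survives — a property of the
rule, visible as a small residue inside the windows); excluded levels
are zeroed wholesale (reconstruction needs full-length arrays at every
level); the scaling band passes through untouched. Soft and
universal/SURE thresholds are deliberately out of scope: fine-scale
noise estimates are exactly what scattering artifacts defeat here.

After shrinkage the advances are reversed and the inverse pyramid is
applied; resonance candidates are strict positive local maxima with
prominence ≥ 5% of the reconstruction's in-band dynamic range
(scipy `find_peaks`). The 5% floor is a package choice — no principled
rule exists for it — and is configurable; hard-threshold amputation of
a feature's coefficient tails rings at the kept scales, and lobes of
that ringing occasionally clear the floor, so small satellite maxima
around strong features (offsets ≈ half the level-5 oscillation period,
~0.08 THz) should be expected and not read as resonances.

## Kirchhoff scattering model

Specular reflectivity |ρ(f)|² = r² exp(−4k²σ²cos²θᵢ) with k = 2πf/c
(c = 299.792458 µm/ps; f in THz, σ in µm; angles are degrees at the
interface, radians internally). Because ln|ρ|² is linear in k², σ is
estimated by ordinary least squares of ln|ρ|² on k²:
slope = −4σ²cos²θᵢ, intercept = ln r²; the fit is convex and
deterministic, so no nonlinear refinement is performed by default.
Samples below 1% of the in-band maximum are dropped to keep the noise
floor from biasing the log fit. A non-negative slope returns σ = 0 with
a warning diagnostic. Uncertainty is first-order propagation of the
slope standard error. The Fraunhofer threshold is λ_th = 32σcosθᵢ,
f_th = c/λ_th (infinite for σ = 0); on noiseless synthetic roll-offs
the fit inverts the generator to better than 0.1% for σ between 15 and
93 µm, and the median error under 1% multiplicative noise is well below
2% over seeded replicates.

## Synthetic fixture

No measured spectra are distributed, so all end-to-end results are
computed on the generator, which multiplies: Fresnel baseline
r² (default 0.3) × Rayleigh roll-off (σ per sandpaper-grit preset:
lactose 16/26/44/93 µm and PABA 15/22/40/91 µm for grits
220/120/80/40, θᵢ = 35°) × Lorentzian dips at the material's published
line centers × Gaussian water-vapor dips (0.557, 0.752, 1.097, 1.163,
1.41 THz; FWHM 5 GHz; depth 0.5) × an off-specular loss lobe; then adds
white Gaussian noise with σ_noise = max|ρ|²·10^(−SNR/20) (default
30 dB) and floors the result at 10⁻³·r². Grid: δf = 5 GHz over
0.2–1.8 THz. Everything is driven by an explicit seed.

Line depths and widths are fixture choices (the materials' absolute
dip depths are not tabulated anywhere): lactose (0.53, 0.8, 25 GHz),
(1.2, 0.15, 15 GHz), (1.38, 0.6, 30 GHz) — the 1.2 THz mode
deliberately the weakest and narrowest of its set — and PABA
(0.6, 0.5, 30), (0.8, 0.6, 30), (1.29, 0.5, 35), (1.54, 0.35, 40 GHz).
Lorentzian profiles are the standard choice for crystalline THz
resonances; a Gaussian option exists. The off-specular lobe is a
*heuristic*, not a physical-optics result: Gaussian in the detection
offset with angular width 0.2/(kσ) rad, so rougher surfaces and higher
frequencies collapse first — reproducing the qualitative
amplitude-and-bandwidth loss of off-specular detection.

What the fixture does not emulate: structured (non-white) scattering
artifacts, which in real measurements dominate the band-edge threshold
windows and thereby raise τⱼ above everything except true resonances.
With white noise the windows see the same statistics as the rest of the
band, so occasional noise excursions survive shrinkage and the
suppression of weak modes (the lactose 1.2 THz case) is a
noise-realization-dependent event (~60% of realizations at 30 dB)
rather than deterministic; benchmark verdicts about suppressed modes
are therefore taken by majority over seeded replicates. The water-vapor
injector is one grid bin wide (FWHM = δf), i.e. spectrally
under-resolved; its energy spreads across all wavelet scales instead of
concentrating at the finest, which is why small water-line residues
survive level exclusion in a way resolved lines would not. Passing
tests on this fixture demonstrate the pipeline's mechanics and its
behavior under the stated noise model — not performance on measured
spectra.

## Degenerate inputs and tie-breaks

Non-uniform axes, bands outside the axis, negative reflectivity, and
depths J > ⌊log₂N⌋ are rejected with explicit messages. Double
alignment, inversion of aligned coefficients, and threshold windows
wholly outside the band are errors; a window clipped to less than
1 pm of width counts as empty. Flat spectra yield an empty peak list,
not an error. When replicate votes tie, the lowest-frequency line is
reported. Pipeline runs are bit-reproducible from (input, config,
seed).
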