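# Methods

## Model

The package implements a microdosimetric kinetic model of clonogenic
survival in which the linear-quadratic terms of an ion exposure are
dose-mean values of a per-event biological effect over the lineal-energy
spectrum d(y):

    α  = Σᵢ (α₀ + β₀·z_d(yᵢ)) · c(yᵢ) · wᵢ
    β  = β₀ · [Σᵢ c(yᵢ) · wᵢ]²

with wᵢ = d(yᵢ)·dyᵢ the dose-probability mass of bin i. z_d and z_n are the
single-event specific energies of the subnuclear domain (radius r_d) and
the whole nucleus (radius R_n): z = K·y/(ρπr²) with K = 0.16022 converting
keV/µm per µm² at ρ = 1 g/cm³ into Gy (1.602·10⁻¹⁶ J over 10⁻¹⁵ kg; stored
to five significant figures). The saturation correction

    c(y) = (1 − e^{−u})/u,   u(y) = (α₀ + β₀·z_d)·z_n + β₀·z_n²

is the non-Poisson (overkill) factor: u is the expected number of lethal
lesions produced by one nuclear traversal, and c discounts lesions formed
in cells that a single event has already killed. c(0) = 1, c is strictly
decreasing, and c ~ 1/u at high y, which produces the characteristic
rise-then-fall of α and RBE with LET while β decreases monotonically from
β₀ (β/β_ref ≤ 1 always, by construction).

The α integrand is evaluated in the expanded form (α₀ + β₀·z_d)·c. The
algebraically equivalent factored form α₀·(1 + (β₀/α₀)z_d) divides by α₀
and is undefined in the purely quadratic limit α₀ = 0; the expanded form is
not. The β expression squares the spectrum-mean of c (the square sits
outside the integral), not the mean of c².

RBE at surviving fraction S uses the closed form

    RBE_S = [α + √(α² − 4β ln S)] / [α_ref + √(α_ref² − 4β_ref ln S)]

and is verified in the test suite against the explicit dose-ratio route
through D(S) = −2·ln S / (α + √(α² − 4β·ln S)), a rationalized root that
stays defined at β = 0.

Model assumptions worth keeping in mind: spherical nucleus and domains,
DNA distributed uniformly over the nuclear volume, population-mean
parameters (no cell-to-cell variability), asynchronized populations,
normoxia, and acute single-fraction exposure. Dose-rate, fractionation,
hypoxia and the high-dose transition to a constant slope are out of scope.

## Parameter chain (all a priori)

| parameter | default / source | units |
| --- | --- | --- |
| γ | built-in: human 3050, rat 2750, Chinese hamster 2700, mouse 2650 | Mbp |
| x_n | built-in: 23 / 21 / 11 / 20 | – |
| p | 2 for healthy or pseudodiploid lines, else x/x_n | – |
| ξ | 4/3 (asynchronized populations; free parameter, no cell-cycle model) | – |
| Γ | γ·p·ξ | Mbp |
| R_n | measured radius; or √(A/π) (sphere) / √(A/π)·3^{−1/3} (volume-matched oblate spheroid, minor axis a third of the equatorial radius); or 3.5 + 0.144·Γ[Gbp] | µm |
| λ | 2 (DNA content of a giant chromatin loop) | Mbp |
| r_d | R_n·(λ/Γ)^{1/3} | µm |
| α_ref, β_ref | photon dose–response; several sets pooled by entry-count-weighted mean | Gy⁻¹, Gy⁻² |
| ȳ_D,ref | 2.3 (γ-rays, MV X-rays) or 4.3 (~200 kV X-rays) | keV/µm |
| β₀ | = β_ref (photon saturation correction ≈ 1) | Gy⁻² |
| α₀ | α_ref − β₀·z_d(ȳ_D,ref) | Gy⁻¹ |
| ρ | 1 | g/cm³ |

Γ is stored in Mbp throughout; the R_n correlation internally converts to
Gbp. The correlation is phenomenological and calibrated on asynchronized
lines with Γ roughly between 5 and 17 Gbp; outside that window the package
warns (`ExtrapolationWarning`) rather than fails, since the boundary is a
soft calibration range, not a physical limit.

α₀ < 0 is rejected (`InconsistentParametersError`): it means the photon set
cannot be decomposed into non-negative y → 0 limits, i.e. β₀·z_d(ȳ_D,ref)
exceeds α_ref. Two bundled lines illustrate the edge: C3H10T1/2, where one
printed reading of β_ref (0.389 Gy⁻²) contradicts the printed α/β ratio and
would trigger exactly this error — the fixtures use the ratio-consistent
0.0389 Gy⁻² and keep the other reading on record; and U-251MG, whose
unusually low α_ref (0.031 Gy⁻¹, α/β ≈ 0.56 Gy) genuinely admits no
non-negative α₀ at ȳ_D,ref = 2.3 keV/µm. Its geometric parameters derive
normally; building the full parameter set raises the documented error
instead of silently clamping.

## Spectra and numerics

Spectra live on a canonical log-uniform grid, 50 bins per decade from 1e-2
to 1e7 keV/µm (450 bins), the standard scoring convention for simulated
microdosimetric distributions. Each bin's representative lineal energy is
the geometric mean of its edges (unbiased for log-uniform bins); weights
are probability *masses* d(y)·dy, which makes every model integral a plain
weighted sum, exactly reproducible on the stored grid without interpolation
or quadrature-rule choices. File input with arbitrary y values is snapped
mass-conservingly into the containing bin. Discretization is validated two
ways in the test suite: closed-form moments of the generators are
reproduced to 0.1%, and halving the bin width moves the dose-mean lineal
energy by less than 0.05%.

c(u) is computed with `expm1`; below u = 1e-8 the series 1 − u/2 + u²/6 is
used to avoid cancellation. Degenerate inputs (all-zero spectra, zero total
mass, support below the grid floor) raise typed errors rather than
returning NaNs.

## Synthetic spectrum generators

The generators stand in for Monte Carlo radiation transport and are
deliberately idealized:

* **delta** — all dose in one bin; models a reference photon exposure via
  its representative dose-mean lineal energy. Resolution is one bin
  (~4.7% width), which is why photon self-consistency checks carry a 1.5%
  tolerance rather than machine precision.
* **track-segment** — straight track of constant LET through a spherical
  site under µ-randomness: chord-length geometry gives
  d(y) = 3y²/y_max³ on [0, (3/2)·LET], hence ȳF = LET and ȳD = (9/8)·LET
  exactly. It omits delta-ray escape, energy-loss straggling, track ends
  and secondary fragments, all of which broaden real spectra — so
  model-level conclusions drawn from it (e.g. the position of the RBE
  maximum in LET) are qualitative, not beam-specific.
* **log-normal** — frequency distribution log-normal in y, converted to
  dose weighting via d(y) ∝ y·f(y); ȳD = exp(µ + 3σ²/2) in closed form.
  Used as an analytic fixture with smooth, realistic spectral width.

Passing tests on these generators demonstrates the correctness of the
model arithmetic and its discretization, not agreement with any measured
beam: real microdosimetric spectra must be supplied as files.

## Survival-entry screening

The batch filter reproduces the standard exclusion rules for benchmarking
against tabulated in-vitro ion survival data, applied in order with reason
codes: malformed records; spread-out-Bragg-peak exposures (not comparable
with monoenergetic calculations); ion energy below 1 MeV/n (partial cell
traversal, large dosimetric uncertainty); synchronized populations; no
linear-quadratic set with positive photon reference terms; no set with a
non-negative ion β; and entries whose only set lists α = 0 with a large β.
"Large" is not defined by any source, so the threshold is exposed as a
parameter defaulting to 0 (any positive β alongside α = 0 counts), which
reproduces the intent without inventing a cutoff.

## Problem sizes and design choices

The bundled benchmark covers 14 cell lines (4 rodent, 10 human) whose
printed nucleus/domain radii the parameter chain reproduces at table
precision (half-up rounding: 1 decimal for R_n, 2 for r_d). Property suites
use track-segment sweeps of ~40 LET points over 1–10⁴ keV/µm per cell line
and 1000 seeded random draws for the RBE identity; the full suite runs in a
few seconds. Sensitivity to binning was checked up to 500 bins/decade.

Open choices resolved here: ȳ_D,ref defaults to 2.3 keV/µm for every
bundled line (the reference radiation of each source experiment is not
recorded per line; 4.3 is switchable via `yD_ref_keV_um`); spectra carry no
LET of their own — LET is opaque metadata attached to predictions, never
recomputed from the spectrum; and the spectrum file format (two-column
delimited text with `#` comments) is a repository convention, since
transport codes export many dialects.
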