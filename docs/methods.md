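# Methods

This note documents the models implemented in `parcf`, their assumptions,
the tunable parameters that matter, and what the synthetic-data tests do and
do not establish.

## Correction factors

A correction factor is the ratio of real-sky to clear-sky PAR for one grid
cell and one period (month, season or year):

    CF = PAR_real / PAR_clear .

CFs are computed from energy-units (W m⁻²) PAR on a common geographic grid.
Conventions, all configurable:

- **Quantum ↔ energy conversion.** Ocean-style PAR arrives in
  mol photon m⁻² day⁻¹ and is converted with a single factor derived from
  the Planck relation at the 550 nm PAR band midpoint:
  1 mol photon m⁻² day⁻¹ = N_A·h·c/(550 nm)/86400 s ≈ 2.5174 W m⁻². The
  conversion is exactly linear and exactly invertible. Using one reference
  wavelength for a broadband flux is an approximation shared by standard
  PAR practice; it cancels in any CF whose numerator and denominator use
  the same convention.
- **Aggregation.** Per-cell arithmetic means: 3-hourly → daily → calendar
  month. Cells missing in some timesteps are averaged over the available
  ones; cells missing everywhere stay missing. Season composites
  (DJF/MAM/JJA/SON) are equal-weight means of the three monthly grids, with
  December assigned to the following year's DJF. The chain is exactly
  mean-preserving when coverage is complete.
- **Merge.** Land product wins where both land and ocean values exist;
  disagreements beyond 5% relative are logged, never raised. The ocean grid
  is converted to energy units first.
- **Polar-night guard.** CF is undefined (masked) where monthly clear-sky
  PAR < 1 W m⁻²; this avoids ratio blow-up in polar winter. CF > 1
  (broken-cloud enhancement, retrieval mismatch) is physical enough to
  retain: values are kept, flagged in logs, never clipped.
- **Statistics.** The representative regional value is the histogram
  **mode** (fixed 0.01-wide bins over [0, max], ties to the higher bin),
  because CF distributions are typically skewed; 0.01 matches the
  two-decimal precision CFs are reported at. The "90% interval" is the
  empirical 5th–95th percentile range of cell values (linear-interpolation
  quantiles). Inter-annual variability is the per-cell sample SD (ddof 1)
  over years with ≥ 2 valid years.

## Clear-sky model

The built-in clear-sky reference is deliberately minimal — the scientific
content of the package is the CF procedure, not radiative transfer:

    PAR = S_PAR · τ^(1/max(cos θz, 0.02)) · cos θz ,

with S_PAR = 531 W m⁻² (the ~39% PAR share of a 1361 W m⁻² solar constant)
and broadband transmittance τ = 0.75 by default. Solar geometry uses the
Cooper declination approximation and the hour angle from solar noon; solar
time is used directly (no longitude/time-zone shift — monthly means are
insensitive to this). The airmass exponent is the plain secant with a 0.02
floor, not a refraction-corrected formula; this model is a stand-in, and
any externally modeled hourly/monthly PAR table or spectrum can be
substituted through the readers (`read_external_spectrum`, monthly CSV
tables). Two calendars are carried (a non-leap and a leap year).

The spectral form distributes broadband PAR over 300–700 nm by a normalized
shape: flat per-nm weights over 400–700 nm with a linear UV tail reaching 0
at 300 nm. The shape integrates to exactly 1 over 400–700 nm (rectangle sum
at 1 nm), so the spectrum's band integral equals the broadband value by
construction. This neutral default is for plumbing and testing; real
kinetics work should supply a measured or modeled spectrum.

**Latitude polynomial.** Monthly clear-sky PAR sampled every 5° of latitude
is interpolated to arbitrary latitudes with an ordinary least-squares
degree-4 polynomial per month (predictions floored at 0, evaluation outside
the fit domain is an error; in-sample RMSE is stored). Measured performance
against held-out 2.5°-offset latitudes: maximum absolute error ≤ 0.7% of
the peak directly modeled value. Note the quartic cannot chase the
monthly-PAR → 0 tail at polar-winter latitudes, so *pointwise relative*
error near those latitudes is large by construction; the fit is adequate on
the scale of the field, which is how it is used (a denominator only where
clear-sky PAR is above the 1 W m⁻² floor).

## Synthetic satellite products

The emulator states a world in which the pipeline's answer is known:

    real-sky PAR = clear-sky PAR × T(lat, day) × (spatial lognormal noise).

The deterministic profile T carries three features of global cloud
climatology: a Gaussian ITCZ depression (default depth 0.25, σ = 10°)
centered at 5°N (the ITCZ sits north of the equator on annual average);
non-seasonal mid-latitude storm-track bands (depth 0.12, σ = 12°, centered
at ±50°) representing the persistent cyclone-belt cloudiness; and a
high-latitude winter depression (depth 0.45) ramping poleward of 40° with a
cosine annual cycle peaking at the local winter solstice. The combination
puts the transmittance maximum near 20°S and the strongest seasonality
above 40°N. Defaults give T ∈ [0.42, 0.89].

The noise is one multiplicative lognormal field per day: a unit-variance
Gaussian random field with an exponential correlogram (correlation length
5°, synthesised spectrally via the (1 + (kL)²)^(−3/2) power spectrum),
exponentiated with log-sd `noise_sd` (default 0.1) — median 1, so the
field's median tracks the deterministic profile. Each day's field is seeded
`seed + day_of_year`: days are independent, reruns bit-identical, and the
station simulator sees exactly the fields the gridded products used. All
3-hourly slots of a day share the day's field. Fields are clipped to
(0, 1]. Land/ocean designation is a binary mask; the default synthetic mask
is simple longitude-band continents, enough to exercise the merge.

**What a green recovery test establishes.** A monthly CF is a ratio of
monthly-mean PAR values, so the quantity it estimates is the
*clear-sky-weighted* monthly-mean transmittance actually applied — exposed
as `monthly_mean_transmittance(weights=...)`. Against that comparator the
pipeline agrees to machine precision, which validates the unit round-trip,
merge, aggregation and masking end to end. Against the *plain* day-mean
transmittance, agreement is within 0.02 equatorward of 40° but degrades at
winter high latitudes, where clear-sky PAR changes strongly within the
month; and the noise-free deterministic profile is recovered only in the
many-day limit (30 daily fields of log-sd 0.1 leave per-cell sampling error
of sd ≈ 0.1/√30 ≈ 0.018). The emulator does not mimic retrieval artifacts
(LUT quantization, diurnal sampling gaps, coastline geometry), so green
tests say nothing about those.

## Station validation

Measured monthly station PAR is paired with (a) modeled clear-sky PAR and
(b) clear-sky PAR × CF at the station's nearest grid cell (multi-year mean
CFs in realistic use). The report is an OLS regression of **measured on
predicted** (direction documented, configurable by swapping arguments),
with RMSE and mean bias of (predicted − measured). Under any mean
transmittance < 1 the uncorrected prediction is biased high; a calibrated
CF removes the bias — on noise-free synthetic stations exactly (slope 1,
r² 1, RMSE 0).

## Direct photolysis

The depth-averaged pseudo-first-order rate constant of a dissolved
photoreactive compound:

    k_dir = ln10 · Σ_λ I₀,λ · ε_λ · Φ_λ · S(K_d,λ, z) · Δλ        [s⁻¹]
    S(K_d, z) = (1 − 10^(−K_d·z)) / (ln10 · K_d·z)

with I₀,λ in mmol photons cm⁻² s⁻¹ nm⁻¹, ε_λ in M⁻¹ cm⁻¹, Φ_λ in
mol (mol photons)⁻¹, decadic K_d in cm⁻¹, z in cm, Δλ = 1 nm on the shared
300–700 nm grid. The unit bookkeeping is exact — the mmol→mol factor
(10⁻³) cancels the litre→cm³ factor (10³) inside the molar absorptivity —
verified against an independent single-wavelength unit-analysis oracle.
Assumptions: the compound's own contribution to K_d is negligible relative
to dissolved organic matter; the water column is well mixed over z.

Numerical choices: S is evaluated as −expm1(−u)/u with u = ln10·K_d·z and
by its series 1 − u/2 + u²/6 below u ≈ 2.3 × 10⁻⁶ to avoid cancellation;
k_dir is exactly linear in the spectrum, so applying a CF to the spectrum
and multiplying k by the CF are identical to machine precision — that
equivalence is the formal content of applying CFs to reference spectra,
and is asserted in tests.

**Conventions and speciation.** K_d is interpreted as a *decadic*
attenuation coefficient (the ln10 appears accordingly); `kd_convention
= "natural"` divides supplied values by ln10 on ingestion for sources that
report natural-log attenuation. K_d can be supplied as an explicit table or
as a DOC power law K_d,λ = a(λ)·DOC^b(λ) + baseline(λ); the coefficients
are site-specific and must be supplied by the user — the package ships no
numbers presented as authoritative. For an acid with pKa near ambient pH,
only the deprotonated (phenolate) form is counted as photolabile:
k_app = k_dir · α with α = 1/(1 + 10^(pKa−pH)). Half-life t½ = ln2/k_app,
reported in days.

**Lake schedule and distributions.** A holomictic lake mixes top-to-bottom
in winter: the default schedule uses the full mean depth December–March and
the epilimnion depth April–November. Annual k is the day-count-weighted
(leap-aware) mean of monthly k values, each with its month's depth.
Seasonal distributions of daily rate constants (surface mode, S = 1, or at
a fixed depth) are summarised as Tukey boxplot statistics: quartiles,
median, whiskers at the most extreme points within 1.5 × IQR of the box,
and an outlier count — computed for clear-sky and CF-corrected runs, the
latter being the former scaled day-wise by the CF.

## Known limitations

- The clear-sky model has no aerosol/ozone/water-vapor parameterisation,
  no direct/diffuse split, nothing above 700 nm; it exists to be replaced.
- The wavelength-independence of CFs rests on Mie scattering by cloud
  droplets; it is an input assumption, not something the package tests.
- The synthetic cloud world is a stated construction: its noise law
  (lognormal, median 1) is a stand-in, not an inference about any real
  retrieval's error distribution.
- Grids are assumed already geographic (EPSG:4326-style axes); no
  projection handling. Raster I/O is plain-text ESRI ASCII + JSON sidecar.
- Station matching is nearest-cell-center; no sub-cell interpolation.
- The case-study compound and lake shipped in examples are synthetic
  stand-ins (labelled as such); reproducing a specific real compound
  requires its measured ε_λ, Φ, pKa, K_d,λ and reference spectra.
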