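# Methods

## Quantities and geometries

The package computes nuclide-specific organ equivalent dose rate
coefficients for two idealized external environmental exposures of a
pregnant female and her fetus:

* **Ground plane at 0.5 g cm⁻²** — a uniformly contaminated infinite plane
  buried at areal-mass depth 0.5 g cm⁻² in soil, the standard model of
  first-year surface roughness after airborne deposition. Activity per unit
  area; coefficients in Sv s⁻¹ Bq⁻¹ m².
* **Air submersion** — a semi-infinite uniformly contaminated air volume
  (radioactive cloud) over a clean ground. Activity per unit volume;
  coefficients in Sv s⁻¹ Bq⁻¹ m³.

Since the environmental fields are photon fields with radiation weight 1,
equivalent and absorbed dose rate coefficients are numerically equal.

The monoenergetic fetal organ tables (skin, eyes, lungs, heart, kidneys,
liver, stomach, brain, skeleton, total body) and the air-kerma tables at
1 m height are packaged verbatim from their published 3-significant-figure
form, energies in MeV, values exactly as printed, no unit conversion
anywhere. The submersion grid has gaps (no 0.4/0.6/0.8/1.1/1.3/4/5/7/8 MeV
rows); the data layer stores only printed nodes and interpolation bridges
the gaps. A curated per-nuclide summary table (air kerma,
detriment-weighted dose and uterus dose of the mother, fetal total-body
dose) is packaged for the nuclides used in the uterus-surrogate analysis.

## Interpolation

Monoenergetic coefficients are interpolated with the Fritsch–Carlson
monotone piecewise cubic Hermite scheme in a log-linear space: abscissa
log₁₀(E/MeV), ordinate the coefficient itself. Node derivatives use the
Brodlie weighted harmonic mean of adjacent secants (zero at local extrema
and sign changes), which lies inside the Fritsch–Carlson monotonicity
region, so data-monotone segments produce monotone interpolants with no
overshoot and node values are reproduced exactly. Because the underlying
field calculations start at 0.015 MeV, the curve is defined to be exactly
zero below that cutoff; above 10 MeV, and in the gap between the cutoff
and a user table's first node, evaluation is an error rather than an
extrapolation. "Log-linear" is read as log-energy/linear-value — the
standard convention for dosimetric tables; a `y_scale="log10"` switch lets
the alternative reading be compared (it requires strictly positive values
and differs between nodes by well under the tabulation precision for these
smooth tables).

## Decay data and folding

Decay records carry the same content as a nuclear decay-data compilation
entry — discrete photon/electron lines with per-decay yields, continuous
spectra (allowed-shape beta branches, spontaneous-fission photon spectra)
as tabulated yield densities in MeV⁻¹ — in a small documented JSON schema.
Native decay-database formats are not parsed; a converter is the user's
one-time task, which keeps the package download-free. A seeded synthetic
nuclide generator (lines uniform in log-energy, allowed-shape beta
branches `p·W·(Q−T)²` normalized to a sampled yield) provides reproducible
records for tests and demos.

The folding engine evaluates, per organ curve,

* discrete photons: `Σ w_R Y_i d(E_i)`; lines below 0.015 MeV contribute
  exactly zero, lines above 10 MeV are an error;
* continuous photon spectra: trapezoid integral of `Y(E)·d(E)`;
* electrons (lines and beta continua alike): through the effective
  coefficient `d_elec(E_e) = ∫ B(k|E_e)·d(k) dk` with the bremsstrahlung
  kernel `B`, then folded like photons. Electrons have no direct field of
  their own — in these geometries only their bremsstrahlung is
  penetrating. `d_elec` is evaluated on the kernel's electron grid and
  interpolated linearly in `E_e`; `E_e` at or below the photon cutoff
  gives exactly zero.

All integrals use a composite trapezoid on the union of the spectrum grid
and the curve nodes, refined uniformly per interval. The refinement
default is 4000 panels (the scheme requires ≥ 400): at 4000 the result
agrees with a 10⁵-panel brute-force reference to ~10⁻⁷ relative even for
coarse, kinked tabulated spectra, and the cost is negligible. Halving the
panel width moves results by far less than 10⁻⁶ relative.

The default bremsstrahlung kernel is a truncated Kramers-like 1/k
spectrum, scaled on its support `[k_min, E_e]` so the radiated energy
equals `Y_rad(E_e)·E_e` exactly (the anchor value: radiative yield ≈ 0.2 %
for a 1 MeV electron in air). It is an explicit approximation standing in
for measured thick-target spectra, which can be loaded from CSV
(`E_e_MeV,k_MeV,B`); whether soil- or air-medium spectra apply is a
per-geometry configuration choice, not hard-wired. Progeny are never
summed implicitly; the CLI's `--combine` flag performs explicit, documented
branching-factor arithmetic on user-listed records.

Reports: air-kerma normalization divides organ coefficients by the
nuclide's air-kerma rate coefficient (Sv Gy⁻¹); the detriment-weighted
scalar is `Σ_T w_T ḣ_T` with the standard tissue-weight set (sums to 1);
the uterus-surrogate report prints per-nuclide uterus/fetal-total-body
ratios rounded to 2 decimals (raw values retained, zero denominators
flagged, identifiers without table rows — e.g. stable nuclides — skipped).

## Environmental Monte Carlo

`fetodose.envmc` implements a deliberately reduced analog photon engine in
the canonical world: an air cylinder of 500 m radius and 500 m height
(about five mean free paths of 0.6 MeV photons in air) over a 1 m soil
layer; dry air at 1.2·10⁻³ g cm⁻³ and a generic mineral soil at 1 g cm⁻³.
Sources are the buried plane (depth converted from g cm⁻² through the soil
density) or a uniform air volume; the nominal 1000 m cloud height is
clamped to the air layer, which matters little because the top 500 m of a
cloud contributes almost nothing at ground level. Interactions:
photoelectric absorption, free-electron Klein–Nishina Compton scattering
(composition-rejection sampling), and pair production terminating the
photon and emitting two isotropic 0.511 MeV quanta. No coherent
scattering, no bound-Compton corrections, no electron transport, no
environmental bremsstrahlung generation, analog weights only — this is the
stated fidelity gap against production transport codes, and it is why the
engine is a diagnostic, not the source of the packaged tables. Photons
below 2 keV are terminated.

Interaction data are synthetic and labelled as such: the incoherent part
is the analytic Klein–Nishina cross-section times the mixture electron
density; photoelectric and pair parts are power-law models calibrated to
standard dry-air anchors (≈ 4.5 cm² g⁻¹ at 10 keV; ≈ 3.9·10⁻⁴ cm² g⁻¹ pair
at 2 MeV). Tables span 2 keV–10 MeV so down-scattered photons never fall
off the grid, interpolate log-log per partial, and can be replaced by user
CSVs of measured coefficients. At 1 MeV the synthetic air total
(0.0635 cm² g⁻¹) is within a fraction of a percent of the standard
coherent-free value, degrading to the few-percent level below 100 keV.

**Coupling cylinder.** Photons entering the ideal-absorber cylinder
(ground: 2 m diameter × 2.5 m; submersion: 0.6 m × 2 m) terminate and are
logged (position, direction, energy, unit weight). Crossings are binned
into p_S(cosϑ, h, E) and p_L(cosϑ, E): cosϑ against the upward vertical in
width-0.1 bins, h from the base in 10 cm bins, energies on the per-decade
grid with mantissas 1.0, 1.5, 2 … 9; bins half-open with the final bin
closed; side and lid probabilities jointly normalized to 1 with per-bin
binomial standard errors. Rotational invariance justifies dropping the
azimuthal coordinates and lid radius; resampling restores them uniformly
(lid radius area-uniform) and smears binned attributes uniformly within
bins. The rare photons that enter through the bottom lid from within the
soil are pooled with the lid density.

**Air kerma at 1 m.** The track-length fluence estimator in the 30 cm air
sphere is folded analytically over the lateral translation invariance of
the infinite source: each in-air flight leg contributes
`∫ π(R² − (z − z_c)²) ds` over the portion crossing the slab
`|z − z_c| < R`, which equals the leg's track length integrated over every
lateral sphere position. This is an exact variance reduction — the naive
single-sphere analog tally would see far less than one crossing per
million histories from a 500 m source disc — and lets the source be
sampled as a point (plane) or axis column (volume, multiplied by the
column height) on the world axis. Fluence is converted with standard
dry-air mass energy-absorption coefficients (the energy-transfer/
energy-absorption difference is negligible in air here). Uncertainties
come from the scatter of ≥ 10 history batches. With 10⁵–2·10⁵ histories
the 1 MeV ground-plane estimate lands within ~1–3 % of the packaged
full-physics table value (8.26·10⁻¹⁶ Gy s⁻¹ Bq⁻¹ m²) — closer than the
simplified physics guarantees in general; treat agreement at the tens-of-
percent level as the design expectation across the energy range.

## What the tests show — and what they do not

Node reproduction, single-line folds and the ratio report are exact
arithmetic on the packaged published values. Quadrature checks compare
against brute-force fine-trapezoid references. The Monte Carlo suite
checks closed-form attenuation, the analytic Compton angular distribution,
exact PDF normalization and resampling round-trips at fixed seeds — i.e.
internal consistency of the simplified engine, not agreement with
full-physics transport. The synthetic decay generator produces
schema-valid, physically shaped records, not real nuclide data; passing
tests therefore demonstrate correctness of the folding machinery, while
accuracy for a real nuclide is bounded by the user's decay data and
bremsstrahlung kernel. The absolute monoenergetic coefficients themselves
required voxel-phantom transport and are consumed as data, never
recomputed here.

Problem sizes used by the default test run and the acceptance script:
10⁵ samples for the stochastic checks, 2·10⁵ histories for the kerma
estimate, 20 random spectra for the quadrature sweep — sizes at which the
statistical tolerances above are comfortably resolved within seconds.

## Known limitations

* Progeny ingrowth (Bateman chains) is out of scope by design; only
  explicit user-directed summing is offered.
* No time-integrated dose, weathering/migration, or location/occupancy
  shielding factors.
* The default 1/k bremsstrahlung kernel underweights the hard end of real
  thick-target spectra; supply measured kernels for production work.
* The Monte Carlo's synthetic cross-sections and reduced physics limit it
  to sanity checks and phase-space construction demonstrations.
* Spontaneous-fission neutrons are not considered (their dose contribution
  is negligible next to the photons, which are handled as continuous
  spectra).
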