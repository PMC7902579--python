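# fetodose

External environmental dose rate coefficients for a pregnant female and her
fetus (24th week of gestation).

After a release of radioactivity — deposition on the ground or a passing
radioactive cloud — the dose to an unborn child is assessed from
*nuclide-specific organ equivalent dose rate coefficients*: organ dose rate
per unit environmental activity concentration, Sv s⁻¹ per Bq m⁻² for an
infinite plane source buried at 0.5 g cm⁻² in soil (first-year ground
shine), or per Bq m⁻³ for submersion in a semi-infinite contaminated air
volume. `fetodose` packages the published monoenergetic coefficient tables
for the fetal organs and the air kerma at 1 m, and computes nuclide
coefficients from decay data by folding:

```
ḣ_T^S = Σ_R w_R [ Σ_i Y_{R,i} ḋ_T,R^S(E_i) + ∫ Y_R(E) ḋ_T,R^S(E) dE ]
```

where `Y_{R,i}` are per-decay yields of discrete photon/electron lines,
`Y_R(E)` continuous spectra (beta electrons, spontaneous-fission photons),
and `ḋ_T^S(E)` the monoenergetic coefficient, interpolated by a
Fritsch–Carlson monotone piecewise cubic Hermite in log₁₀(E)/linear space
with `ḋ ≡ 0` below 0.015 MeV. Electrons contribute only through the
bremsstrahlung photons they generate while stopping in soil or air
(thick-target kernel; a Kramers-like 1/k default is provided). Progeny are
never summed implicitly.

A separate subpackage, `fetodose.envmc`, is a deliberately simplified
analog photon Monte Carlo of the environmental field itself (air cylinder
over soil, photoelectric/Compton/pair only): it records photons on the
ideal-absorber *coupling cylinder*, builds the binned phase-space densities
`p_S(cosϑ, h, E)` and `p_L(cosϑ, E)` that exploit the field's rotational
invariance, resamples them, and estimates the air kerma at 1 m with a
track-length estimator in a 30 cm air sphere. It is a teaching/diagnostic
engine — the packaged tables, produced with production transport codes and
a voxel phantom, carry the reference numbers.

## Worked example

```python
from fetodose import (Geometry, builtin_fixture, make_curve,
                      nuclide_coefficient, kerma_normalize, parse_decay_json)

record = parse_decay_json('''{
  "nuclide": "Co60-like",
  "discrete": [{"type": "photon", "energy_MeV": 1.173, "yield": 0.9985},
               {"type": "photon", "energy_MeV": 1.332, "yield": 0.9998}]
}''')
curves = {o: make_curve(builtin_fixture(Geometry.GROUND_PLANE, o))
          for o in ("total_body", "skin", "skeleton")}
result = nuclide_coefficient(record, curves)
kerma = make_curve(builtin_fixture(Geometry.GROUND_PLANE, "air_kerma"))
print(result.per_organ["total_body"])
print(kerma_normalize(result, nuclide_coefficient(
    record, {"k": kerma}).per_organ["k"])["total_body"])
```

prints

```
1.4357124773936566e-15
0.721728376661598
```

i.e. a fetal total-body coefficient of 1.44·10⁻¹⁵ Sv s⁻¹ Bq⁻¹ m² for this
two-line gamma emitter on contaminated ground — matching the published
per-nuclide value for ⁶⁰Co to 0.3 % — and about 0.72 Sv of fetal dose per
Gy of air kerma measured at 1 m, the form used for quick field estimates.

The `examples/` directory has one short script per capability
(interpolation, gamma folding, beta/bremsstrahlung routing, the
uterus-surrogate ratio report, the environmental Monte Carlo); each prints
its numbers with a line on what they mean. A thin CLI wraps the same
library calls:

```sh
fetodose tables --geometry ground_plane_0p5gcm2 --organ total_body --out tb.csv
fetodose fold --geometry air_submersion --decay-json mono.json --outdir run/
fetodose ratio --out ratios.csv
fetodose simulate --energy 0.662 --histories 100000 --seed 1 --outdir sim/
```

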