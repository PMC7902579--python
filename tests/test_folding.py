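"""Folding engine: discrete/continuous folds, electron routing, reports."""

import numpy as np
import pytest

from fetodose.decay import (
    BremsKernel,
    ContinuousSpectrum,
    DecayRecord,
    DiscreteEmission,
    SynthSpec,
    WeightingConfig,
    kramers_kernel,
    synth_nuclide,
)
from fetodose.dose_tables import (
    Geometry,
    SOIL,
    builtin_fixture,
    nuclide_summary,
)
from fetodose.interp import EnergyRangeError, make_curve
from fetodose.folding import (
    detriment_weighted,
    electron_dose_curve,
    fold_continuous,
    fold_discrete,
    kerma_normalize,
    nuclide_coefficient,
    uterus_fetus_ratio,
)

G, S = Geometry.GROUND_PLANE, Geometry.AIR_SUBMERSION
W = WeightingConfig()


def line(e, y=1.0, kind="photon"):
    return DiscreteEmission(kind, e, y)


def fine_trapezoid(f, lo, hi, n=100_001):
    x = np.linspace(lo, hi, n)
    return np.trapezoid(f(x), x)


class TestFoldDiscrete:
    def test_single_line_reproduces_table_cell(self, submersion_total_body_curve):
        assert fold_discrete([line(1.0)], submersion_total_body_curve, W) == 4.29e-14

    def test_two_line_combination(self, ground_total_body_curve):
        v = fold_discrete([line(0.5, 0.5), line(1.0, 0.5)], ground_total_body_curve, W)
        assert v == pytest.approx(0.5 * 2.91e-16 + 0.5 * 5.83e-16, rel=1e-12)

    def test_empty_and_subcutoff_lines(self, ground_total_body_curve):
        assert fold_discrete([], ground_total_body_curve, W) == 0.0
        assert fold_discrete([line(0.01)], ground_total_body_curve, W) == 0.0

    def test_line_above_10mev_is_an_error(self, ground_total_body_curve):
        with pytest.raises(EnergyRangeError):
            fold_discrete([line(11.0)], ground_total_body_curve, W)


class TestFoldContinuous:
    def test_rectangular_spectrum_matches_fine_quadrature(
        self, ground_total_body_curve
    ):
        spec = ContinuousSpectrum(
            "photon_sf", np.array([[0.5, 1.0], [1.0, 1.0]])
        )
        mine = fold_continuous(spec, ground_total_body_curve)
        oracle = fine_trapezoid(ground_total_body_curve, 0.5, 1.0)
        assert mine == pytest.approx(oracle, rel=1e-6)

    def test_spectrum_below_cutoff_contributes_zero(self, ground_total_body_curve):
        spec = ContinuousSpectrum(
            "photon_sf", np.array([[0.002, 5.0], [0.012, 5.0]])
        )
        assert fold_continuous(spec, ground_total_body_curve) == 0.0

    def test_zero_density_spectrum(self, ground_total_body_curve):
        spec = ContinuousSpectrum("photon_sf", np.array([[0.1, 0.0], [1.0, 0.0]]))
        assert fold_continuous(spec, ground_total_body_curve) == 0.0

    def test_panel_refinement_converged(self, ground_total_body_curve):
        spec = ContinuousSpectrum(
            "photon_sf", np.array([[0.02, 0.3], [0.7, 1.4], [3.0, 0.1]])
        )
        a = fold_continuous(spec, ground_total_body_curve, min_panels=400)
        b = fold_continuous(spec, ground_total_body_curve, min_panels=800)
        assert a == pytest.approx(b, rel=1e-6)


class TestElectronDoseCurve:
    def test_zero_kernel_gives_zero(self, ground_total_body_curve):
        kernel = kramers_kernel(SOIL, [(0.1, 0.0), (10.0, 0.0)])
        d = electron_dose_curve(ground_total_body_curve, kernel)
        assert d(1.0) == 0.0

    def test_degenerate_monochromatic_kernel(self, ground_total_body_curve):
        # a single narrow bin at k = E_e carrying photon yield y acts like a
        # delta: d_elec(E_e) -> y * curve(E_e)
        e_e, y, eps = 1.0, 0.37, 1e-7
        k = np.array([e_e * (1 - eps), e_e])
        b = np.full(2, y / (e_e * eps))
        kernel = BremsKernel("x", [e_e], (k,), (b,))
        d = electron_dose_curve(ground_total_body_curve, kernel)
        assert d(e_e) == pytest.approx(y * ground_total_body_curve(e_e), rel=1e-4)

    def test_kramers_kernel_matches_fine_quadrature(self, ground_total_body_curve):
        kernel = kramers_kernel(SOIL, [(1.0, 0.002)])
        d = electron_dose_curve(ground_total_body_curve, kernel)
        k0 = kernel.photon_grids[0][0]
        c = 0.002 * 1.0 / (1.0 - k0)

        def integrand(k):
            lo = max(ground_total_body_curve.cutoff, k0)
            vals = np.where(k >= lo, c / np.maximum(k, lo), 0.0)
            return vals * ground_total_body_curve(np.maximum(k, lo))

        oracle = fine_trapezoid(integrand, 0.015, 1.0)
        assert d(1.0) == pytest.approx(oracle, rel=1e-6)

    def test_subcutoff_electron_is_zero_and_range_checked(
        self, ground_total_body_curve
    ):
        kernel = kramers_kernel(SOIL, [(0.1, 0.001), (2.0, 0.003)])
        d = electron_dose_curve(ground_total_body_curve, kernel)
        assert d(0.01) == 0.0
        with pytest.raises(EnergyRangeError):
            d(5.0)


class TestNuclideCoefficient:
    def _curves(self, geometry):
        return {
            organ: make_curve(builtin_fixture(geometry, organ))
            for organ in ("total_body", "skin", "skeleton")
        }

    def test_empty_record_gives_zeros(self):
        result = nuclide_coefficient(DecayRecord("Quiet-0"), self._curves(S))
        assert all(v == 0.0 for v in result.per_organ.values())

    def test_single_line_reproduces_cell(self):
        rec = DecayRecord("Mono-1", (line(1.0),))
        result = nuclide_coefficient(rec, self._curves(S))
        assert result.per_organ["total_body"] == 4.29e-14

    def test_linearity_in_yields(self):
        curves = self._curves(G)
        kernel = kramers_kernel(
            SOIL, [(e, 0.002 * e) for e in np.geomspace(0.015, 10, 15)]
        )
        rng = np.random.default_rng(11)
        for seed in rng.integers(0, 2**31, 25):
            rec = synth_nuclide(int(seed), SynthSpec(n_lines=2, n_beta=1))
            scale = float(rng.uniform(0.5, 3.0))
            base = nuclide_coefficient(rec, curves, kernel)
            scaled = nuclide_coefficient(rec.scaled(scale), curves, kernel)
            for organ in curves:
                assert scaled.per_organ[organ] == pytest.approx(
                    scale * base.per_organ[organ], rel=1e-9
                )

    def test_component_breakdown_sums_to_total(self):
        curves = self._curves(G)
        kernel = kramers_kernel(
            SOIL, [(e, 0.002 * e) for e in np.geomspace(0.015, 10, 15)]
        )
        rec = DecayRecord(
            "Mix-1",
            (line(0.662, 0.85), line(0.5, 0.3, "electron")),
            (
                synth_nuclide(3, SynthSpec(n_lines=0, n_beta=1)).continuous[0],
                ContinuousSpectrum("photon_sf", np.array([[0.3, 0.1], [2.0, 0.05]])),
            ),
        )
        result = nuclide_coefficient(rec, curves, kernel)
        for organ in curves:
            comps = result.components[organ]
            assert comps["bremsstrahlung"] > 0
            assert comps["continuous_photon"] > 0
            assert sum(comps.values()) == pytest.approx(
                result.per_organ[organ], rel=1e-12
            )

    def test_electrons_require_a_kernel(self):
        rec = DecayRecord("Beta-1", (line(0.5, 1.0, "electron"),))
        with pytest.raises(ValueError, match="kernel"):
            nuclide_coefficient(rec, self._curves(G), kernel=None)

    def test_geometry_mismatch_rejected(self):
        curves = {
            "total_body": make_curve(builtin_fixture(G, "total_body")),
            "skin": make_curve(builtin_fixture(S, "skin")),
        }
        with pytest.raises(ValueError, match="mix"):
            nuclide_coefficient(DecayRecord("X", (line(1.0),)), curves)


class TestReports:
    def test_kerma_normalization_quotient(self):
        rec = DecayRecord("Mono-1", (line(1.0),))
        curves = {"total_body": make_curve(builtin_fixture(G, "total_body"))}
        result = nuclide_coefficient(rec, curves)
        kerma = make_curve(builtin_fixture(G, "air_kerma"))(1.0)
        per_kerma = kerma_normalize(result, kerma)
        assert per_kerma["total_body"] == pytest.approx(0.706, abs=5e-4)
        # re-multiplication recovers the original
        assert per_kerma["total_body"] * kerma == pytest.approx(
            result.per_organ["total_body"], rel=1e-12
        )

    def test_kerma_normalize_rejects_nonpositive(self):
        rec = DecayRecord("Mono-1", (line(1.0),))
        curves = {"total_body": make_curve(builtin_fixture(G, "total_body"))}
        result = nuclide_coefficient(rec, curves)
        with pytest.raises(ValueError):
            kerma_normalize(result, 0.0)

    def test_detriment_weighted(self, rng):
        assert detriment_weighted({"a": 3.0, "b": 3.0}, {"a": 0.5, "b": 0.5}) == 3.0
        assert detriment_weighted({"a": 1.0, "b": 2.0}, {"a": 0.5, "b": 0.5}) == 1.5
        organs = {f"o{i}": float(v) for i, v in enumerate(rng.uniform(0, 1, 8))}
        weights = {k: float(w) for k, w in zip(organs, rng.uniform(0, 1, 8))}
        oracle = float(
            np.dot([organs[k] for k in organs], [weights[k] for k in organs])
        )
        assert detriment_weighted(organs, weights) == pytest.approx(oracle, rel=1e-12)
        with pytest.raises(KeyError, match="lungs"):
            detriment_weighted({"skin": 1.0}, {"skin": 0.5, "lungs": 0.5})

    def test_uterus_fetus_ratio_report(self):
        summary = nuclide_summary(G)
        frame = uterus_fetus_ratio(
            ["Xe-133", "Te-132", "Mo-95", "Cs-137"],
            summary["uterus"].to_dict(),
            summary["total_body"].to_dict(),
        )
        assert frame.loc["Xe-133", "ratio"] == 1.09
        assert frame.loc["Te-132", "ratio"] == 1.06
        assert frame.loc["Te-132", "ratio_raw"] == pytest.approx(1.0588, abs=1e-4)
        assert "Mo-95" not in frame.index  # stable, no table row
        ident = uterus_fetus_ratio(["A"], {"A": 2.0}, {"A": 2.0})
        assert ident.loc["A", "ratio"] == 1.00

    def test_gamma_emitter_fold_consistent_with_published_nuclide_value(self):
        # folding the two Co-60 gamma lines through our interpolated
        # monoenergetic curve must land close to the independently computed
        # per-nuclide coefficient in the packaged summary (small differences:
        # beta bremsstrahlung omitted here, 3-significant-figure tables)
        rec = DecayRecord(
            "Co-60", (line(1.173, 0.9985), line(1.332, 0.9998))
        )
        curves = {"total_body": make_curve(builtin_fixture(G, "total_body"))}
        mine = nuclide_coefficient(rec, curves).per_organ["total_body"]
        published = nuclide_summary(G).loc["Co-60", "total_body"]
        assert mine == pytest.approx(published, rel=0.02)

    def test_zero_fetal_coefficient_flagged(self):
        frame = uterus_fetus_ratio(["A"], {"A": 1.0}, {"A": 0.0})
        assert not frame.loc["A", "defined"]
        assert np.isnan(frame.loc["A", "ratio"])
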