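import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from memscaffold.energetics import (
    AdhesionEnergy,
    MembraneMechanics,
    PatchSpec,
    ade_bending_energy,
    adhesion_free_energy,
    cost_benefit,
    tube_area_difference,
    tube_bending_energy,
)


def quadrature_tube_energy(
    area_nm2: float, radius_nm: float, mech: MembraneMechanics, n_elements: int = 20000
) -> float:
    """Independent oracle: sum the bending-energy density element-by-element
    over a discretised cylindrical patch, deriving the leaflet area
    difference numerically as D * sum(c * dA)."""
    da = area_nm2 / n_elements
    c = 1.0 / radius_nm
    local = 0.0
    delta_a = 0.0
    for _ in range(n_elements):
        local += 0.5 * da * (c + 0.0 - mech.c0_per_nm) ** 2
        delta_a += mech.thickness_nm * c * da
    nonlocal_ = (
        0.5 * mech.alpha * math.pi / (area_nm2 * mech.thickness_nm**2)
        * (delta_a - mech.delta_a0_nm2) ** 2
    )
    return mech.kappa_kbt * (local + nonlocal_)


class TestTubeBendingEnergy:
    @pytest.mark.parametrize(
        "area, radius, printed, rel_window",
        [
            (1800.0, 84.0, 11.0, 0.10),  # quarter-circle scaffold footprint
            (1800.0, 46.0, 38.0, 0.10),  # half-circle
            (23.0, 11.0, 9.0, 0.05),     # amphiphysin BAR domain
        ],
    )
    def test_matches_printed_costs(self, dopc, area, radius, printed, rel_window):
        e = tube_bending_energy(area, radius, dopc)
        assert abs(e - printed) / printed <= rel_window

    def test_closed_form_value(self, dopc):
        # With alpha = 3/pi the ADE tube energy is exactly 2*kappa*A/R^2.
        e = tube_bending_energy(1800.0, 84.0, dopc)
        assert e == pytest.approx(2 * 23.1 * 1800.0 / 84.0**2, rel=1e-12)

    def test_agrees_with_quadrature_oracle(self, rng, dopc):
        for _ in range(10):
            area = rng.uniform(20.0, 3000.0)
            radius = rng.uniform(10.0, 200.0)
            kappa = rng.uniform(5.0, 50.0)
            mech = MembraneMechanics(kappa_kbt=kappa)
            closed = tube_bending_energy(area, radius, mech)
            assert closed == pytest.approx(
                quadrature_tube_energy(area, radius, mech), rel=1e-6
            )

    def test_equals_general_ade_on_same_inputs(self, dopc):
        area, radius = 1800.0, 46.0
        patch = PatchSpec(
            area_nm2=area,
            c1_per_nm=1.0 / radius,
            delta_a_nm2=tube_area_difference(area, radius, dopc.thickness_nm),
        )
        assert tube_bending_energy(area, radius, dopc) == pytest.approx(
            ade_bending_energy(patch, dopc), rel=1e-9
        )

    def test_thickness_cancels(self):
        thin = MembraneMechanics(thickness_nm=2.0)
        thick = MembraneMechanics(thickness_nm=8.0)
        assert tube_bending_energy(1800.0, 46.0, thin) == pytest.approx(
            tube_bending_energy(1800.0, 46.0, thick), rel=1e-12
        )

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(area=st.floats(10.0, 5000.0), radius=st.floats(5.0, 500.0))
    def test_scaling_laws(self, area, radius):
        base = tube_bending_energy(area, radius)
        assert tube_bending_energy(2 * area, radius) == pytest.approx(2 * base)
        assert tube_bending_energy(area, radius / 2) == pytest.approx(4 * base)


class TestAdeBendingEnergy:
    def test_flat_patch_costs_nothing(self, dopc):
        patch = PatchSpec(area_nm2=1800.0, c1_per_nm=0.0, c2_per_nm=0.0,
                          delta_a_nm2=0.0)
        assert ade_bending_energy(patch, dopc) == 0.0

    def test_missing_delta_a_instructs_caller(self, dopc):
        patch = PatchSpec(area_nm2=1800.0, c1_per_nm=0.02)
        with pytest.raises(ValueError, match="tube_bending_energy"):
            ade_bending_energy(patch, dopc)

    def test_nonnegative_for_symmetric_bilayer(self, rng, dopc):
        for _ in range(20):
            patch = PatchSpec(
                area_nm2=rng.uniform(10, 3000),
                c1_per_nm=rng.uniform(-0.1, 0.1),
                c2_per_nm=rng.uniform(-0.1, 0.1),
                delta_a_nm2=rng.uniform(-100, 100),
            )
            assert ade_bending_energy(patch, dopc) >= 0.0


class TestTubeAreaDifference:
    @pytest.mark.parametrize(
        "area, radius, thickness, expected",
        [
            (1800.0, 46.0, 4.0, 156.5),
            (23.0, 11.0, 4.0, 8.36),
        ],
    )
    def test_values(self, area, radius, thickness, expected):
        assert tube_area_difference(area, radius, thickness) == pytest.approx(
            expected, rel=1e-2
        )

    def test_flat_patch_has_no_difference(self):
        assert tube_area_difference(1800.0, math.inf, 4.0) == 0.0


class TestAdhesionFreeEnergy:
    @pytest.mark.parametrize(
        "kd_molar, expected_kbt",
        [(0.68e-9, -21.1), (2.0e-9, -20.0), (1.0, 0.0)],
    )
    def test_printed_values(self, kd_molar, expected_kbt):
        dg = adhesion_free_energy(kd_molar).delta_g_kbt
        assert round(dg, 1) == expected_kbt

    def test_strictly_increasing_in_kd(self):
        kds = [0.1e-9, 0.68e-9, 2e-9, 1e-6, 1.0]
        dgs = [adhesion_free_energy(k).delta_g_kbt for k in kds]
        assert all(a < b for a, b in zip(dgs, dgs[1:]))

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        a=st.floats(1e-12, 1e-3), b=st.floats(1e-3, 1e3)
    )
    def test_log_additivity(self, a, b):
        dg_ab = adhesion_free_energy(a * b).delta_g_kbt
        dg_a = adhesion_free_energy(a).delta_g_kbt
        assert dg_ab == pytest.approx(dg_a + math.log(b), abs=1e-9)

    def test_nonpositive_kd_rejected(self):
        with pytest.raises(ValueError):
            adhesion_free_energy(0.0)

    def test_joule_conversion(self):
        adh = adhesion_free_energy(1.0e-9, temperature_k=298.15)
        kbt = 1.380649e-23 * 298.15
        assert adh.delta_g_joule() == pytest.approx(adh.delta_g_kbt * kbt)


class TestCostBenefit:
    def test_moderate_curvature_is_permitted(self):
        verdict = cost_benefit(AdhesionEnergy(-21.1, 0.68e-9), 11.0)
        assert verdict.permitted
        assert verdict.margin_kbt == pytest.approx(10.1)

    def test_high_curvature_is_not(self):
        verdict = cost_benefit(AdhesionEnergy(-20.0, 2.0e-9), 38.0)
        assert not verdict.permitted
        assert verdict.margin_kbt == pytest.approx(-18.0)

    def test_tie_counts_as_permitted(self):
        verdict = cost_benefit(AdhesionEnergy(-10.0, 1e-6), 10.0)
        assert verdict.permitted
        assert verdict.margin_kbt == 0.0

    def test_monotone_in_adhesion_strength(self):
        bending = 15.0
        permitted = [
            cost_benefit(AdhesionEnergy(-dg, 1e-9), bending).permitted
            for dg in np.linspace(1.0, 40.0, 40)
        ]
        # Once permitted, stays permitted as |dG| grows.
        assert permitted == sorted(permitted)

    def test_negative_bending_rejected(self):
        with pytest.raises(ValueError):
            cost_benefit(AdhesionEnergy(-20.0, 1e-9), -1.0)


class TestMembraneMechanics:
    def test_invalid_constants_rejected(self):
        for kwargs in ({"kappa_kbt": 0}, {"alpha": -1}, {"thickness_nm": 0}):
            with pytest.raises(ValueError):
                MembraneMechanics(**kwargs)
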