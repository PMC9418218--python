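"""Nusselt numbers, enhancement arithmetic, and parameter-sweep trends."""

import math

import numpy as np
import pytest

from fracbioheat import (
    InversionSettings,
    MATERIALS,
    NanofluidMixture,
    SHAPES,
    TherapyParams,
    enhancement_percent,
    nusselt,
    nusselt_table,
    sweep,
)
from fracbioheat.analysis import (
    REFERENCE_NUSSELT_SHAPES,
    REFERENCE_NUSSELT_SPECIES,
    REFERENCE_PHI_GRID,
    NusseltRecord,
)


class TestEnhancementPercent:
    def test_identity_is_zero(self):
        assert enhancement_percent(20.88, 20.88) == 0.0
        assert enhancement_percent(3.7, 3.7) == 0.0

    def test_zero_baseline_rejected(self):
        with pytest.raises(ZeroDivisionError):
            enhancement_percent(0.0, 1.0)

    def test_headline_cells(self):
        """The strongest-enhancement cells of the published tables."""
        assert enhancement_percent(20.88, 24.307) == 16.412
        assert enhancement_percent(20.88, 22.602) == 8.247

    def test_truncation_not_rounding(self):
        # 100*(21.731-20.88)/20.88 = 4.07567...; rounding would give 4.076
        assert enhancement_percent(20.88, 21.731) == 4.075

    def test_exact_rational_arithmetic_before_truncation(self):
        # 100*(22.185-20.88)/20.88 is exactly 6.25; naive float subtraction
        # (1.3049999...) would truncate to 6.249
        assert enhancement_percent(20.88, 22.185) == 6.25

    @pytest.mark.parametrize("table,label", [
        (REFERENCE_NUSSELT_SPECIES, "species"),
        (REFERENCE_NUSSELT_SHAPES, "shapes"),
    ])
    def test_reproduces_every_published_percentage_cell(self, table, label):
        """All 16 non-baseline cells per table follow from the printed
        Nusselt columns by truncated-percentage arithmetic."""
        checked = 0
        for column in table.values():
            nu0 = column["Nu"][0]
            for nu, pct in zip(column["Nu"][1:], column["pct"][1:]):
                assert enhancement_percent(nu0, nu) == pct, (label, nu)
                checked += 1
        assert checked == 16


class TestNusselt:
    def test_flat_equilibrium_profile_has_zero_nusselt(self):
        mix = NanofluidMixture(
            MATERIALS["blood"], MATERIALS["gold"], 0.0, SHAPES["platelet"]
        )
        # lam = beta = 0 gives c = s = gamma, so the reaction fixed point is
        # 1; placing initial and boundary values there keeps the field flat
        params = TherapyParams(
            alpha=0.8, R=0.0, theta_init=1.0, theta_left=1.0, theta_right=1.0,
            gamma=1.0, lam=0.0, beta=0.0,
        )
        assert nusselt(params, mix, t_eval=1.0) == pytest.approx(0.0, abs=1e-8)

    def test_steady_regime_matches_closed_form_wall_gradient(self):
        """D=1, c=1, s=0, boundaries 0/1, phi=0, R=0:
        Nu(t=inf) = -theta_ss'(0) = -1/sinh(1)."""
        mix = NanofluidMixture(
            MATERIALS["blood"], MATERIALS["gold"], 0.0, SHAPES["platelet"]
        )
        params = TherapyParams(
            alpha=1.0, R=0.0, gamma=1.0, lam=0.0, beta=0.0,
            theta_init=0.0, theta_left=0.0, theta_right=1.0,
        )
        # gamma=1, lam=0 -> c=1; beta=0 -> s=1, not 0; steady-state gradient
        # still follows the closed form through steady_state_dy:
        nu_inf = nusselt(params, mix, t_eval=math.inf)
        from fracbioheat.model_core import steady_state_dy, PDECoefficients

        expected = -steady_state_dy(
            0.0, PDECoefficients(D=1.0, c=1.0, s=1.0), params
        )
        assert nu_inf == pytest.approx(expected, rel=1e-12)

    def test_pure_conduction_steady_wall_gradient_hand_value(self):
        """Direct check of the -1/sinh(1) closed form for the c=1, s=0
        configuration, via the analytic steady state."""
        from fracbioheat.model_core import steady_state_dy, PDECoefficients

        params = TherapyParams(theta_left=0.0, theta_right=1.0)
        grad0 = steady_state_dy(0.0, PDECoefficients(D=1.0, c=1.0, s=0.0), params)
        assert -grad0 == pytest.approx(-1.0 / math.sinh(1.0), rel=1e-12)
        assert grad0 == pytest.approx(0.8509181282, abs=1e-9)

    def test_transient_nusselt_agrees_with_fd_wall_gradient(self):
        """Inverted analytic wall gradient vs one-sided differences of the
        finite-difference field."""
        from fracbioheat import FDGrid, assemble_coefficients, solve_fd

        mix = NanofluidMixture(
            MATERIALS["blood"], MATERIALS["gold"], 0.04, SHAPES["platelet"]
        )
        params = TherapyParams(alpha=0.8, R=0.5)
        coeff = assemble_coefficients(params, mix)
        t_eval = 1.0
        nu = nusselt(params, mix, t_eval=t_eval)
        fd = solve_fd(params, coeff, FDGrid(ny=401, nt=800, dt=t_eval / 800))
        dy = 1.0 / 400
        u = fd.values[:, -1]
        grad_fd = (-3 * u[0] + 4 * u[1] - u[2]) / (2 * dy)
        factor = mix.conductivity_ratio * (1 + 4 * params.R / 3)
        assert nu == pytest.approx(-factor * grad_fd, rel=2e-2)

    def test_loading_with_gold_platelets_strengthens_wall_transfer(self):
        """|Nu| grows with phi through the conductivity ratio."""
        params = TherapyParams()
        base = NanofluidMixture(
            MATERIALS["blood"], MATERIALS["gold"], 0.0, SHAPES["platelet"]
        )
        nu0 = nusselt(params, base, t_eval=1.0)
        nu4 = nusselt(params, base.with_phi(0.04), t_eval=1.0)
        assert abs(nu4) > abs(nu0)

    def test_nusselt_table_structure_and_baseline(self):
        params = TherapyParams()
        base = NanofluidMixture(
            MATERIALS["blood"], MATERIALS["gold"], 0.0, SHAPES["platelet"]
        )
        table = nusselt_table(params, base, phis=(0.0, 0.02, 0.04), t_eval=0.5)
        assert list(table.columns) == [
            "phi", "particle", "shape", "Nu", "enhancement_pct"
        ]
        assert table["enhancement_pct"].iloc[0] == 0.0
        assert (table["enhancement_pct"].diff().iloc[1:] > 0).all()

    def test_baseline_record_with_nonzero_enhancement_rejected(self):
        with pytest.raises(ValueError, match="baseline"):
            NusseltRecord(phi=0.0, particle="gold", shape="platelet",
                          Nu=20.0, enhancement_pct=1.0)


class TestSweep:
    @pytest.fixture
    def base(self):
        mix = NanofluidMixture(
            MATERIALS["blood"], MATERIALS["gold"], 0.02, SHAPES["platelet"]
        )
        return TherapyParams(), mix

    def _interior_profile(self, frame, value):
        sel = frame[(frame["value"] == value) & (frame["y"] > 0) & (frame["y"] < 1)]
        return sel.sort_values(["y", "t"])["theta"].to_numpy()

    @pytest.mark.parametrize(
        "param,values",
        [
            ("phi", (0.0, 0.01, 0.02, 0.03, 0.04)),
            ("R", (0.0, 0.5, 1.0)),
            ("lambda", (0.0, 0.5, 1.0)),
            ("beta", (0.0, 0.5, 1.0)),
        ],
    )
    def test_interior_temperature_monotone_in_driving_parameters(
        self, base, param, values, y21
    ):
        """Temperature rises with particle loading, radiation, metabolic
        heating and porosity at every interior point and time."""
        params, mix = base
        frame = sweep(param, values, params, mix, y21, np.array([0.5, 1.0]))
        prev = None
        for v in values:
            prof = self._interior_profile(frame, v)
            if prev is not None:
                assert np.all(prof >= prev - 1e-7), (param, v)
            prev = prof

    def test_interior_temperature_rises_with_time(self, base, y21):
        params, mix = base
        frame = sweep("t", (0.1, 0.5, 1.0, 2.0), params, mix, y21, np.array([1.0]))
        prev = None
        for v in (0.1, 0.5, 1.0, 2.0):
            sel = frame[(frame["value"] == v) & (frame["y"] > 0) & (frame["y"] < 1)]
            prof = sel.sort_values("y")["theta"].to_numpy()
            if prev is not None:
                assert np.all(prof >= prev - 1e-7)
            prev = prof

    def test_single_value_sweep_equals_direct_simulation(self, base, y21):
        from fracbioheat import LaplaceField, assemble_coefficients, invert_field

        params, mix = base
        t = np.array([0.5, 1.5])
        frame = sweep("alpha", [0.8], params, mix, y21, t)
        coeff = assemble_coefficients(params, mix)
        direct = invert_field(LaplaceField(coeff, params), y21, t)
        np.testing.assert_allclose(
            frame["theta"].to_numpy(),
            direct.to_frame()["theta"].to_numpy(),
            rtol=0, atol=1e-12,
        )

    def test_shape_sweep_orders_by_shape_factor(self, base, y21):
        """Higher shape factor (platelet > cylinder > brick > sphere among
        the defaults used here) conducts better and heats the tissue more."""
        params, mix = base
        frame = sweep(
            "shape", ["sphere", "brick", "cylinder", "platelet"],
            params, mix, y21, np.array([1.0]),
        )
        mids = {
            s: frame[(frame["value"] == s) & (np.isclose(frame["y"], 0.5))][
                "theta"
            ].item()
            for s in ("sphere", "brick", "cylinder", "platelet")
        }
        assert mids["sphere"] < mids["brick"] < mids["cylinder"] < mids["platelet"]

    def test_unknown_parameter_rejected(self, base, y21):
        params, mix = base
        with pytest.raises(ValueError, match="unknown sweep parameter"):
            sweep("viscosity", [1.0], params, mix, y21, np.array([1.0]))

    def test_long_format_schema(self, base, y21):
        params, mix = base
        frame = sweep("R", [0.0, 1.0], params, mix, y21, np.array([1.0]))
        assert list(frame.columns) == ["parameter", "value", "y", "t", "theta"]
        assert len(frame) == 2 * len(y21)


def test_reference_tables_share_the_particle_free_baseline():
    for table in (REFERENCE_NUSSELT_SPECIES, REFERENCE_NUSSELT_SHAPES):
        for column in table.values():
            assert column["Nu"][0] == 20.88
            assert column["pct"][0] == 0.0
            assert len(column["Nu"]) == len(REFERENCE_PHI_GRID)
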