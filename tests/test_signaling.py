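import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from abmtki import signaling as sig
from abmtki.signaling import (
    PathwayConfigError,
    PathwaySpec,
    PathwayState,
    Reaction,
    TkiBinding,
    default_pathway,
    derivatives,
    division_ready,
    effective_egfr,
    integrate_pathway,
    integrate_population,
    migration_potential,
)


# ---------------------------------------------------------------------------
# effective_egfr (quasi-steady-state receptor blockade)
# ---------------------------------------------------------------------------


class TestEffectiveEgfr:
    BINDING = TkiBinding(egfr0=1.0, km=0.5)

    def test_no_drug_full_receptor(self):
        assert effective_egfr(self.BINDING, 0.0) == pytest.approx(1.0)

    def test_half_saturation(self):
        assert effective_egfr(self.BINDING, self.BINDING.km) == pytest.approx(0.5)

    def test_saturation_limit(self):
        assert effective_egfr(self.BINDING, 1e6 * self.BINDING.km) == pytest.approx(
            0.0, abs=1e-6 * self.BINDING.egfr0
        )

    def test_negative_drug_rejected(self):
        with pytest.raises(ValueError):
            effective_egfr(self.BINDING, -0.1)

    def test_invalid_binding_params(self):
        with pytest.raises(ValueError):
            TkiBinding(egfr0=1.0, km=0.0)
        with pytest.raises(ValueError):
            TkiBinding(egfr0=-1.0, km=1.0)

    @given(
        tki=st.lists(st.floats(0.0, 1e6), min_size=2, max_size=20),
        egfr0=st.floats(0.01, 100.0),
        km=st.floats(0.01, 100.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_monotone_decreasing_and_bounded(self, tki, egfr0, km):
        binding = TkiBinding(egfr0=egfr0, km=km)
        values = [effective_egfr(binding, t) for t in sorted(tki)]
        assert all(0.0 <= v <= egfr0 for v in values)
        for lo, hi in zip(values[1:], values[:-1]):
            assert lo <= hi + 1e-12


# ---------------------------------------------------------------------------
# derivatives
# ---------------------------------------------------------------------------


def _decay_spec(k=0.1):
    return PathwaySpec(
        species=["X1", "X2", "X6", "A"],
        reactions=[
            Reaction("decay", "k", {"A": 1}, {"A": -1}),
            Reaction("probe", "k0", {"X1": 1, "X2": 1}, {"X6": 1}),
        ],
        params={"k": k, "k0": 0.0},
        initial={"X1": 0.0, "X2": 0.0, "X6": 0.0, "A": 2.0},
    )


class TestDerivatives:
    def test_single_reaction_mass_action(self):
        spec = _decay_spec(k=0.1)
        state = PathwayState(conc=spec.initial_vector())
        rates = derivatives(spec, state, tgf_local=0.0, egfr_eff=1.0)
        assert rates[spec.index("A")] == pytest.approx(-0.2)

    def test_fixed_point_gives_zero_rates(self):
        # A <-> B with equal rates and equal concentrations is an equilibrium
        spec = PathwaySpec(
            species=["X1", "X2", "X6", "A", "B"],
            reactions=[
                Reaction("fwd", "k", {"A": 1}, {"A": -1, "B": 1}),
                Reaction("rev", "k", {"B": 1}, {"B": -1, "A": 1}),
                Reaction("probe", "k0", {"X1": 1, "X2": 1}, {"X6": 1}),
            ],
            params={"k": 0.7, "k0": 0.0},
            initial={"X1": 0.0, "X2": 0.0, "X6": 0.0, "A": 1.3, "B": 1.3},
        )
        state = PathwayState(conc=spec.initial_vector())
        assert derivatives(spec, state, 0.0, 1.0) == pytest.approx(np.zeros(5))

    def test_default_network_term_by_term_oracle(self, default_spec):
        """Hand-summed evaluation of every rate-law term of the default table."""
        p = default_spec.params
        tgf, egfr_eff = 0.2, 1.0
        c = dict(zip(default_spec.species, default_spec.initial_vector()))
        c["X1"] = tgf  # input clamp
        c["X2"] = min(c["X2"], egfr_eff)

        bind = p["k1"] * c["X1"] * c["X2"]
        unbind = p["k1r"] * c["X3"]
        phos = p["k2"] * c["X3"]
        recyc = p["k3"] * c["X4"]
        desens = p["kf"] * c["X6"] * c["X4"]
        recruit = p["k12"] * c["X1"]
        act = p["V4"] * c["X4"] ** 2 * c["X5"] / (p["K4"] + c["X5"])
        deact = p["k5"] * c["X6"]
        cyc_drive = p["k6"] * c["X4"] / (p["K6"] + c["X4"])
        cyc_basal = p["k60"]
        cyc_deg = p["k7"] * c["CDh1"] * c["cycCDK"]
        cyc_dec = p["k7d"] * c["cycCDK"]
        cdh1_s = p["k8"]
        cdh1_i = p["k9"] * c["cycCDK"] * c["CDh1"]
        cdh1_d = p["k9d"] * c["CDh1"]

        expected = {
            "X1": 0.0,  # clamped input
            "X2": -bind + unbind + recyc + desens + recruit,
            "X3": bind - unbind - phos,
            "X4": phos - recyc - desens,
            "X5": -act + deact,
            "X6": act - deact,
            "CDh1": cdh1_s - cdh1_i - cdh1_d,
            "cycCDK": cyc_drive + cyc_basal - cyc_deg - cyc_dec,
        }
        state = PathwayState(conc=default_spec.initial_vector())
        rates = derivatives(default_spec, state, tgf, egfr_eff)
        for name, value in expected.items():
            assert rates[default_spec.index(name)] == pytest.approx(value), name

    def test_species_mismatch_rejected(self, default_spec):
        state = PathwayState(conc=np.zeros(3))
        with pytest.raises(PathwayConfigError):
            derivatives(default_spec, state, 0.0, 1.0)

    def test_negative_inputs_rejected(self, default_spec):
        state = PathwayState(conc=default_spec.initial_vector())
        with pytest.raises(ValueError):
            derivatives(default_spec, state, -1.0, 1.0)


# ---------------------------------------------------------------------------
# integrate_pathway
# ---------------------------------------------------------------------------


class TestIntegratePathway:
    def test_pure_decay_closed_form(self):
        spec = PathwaySpec(
            species=["X1", "X2", "X6", "A"],
            reactions=[
                Reaction("decay", "k", {"A": 1}, {"A": -1}),
                Reaction("probe", "k0", {"X1": 1, "X2": 1}, {"X6": 1}),
            ],
            params={"k": 0.5, "k0": 0.0},
            initial={"X1": 0.0, "X2": 0.0, "X6": 0.0, "A": 1.0},
        )
        state = PathwayState(conc=spec.initial_vector())
        out = integrate_pathway(spec, state, dt=1.0)
        assert out.conc[spec.index("A")] == pytest.approx(math.exp(-0.5), abs=1e-6)

    def test_fixed_point_unchanged(self):
        spec = PathwaySpec(
            species=["X1", "X2", "X6", "A", "B"],
            reactions=[
                Reaction("fwd", "k", {"A": 1}, {"A": -1, "B": 1}),
                Reaction("rev", "k", {"B": 1}, {"B": -1, "A": 1}),
                Reaction("probe", "k0", {"X1": 1, "X2": 1}, {"X6": 1}),
            ],
            params={"k": 0.7, "k0": 0.0},
            initial={"X1": 0.0, "X2": 0.0, "X6": 0.0, "A": 1.3, "B": 1.3},
        )
        state = PathwayState(conc=spec.initial_vector())
        out = integrate_pathway(spec, state, dt=5.0)
        assert out.conc == pytest.approx(spec.initial_vector(), abs=1e-7)

    def test_default_network_against_tight_tolerance_oracle(self, default_spec):
        state = PathwayState(conc=default_spec.initial_vector())
        out = integrate_pathway(default_spec, state, dt=1.0, tgf_local=0.2, egfr_eff=1.0)
        oracle = integrate_pathway(
            default_spec, state, dt=1.0, tgf_local=0.2, egfr_eff=1.0,
            rtol=1e-10, atol=1e-12,
        )
        scale = np.maximum(np.abs(oracle.conc), 1e-3)
        assert np.max(np.abs(out.conc - oracle.conc) / scale) < 1e-4

    def test_invalid_dt(self, default_spec):
        state = PathwayState(conc=default_spec.initial_vector())
        with pytest.raises(ValueError):
            integrate_pathway(default_spec, state, dt=0.0)

    def test_nonnegativity_over_random_inputs(self, default_spec):
        rng = np.random.default_rng(0)
        for _ in range(20):
            conc = rng.uniform(0.0, 2.0, size=len(default_spec.species))
            state = PathwayState(conc=conc)
            out = integrate_pathway(
                default_spec, state, dt=1.0,
                tgf_local=rng.uniform(0, 1), egfr_eff=rng.uniform(0, 1),
            )
            assert np.all(out.conc >= 0.0)


class TestIntegratePopulation:
    def test_matches_adaptive_integrator(self, default_spec):
        rng = np.random.default_rng(7)
        conc = rng.uniform(0.0, 1.0, size=(5, len(default_spec.species)))
        tgf = rng.uniform(0.0, 0.5, size=5)
        eff = rng.uniform(0.3, 1.0, size=5)
        pop, rates = integrate_population(default_spec, conc, 1.0, tgf, eff, n_substeps=20)
        for k in range(5):
            single = integrate_pathway(
                default_spec, PathwayState(conc=conc[k].copy()), 1.0,
                tgf_local=tgf[k], egfr_eff=eff[k],
            )
            assert pop[k] == pytest.approx(single.conc, abs=1e-5)
            assert rates[k] == pytest.approx(single.plc_gamma_rate, abs=1e-5)

    def test_stabilises_stiff_fold_change(self, default_spec):
        # 100x faster kinetics must not blow up the fixed-step integrator
        spec = default_spec.with_params(V4=300.0, k5=6.0)
        conc = spec.initial_vector()[None, :]
        out, rates = integrate_population(spec, conc, 1.0, np.array([0.2]), np.array([1.0]))
        assert np.all(np.isfinite(out)) and np.all(out >= 0)


# ---------------------------------------------------------------------------
# migration potential & division readiness
# ---------------------------------------------------------------------------


class TestMigrationPotential:
    def test_identity(self):
        state = PathwayState(conc=np.zeros(8), plc_gamma_rate=0.03)
        assert migration_potential(state) == 0.03

    def test_equilibrium_zero(self):
        spec = _decay_spec()
        state = PathwayState(conc=spec.initial_vector(), plc_gamma_rate=0.0)
        assert migration_potential(state) == 0.0

    def test_finite_difference_oracle(self, default_spec):
        """MP agrees with (X6(t+d) - X6(t))/d for small d."""
        state = PathwayState(conc=default_spec.initial_vector())
        state = integrate_pathway(default_spec, state, 4.0, tgf_local=0.2, egfr_eff=1.0)
        d = 1e-3
        later = integrate_pathway(
            default_spec, state, d, tgf_local=0.2, egfr_eff=1.0, rtol=1e-10, atol=1e-12
        )
        i6 = default_spec.index("X6")
        fd = (later.conc[i6] - state.conc[i6]) / d
        assert migration_potential(state) == pytest.approx(fd, rel=1e-3)


class TestDivisionReady:
    @pytest.fixture()
    def make_state(self, default_spec):
        def make(cdh1, cyc):
            conc = default_spec.initial_vector()
            conc[default_spec.index("CDh1")] = cdh1
            conc[default_spec.index("cycCDK")] = cyc
            return PathwayState(conc=conc)

        return make

    def test_equality_is_not_enough(self, default_spec, make_state):
        assert not division_ready(make_state(0.5, 1.0), default_spec, thr1=0.5, thr2=0.4)
        assert not division_ready(make_state(0.2, 0.4), default_spec, thr1=0.5, thr2=0.4)

    def test_ready(self, default_spec, make_state):
        assert division_ready(make_state(0.25, 0.8), default_spec, thr1=0.5, thr2=0.4)

    def test_not_ready_low_cyccdk(self, default_spec, make_state):
        assert not division_ready(make_state(0.25, 0.2), default_spec, thr1=0.5, thr2=0.4)

    def test_invalid_thresholds(self, default_spec, make_state):
        with pytest.raises(ValueError):
            division_ready(make_state(0.2, 0.8), default_spec, thr1=0.0, thr2=0.4)


# ---------------------------------------------------------------------------
# spec validation and the tabular interchange format
# ---------------------------------------------------------------------------


class TestPathwaySpec:
    def test_undeclared_species_rejected(self):
        with pytest.raises(PathwayConfigError):
            PathwaySpec(
                species=["X1"],
                reactions=[Reaction("r", "k", {"Z": 1}, {"Z": -1})],
                params={"k": 1.0},
                initial={"X1": 0.0},
            )

    def test_unused_species_rejected(self):
        with pytest.raises(PathwayConfigError):
            PathwaySpec(
                species=["X1", "ghost"],
                reactions=[Reaction("r", "k", {"X1": 1}, {"X1": -1})],
                params={"k": 1.0},
                initial={"X1": 0.0, "ghost": 0.0},
            )

    def test_negative_rate_constant_rejected(self, default_spec):
        with pytest.raises(PathwayConfigError):
            default_spec.with_params(k1=-0.1)

    def test_required_names_present(self, default_spec):
        for name in ("X1", "X2", "X6", "CDh1", "cycCDK"):
            assert name in default_spec.species
        for name in ("k1", "k2", "k3", "k5", "K4", "V4"):
            assert name in default_spec.params

    def test_rate_table_round_trip(self, default_spec, tmp_path):
        path = tmp_path / "table.tsv"
        sig.save_rate_table(default_spec, path)
        loaded = sig.load_rate_table(path)
        assert loaded.species == default_spec.species
        assert loaded.params == default_spec.params
        assert loaded.initial == default_spec.initial
        state = PathwayState(conc=default_spec.initial_vector())
        a = derivatives(default_spec, state, 0.2, 1.0)
        b = derivatives(loaded, state, 0.2, 1.0)
        assert a == pytest.approx(b)
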