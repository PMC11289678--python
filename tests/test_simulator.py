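"""Coupled simulation: initial conditions, integration, robustness."""

from dataclasses import replace

import numpy as np
import pytest

import scleraxl as sx
from scleraxl import kinetics as kin
from scleraxl import metrics
from scleraxl.mesh import build_mesh
from scleraxl.optics import melanin_profile
from scleraxl.simulator import AnalyticJacobian, initial_state
from scleraxl.transport import BoundaryConditions, DiffusionOperator, \
    assemble_diffusivity

SMALL_COUNTS = {"choroid": 3, "sclera": 5, "tenon": 2, "reservoir": 4}


class TestInitialState:
    def test_rat_reservoir_partition_and_scleral_his(self, rat_params,
                                                     consts):
        m = build_mesh(rat_params)
        y = initial_state(rat_params, sx.TreatmentConditions(), m, consts)
        res = m.reservoir_mask
        assert np.allclose(y[res, kin.MB], 3.523e-4, rtol=1e-3)
        assert np.allclose(y[res, kin.MBD], 1.324e-3, rtol=1e-3)
        assert np.all(y[~res, kin.MB] == 0.0)
        his = kin.AA0 + sx.AMINO_ACIDS.index("His")
        assert np.allclose(y[m.mask("sclera"), his], 1.335e-2)
        assert np.allclose(y[m.mask("tenon"), his], 1.335e-2)
        assert np.allclose(y[m.mask("choroid"), his], 6.46e-3)

    def test_no_mb_injected(self, rat_params, consts):
        m = build_mesh(rat_params)
        y = initial_state(rat_params,
                          sx.TreatmentConditions(mb_injected_mm=0.0), m,
                          consts)
        assert np.all(y[:, kin.MB] == 0.0)
        assert np.all(y[:, kin.MBD] == 0.0)

    def test_human_oxygen_profile(self, consts):
        p = sx.load_species_params("human")
        m = build_mesh(p)
        y = initial_state(p, sx.TreatmentConditions(), m, consts)
        o2 = y[:, kin.O2T]
        assert np.allclose(o2[m.mask("choroid")], 7.02e-5)
        assert np.allclose(o2[m.reservoir_mask], 3.09e-5)
        # sclera/Tenon bridge decreases monotonically between the anchors
        bridge = o2[m.mask("sclera", "tenon")]
        assert np.all(np.diff(bridge) < 0)
        assert 3.09e-5 < bridge[-1] < bridge[0] < 7.02e-5

    def test_crosslinks_and_radicals_start_empty(self, rat_params, consts):
        m = build_mesh(rat_params)
        y = initial_state(rat_params, sx.TreatmentConditions(), m, consts)
        assert np.all(y[:, kin.RAD_SLICE] == 0.0)
        assert np.all(y[:, kin.XL1_SLICE] == 0.0)
        assert np.all(y[:, kin.XL2_SLICE] == 0.0)
        assert np.all(y[m.reservoir_mask, kin.AA_SLICE] == 0.0)


def test_analytic_jacobian_matches_finite_differences(rat_params, consts):
    """The hand-assembled sparse Jacobian agrees with 3-point finite
    differences of the full RHS (reactions + diffusion + light shading)."""
    from scipy.optimize._numdiff import approx_derivative
    cond = sx.TreatmentConditions()
    m = build_mesh(rat_params, SMALL_COUNTS)
    bc = BoundaryConditions.for_treatment(rat_params, consts, 21.0)
    mel = melanin_profile(m, rat_params)
    op_mb = DiffusionOperator(m, assemble_diffusivity(m, consts, "MB"))
    op_o2 = DiffusionOperator(m, assemble_diffusivity(m, consts, "O2"))
    rng = np.random.default_rng(3)
    y = initial_state(rat_params, cond, m, consts)
    y += rng.uniform(1e-7, 1e-6, y.shape)  # populate every pool

    def rhs(y_flat):
        state = y_flat.reshape(m.n_nodes, kin.N_SPECIES)
        from scleraxl.optics import compute_light_field, \
            excitation_rate_constant
        lf = compute_light_field(m, state[:, kin.MB], state[:, kin.MBD],
                                 cond.fluence, rat_params, consts,
                                 melanin=mel)
        dy = kin.reaction_rhs(state,
                              excitation_rate_constant(lf.intensity, consts),
                              consts)
        for s in kin.MB_FAMILY:
            dy[:, s] += op_mb.rhs(state[:, s], bc.mb_anterior,
                                  bc.mb_posterior)
        dy[:, kin.O2T] += op_o2.rhs(state[:, kin.O2T], bc.o2_anterior,
                                    bc.o2_posterior)
        return dy.ravel()

    jac = AnalyticJacobian(m, rat_params, consts, bc, mel, op_mb, op_o2,
                           cond.fluence)
    J = jac(0.0, y.ravel()).toarray()
    Jfd = approx_derivative(rhs, y.ravel(), method="3-point", rel_step=1e-6)
    scale = np.abs(Jfd).max()
    assert np.allclose(J, Jfd, rtol=1e-3, atol=1e-6 * scale)


@pytest.fixture(scope="module")
def short_run(rat_params):
    return sx.simulate(rat_params, sx.TreatmentConditions(duration=120.0))


class TestSimulate:
    def test_dark_run_has_no_crosslinks(self, rat_params):
        r = sx.simulate(rat_params,
                        sx.TreatmentConditions(fluence=0.0, duration=120.0))
        assert np.all(r.states[:, :, kin.XL1_SLICE] == 0.0)
        assert np.all(r.states[:, :, kin.XL2_SLICE] == 0.0)
        # MB still moves as a passive tracer
        assert r.states[-1][r.mesh.tissue_mask, kin.MB].max() > 0.0

    def test_crosslink_series_nondecreasing(self, short_run):
        ts = short_run.crosslink_series()
        assert np.all(np.diff(ts.XL_total_M) >= -1e-18)
        assert np.all(np.diff(ts.XL_typeI_M) >= -1e-18)

    def test_states_nonnegative(self, short_run):
        assert np.all(short_run.states >= 0.0)

    def test_light_intensity_nonincreasing_with_depth(self, short_run):
        for t in (0.0, 120.0):
            lf = short_run.light_field_at(t)
            assert np.all(np.diff(lf.intensity) <= 1e-15)

    def test_mb_moiety_decreases_only_via_clearance(self, rat_params, consts):
        """With a closed posterior boundary the whole-domain MB moiety is
        conserved; the default clearance sink strictly drains it."""
        cond = sx.TreatmentConditions(duration=120.0)
        m = build_mesh(rat_params, SMALL_COUNTS)
        closed = sx.simulate(rat_params, cond, mesh=m,
                             bc=BoundaryConditions(
                                 mb_anterior=sx.BoundarySpec("no_flux"),
                                 mb_posterior=sx.BoundarySpec("no_flux"),
                                 o2_anterior=sx.BoundarySpec(
                                     "dirichlet", value=4.81e-5),
                                 o2_posterior=sx.BoundarySpec(
                                     "dirichlet", value=2.18e-5)))
        w = closed.mesh.thickness_cm
        moiety = np.array([kin.mb_moiety_total(s) @ w for s in closed.states])
        assert np.allclose(moiety, moiety[0], rtol=1e-6)
        default = sx.simulate(rat_params, cond, mesh=m)
        moiety_d = np.array([kin.mb_moiety_total(s) @ w
                             for s in default.states])
        assert np.all(np.diff(moiety_d) < 0)

    def test_solver_tolerance_robustness(self, rat_params, short_run):
        tight = sx.simulate(rat_params,
                            sx.TreatmentConditions(duration=120.0),
                            rtol=1e-8, atol=1e-16)
        a = metrics.mean_crosslink_concentration(short_run)
        b = metrics.mean_crosslink_concentration(tight)
        assert abs(a - b) / b < 0.01

    def test_snapshot_access_and_save(self, tmp_path, short_run):
        assert short_run.state_at(0.0).shape == \
            (short_run.mesh.n_nodes, kin.N_SPECIES)
        with pytest.raises(ValueError):
            short_run.state_at(1e6)
        out = short_run.save(tmp_path / "run")
        assert (out / "timeseries.tsv").exists()
        assert (out / "config.json").exists()
        assert any(out.glob("profile_t*.tsv"))

    def test_config_hash_is_deterministic(self, rat_params, short_run):
        again = sx.simulate(rat_params,
                            sx.TreatmentConditions(duration=120.0))
        assert again.config_hash == short_run.config_hash
        other = sx.simulate(rat_params,
                            sx.TreatmentConditions(duration=120.0,
                                                   fluence=500.0))
        assert other.config_hash != short_run.config_hash

    def test_qualitative_front_contrast(self, baseline_results):
        """The rat MB monomer front stays posterior while the human front
        advances: compare the anterior-half share of scleral MB."""
        shares = {}
        for s in ("rat", "human"):
            r = baseline_results[s]
            m = r.mesh
            scl = m.mask("sclera")
            mb = r.states[-1][scl, kin.MB] + 2 * r.states[-1][scl, kin.MBD]
            half = mb.size // 2
            shares[s] = mb[:half].sum() / mb.sum()
        assert shares["human"] < shares["rat"]

    def test_oxygen_transient_relaxes(self, baseline_results):
        """Reservoir-borne O₂ elevates the posterior sclera early and then
        relaxes back toward the vascular profile."""
        r = baseline_results["rat"]
        m = r.mesh
        post_scl = m.layer_slice("sclera").stop - 1
        o2 = r.states[:, post_scl, kin.O2T]
        i30 = r.index_of_time(30.0)
        assert o2[i30] > o2[-1]
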