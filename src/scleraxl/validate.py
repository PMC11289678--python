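"""Fast structural invariant checks, callable from the CLI ``validate`` verb.

These are smoke-level versions of the package's property tests: they run in
seconds on toy configurations and return a list of human-readable failure
descriptions (empty list = all good).
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp

from . import kinetics as kin
from .mesh import build_mesh
from .optics import compute_light_field
from .parameters import (TreatmentConditions, load_shared_constants,
                         load_species_params, mb_equilibrium_partition)
from .simulator import initial_state
from .transport import BoundaryConditions


def run_checks() -> list[str]:
    failures: list[str] = []
    consts = load_shared_constants()
    params = load_species_params("rat")
    mesh = build_mesh(params)

    # light field: flat with absorbers and reflection off
    from dataclasses import replace
    c0 = replace(consts, eps_mbm=0.0, eps_mbd=0.0, eps_mel=0.0,
                 phi_fundus=0.0)
    lf = compute_light_field(mesh, np.zeros(mesh.n_nodes),
                             np.zeros(mesh.n_nodes), 424.0, params, c0)
    if not np.allclose(lf.intensity, 424.0, rtol=1e-12):
        failures.append("light field not flat with zero absorbers")

    # monotone light decay with baseline absorbers
    y0 = initial_state(params, TreatmentConditions(), mesh, consts)
    lf = compute_light_field(mesh, y0[:, kin.MB], y0[:, kin.MBD], 424.0,
                             params, consts)
    if np.any(np.diff(lf.intensity) > 1e-15):
        failures.append("light intensity not nonincreasing with depth")

    # dark closed-node kinetics conserve MB moiety and relax to K_D
    y = np.zeros((1, kin.N_SPECIES))
    y[0, kin.MB] = 1e-3

    def rhs(t, yy):
        return kin.reaction_rhs(np.maximum(yy.reshape(1, -1), 0.0),
                                np.zeros(1), consts).ravel()

    sol = solve_ivp(rhs, (0.0, 0.05), y.ravel(), method="BDF",
                    rtol=1e-10, atol=1e-16)
    yf = sol.y[:, -1].reshape(1, -1)
    moiety0 = kin.mb_moiety_total(y)[0]
    moietyf = kin.mb_moiety_total(yf)[0]
    if abs(moietyf - moiety0) / moiety0 > 1e-8:
        failures.append("MB moiety not conserved in dark closed node")
    ratio = yf[0, kin.MBD] / yf[0, kin.MB] ** 2
    if abs(ratio - consts.k_dim) / consts.k_dim > 1e-4:
        failures.append("dark dimerization does not relax to K_D")
    mono, dim = mb_equilibrium_partition(1e-3, consts.k_dim)
    if abs(yf[0, kin.MB] - mono) / mono > 1e-4:
        failures.append("dark equilibrium disagrees with closed-form partition")

    # closed-domain diffusion conserves mass
    from .transport import DiffusionOperator, assemble_diffusivity
    op = DiffusionOperator(mesh, assemble_diffusivity(mesh, consts, "MB"))
    bc = BoundaryConditions.closed()
    c = np.zeros(mesh.n_nodes)
    c[mesh.reservoir_mask] = 1e-3

    sol = solve_ivp(lambda t, cc: op.rhs(cc, bc.mb_anterior, bc.mb_posterior),
                    (0.0, 200.0), c, method="BDF", rtol=1e-10, atol=1e-16)
    m0 = float(c @ mesh.thickness_cm)
    mf = float(sol.y[:, -1] @ mesh.thickness_cm)
    if abs(mf - m0) / m0 > 1e-8:
        failures.append("closed diffusion does not conserve mass")
    return failures
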