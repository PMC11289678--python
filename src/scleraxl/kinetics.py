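"""Photochemical reaction network: type I / type II crosslinking and side paths.

All reactions are elementary mass-action terms evaluated per node. The type I
pathway runs ³MB + AA → AA• (chemical quenching, k5) followed by
AA• + ³O₂ → crosslink (k8). The type II pathway runs ³MB + ³O₂ → ¹O₂ (k9)
followed by ¹O₂ + AA → crosslink (k14). Unproductive channels: dimerization
(k1/k2), solvent and collisional quenching of ³MB (k3, k4), leuco-MB
formation (k7), solvent and physical quenching of ¹O₂ (k10, k11), amino-acid
oxidation (k13) and optional MB photodegradation (k_deg, off by default).

Crosslink stoichiometry is one crosslink per reacting amino-acid event, and
amino-acid bookkeeping (ground / radical / oxidized / type I / type II sinks)
is kept per amino acid so that per-AA conservation is exact.
"""

from __future__ import annotations

import numpy as np

from .parameters import AMINO_ACIDS, SharedConstants

# ---------------------------------------------------------------------------
# state layout: one row per node, one column per chemical pool.

MB, MBD, MBT, MBSR, MBL, MBX, O2T, O2S = range(8)
N_MOBILE = 8
N_AA = len(AMINO_ACIDS)

AA0 = N_MOBILE                 # ground-state amino acids, 5 columns
RAD0 = AA0 + N_AA              # amino-acid radicals
OX0 = RAD0 + N_AA              # oxidized amino acids
XL1_0 = OX0 + N_AA             # type I crosslinks (per contributing AA)
XL2_0 = XL1_0 + N_AA           # type II crosslinks (per contributing AA)
N_SPECIES = XL2_0 + N_AA       # = 33

AA_SLICE = slice(AA0, AA0 + N_AA)
RAD_SLICE = slice(RAD0, RAD0 + N_AA)
OX_SLICE = slice(OX0, OX0 + N_AA)
XL1_SLICE = slice(XL1_0, XL1_0 + N_AA)
XL2_SLICE = slice(XL2_0, XL2_0 + N_AA)

#: Mobile species that diffuse with the MB diffusivity.
MB_FAMILY = (MB, MBD, MBSR, MBL, MBX)
#: Mobile species that diffuse with the O2 diffusivity (³O₂ only; ¹O₂ and
#: ³MB lifetimes are far below the per-node diffusion time).
O2_FAMILY = (O2T,)
DIFFUSING = MB_FAMILY + O2_FAMILY

SPECIES_NAMES: tuple[str, ...] = (
    "MB_monomer", "MB_dimer", "MB_triplet", "MB_semireduced", "MB_leuco",
    "MB_degraded", "O2_triplet", "O2_singlet",
    *(f"AA_{a}" for a in AMINO_ACIDS),
    *(f"AArad_{a}" for a in AMINO_ACIDS),
    *(f"AAox_{a}" for a in AMINO_ACIDS),
    *(f"XL_typeI_{a}" for a in AMINO_ACIDS),
    *(f"XL_typeII_{a}" for a in AMINO_ACIDS),
)


def reaction_rhs(state: np.ndarray, gamma: np.ndarray,
                 consts: SharedConstants, out: np.ndarray | None = None
                 ) -> np.ndarray:
    """Local reaction time-derivatives (M s⁻¹) for every node.

    Parameters
    ----------
    state : (n_nodes, N_SPECIES) nonnegative concentrations (M).
    gamma : (n_nodes,) first-order excitation rate constant Γ (s⁻¹).
    out : optional preallocated output array.
    """
    if np.any(state < 0):
        raise ValueError("reaction_rhs requires a nonnegative state")
    c = consts
    if out is None:
        out = np.zeros_like(state)
    else:
        out[:] = 0.0

    mb = state[:, MB]
    mbd = state[:, MBD]
    mbt = state[:, MBT]
    mbsr = state[:, MBSR]
    o2t = state[:, O2T]
    o2s = state[:, O2S]
    aa = state[:, AA_SLICE]
    rad = state[:, RAD_SLICE]

    k_phys, k_rad = c.triplet_quench_vectors()
    k11 = c.rate_vector("k11")
    k13 = c.rate_vector("k13")
    k14 = c.rate_vector("k14")

    # 1. photoexcitation MB -> 3MB
    r_exc = gamma * mb
    # 2. dimerization 2 MB <-> MBD
    r_dim = c.k1 * mb * mb
    r_dis = c.k2 * mbd
    # 3. 3MB solvent quench
    r_q3 = c.k3 * mbt
    # 4. 3MB physical quenching by MB monomer (and, if configured strictly
    #    physically, by Met/Cys); quencher kept
    r_q4_mb = c.k4.get("MB", 0.0) * mbt * mb
    r_q4_aa = k_phys * mbt[:, None] * aa       # (n, 5)
    # 5. 3MB radical-forming quenching -> MBsr + AA radical (k5, and the
    #    Met/Cys k4 channels under the default chemical routing)
    r_q5 = k_rad * mbt[:, None] * aa
    # 6. leuco formation MBsr + 3O2 -> MBleuco
    r_leuco = c.k7 * mbsr * o2t
    # 7. type I crosslink AArad + 3O2 -> XL1
    r_xl1 = c.k8 * rad * o2t[:, None]
    # 8. singlet oxygen generation 3MB + 3O2 -> MB + 1O2
    r_sing = c.k9 * mbt * o2t
    # 9. 1O2 solvent quench
    r_q10 = c.k10 * o2s
    # 10. 1O2 physical quenching by AA (AA kept)
    r_q11 = k11 * o2s[:, None] * aa
    # 11. oxidized AA from 1O2 chemical quenching
    r_ox = k13 * o2s[:, None] * aa
    # 12. type II crosslink 1O2 + AA -> XL2
    r_xl2 = k14 * o2s[:, None] * aa
    # 13. optional MB photodegradation 1O2 + MB -> MBdeg
    r_deg = c.k_deg * o2s * mb

    out[:, MB] = (-r_exc - 2.0 * r_dim + 2.0 * r_dis + r_q3 + r_q4_mb
                  + r_q4_aa.sum(axis=1) + r_sing - r_deg)
    out[:, MBD] = r_dim - r_dis
    out[:, MBT] = (r_exc - r_q3 - r_q4_mb - r_q4_aa.sum(axis=1)
                   - r_q5.sum(axis=1) - r_sing)
    out[:, MBSR] = r_q5.sum(axis=1) - r_leuco
    out[:, MBL] = r_leuco
    out[:, MBX] = r_deg
    out[:, O2T] = (-r_leuco - r_xl1.sum(axis=1) - r_sing + r_q10
                   + r_q11.sum(axis=1))
    out[:, O2S] = (r_sing - r_q10 - r_q11.sum(axis=1) - r_ox.sum(axis=1)
                   - r_xl2.sum(axis=1) - r_deg)
    out[:, AA_SLICE] = -r_q5 - r_ox - r_xl2
    out[:, RAD_SLICE] = r_q5 - r_xl1
    out[:, OX_SLICE] = r_ox
    out[:, XL1_SLICE] = r_xl1
    out[:, XL2_SLICE] = r_xl2
    return out


def mb_moiety_total(state: np.ndarray) -> np.ndarray:
    """Per-node MB monomer-equivalents: M + 2·D + ³MB + MBsr + leuco + degraded."""
    return (state[:, MB] + 2.0 * state[:, MBD] + state[:, MBT]
            + state[:, MBSR] + state[:, MBL] + state[:, MBX])


def per_aa_totals(state: np.ndarray) -> np.ndarray:
    """Per-node, per-AA invariant: ground + radical + oxidized + XL1 + XL2."""
    return (state[:, AA_SLICE] + state[:, RAD_SLICE] + state[:, OX_SLICE]
            + state[:, XL1_SLICE] + state[:, XL2_SLICE])


def reaction_registry(consts: SharedConstants) -> list[dict]:
    """Auditable listing of every reaction (name, reactants, products, rate)."""
    c = consts
    reg: list[dict] = [
        {"name": "photoexcitation", "reactants": ["MB", "photon"],
         "products": ["MB_triplet"], "rate": "Gamma(I)"},
        {"name": "dimer_formation", "reactants": ["MB", "MB"],
         "products": ["MB_dimer"], "rate": c.k1},
        {"name": "dimer_dissociation", "reactants": ["MB_dimer"],
         "products": ["MB", "MB"], "rate": c.k2},
        {"name": "triplet_solvent_quench", "reactants": ["MB_triplet"],
         "products": ["MB"], "rate": c.k3},
        {"name": "triplet_physical_quench_MB",
         "reactants": ["MB_triplet", "MB"], "products": ["MB", "MB"],
         "rate": c.k4.get("MB", 0.0)},
    ]
    k_phys, k_rad = c.triplet_quench_vectors()
    for a, kp, kr in zip(AMINO_ACIDS, k_phys, k_rad):
        if kp:
            reg.append({"name": f"triplet_physical_quench_{a}",
                        "reactants": ["MB_triplet", f"AA_{a}"],
                        "products": ["MB", f"AA_{a}"], "rate": float(kp)})
        if kr:
            reg.append({"name": f"triplet_radical_quench_{a}",
                        "reactants": ["MB_triplet", f"AA_{a}"],
                        "products": ["MB_semireduced", f"AArad_{a}"],
                        "rate": float(kr)})
    reg.append({"name": "leuco_formation",
                "reactants": ["MB_semireduced", "O2_triplet"],
                "products": ["MB_leuco"], "rate": c.k7})
    for a in AMINO_ACIDS:
        reg.append({"name": f"type_I_crosslink_{a}",
                    "reactants": [f"AArad_{a}", "O2_triplet"],
                    "products": [f"XL_typeI_{a}"], "rate": c.k8})
    reg.append({"name": "singlet_oxygen_generation",
                "reactants": ["MB_triplet", "O2_triplet"],
                "products": ["MB", "O2_singlet"], "rate": c.k9})
    reg.append({"name": "singlet_solvent_quench", "reactants": ["O2_singlet"],
                "products": ["O2_triplet"], "rate": c.k10})
    for a, k in c.k11.items():
        reg.append({"name": f"singlet_physical_quench_{a}",
                    "reactants": ["O2_singlet", f"AA_{a}"],
                    "products": ["O2_triplet", f"AA_{a}"], "rate": k})
    for a, k in c.k13.items():
        reg.append({"name": f"aa_oxidation_{a}",
                    "reactants": ["O2_singlet", f"AA_{a}"],
                    "products": [f"AAox_{a}"], "rate": k})
    for a, k in c.k14.items():
        reg.append({"name": f"type_II_crosslink_{a}",
                    "reactants": ["O2_singlet", f"AA_{a}"],
                    "products": [f"XL_typeII_{a}"], "rate": k})
    if c.k_deg:
        reg.append({"name": "mb_photodegradation",
                    "reactants": ["O2_singlet", "MB"],
                    "products": ["MB_degraded"], "rate": c.k_deg})
    for name, k in c.extra_rates.items():
        reg.append({"name": name, "reactants": [], "products": [], "rate": k})
    return reg
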