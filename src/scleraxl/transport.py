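"""Finite-volume Fickian diffusion over the heterogeneous 1D mesh.

Fluxes between adjacent nodes use the harmonic mean of the node
diffusivities and the center-to-center distance; each node's derivative is
the net flux divided by its slab thickness, so mass is conserved to
round-off under closed boundaries.

Default boundary conditions for the treatment geometry:

* anterior face (RPE): no-flux for all MB species (the RPE is a barrier);
  fixed concentration for ³O₂ at the choroidal baseline (the choroidal
  vasculature as O₂ source);
* posterior face: Robin-type clearance sink for MB species toward a
  zero-concentration retrobulbar bath across the clearance distance
  X_Retro (series resistance X_Retro / D_MB,res plus the boundary half
  node); fixed ³O₂ at the retrobulbar baseline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .mesh import Mesh
from .parameters import SharedConstants, SpeciesParams, oxygen_baseline

UM_PER_CM = 1.0e4

BCKind = Literal["no_flux", "dirichlet", "robin"]


@dataclass(frozen=True)
class BoundarySpec:
    """One boundary face: ``no_flux``, ``dirichlet`` (value, M) or ``robin``
    (external resistance in s cm⁻¹ toward a zero-concentration bath)."""

    kind: BCKind
    value: float = 0.0       # Dirichlet concentration (M)
    resistance: float = 0.0  # Robin external resistance (s cm^-1)

    def __post_init__(self) -> None:
        if self.kind == "dirichlet" and self.value < 0:
            raise ValueError("Dirichlet boundary value must be >= 0")
        if self.kind == "robin" and self.resistance < 0:
            raise ValueError("Robin resistance must be >= 0")


@dataclass(frozen=True)
class BoundaryConditions:
    """Boundary set for the two mobile families."""

    mb_anterior: BoundarySpec
    mb_posterior: BoundarySpec
    o2_anterior: BoundarySpec
    o2_posterior: BoundarySpec
    distributed_o2_source: bool = False

    @classmethod
    def closed(cls) -> "BoundaryConditions":
        """All no-flux: used for conservation checks."""
        nf = BoundarySpec("no_flux")
        return cls(nf, nf, nf, nf)

    @classmethod
    def for_treatment(cls, params: SpeciesParams, consts: SharedConstants,
                      pct_inspired_o2: float,
                      closed_posterior_mb: bool = False
                      ) -> "BoundaryConditions":
        """Standard retrobulbar-injection treatment boundaries."""
        r_clear = (params.x_retro / UM_PER_CM) / consts.d_mb_res
        return cls(
            mb_anterior=BoundarySpec("no_flux"),
            mb_posterior=(BoundarySpec("no_flux") if closed_posterior_mb
                          else BoundarySpec("robin", resistance=r_clear)),
            o2_anterior=BoundarySpec(
                "dirichlet",
                value=oxygen_baseline(pct_inspired_o2, params, "choroid")),
            o2_posterior=BoundarySpec(
                "dirichlet",
                value=oxygen_baseline(pct_inspired_o2, params, "reservoir")),
        )


def assemble_diffusivity(mesh: Mesh, consts: SharedConstants,
                         family: Literal["MB", "O2"]) -> np.ndarray:
    """Per-node diffusivity profile (cm² s⁻¹) for one mobile family."""
    if family == "MB":
        d = np.full(mesh.n_nodes, consts.d_mb_tis)
        d[mesh.reservoir_mask] = consts.d_mb_res
    elif family == "O2":
        d = np.full(mesh.n_nodes, consts.d_o2_tis)
    else:
        raise ValueError("family must be 'MB' or 'O2'")
    return d


class DiffusionOperator:
    """Precomputed finite-volume geometry for one diffusivity profile.

    ``rhs(c, anterior, posterior)`` returns dc/dt (M s⁻¹).
    """

    def __init__(self, mesh: Mesh, d_profile: np.ndarray):
        d_profile = np.asarray(d_profile, dtype=float)
        if d_profile.shape != (mesh.n_nodes,):
            raise ValueError("diffusivity profile does not match mesh")
        if np.any(d_profile <= 0):
            raise ValueError("diffusivities must be > 0")
        self.mesh = mesh
        self.d = d_profile
        dx = mesh.thickness_cm
        self.dx = dx
        # interior faces: harmonic-mean conductance per unit concentration
        # difference, G = D_face / distance-between-centers
        d_face = 2.0 * d_profile[:-1] * d_profile[1:] / (
            d_profile[:-1] + d_profile[1:])
        dist = 0.5 * (dx[:-1] + dx[1:])
        self.g_face = d_face / dist
        # boundary half-node resistances (s cm^-1)
        self.r_half_ant = 0.5 * dx[0] / d_profile[0]
        self.r_half_post = 0.5 * dx[-1] / d_profile[-1]

    def _boundary_flux(self, c_node: float, r_half: float,
                       spec: BoundarySpec) -> float:
        """Flux INTO the domain through a boundary face (mol cm⁻² s⁻¹ / M·cm·s⁻¹)."""
        if spec.kind == "no_flux":
            return 0.0
        if spec.kind == "dirichlet":
            return (spec.value - c_node) / r_half
        if spec.kind == "robin":
            return (0.0 - c_node) / (r_half + spec.resistance)
        raise ValueError(f"unknown boundary kind {spec.kind!r}")

    def rhs(self, c: np.ndarray, anterior: BoundarySpec,
            posterior: BoundarySpec, out: np.ndarray | None = None
            ) -> np.ndarray:
        if c.shape != (self.mesh.n_nodes,):
            raise ValueError("field length does not match mesh")
        if out is None:
            out = np.empty_like(c)
        flux = self.g_face * (c[:-1] - c[1:])  # positive = anterior→posterior
        f_ant = self._boundary_flux(c[0], self.r_half_ant, anterior)
        f_post = -self._boundary_flux(c[-1], self.r_half_post, posterior)
        out[0] = (f_ant - flux[0]) / self.dx[0] if c.size > 1 else \
            (f_ant - f_post) / self.dx[0]
        if c.size > 1:
            out[1:-1] = (flux[:-1] - flux[1:]) / self.dx[1:-1]
            out[-1] = (flux[-1] - f_post) / self.dx[-1]
        return out


def diffusion_rhs(field: np.ndarray, mesh: Mesh, d_profile: np.ndarray,
                  anterior: BoundarySpec = BoundarySpec("no_flux"),
                  posterior: BoundarySpec = BoundarySpec("no_flux")
                  ) -> np.ndarray:
    """One-shot finite-volume diffusion derivative for a single species."""
    return DiffusionOperator(mesh, d_profile).rhs(
        np.asarray(field, dtype=float), anterior, posterior)
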