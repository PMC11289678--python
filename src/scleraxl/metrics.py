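"""Summary quantities derived from a simulation result.

All tissue averages are thickness-weighted over choroid + sclera + Tenon
(the reservoir is excluded); total moles multiply the mean concentration by
the peripapillary tissue volume (a hollow spherical frustum around the
optic nerve head, supplied as a species constant).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import kinetics as kin
from .parameters import AMINO_ACIDS, SpeciesParams, crosslink_sites_possible
from .simulator import SimulationResult

MB_POOLS = (("monomer", kin.MB), ("dimer", kin.MBD), ("triplet", kin.MBT),
            ("semireduced", kin.MBSR), ("leuco", kin.MBL),
            ("degraded", kin.MBX))


def _tissue_weights(result: SimulationResult) -> tuple[np.ndarray, np.ndarray]:
    mask = result.mesh.tissue_mask
    w = result.mesh.thickness_cm[mask]
    return mask, w / w.sum()


def mean_crosslink_concentration(result: SimulationResult,
                                 t: float | None = None) -> float:
    """Thickness-weighted mean of type I + type II crosslinks (M) over tissue."""
    mask, w = _tissue_weights(result)
    s = result.states[-1] if t is None else result.state_at(t)
    xl = s[mask, kin.XL1_SLICE].sum(axis=1) + s[mask, kin.XL2_SLICE].sum(axis=1)
    return float(xl @ w)


def total_crosslinks(result: SimulationResult,
                     params: SpeciesParams | None = None) -> float:
    """Total crosslinks (mol): mean concentration × tissue volume.

    Volume in cm³ is converted to litres since concentrations are molar.
    """
    params = params or result.params
    return mean_crosslink_concentration(result) * params.tissue_volume_cm3 * 1e-3


def site_utilization(result: SimulationResult,
                     params: SpeciesParams | None = None) -> float:
    """Crosslink site utilization (% of sites possible)."""
    params = params or result.params
    return 100.0 * mean_crosslink_concentration(result) / \
        crosslink_sites_possible(params)


def peak_location(result: SimulationResult
                  ) -> tuple[float, float] | None:
    """(µm from RPE, % of scleral depth) of the final crosslink maximum.

    Returns None if no crosslinks formed. The scleral-depth fraction is
    (x − X_Chor) / X_Scl; values < 0 or > 100 indicate a peak outside
    the sclera.
    """
    mask = result.mesh.tissue_mask
    s = result.states[-1]
    xl = s[mask, kin.XL1_SLICE].sum(axis=1) + s[mask, kin.XL2_SLICE].sum(axis=1)
    if not np.any(xl > 0):
        return None
    x = float(result.mesh.center_um[mask][int(np.argmax(xl))])
    frac = 100.0 * (x - result.params.x_chor) / result.params.x_scl
    return x, frac


def amino_acid_depletion(result: SimulationResult, aa: str,
                         location: str | int = "posterior_sclera") -> float:
    """Percent depletion of one amino acid at a node.

    ``location`` is either a node index or ``"posterior_sclera"`` (the
    posterior-most scleral node). Returns 100·(1 − [AA]_final/[AA]_initial).
    """
    if aa not in AMINO_ACIDS:
        raise ValueError(f"unknown amino acid {aa!r}; expected {AMINO_ACIDS}")
    col = kin.AA0 + AMINO_ACIDS.index(aa)
    if location == "posterior_sclera":
        node = result.mesh.layer_slice("sclera").stop - 1
    else:
        node = int(location)
    c0 = result.states[0, node, col]
    if c0 == 0:
        return 0.0
    return 100.0 * (1.0 - result.states[-1, node, col] / c0)


def mb_speciation(result: SimulationResult, t: float) -> dict[str, float]:
    """Percent of MB-derived species in each pool at time ``t``.

    Thickness-weighted totals over the whole domain (tissue + reservoir);
    fractions are over species concentrations with the dimer counted once
    (not in monomer-equivalents). ``monomer_equiv_total_M`` is also included
    for mass-balance checks.
    """
    s = result.state_at(t)
    w = result.mesh.thickness_cm / result.mesh.thickness_cm.sum()
    totals = {name: float(s[:, idx] @ w) for name, idx in MB_POOLS}
    denom = sum(totals.values())
    out = {f"{name}_pct": (100.0 * v / denom if denom > 0 else 0.0)
           for name, v in totals.items()}
    out["monomer_equiv_total_M"] = float(kin.mb_moiety_total(s) @ w)
    out["species_total_M"] = denom
    return out


def pathway_split(result: SimulationResult) -> float | None:
    """Type I share of final crosslinks (%), or None if none formed."""
    mask, w = _tissue_weights(result)
    s = result.states[-1]
    xl1 = float(s[mask, kin.XL1_SLICE].sum(axis=1) @ w)
    xl2 = float(s[mask, kin.XL2_SLICE].sum(axis=1) @ w)
    if xl1 + xl2 == 0:
        return None
    return 100.0 * xl1 / (xl1 + xl2)


@dataclass(frozen=True)
class MetricsReport:
    """The summary rows reported for one run."""

    species: str
    total_crosslinks_mol: float
    mean_crosslink_concentration_M: float
    sites_possible_M: float
    utilization_pct: float
    peak_um: float | None
    peak_pct_sclera: float | None
    typeI_pct: float | None
    depletion_posterior_sclera_pct: dict[str, float]
    dimer_fraction_final_pct: float

    def to_text(self) -> str:
        lines = [
            f"species\t{self.species}",
            f"total crosslinks (mol)\t{self.total_crosslinks_mol:.3e}",
            f"total crosslink concentration (M)\t"
            f"{self.mean_crosslink_concentration_M:.3e}",
            f"crosslink sites possible (M)\t{self.sites_possible_M:.3e}",
            f"crosslink site utilization (% crosslink sites possible)\t"
            f"{self.utilization_pct:.3e}",
            f"peak crosslink location (um from RPE)\t"
            f"{'' if self.peak_um is None else f'{self.peak_um:.1f}'}",
            f"peak location (% of scleral depth)\t"
            f"{'' if self.peak_pct_sclera is None else f'{self.peak_pct_sclera:.1f}'}",
            f"type I fraction (%)\t"
            f"{'' if self.typeI_pct is None else f'{self.typeI_pct:.2f}'}",
            f"MB dimer fraction at end (%)\t{self.dimer_fraction_final_pct:.2f}",
        ]
        for aa, d in self.depletion_posterior_sclera_pct.items():
            lines.append(f"depletion {aa} at posterior sclera (%)\t{d:.2f}")
        return "\n".join(lines) + "\n"

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_text())


def metrics_report(result: SimulationResult) -> MetricsReport:
    """Compute the full summary for one finished run."""
    peak = peak_location(result)
    spec_end = mb_speciation(result, float(result.t[-1]))
    return MetricsReport(
        species=result.params.species_id,
        total_crosslinks_mol=total_crosslinks(result),
        mean_crosslink_concentration_M=mean_crosslink_concentration(result),
        sites_possible_M=crosslink_sites_possible(result.params),
        utilization_pct=site_utilization(result),
        peak_um=None if peak is None else peak[0],
        peak_pct_sclera=None if peak is None else peak[1],
        typeI_pct=pathway_split(result),
        depletion_posterior_sclera_pct={
            aa: amino_acid_depletion(result, aa) for aa in AMINO_ACIDS},
        dimer_fraction_final_pct=spec_end["dimer_pct"],
    )
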