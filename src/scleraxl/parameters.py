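"""Parameter registry for the scleral photocrosslinking model.

Holds the per-species anatomy/composition presets, the shared photochemical
and transport constants, and the small derived quantities built from them:
the inspired-O2 scaling of tissue oxygen baselines, the monomer/dimer
equilibrium partition of injected methylene blue (MB), and the
crosslink-sites-possible concentration used to express utilization.

Units follow the printed convention of the source tables: lengths in µm,
concentrations in M (except the injected MB dose, quoted in mM), molar
absorptivities in M⁻¹ cm⁻¹ (decadic), diffusivities in cm² s⁻¹. Conversions
to the cm/M/s system used by the solver happen once, at mesh / initial-state
assembly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import yaml

#: Canonical amino-acid ordering used throughout the package.
AMINO_ACIDS: tuple[str, ...] = ("His", "Met", "Trp", "Cys", "Tyr")

SPECIES_IDS: tuple[str, ...] = ("rat", "minipig", "human")


class ConfigurationError(ValueError):
    """Raised for unknown presets or inconsistent parameter bundles."""


@dataclass(frozen=True)
class SpeciesParams:
    """Anatomy and composition of one species' posterior eye wall.

    Lengths are in µm, concentrations in M, densities in g cm⁻³ and the
    peripapillary tissue volume (a hollow spherical frustum around the
    optic nerve head) in cm³.
    """

    species_id: str
    x_rpe: float
    x_chor: float
    x_scl: float
    x_ten: float
    x_inj: float
    x_retro: float
    aa_scleral: dict[str, float]
    aa_choroidal: dict[str, float]
    mel_rpe: float
    mel_chor: float
    mel_scl: float
    o2_chor_21: float
    o2_res_21: float
    rho_scl: float
    rho_chor: float
    tissue_volume_cm3: float

    def __post_init__(self) -> None:
        for name in ("x_rpe", "x_chor", "x_scl", "x_ten", "x_inj", "x_retro"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        for pool in (self.aa_scleral, self.aa_choroidal):
            if set(pool) != set(AMINO_ACIDS):
                raise ConfigurationError(
                    f"amino-acid map must cover exactly {AMINO_ACIDS}"
                )
            if any(v < 0 for v in pool.values()):
                raise ConfigurationError("amino-acid concentrations must be >= 0")
        for name in ("mel_rpe", "mel_chor", "mel_scl", "o2_chor_21",
                     "o2_res_21", "tissue_volume_cm3"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")

    @property
    def tissue_length_um(self) -> float:
        """Total meshed tissue length choroid + sclera + Tenon (µm)."""
        return self.x_chor + self.x_scl + self.x_ten


@dataclass(frozen=True)
class SharedConstants:
    """Photochemical and transport constants shared across species.

    ``k2`` (MB dimer dissociation, s⁻¹) is derived as ``k1 / K_D``.
    ``extra_rates`` accepts additional named rate constants so the reaction
    registry can be extended without code changes.
    """

    t_default: float = 1800.0
    i_default: float = 424.0
    c0_mb_default_mm: float = 3.0
    wavelength_nm: float = 660.0
    phi_lumen: float = 5.1e-1
    phi_fundus: float = 9.6e-2
    phi_mbt: float = 5.2e-1
    eps_mbm: float = 7.33e4
    eps_mbd: float = 3.53e4
    eps_mel: float = 646.0
    d_mb_res: float = 4.60e-6
    d_mb_tis: float = 3.16e-7
    d_o2_tis: float = 6.00e-6
    k_dim: float = 1.0665e4  # K_D
    k1: float = 3.02e8
    k3: float = 1.3e4
    k4: Mapping[str, float] = field(
        default_factory=lambda: {"MB": 4.1e7, "Met": 1.0e8, "Cys": 1.92e9})
    k5: Mapping[str, float] = field(
        default_factory=lambda: {"His": 2.0e6, "Trp": 6.0e8, "Tyr": 2.96e7})
    k7: float = 89.0
    k8: float = 4.0e6
    k9: float = 2.6e9
    k10: float = 2.56e5
    k11: Mapping[str, float] = field(
        default_factory=lambda: {"Trp": 2.1e7, "Tyr": 2.7e7, "Cys": 4.2e7})
    k13: Mapping[str, float] = field(
        default_factory=lambda: {"Met": 1.6e7, "Cys": 8.9e6})
    k14: Mapping[str, float] = field(
        default_factory=lambda: {"His": 1.0e8, "Trp": 3.0e7, "Tyr": 8.0e6})
    k_deg: float = 0.0
    #: Route the Met/Cys MB-triplet quenching channels (k4) into the
    #: radical-forming (type I) pathway, so that all five amino acids feed
    #: crosslink formation. False makes them strictly physical
    #: (quencher-conserving), which suppresses Met/Cys radical chemistry.
    triplet_aa_quench_chemical: bool = True
    extra_rates: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        scalars = ("k1", "k3", "k7", "k8", "k9", "k10", "k_deg", "k_dim")
        if any(getattr(self, n) < 0 for n in scalars):
            raise ConfigurationError("rate constants must be >= 0")
        for name in ("k4", "k5", "k11", "k13", "k14"):
            if any(v < 0 for v in getattr(self, name).values()):
                raise ConfigurationError(f"{name} entries must be >= 0")

    @property
    def k2(self) -> float:
        """MB dimer dissociation rate (s⁻¹), k1 / K_D."""
        return self.k1 / self.k_dim

    def rate_vector(self, kmap: str) -> np.ndarray:
        """Per-amino-acid rate vector in :data:`AMINO_ACIDS` order (0 where absent)."""
        m = getattr(self, kmap)
        return np.array([m.get(a, 0.0) for a in AMINO_ACIDS])

    def triplet_quench_vectors(self) -> tuple[np.ndarray, np.ndarray]:
        """(physical, radical-forming) per-AA ³MB quenching rate vectors.

        The radical channel is k5 plus — unless
        ``triplet_aa_quench_chemical`` is False — the amino-acid entries of
        k4; the physical channel is the remainder of k4.
        """
        k4 = self.rate_vector("k4")
        k5 = self.rate_vector("k5")
        if self.triplet_aa_quench_chemical:
            return np.zeros_like(k4), k5 + k4
        return k4, k5


@dataclass(frozen=True)
class TreatmentConditions:
    """Clinically adjustable treatment settings.

    fluence in mW cm⁻², injected MB in mM (monomer-equivalents),
    inspired O2 in % (21 = air), duration in s, injection volume in µl.
    """

    fluence: float = 424.0
    mb_injected_mm: float = 3.0
    pct_inspired_o2: float = 21.0
    duration: float = 1800.0
    injection_volume_ul: float = 100.0

    def __post_init__(self) -> None:
        if min(self.fluence, self.mb_injected_mm, self.pct_inspired_o2,
               self.injection_volume_ul) < 0:
            raise ConfigurationError("treatment settings must be >= 0")
        if self.duration <= 0:
            raise ConfigurationError("duration must be > 0")


# ---------------------------------------------------------------------------
# preset loading


def _data_text(name: str) -> str:
    return resources.files("scleraxl.data").joinpath(name).read_text()


def _num(value) -> float:
    # YAML 1.1 reads exponents without a sign ("3.02e8") as strings
    return float(value)


def _nummap(mapping: Mapping[str, object]) -> dict[str, float]:
    return {k: float(v) for k, v in mapping.items()}


def load_species_params(species_id: str,
                        overrides: Mapping[str, object] | None = None
                        ) -> SpeciesParams:
    """Load one of the bundled species presets (``rat``/``minipig``/``human``).

    ``overrides`` replaces top-level fields of the resulting
    :class:`SpeciesParams` (e.g. ``{"x_scl": 120.0}``).
    """
    if species_id not in SPECIES_IDS:
        raise ConfigurationError(
            f"unknown species {species_id!r}; valid options: {SPECIES_IDS}")
    raw = yaml.safe_load(_data_text(f"species_{species_id}.yaml"))
    lengths = raw["lengths_um"]
    params = SpeciesParams(
        species_id=raw["species_id"],
        x_rpe=_num(lengths["X_RPE"]), x_chor=_num(lengths["X_Chor"]),
        x_scl=_num(lengths["X_Scl"]), x_ten=_num(lengths["X_Ten"]),
        x_inj=_num(lengths["X_Inj"]), x_retro=_num(lengths["X_Retro"]),
        aa_scleral=_nummap(raw["amino_acids_scleral_M"]),
        aa_choroidal=_nummap(raw["amino_acids_choroidal_M"]),
        mel_rpe=_num(raw["melanin_M"]["RPE"]),
        mel_chor=_num(raw["melanin_M"]["choroid"]),
        mel_scl=_num(raw["melanin_M"]["sclera"]),
        o2_chor_21=_num(raw["oxygen_21pct_M"]["choroid"]),
        o2_res_21=_num(raw["oxygen_21pct_M"]["reservoir"]),
        rho_scl=_num(raw["density_g_cm3"]["sclera"]),
        rho_chor=_num(raw["density_g_cm3"]["choroid"]),
        tissue_volume_cm3=_num(raw["tissue_volume_cm3"]),
    )
    if overrides:
        params = replace(params, **dict(overrides))
    return params


def load_shared_constants(overrides: Mapping[str, object] | None = None
                          ) -> SharedConstants:
    """Load the bundled shared-constants preset, with optional field overrides."""
    raw = yaml.safe_load(_data_text("shared_constants.yaml"))
    kwargs = dict(
        t_default=_num(raw["t_default_s"]),
        i_default=_num(raw["I_default_mW_cm2"]),
        c0_mb_default_mm=_num(raw["C0_MB_default_mM"]),
        wavelength_nm=_num(raw["wavelength_nm"]),
        phi_lumen=_num(raw["Phi_Lumen"]),
        phi_fundus=_num(raw["Phi_Fundus"]),
        phi_mbt=_num(raw["Phi_MBT"]),
        eps_mbm=_num(raw["eps_MBM_M_cm"]),
        eps_mbd=_num(raw["eps_MBD_M_cm"]),
        eps_mel=_num(raw["eps_Mel_M_cm"]),
        d_mb_res=_num(raw["D_MB_Res_cm2_s"]),
        d_mb_tis=_num(raw["D_MB_Tis_cm2_s"]),
        d_o2_tis=_num(raw["D_O2_Tis_cm2_s"]),
        k_dim=_num(raw["K_D_per_M"]),
        k1=_num(raw["k1"]), k3=_num(raw["k3"]),
        k4=_nummap(raw["k4"]), k5=_nummap(raw["k5"]),
        k7=_num(raw["k7"]), k8=_num(raw["k8"]), k9=_num(raw["k9"]),
        k10=_num(raw["k10"]),
        k11=_nummap(raw["k11"]), k13=_nummap(raw["k13"]),
        k14=_nummap(raw["k14"]),
        k_deg=_num(raw["k_deg"]),
    )
    if overrides:
        kwargs.update(overrides)
    return SharedConstants(**kwargs)


# ---------------------------------------------------------------------------
# derived quantities


def oxygen_baseline(pct: float, params: SpeciesParams, compartment: str,
                    anchors: Sequence[tuple[float, float]] | None = None
                    ) -> float:
    """Baseline triplet-O2 concentration (M) at ``pct`` % inspired O2.

    Dissolved O2 is taken proportional to its inspired partial pressure
    (Henry's law), anchored at the measured 21 % value and at 0 M for 0 %
    inspired O2; the default is therefore a single line through the origin,
    covering hyperoxic (100 %) and hyperbaric (300 %) settings by
    extrapolation. A richer piecewise-linear anchor set ``[(pct, conc), ...]``
    may be supplied; beyond the last anchor the final segment's slope is
    extended.
    """
    if pct < 0:
        raise ValueError("per cent inspired O2 must be >= 0")
    if compartment == "choroid":
        c21 = params.o2_chor_21
    elif compartment == "reservoir":
        c21 = params.o2_res_21
    else:
        raise ValueError("compartment must be 'choroid' or 'reservoir'")
    if anchors is None:
        return c21 * pct / 21.0
    pts = sorted([(0.0, 0.0), *anchors])
    xs = np.array([p for p, _ in pts])
    ys = np.array([c for _, c in pts])
    if pct <= xs[-1]:
        return float(np.interp(pct, xs, ys))
    slope = (ys[-1] - ys[-2]) / (xs[-1] - xs[-2])
    return float(ys[-1] + slope * (pct - xs[-1]))


def mb_equilibrium_partition(total_mb: float, k_dim: float
                             ) -> tuple[float, float]:
    """Monomer/dimer split of a total MB pool at dimerization equilibrium.

    ``total_mb`` is in monomer-equivalents (M + 2D). Solves
    ``K_D·M² = D`` with ``M + 2D = total``, i.e.
    ``M = (−1 + sqrt(1 + 8·K_D·total)) / (4·K_D)``.

    Returns ``(monomer, dimer)`` in the same concentration unit as the input.
    """
    if total_mb < 0:
        raise ValueError("total MB must be >= 0")
    if k_dim < 0:
        raise ValueError("K_D must be >= 0")
    if total_mb == 0.0:
        return 0.0, 0.0
    if k_dim == 0.0:
        return total_mb, 0.0
    # conjugate form of (sqrt(1+8KC)-1)/(4K): stable as K·C -> 0
    monomer = 2.0 * total_mb / (1.0 + math.sqrt(1.0 + 8.0 * k_dim * total_mb))
    dimer = (total_mb - monomer) / 2.0
    return monomer, dimer


def crosslink_sites_possible(params: SpeciesParams) -> float:
    """Concentration of crosslinkable amino-acid sites (M).

    Length-weighted mean of the summed five-amino-acid initial
    concentrations over Tenon's capsule + sclera + choroid, with Tenon
    carrying scleral composition (its own is not characterized).
    """
    total_len = params.x_ten + params.x_scl + params.x_chor
    if total_len <= 0:
        raise ValueError("total tissue length must be > 0")
    s_scl = sum(params.aa_scleral[a] for a in AMINO_ACIDS)
    s_chor = sum(params.aa_choroidal[a] for a in AMINO_ACIDS)
    return (s_scl * (params.x_ten + params.x_scl)
            + s_chor * params.x_chor) / total_len
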