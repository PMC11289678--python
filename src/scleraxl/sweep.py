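"""Treatment-parameter sweeps and grid-search optimization.

Runs the simulator over the Cartesian product of injected MB concentration,
laser fluence and per cent inspired O₂ (per species) and reports a
long-format results table. The optimum is the grid argmax of total
crosslinks, with ties broken toward the mildest treatment (lower MB, then
lower fluence, then lower O₂).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import metrics
from .mesh import build_mesh
from .parameters import (SharedConstants, SpeciesParams, TreatmentConditions,
                         load_shared_constants, load_species_params)
from .simulator import SimulationResult, SolverError, simulate

#: Anchor values named in the published sweep figures.
DEFAULT_MB_VALUES_MM = (0.3, 3.0, 30.0, 100.0)
DEFAULT_FLUENCE_VALUES = (10.0, 424.0, 1000.0)
DEFAULT_O2_VALUES_PCT = (21.0, 100.0, 300.0)

RESULT_COLUMNS = ("species", "mb_mM", "fluence_mW_cm2", "o2_pct",
                  "total_crosslinks_mol", "utilization_pct", "peak_um",
                  "typeI_pct", "status", "config_hash")


@dataclass
class SweepGrid:
    """Completed sweep: long-format table plus the per-cell results."""

    table: pd.DataFrame
    results: dict[tuple[str, float, float, float], SimulationResult] = \
        field(default_factory=dict)

    def save(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def run_sweep(species: str | SpeciesParams | list,
              mb_values=DEFAULT_MB_VALUES_MM,
              fluence_values=DEFAULT_FLUENCE_VALUES,
              o2_values=DEFAULT_O2_VALUES_PCT,
              duration: float | None = None,
              consts: SharedConstants | None = None,
              node_counts: dict[str, int] | None = None,
              keep_results: bool = False,
              **solver_opts) -> SweepGrid:
    """Run the full Cartesian grid for one or more species.

    A failing cell is recorded with ``status='failed'`` and NaN metrics
    instead of aborting the sweep. Cells are keyed and sorted by
    (species, mb, fluence, o2) so results are independent of execution order.
    """
    if not (len(mb_values) and len(fluence_values) and len(o2_values)):
        raise ValueError("sweep value lists must be nonempty")
    consts = consts if consts is not None else load_shared_constants()
    duration = duration if duration is not None else consts.t_default

    species_list = species if isinstance(species, list) else [species]
    params_list = [p if isinstance(p, SpeciesParams) else
                   load_species_params(p) for p in species_list]

    rows = []
    grid = SweepGrid(table=pd.DataFrame())
    for params in params_list:
        mesh = build_mesh(params, node_counts)
        for mb in sorted(mb_values):
            for fl in sorted(fluence_values):
                for o2 in sorted(o2_values):
                    cond = TreatmentConditions(
                        fluence=fl, mb_injected_mm=mb, pct_inspired_o2=o2,
                        duration=duration)
                    row = {"species": params.species_id, "mb_mM": mb,
                           "fluence_mW_cm2": fl, "o2_pct": o2}
                    try:
                        res = simulate(params, cond, mesh=mesh, consts=consts,
                                       **solver_opts)
                    except SolverError as err:
                        row.update(total_crosslinks_mol=float("nan"),
                                   utilization_pct=float("nan"),
                                   peak_um=float("nan"),
                                   typeI_pct=float("nan"),
                                   status=f"failed: {err}", config_hash="")
                        rows.append(row)
                        continue
                    peak = metrics.peak_location(res)
                    t1 = metrics.pathway_split(res)
                    row.update(
                        total_crosslinks_mol=metrics.total_crosslinks(res),
                        utilization_pct=metrics.site_utilization(res),
                        peak_um=float("nan") if peak is None else peak[0],
                        typeI_pct=float("nan") if t1 is None else t1,
                        status="ok", config_hash=res.config_hash)
                    rows.append(row)
                    if keep_results:
                        grid.results[(params.species_id, mb, fl, o2)] = res
    grid.table = pd.DataFrame(rows, columns=list(RESULT_COLUMNS))
    return grid


def find_optimum(sweep: SweepGrid, species: str
                 ) -> tuple[dict[str, float], pd.Series]:
    """Grid cell maximizing total crosslinks for one species.

    Ties (within float equality) break toward lower MB, then lower fluence,
    then lower O₂. Returns (conditions dict, full table row).
    """
    tab = sweep.table
    ok = tab[(tab.species == species) & (tab.status == "ok")]
    if ok.empty:
        raise ValueError(f"no successful sweep cells for {species!r}")
    best = ok.sort_values(
        ["total_crosslinks_mol", "mb_mM", "fluence_mW_cm2", "o2_pct"],
        ascending=[False, True, True, True]).iloc[0]
    cond = {"mb_mM": float(best.mb_mM),
            "fluence_mW_cm2": float(best.fluence_mW_cm2),
            "o2_pct": float(best.o2_pct)}
    return cond, best
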