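"""1D computational grid along the posterior eye wall.

The domain runs anterior → posterior: choroid (x = 0 at the RPE/choroid
interface), sclera, Tenon's capsule, then the retrobulbar MB injection
reservoir. The RPE itself is not meshed — it acts purely as an optical
attenuation slab anterior to the domain. Node centers carry the
"distance from RPE" coordinate used for all spatial reporting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .parameters import ConfigurationError, SpeciesParams

UM_PER_CM = 1.0e4

LAYERS: tuple[str, ...] = ("choroid", "sclera", "tenon", "reservoir")
TISSUE_LAYERS: tuple[str, ...] = ("choroid", "sclera", "tenon")

# Tissue counts follow the published discretization (12 choroid, 28 sclera,
# 7 Tenon). The reservoir count is not published; 48 keeps the early
# injection-interface flux grid-converged (a 3x refinement moves totals by
# <5%, which 12 reservoir nodes does not achieve for the deep rat reservoir).
DEFAULT_NODE_COUNTS: dict[str, int] = {
    "choroid": 12, "sclera": 28, "tenon": 7, "reservoir": 48}


@dataclass(frozen=True)
class Mesh:
    """Ordered 1D node chain with layer labels and geometry.

    Attributes
    ----------
    layer : array of str, per-node layer label.
    thickness_cm : per-node slab thickness (cm); equal within a layer.
    center_um : node-center distance from the RPE (µm), strictly increasing.
    counts : nodes per layer.
    layer_lengths_um : physical length of each layer (µm).
    """

    layer: np.ndarray
    thickness_cm: np.ndarray
    center_um: np.ndarray
    counts: dict[str, int]
    layer_lengths_um: dict[str, float]

    @property
    def n_nodes(self) -> int:
        return self.layer.size

    def mask(self, *layers: str) -> np.ndarray:
        """Boolean node mask for the named layer(s)."""
        return np.isin(self.layer, layers)

    @property
    def tissue_mask(self) -> np.ndarray:
        return self.mask(*TISSUE_LAYERS)

    @property
    def reservoir_mask(self) -> np.ndarray:
        return self.mask("reservoir")

    def layer_slice(self, layer: str) -> slice:
        idx = np.flatnonzero(self.layer == layer)
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "index": np.arange(self.n_nodes),
            "layer": self.layer,
            "thickness_cm": self.thickness_cm,
            "center_um": self.center_um,
        })

    def dump(self, path) -> None:
        """Write the node table as TSV for inspection / fixtures."""
        self.to_dataframe().to_csv(path, sep="\t", index=False)


def build_mesh(params: SpeciesParams,
               node_counts: dict[str, int] | None = None) -> Mesh:
    """Build the anterior→posterior grid for one species.

    ``node_counts`` maps layer name → node count; defaults to
    12 choroid / 28 sclera / 7 Tenon / 12 reservoir. Nodes within a layer
    share a uniform thickness so that they tile the layer exactly.
    """
    counts = dict(DEFAULT_NODE_COUNTS)
    if node_counts:
        unknown = set(node_counts) - set(LAYERS)
        if unknown:
            raise ConfigurationError(f"unknown layers in node_counts: {unknown}")
        counts.update(node_counts)
    if any(int(c) < 1 or int(c) != c for c in counts.values()):
        raise ConfigurationError("node counts must be integers >= 1")
    counts = {k: int(v) for k, v in counts.items()}

    lengths_um = {
        "choroid": params.x_chor, "sclera": params.x_scl,
        "tenon": params.x_ten, "reservoir": params.x_inj}

    layer_arr: list[str] = []
    thick_cm: list[float] = []
    center_um: list[float] = []
    x0 = 0.0
    for lay in LAYERS:
        n = counts[lay]
        dx_um = lengths_um[lay] / n
        for i in range(n):
            layer_arr.append(lay)
            thick_cm.append(dx_um / UM_PER_CM)
            center_um.append(x0 + (i + 0.5) * dx_um)
        x0 += lengths_um[lay]

    return Mesh(layer=np.array(layer_arr),
                thickness_cm=np.array(thick_cm),
                center_um=np.array(center_um),
                counts=counts,
                layer_lengths_um=lengths_um)


def refine(mesh: Mesh, factor: int | dict[str, int]) -> Mesh:
    """Return a mesh with per-layer node counts multiplied by ``factor``.

    ``factor`` may be a single integer applied to every layer or a map
    layer → integer (unlisted layers keep their count). Layer lengths and
    boundaries are preserved exactly.
    """
    if isinstance(factor, dict):
        factors = {lay: int(factor.get(lay, 1)) for lay in LAYERS}
    else:
        factors = {lay: int(factor) for lay in LAYERS}
    if any(f < 1 for f in factors.values()):
        raise ValueError("refinement factor must be >= 1")
    counts = {lay: mesh.counts[lay] * factors[lay] for lay in LAYERS}

    layer_arr: list[str] = []
    thick_cm: list[float] = []
    center_um: list[float] = []
    x0 = 0.0
    for lay in LAYERS:
        n = counts[lay]
        length = mesh.layer_lengths_um[lay]
        dx_um = length / n
        for i in range(n):
            layer_arr.append(lay)
            thick_cm.append(dx_um / UM_PER_CM)
            center_um.append(x0 + (i + 0.5) * dx_um)
        x0 += length
    return Mesh(layer=np.array(layer_arr),
                thickness_cm=np.array(thick_cm),
                center_um=np.array(center_um),
                counts=counts,
                layer_lengths_um=dict(mesh.layer_lengths_um))
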