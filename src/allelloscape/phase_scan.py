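"""Parameter-plane sweeps of the continuous model.

For each cell of a 2-D parameter grid the scan sets the two scanned traits
uniformly across species (an off-diagonal competition value ``nu`` keeps
``nu_ii = 1``; the diffusivity axis ties species and toxin diffusivities,
``D = D_i = d_i``), integrates from the standard patched initial condition,
and classifies the final state as homogeneous or inhomogeneous.  The
qualitative structure is that low diffusivities support coexistence with
self-organized (inhomogeneous) patterns while large diffusivities drive
extinctions and homogeneous final states.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .analysis import PatternReport, classify_pattern
from .networks import InteractionNetwork
from .pde import (
    ContinuousParameters,
    GridSpec,
    NumericalBlowupError,
    init_circular_patches,
    integrate,
)

__all__ = ["ScanSpec", "ScanResult", "scan_plane", "PLANES"]

#: Scannable planes: (x-axis trait, y-axis trait); "D" ties d = D.
PLANES = {
    "mu_vs_D": ("D", "mu"),
    "nu_vs_D": ("D", "nu"),
    "r_vs_D": ("D", "r"),
}

DEFAULT_RANGES = {"D": (0.0, 0.1), "mu": (0.0, 0.2), "nu": (0.0, 1.0), "r": (0.0, 0.6)}


@dataclass(frozen=True)
class ScanSpec:
    """Specification of a parameter-plane scan."""

    plane: str
    base: ContinuousParameters
    grid: GridSpec = field(default_factory=lambda: GridSpec(64, 64, 1.0))
    x_range: tuple[float, float] | None = None
    y_range: tuple[float, float] | None = None
    nx_cells: int = 8
    ny_cells: int = 8
    t_end: float = 600.0
    dt: float = 0.05
    density0: float = 0.25

    def __post_init__(self) -> None:
        if self.plane not in PLANES:
            raise ValueError(f"unknown plane {self.plane!r}; expected {set(PLANES)}")
        if self.nx_cells < 1 or self.ny_cells < 1:
            raise ValueError("cell counts must be >= 1")
        xt, yt = PLANES[self.plane]
        if self.x_range is None:
            object.__setattr__(self, "x_range", DEFAULT_RANGES[xt])
        if self.y_range is None:
            object.__setattr__(self, "y_range", DEFAULT_RANGES[yt])
        for rng, ncells, name in (
            (self.x_range, self.nx_cells, "x_range"),
            (self.y_range, self.ny_cells, "y_range"),
        ):
            if ncells > 1 and rng[0] >= rng[1]:
                raise ValueError(f"{name} must be non-degenerate for >1 cells")
        if self.t_end <= 0:
            raise ValueError("t_end must be positive")

    def axis_values(self) -> tuple[np.ndarray, np.ndarray]:
        def vals(rng, ncells):
            if ncells == 1:
                return np.array([rng[0]])
            return np.linspace(rng[0], rng[1], ncells)

        return vals(self.x_range, self.nx_cells), vals(self.y_range, self.ny_cells)


@dataclass(frozen=True)
class ScanResult:
    """Grid of pattern reports; ``reports[iy][ix]`` is None for failed cells."""

    spec: ScanSpec
    x_values: np.ndarray
    y_values: np.ndarray
    reports: list  # list of rows, each a list of PatternReport | None

    def classification_grid(self) -> np.ndarray:
        """String grid: 'homogeneous' | 'inhomogeneous' | 'failed'."""
        out = np.empty((len(self.y_values), len(self.x_values)), dtype=object)
        for iy, row in enumerate(self.reports):
            for ix, rep in enumerate(row):
                out[iy, ix] = rep.classification if rep is not None else "failed"
        return out

    def inhomogeneous_fraction(self, ix: int) -> float:
        """Fraction of inhomogeneous cells in column ``ix`` (failed excluded)."""
        col = [row[ix] for row in self.reports if row[ix] is not None]
        if not col:
            return float("nan")
        return sum(r.classification == "inhomogeneous" for r in col) / len(col)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for iy, y in enumerate(self.y_values):
            for ix, x in enumerate(self.x_values):
                rep = self.reports[iy][ix]
                rows.append(
                    {
                        "x": x,
                        "y": y,
                        "classification": rep.classification if rep else "failed",
                        "n_survivors": rep.n_survivors if rep else -1,
                    }
                )
        return pd.DataFrame(rows)


def _cell_params(
    base: ContinuousParameters, xt: str, yt: str, x: float, y: float
) -> ContinuousParameters:
    traits = {}
    for trait, val in ((xt, x), (yt, y)):
        if trait == "D":
            traits["d"] = val
            traits["D"] = val
        else:
            traits[trait] = val
    return base.with_traits(**traits)


def scan_cell(
    spec: ScanSpec, net: InteractionNetwork, x: float, y: float
) -> PatternReport | None:
    """Integrate and classify a single parameter-plane cell; ``None`` on
    numerical blow-up."""
    xt, yt = PLANES[spec.plane]
    params = _cell_params(spec.base, xt, yt, x, y)
    state = init_circular_patches(spec.grid, params.n_species, density0=spec.density0)
    try:
        final, _ = integrate(state, params, net, spec.t_end, record_dt=spec.t_end, dt=spec.dt)
    except NumericalBlowupError:
        return None
    return classify_pattern(final)


def scan_plane(spec: ScanSpec, net: InteractionNetwork, progress=None) -> ScanResult:
    """Run the full scan; cells whose integration blows up are flagged failed
    and the scan continues."""
    xs, ys = spec.axis_values()
    reports = []
    for y in ys:
        row = []
        for x in xs:
            row.append(scan_cell(spec, net, x, y))
            if progress is not None:
                progress()
        reports.append(row)
    return ScanResult(spec, xs, ys, reports)
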