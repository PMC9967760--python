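"""Observables and pattern classifiers for both models.

The central diagnostic is the spatial coefficient of variation (CV,
std/mean over grid nodes) of each surviving species: a final state is
*homogeneous* when every survivor's CV falls below a threshold (default
0.05, far above machine-level ripples but far below the CV of visible
stripes or spirals) and *inhomogeneous* otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .ca import Lattice, ToxinFields
from .pde import FieldState

__all__ = [
    "PatternReport",
    "spatial_means",
    "ternary_coordinates",
    "dominant_species_map",
    "count_survivors",
    "classify_pattern",
    "species_toxin_correlation",
    "characteristic_length",
]

EXTINCTION_EPS = 1e-3  # continuous-model extinction threshold on spatial means
CV_THRESHOLD = 0.05  # homogeneous/inhomogeneous cut on survivor CV
DOMINANT_FLOOR = 1e-3  # density below which a node counts as empty


@dataclass(frozen=True)
class PatternReport:
    """Survivor set and homogeneity classification of a final state."""

    survivors: frozenset
    classification: str  # "homogeneous" | "inhomogeneous"
    per_species_cv: dict

    @property
    def n_survivors(self) -> int:
        return len(self.survivors)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["survivors"] = sorted(self.survivors)
        d["per_species_cv"] = {int(k): float(v) for k, v in self.per_species_cv.items()}
        return d


def _species_fields(state) -> np.ndarray:
    """Per-species scalar field: densities (continuous) or occupancy
    indicators (lattice), shape (n, ny, nx)."""
    if isinstance(state, FieldState):
        return state.N
    if isinstance(state, Lattice):
        n = int(state.occ.max()) + 1 if np.any(state.occ >= 0) else 1
        return np.stack([(state.occ == k).astype(float) for k in range(n)])
    raise TypeError(f"expected FieldState or Lattice, got {type(state).__name__}")


def spatial_means(state) -> np.ndarray:
    """Per-species spatial mean density (continuous model) or occupancy
    fraction count / L^2 (lattice model)."""
    return _species_fields(state).mean(axis=(1, 2))


def ternary_coordinates(means) -> np.ndarray:
    """Fractional densities (f1, f2, f3) of a three-species state; sums to 1."""
    m = np.asarray(means, dtype=float)
    if m.shape != (3,):
        raise ValueError("ternary coordinates require exactly 3 species")
    if np.any(m < 0):
        raise ValueError("densities must be nonnegative")
    total = m.sum()
    if total == 0:
        raise ValueError("degenerate state: all three densities are zero")
    return m / total


def dominant_species_map(state: FieldState, floor: float = DOMINANT_FLOOR) -> np.ndarray:
    """Label grid of the locally dominant species (greatest density).

    Nodes where no species reaches ``floor`` are labeled -1 (empty);
    density ties go to the lowest species index.
    """
    N = _species_fields(state)
    labels = N.argmax(axis=0)  # argmax takes the first (lowest) index on ties
    labels[N.max(axis=0) < floor] = -1
    return labels


def count_survivors(state, eps: float = EXTINCTION_EPS) -> tuple[int, set]:
    """Survivor count and set.

    Lattice model: a species survives iff it has at least one individual
    (extinction is unambiguous; ``eps`` is ignored).  Continuous model: a
    species survives iff its spatial mean density is >= ``eps``.
    """
    if isinstance(state, Lattice):
        occupied = state.occ[state.occ >= 0]
        survivors = set(np.unique(occupied).tolist())
        return len(survivors), survivors
    if eps <= 0:
        raise ValueError("extinction threshold eps must be positive")
    means = spatial_means(state)
    survivors = set(np.flatnonzero(means >= eps).tolist())
    return len(survivors), survivors


def classify_pattern(
    state,
    cv_threshold: float = CV_THRESHOLD,
    eps: float = EXTINCTION_EPS,
    margin: int | None = None,
) -> PatternReport:
    """Classify a final state as homogeneous or inhomogeneous.

    Homogeneous iff every surviving species' spatial coefficient of
    variation (std/mean over nodes) is below ``cv_threshold``.

    Under zero-Dirichlet boundaries every field carries a depletion layer
    at the domain edge, so a bulk-uniform state would register a spurious
    CV from the edge alone.  For such states the CV is therefore evaluated
    on the interior, excluding a margin of ``max(2, min(nx, ny) // 16)``
    nodes per side (several boundary-layer widths at the diffusivities of
    interest); pass ``margin`` to override, or 0 to use every node.
    Survivor detection always uses the full domain.
    """
    _, survivors = count_survivors(state, eps)
    fields = _species_fields(state)
    if margin is None:
        if isinstance(state, FieldState) and state.grid.boundary == "dirichlet_zero":
            margin = max(2, min(state.grid.nx, state.grid.ny) // 16)
        else:
            margin = 0
    if margin:
        if 2 * margin >= min(fields.shape[1], fields.shape[2]):
            raise ValueError("margin leaves no interior nodes")
        fields = fields[:, margin:-margin, margin:-margin]
    cvs = {}
    for k in sorted(survivors):
        f = fields[k]
        mean = f.mean()
        cvs[k] = float(f.std() / mean) if mean > 0 else 0.0
    homogeneous = all(cv < cv_threshold for cv in cvs.values())
    return PatternReport(
        survivors=frozenset(survivors),
        classification="homogeneous" if homogeneous else "inhomogeneous",
        per_species_cv=cvs,
    )


def species_toxin_correlation(lat: Lattice, fields: ToxinFields, k: int) -> float:
    """Pearson correlation between the binary occupancy indicator of species
    ``k`` and its own toxin field ``B_k`` over all lattice sites."""
    if not 0 <= k < fields.B.shape[0]:
        raise IndexError(f"species index {k} out of range")
    ind = (lat.occ == k).astype(float).ravel()
    tox = fields.B[k].ravel()
    if ind.std() == 0 or tox.std() == 0:
        raise ValueError(
            "correlation undefined: occupancy or toxin field is constant"
        )
    return float(np.corrcoef(ind, tox)[0, 1])


def characteristic_length(D: float, gamma: float, literal_ratio: bool = False) -> float:
    """Characteristic toxin diffusion length before degradation.

    The dimensionally consistent diffusion-decay balance gives
    ``sqrt(D / gamma)``; ``literal_ratio=True`` returns the plain ratio
    ``D / gamma`` instead.
    """
    if gamma <= 0:
        raise ValueError("degradation rate gamma must be positive")
    if D < 0:
        raise ValueError("diffusivity D must be nonnegative")
    ratio = D / gamma
    return ratio if literal_ratio else float(np.sqrt(ratio))
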