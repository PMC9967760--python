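"""Continuous reaction-diffusion model of allelopathic warfare.

``l`` species with densities ``N_i(x, y, t)`` secrete toxins with
concentrations ``B_i(x, y, t)`` on a two-dimensional landscape.  Species
grow logistically under intra- and interspecific resource competition
(``nu`` matrix), suffer extra mortality from toxins released by the species
that poison them (Holling type-I functional responses), and both species
and toxins spread by normal diffusion:

    dN_i/dt = d_i lap(N_i) + r_i N_i (1 - sum_j nu_ij N_j)
              - sum_{j poisons i} mu Phi_ij(B_j) N_i
    dB_i/dt = D_i lap(B_i) + beta_i N_i - delta_i B_i
              - sum_{j poisons i} gamma N_j B_i

with Phi_ij = B_j (response kind 1, free local toxin) or
Phi_ij = gamma N_i B_j (kind 2, uptaken toxin).  All quantities are
dimensionless.  Integration is explicit forward Euler with a 5-point
Laplacian; the diffusive stability bound dt <= dx^2 / (4 max(d, D)) is
enforced with a configurable safety factor.

The toxin sink term is evaluated, by default, with the published mask
orientation (the sum runs over the poisoners of the focal species).  The
mass-consistent alternative — toxin ``i`` is consumed by the species that
``i`` poisons — is available via ``uptake_mask="transposed"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .networks import InteractionNetwork

__all__ = [
    "GridSpec",
    "ContinuousParameters",
    "FieldState",
    "TrajectoryRecord",
    "GeometryError",
    "NumericalBlowupError",
    "laplacian",
    "holling_response",
    "reaction_terms",
    "init_circular_patches",
    "init_random_patchwork",
    "init_homogeneous",
    "step",
    "integrate",
]

BOUNDARY_KINDS = ("dirichlet_zero", "periodic", "neumann_zero")

#: Safety factor applied to the diffusive stability bound when auto-reducing dt.
STABILITY_SAFETY = 0.9


class GeometryError(ValueError):
    """Initial-condition geometry is infeasible (overlap / outside domain)."""


class NumericalBlowupError(RuntimeError):
    """Non-finite field values encountered during integration."""

    def __init__(self, t: float):
        self.t = t
        super().__init__(f"non-finite field values at t={t:g}")


@dataclass(frozen=True)
class GridSpec:
    """Uniform 2-D grid. ``L = nx * dx`` is the landscape linear size."""

    nx: int = 128
    ny: int = 128
    dx: float = 1.0
    boundary: str = "dirichlet_zero"

    def __post_init__(self) -> None:
        if self.nx < 3 or self.ny < 3:
            raise ValueError("grid must be at least 3x3 nodes")
        if self.dx <= 0:
            raise ValueError("dx must be positive")
        if self.boundary not in BOUNDARY_KINDS:
            raise ValueError(
                f"unknown boundary {self.boundary!r}; expected one of {BOUNDARY_KINDS}"
            )

    @property
    def L(self) -> float:
        return self.nx * self.dx

    @property
    def Ly(self) -> float:
        return self.ny * self.dx


def _per_species(value, n: int, name: str) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if arr.ndim == 0:
        arr = np.full(n, float(arr))
    if arr.shape != (n,):
        raise ValueError(f"{name} must be a scalar or length-{n} vector")
    if np.any(arr < 0):
        raise ValueError(f"{name} must be nonnegative")
    return arr


@dataclass(frozen=True)
class ContinuousParameters:
    """Rates of the coupled species/toxin system.

    ``nu`` is the full competition matrix with unit diagonal; ``mu`` and
    ``gamma`` are the scalar allelopathic mortality and uptake strengths
    multiplied onto the binary interaction mask.
    """

    n_species: int
    r: np.ndarray
    nu: np.ndarray
    mu: float
    gamma: float
    beta: np.ndarray
    delta: np.ndarray
    d: np.ndarray
    D: np.ndarray
    response_kind: int = 2
    uptake_mask: str = "printed"

    def __post_init__(self) -> None:
        n = self.n_species
        object.__setattr__(self, "r", _per_species(self.r, n, "r"))
        object.__setattr__(self, "beta", _per_species(self.beta, n, "beta"))
        object.__setattr__(self, "delta", _per_species(self.delta, n, "delta"))
        object.__setattr__(self, "d", _per_species(self.d, n, "d"))
        object.__setattr__(self, "D", _per_species(self.D, n, "D"))
        nu = np.asarray(self.nu, dtype=float)
        if nu.ndim == 0:
            off = float(nu)
            nu = np.full((n, n), off)
            np.fill_diagonal(nu, 1.0)
        if nu.shape != (n, n):
            raise ValueError(f"nu must be scalar or {n}x{n} matrix")
        if not np.allclose(np.diagonal(nu), 1.0):
            raise ValueError("nu must have unit diagonal (nu_ii = 1)")
        if np.any(nu < 0):
            raise ValueError("nu entries must be nonnegative")
        nu = nu.copy()
        nu.setflags(write=False)
        object.__setattr__(self, "nu", nu)
        if self.mu < 0 or self.gamma < 0:
            raise ValueError("mu and gamma must be nonnegative")
        if self.response_kind not in (1, 2):
            raise ValueError("response_kind must be 1 or 2")
        if self.uptake_mask not in ("printed", "transposed"):
            raise ValueError("uptake_mask must be 'printed' or 'transposed'")

    @classmethod
    def uniform(
        cls,
        n_species: int,
        *,
        r: float = 0.3,
        nu: float = 0.5,
        mu: float = 0.4,
        gamma: float = 0.1,
        beta: float = 0.5,
        delta: float = 0.1,
        d: float = 0.005,
        D: float = 0.005,
        response_kind: int = 2,
        uptake_mask: str = "printed",
    ) -> "ContinuousParameters":
        """All species share the same traits; ``nu`` is the off-diagonal value."""
        return cls(
            n_species=n_species,
            r=r,
            nu=nu,
            mu=mu,
            gamma=gamma,
            beta=beta,
            delta=delta,
            d=d,
            D=D,
            response_kind=response_kind,
            uptake_mask=uptake_mask,
        )

    def with_traits(self, **traits) -> "ContinuousParameters":
        """Copy with uniform traits replaced (``nu`` as off-diagonal scalar)."""
        kwargs = {}
        n = self.n_species
        for key, val in traits.items():
            if key == "nu" and np.ndim(val) == 0:
                nu = np.full((n, n), float(val))
                np.fill_diagonal(nu, 1.0)
                kwargs["nu"] = nu
            else:
                kwargs[key] = val
        return replace(self, **kwargs)


@dataclass
class FieldState:
    """Species density fields ``N`` and toxin fields ``B``, shape (n, ny, nx)."""

    N: np.ndarray
    B: np.ndarray
    t: float = 0.0
    grid: GridSpec = field(default_factory=GridSpec)

    def __post_init__(self) -> None:
        self.N = np.asarray(self.N, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        expected = (self.n_species, self.grid.ny, self.grid.nx)
        if self.N.shape != expected or self.B.shape != expected:
            raise ValueError(
                f"field shapes {self.N.shape}/{self.B.shape} inconsistent with "
                f"grid {expected}"
            )

    @property
    def n_species(self) -> int:
        return self.N.shape[0]

    def copy(self) -> "FieldState":
        return FieldState(self.N.copy(), self.B.copy(), self.t, self.grid)

    def spatial_means(self) -> np.ndarray:
        return self.N.mean(axis=(1, 2))


@dataclass(frozen=True)
class TrajectoryRecord:
    """Sampled per-species spatial-average densities over time.

    ``means[k, i]`` is the spatial mean of species ``i`` at ``times[k]``.
    """

    times: np.ndarray
    means: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        means = np.asarray(self.means, dtype=float)
        if np.any(np.diff(times) <= 0):
            raise ValueError("sample times must be strictly increasing")
        if means.shape[0] != times.shape[0]:
            raise ValueError("means and times length mismatch")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "means", means)

    @property
    def n_species(self) -> int:
        return self.means.shape[1]

    def to_dataframe(self):
        import pandas as pd

        cols = {"t": self.times}
        for i in range(self.n_species):
            cols[f"mean_N{i + 1}"] = self.means[:, i]
        return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# Spatial operators


def laplacian(fieldarr: np.ndarray, dx: float, boundary: str) -> np.ndarray:
    """5-point Laplacian on the trailing two axes.

    ``dirichlet_zero`` treats values outside the domain as zero,
    ``neumann_zero`` mirrors the edge values (zero flux), ``periodic`` wraps.
    """
    f = np.asarray(fieldarr, dtype=float)
    if f.shape[-1] < 3 or f.shape[-2] < 3:
        raise ValueError("field must be at least 3x3")
    if boundary == "periodic":
        out = (
            np.roll(f, 1, axis=-1)
            + np.roll(f, -1, axis=-1)
            + np.roll(f, 1, axis=-2)
            + np.roll(f, -1, axis=-2)
            - 4.0 * f
        )
    elif boundary in ("dirichlet_zero", "neumann_zero"):
        pad = [(0, 0)] * (f.ndim - 2) + [(1, 1), (1, 1)]
        mode = "constant" if boundary == "dirichlet_zero" else "edge"
        p = np.pad(f, pad, mode=mode)
        out = (
            p[..., 1:-1, :-2]
            + p[..., 1:-1, 2:]
            + p[..., :-2, 1:-1]
            + p[..., 2:, 1:-1]
            - 4.0 * f
        )
    else:
        raise ValueError(
            f"unknown boundary {boundary!r}; expected one of {BOUNDARY_KINDS}"
        )
    return out / (dx * dx)


def holling_response(kind: int, B_j, N_i, gamma: float):
    """Type-I functional response of victim ``i`` to toxin ``j``.

    Kind 1 responds to the free local toxin concentration (returns ``B_j``);
    kind 2 to the locally uptaken amount (returns ``gamma * N_i * B_j``).
    """
    if kind == 1:
        return B_j
    if kind == 2:
        return gamma * np.multiply(N_i, B_j)
    raise ValueError(f"response kind must be 1 or 2, got {kind!r}")


def reaction_terms(
    state: FieldState, params: ContinuousParameters, net: InteractionNetwork
):
    """Pointwise non-diffusive rates ``(dN/dt, dB/dt)``.

    Sums over poisoning pairs run only where the interaction mask is 1.
    """
    N, B = state.N, state.B
    n = state.n_species
    if params.n_species != n or net.n_species != n:
        raise ValueError("state, parameters and network species counts differ")

    victim = net.victim_mask.astype(float)  # victim[i, j] = 1 iff j poisons i
    # toxin load from poisoners: S_i = sum_j victim[i,j] B_j
    S = np.tensordot(victim, B, axes=1)
    comp = np.tensordot(params.nu, N, axes=1)
    r = params.r[:, None, None]
    growth = r * N * (1.0 - comp)
    phi = holling_response(params.response_kind, S, N, params.gamma)
    dN = growth - params.mu * phi * N

    sink_mask = victim if params.uptake_mask == "printed" else net.poison.astype(float)
    Nsum = np.tensordot(sink_mask, N, axes=1)
    beta = params.beta[:, None, None]
    delta = params.delta[:, None, None]
    dB = beta * N - delta * B - params.gamma * Nsum * B
    return dN, dB


# ---------------------------------------------------------------------------
# Initial conditions


def init_circular_patches(
    grid: GridSpec,
    n: int,
    radius: float | None = None,
    density0: float = 0.25,
    ring_radius: float | None = None,
) -> FieldState:
    """Each species starts on its own circular patch, density ``density0``
    inside and zero elsewhere; toxins start at zero.

    Patch centers are placed evenly on a ring of radius ``ring_radius``
    (default ``L/4``) about the domain center; default patch radius is
    ``L/10``.  Patches must be pairwise disjoint and clear of the boundary.
    """
    L = min(grid.L, grid.Ly)
    if radius is None:
        radius = L / 10.0
    if ring_radius is None:
        ring_radius = L / 4.0 if n > 1 else 0.0
    if radius <= 0:
        raise ValueError("patch radius must be positive")

    cx = (grid.nx - 1) / 2.0 * grid.dx
    cy = (grid.ny - 1) / 2.0 * grid.dx
    angles = 2.0 * np.pi * np.arange(n) / max(n, 1)
    centers = np.stack(
        [cx + ring_radius * np.cos(angles), cy + ring_radius * np.sin(angles)], axis=1
    )

    if n > 1:
        # adjacent centers are closest on the ring
        min_sep = 2.0 * ring_radius * np.sin(np.pi / n)
        if min_sep <= 2.0 * radius:
            raise GeometryError(
                f"{n} patches of radius {radius:g} overlap on a ring of radius "
                f"{ring_radius:g} (center separation {min_sep:g})"
            )
    for px, py in centers:
        if (
            px - radius <= 0
            or py - radius <= 0
            or px + radius >= grid.L - grid.dx
            or py + radius >= grid.Ly - grid.dx
        ):
            raise GeometryError(
                f"patch at ({px:g},{py:g}) radius {radius:g} touches the boundary"
            )

    x = np.arange(grid.nx) * grid.dx
    y = np.arange(grid.ny) * grid.dx
    X, Y = np.meshgrid(x, y)  # shape (ny, nx)
    N = np.zeros((n, grid.ny, grid.nx))
    for i, (px, py) in enumerate(centers):
        mask = (X - px) ** 2 + (Y - py) ** 2 <= radius**2
        N[i][mask] = density0
    B = np.zeros_like(N)
    return FieldState(N, B, 0.0, grid)


def init_random_patchwork(
    grid: GridSpec, n: int, a: float | None = None, seed=None
) -> FieldState:
    """Random patchwork start: the landscape is tiled by small square patches
    of linear size ``a`` (default ``L/20``); each patch holds exactly one
    uniformly chosen species at a density drawn uniformly from [0.01, 1].

    Trailing partial patches at the far edges are filled by the same rule.
    """
    L = min(grid.L, grid.Ly)
    if a is None:
        a = L / 20.0
    if a <= 0 or a >= L:
        raise ValueError(f"patch size a={a:g} must satisfy 0 < a < L={L:g}")
    rng = np.random.default_rng(seed)
    side = max(1, int(round(a / grid.dx)))
    N = np.zeros((n, grid.ny, grid.nx))
    for y0 in range(0, grid.ny, side):
        for x0 in range(0, grid.nx, side):
            sp = int(rng.integers(n))
            dens = rng.uniform(0.01, 1.0)
            N[sp, y0 : y0 + side, x0 : x0 + side] = dens
    B = np.zeros_like(N)
    return FieldState(N, B, 0.0, grid)


def init_homogeneous(grid: GridSpec, densities) -> FieldState:
    """Spatially uniform start at the given per-species densities, no toxins."""
    dens = np.asarray(densities, dtype=float)
    N = np.broadcast_to(dens[:, None, None], (dens.size, grid.ny, grid.nx)).copy()
    return FieldState(N, np.zeros_like(N), 0.0, grid)


# ---------------------------------------------------------------------------
# Time stepping


def stable_dt(grid: GridSpec, params: ContinuousParameters) -> float:
    """Diffusive stability bound with safety factor; inf when no diffusion."""
    dmax = max(params.d.max(), params.D.max())
    if dmax == 0:
        return np.inf
    return STABILITY_SAFETY * grid.dx**2 / (4.0 * dmax)


def _reaction_rate_scale(
    state: FieldState, params: ContinuousParameters, net: InteractionNetwork
) -> float:
    # crude per-capita rate bound at the current field amplitudes
    nmax = float(state.N.max(initial=0.0))
    bmax = float(state.B.max(initial=0.0))
    in_deg = float(net.poison.sum(axis=0).max())
    growth = float(np.max(params.r)) * (
        1.0 + float(np.abs(params.nu).sum(axis=1).max()) * nmax
    )
    supp = params.mu * in_deg * bmax
    if params.response_kind == 2:
        supp *= params.gamma * nmax
    decay = float(np.max(params.delta)) + params.gamma * in_deg * nmax
    return max(growth + supp, decay)


def step(
    state: FieldState,
    params: ContinuousParameters,
    net: InteractionNetwork,
    dt: float,
) -> FieldState:
    """One explicit forward-Euler step; returns a new state at ``t + dt``."""
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    bound = stable_dt(state.grid, params)
    if dt > bound / STABILITY_SAFETY * (1 + 1e-12):
        warnings.warn(
            f"dt={dt:g} exceeds the diffusive stability bound "
            f"{bound / STABILITY_SAFETY:g}",
            RuntimeWarning,
            stacklevel=2,
        )
    if dt * _reaction_rate_scale(state, params, net) > 1.0:
        warnings.warn(
            f"dt={dt:g} is large relative to the reaction rates", RuntimeWarning,
            stacklevel=2,
        )
    new = state.copy()
    _advance(new, params, net, dt)
    return new


def _advance(
    state: FieldState, params: ContinuousParameters, net: InteractionNetwork, dt: float
) -> None:
    """In-place Euler update (no stability checks; used by the main loop)."""
    dN, dB = reaction_terms(state, params, net)
    if params.d.max() > 0:
        dN += params.d[:, None, None] * laplacian(
            state.N, state.grid.dx, state.grid.boundary
        )
    if params.D.max() > 0:
        dB += params.D[:, None, None] * laplacian(
            state.B, state.grid.dx, state.grid.boundary
        )
    state.N += dt * dN
    state.B += dt * dB
    state.t += dt


def integrate(
    state: FieldState,
    params: ContinuousParameters,
    net: InteractionNetwork,
    t_end: float,
    record_dt: float = 1.0,
    dt: float = 0.05,
) -> tuple[FieldState, TrajectoryRecord]:
    """Integrate to ``t_end``, sampling spatial means every ``record_dt``.

    ``dt`` is auto-reduced to satisfy the diffusive stability bound.  Raises
    :class:`NumericalBlowupError` if non-finite values appear.
    """
    if t_end <= state.t:
        raise ValueError(f"t_end={t_end:g} must exceed current time {state.t:g}")
    dt_eff = min(dt, stable_dt(state.grid, params))
    n_steps = int(np.ceil((t_end - state.t) / dt_eff))
    dt_eff = (t_end - state.t) / n_steps
    every = max(1, int(round(record_dt / dt_eff)))

    cur = state.copy()
    times = [cur.t]
    means = [cur.spatial_means()]
    for k in range(1, n_steps + 1):
        _advance(cur, params, net, dt_eff)
        if k % every == 0 or k == n_steps:
            m = cur.spatial_means()
            if not np.all(np.isfinite(m)):
                raise NumericalBlowupError(cur.t)
            if cur.t > times[-1]:
                times.append(cur.t)
                means.append(m)
    if not (np.all(np.isfinite(cur.N)) and np.all(np.isfinite(cur.B))):
        raise NumericalBlowupError(cur.t)
    return cur, TrajectoryRecord(np.array(times), np.array(means))
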