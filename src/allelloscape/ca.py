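"""Hybrid stochastic lattice model of allelopathic warfare.

Individuals live on a periodic L x L square lattice under a spatial
exclusion rule (at most one individual per site).  Agents never move; only
their toxins do.  Each Monte Carlo step (MCS) every individual is selected
and draws one action — a replication attempt or a death attempt with equal
probability.  Success probabilities depend on the squared local
concentrations of the toxins secreted by the focal species' poisoners,

    prep_k = p0_k * C_k / (C_k + S),   pdel_k = q0_k * S / (A_k + S),
    S = sum_{l poisons k} B_l^2,

so an agent with no toxin exposure replicates at its natural rate and never
dies.  A successful replication places the offspring on a uniformly random
empty von Neumann neighbor; when several species propose the same empty
site, the proposer with the largest local replication probability wins
(ties broken uniformly at random).  After each sweep the per-species toxin
fields are relaxed by a fixed number of explicit-Euler iterations of a
diffusion-decay equation with point sources at the occupied sites,
continuing from the previous profile (quasi-stationary solution).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .networks import InteractionNetwork

__all__ = [
    "CAParameters",
    "Lattice",
    "ToxinFields",
    "SweepStats",
    "CountsRecord",
    "EMPTY",
    "replication_prob",
    "death_prob",
    "relax_toxins",
    "mcs_step",
    "init_lattice",
    "run_ca",
]

EMPTY = -1

ACTION_SEMANTICS = ("choose", "independent")


def _per_species(value, n: int, name: str, lo=0.0, hi=None, strict_lo=False):
    arr = np.asarray(value, dtype=float)
    if arr.ndim == 0:
        arr = np.full(n, float(arr))
    if arr.shape != (n,):
        raise ValueError(f"{name} must be a scalar or length-{n} vector")
    if strict_lo:
        if np.any(arr <= lo):
            raise ValueError(f"{name} must be > {lo}")
    elif np.any(arr < lo):
        raise ValueError(f"{name} must be >= {lo}")
    if hi is not None and np.any(arr > hi):
        raise ValueError(f"{name} must be <= {hi}")
    return arr


@dataclass(frozen=True)
class CAParameters:
    """Lattice-model parameters.

    ``gamma_deg`` is the toxin degradation rate (the continuous model calls
    this role delta); ``relax_iters`` explicit-Euler iterations with step
    ``relax_dt`` relax the toxin fields once per MCS.  ``baseline_death``
    adds an optional toxin-independent death probability floor (0 by
    default: isolated agents never die).
    """

    n_species: int
    L: int = 100
    p0: np.ndarray = 0.5
    q0: np.ndarray = 0.5
    A: np.ndarray = 0.5
    C: np.ndarray = 0.5
    beta: np.ndarray = 0.7
    gamma_deg: np.ndarray = 0.2
    D: np.ndarray = 0.001
    relax_iters: int = 400
    relax_dt: float | None = None
    action_semantics: str = "choose"
    baseline_death: float = 0.0

    def __post_init__(self) -> None:
        n = self.n_species
        if self.L < 3:
            raise ValueError("lattice size L must be >= 3")
        object.__setattr__(self, "p0", _per_species(self.p0, n, "p0", 0.0, 1.0))
        object.__setattr__(self, "q0", _per_species(self.q0, n, "q0", 0.0, 1.0))
        object.__setattr__(self, "A", _per_species(self.A, n, "A", 0.0, strict_lo=True))
        object.__setattr__(self, "C", _per_species(self.C, n, "C", 0.0, strict_lo=True))
        object.__setattr__(self, "beta", _per_species(self.beta, n, "beta"))
        object.__setattr__(
            self, "gamma_deg", _per_species(self.gamma_deg, n, "gamma_deg")
        )
        object.__setattr__(self, "D", _per_species(self.D, n, "D"))
        if self.relax_iters < 1:
            raise ValueError("relax_iters must be >= 1")
        if self.relax_dt is None:
            denom = 4.0 * float(self.D.max()) + float(self.gamma_deg.max())
            object.__setattr__(self, "relax_dt", 0.2 / denom if denom > 0 else 0.2)
        elif self.relax_dt <= 0:
            raise ValueError("relax_dt must be positive")
        if self.action_semantics not in ACTION_SEMANTICS:
            raise ValueError(
                f"action_semantics must be one of {ACTION_SEMANTICS}"
            )
        if not 0.0 <= self.baseline_death <= 1.0:
            raise ValueError("baseline_death must be in [0, 1]")


@dataclass
class Lattice:
    """Occupancy grid: ``occ[y, x]`` is a species id or ``EMPTY`` (-1)."""

    occ: np.ndarray
    mcs: int = 0

    def __post_init__(self) -> None:
        self.occ = np.asarray(self.occ, dtype=np.int64)
        if self.occ.ndim != 2 or self.occ.shape[0] != self.occ.shape[1]:
            raise ValueError("occupancy grid must be square")

    @property
    def L(self) -> int:
        return self.occ.shape[0]

    def counts(self, n_species: int) -> np.ndarray:
        filled = self.occ[self.occ >= 0]
        return np.bincount(filled, minlength=n_species)

    def copy(self) -> "Lattice":
        return Lattice(self.occ.copy(), self.mcs)


@dataclass
class ToxinFields:
    """Per-species toxin concentration fields, shape ``(n_species, L, L)``."""

    B: np.ndarray

    def __post_init__(self) -> None:
        self.B = np.asarray(self.B, dtype=float)
        if self.B.ndim != 3 or self.B.shape[1] != self.B.shape[2]:
            raise ValueError("toxin fields must have shape (n_species, L, L)")

    @classmethod
    def zeros(cls, n_species: int, L: int) -> "ToxinFields":
        return cls(np.zeros((n_species, L, L)))

    def copy(self) -> "ToxinFields":
        return ToxinFields(self.B.copy())


@dataclass(frozen=True)
class SweepStats:
    """Births and deaths logged during one MCS, per species."""

    births: np.ndarray
    deaths: np.ndarray


@dataclass(frozen=True)
class CountsRecord:
    """Per-species individual counts sampled over Monte Carlo time."""

    mcs: np.ndarray
    counts: np.ndarray

    def to_dataframe(self):
        import pandas as pd

        cols = {"mcs": self.mcs}
        for i in range(self.counts.shape[1]):
            cols[f"count_{i + 1}"] = self.counts[:, i]
        return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# Probabilities (Holling-type saturating responses in squared toxin load)


def _toxin_load(k: int, local_toxins, net: InteractionNetwork):
    tox = np.asarray(local_toxins, dtype=float)
    mask = net.victim_mask[k].astype(float)  # 1 for species that poison k
    return np.tensordot(mask, tox * tox, axes=1)


def replication_prob(
    k: int, local_toxins, params: CAParameters, net: InteractionNetwork
):
    """Probability that a species-``k`` replication attempt succeeds,
    given the local per-species toxin concentrations; in ``[0, p0_k]``."""
    S = _toxin_load(k, local_toxins, net)
    return params.p0[k] * params.C[k] / (params.C[k] + S)


def death_prob(k: int, local_toxins, params: CAParameters, net: InteractionNetwork):
    """Probability that a species-``k`` death attempt succeeds; in
    ``[baseline_death, q0_k)`` and zero without poisoner toxins (at the
    default zero baseline)."""
    S = _toxin_load(k, local_toxins, net)
    p = params.q0[k] * S / (params.A[k] + S)
    if params.baseline_death:
        p = np.minimum(1.0, params.baseline_death + p)
    return p


def _prob_fields(fields: ToxinFields, params: CAParameters, net: InteractionNetwork):
    """Vectorized prep/pdel over the whole lattice -> (n, L, L) each."""
    victim = net.victim_mask.astype(float)
    S = np.tensordot(victim, fields.B * fields.B, axes=1)
    C = params.C[:, None, None]
    A = params.A[:, None, None]
    prep = params.p0[:, None, None] * C / (C + S)
    pdel = params.q0[:, None, None] * S / (A + S)
    if params.baseline_death:
        pdel = np.minimum(1.0, params.baseline_death + pdel)
    return prep, pdel


# ---------------------------------------------------------------------------
# Toxin sub-solver


def _periodic_lap(B: np.ndarray) -> np.ndarray:
    return (
        np.roll(B, 1, axis=-1)
        + np.roll(B, -1, axis=-1)
        + np.roll(B, 1, axis=-2)
        + np.roll(B, -1, axis=-2)
        - 4.0 * B
    )


def relax_toxins(
    lat: Lattice,
    fields: ToxinFields,
    params: CAParameters,
    iters: int | None = None,
) -> ToxinFields:
    """Advance every toxin field ``relax_iters`` explicit-Euler steps of
    ``dB/dt = D lap(B) + beta * occupancy - gamma_deg * B`` (periodic,
    dx = 1), continuing from the current profile.  Returns new fields.
    """
    if iters is None:
        iters = params.relax_iters
    dt = params.relax_dt
    bound = 1.0 / (4.0 * params.D + params.gamma_deg + 1e-300)
    if np.any(dt > bound):
        warnings.warn(
            f"relax_dt={dt:g} exceeds the stability bound {bound.min():g}",
            RuntimeWarning,
            stacklevel=2,
        )
    n = params.n_species
    src = np.zeros((n, lat.L, lat.L))
    occ = lat.occ
    for k in range(n):
        src[k][occ == k] = params.beta[k]
    B = fields.B.copy()
    D = params.D[:, None, None]
    g = params.gamma_deg[:, None, None]
    for _ in range(iters):
        B += dt * (D * _periodic_lap(B) + src - g * B)
    if not np.all(np.isfinite(B)):
        raise RuntimeError("toxin relaxation diverged (non-finite values)")
    return ToxinFields(B)


# ---------------------------------------------------------------------------
# Monte Carlo sweep


def mcs_step(
    lat: Lattice,
    fields: ToxinFields,
    params: CAParameters,
    net: InteractionNetwork,
    rng: np.random.Generator,
    return_stats: bool = False,
):
    """One Monte Carlo step; returns new ``(Lattice, ToxinFields)``.

    All individuals act on the same pre-sweep occupancy: each draws a
    replication attempt or a death attempt (probability 1/2 each under the
    default ``choose`` semantics), deaths are applied first, colonization
    conflicts are resolved by the largest proposer replication probability,
    then the toxin fields are relaxed once.  With
    ``action_semantics="independent"`` every agent instead makes both an
    independent death trial and, if it survives it, a replication trial.
    """
    occ = lat.occ
    L = lat.L
    n = params.n_species
    prep_f, pdel_f = _prob_fields(fields, params, net)

    ys, xs = np.nonzero(occ >= 0)
    m = ys.size
    new_occ = occ.copy()
    births = np.zeros(n, dtype=np.int64)
    deaths = np.zeros(n, dtype=np.int64)

    if m > 0:
        sp = occ[ys, xs]
        prep = prep_f[sp, ys, xs]
        pdel = pdel_f[sp, ys, xs]

        if params.action_semantics == "choose":
            replicate_attempt = rng.random(m) < 0.5
            u = rng.random(m)
            dies = (~replicate_attempt) & (u < pdel)
            tries_birth = replicate_attempt & (u < prep)
        else:  # independent death-then-birth trials
            dies = rng.random(m) < pdel
            tries_birth = (~dies) & (rng.random(m) < prep)

        # offspring placement: uniformly random empty von Neumann neighbor,
        # emptiness judged on the pre-sweep occupancy
        idx = np.nonzero(tries_birth)[0]
        if idx.size:
            py, px = ys[idx], xs[idx]
            ny = np.stack([py, py, (py - 1) % L, (py + 1) % L])  # (4, b)
            nx = np.stack([(px - 1) % L, (px + 1) % L, px, px])
            empty = occ[ny, nx] == EMPTY  # (4, b)
            cnt = empty.sum(axis=0)
            has_room = cnt > 0
            idx = idx[has_room]
            if idx.size:
                ny, nx, empty, cnt = (
                    ny[:, has_room],
                    nx[:, has_room],
                    empty[:, has_room],
                    cnt[has_room],
                )
                pick = (rng.random(idx.size) * cnt).astype(np.int64)  # k-th empty
                rank = np.cumsum(empty, axis=0) - 1
                sel = empty & (rank == pick[None, :])
                slot = sel.argmax(axis=0)
                b = np.arange(idx.size)
                ty, tx = ny[slot, b], nx[slot, b]
                tgt = ty * L + tx
                prop_sp = sp[idx]
                prop_prep = prep[idx]
                # conflict resolution: highest proposer prep wins, ties random
                order = np.lexsort((rng.random(idx.size), -prop_prep, tgt))
                tgt_o = tgt[order]
                first = np.ones(tgt_o.size, dtype=bool)
                first[1:] = tgt_o[1:] != tgt_o[:-1]
                win = order[first]
            else:
                win = np.array([], dtype=np.int64)
        else:
            win = np.array([], dtype=np.int64)

        # deaths first, then colonization
        dy, dx_ = ys[dies], xs[dies]
        new_occ[dy, dx_] = EMPTY
        np.add.at(deaths, sp[dies], 1)
        if idx.size and win.size:
            wy, wx = ty[win], tx[win]
            wsp = prop_sp[win]
            new_occ[wy, wx] = wsp
            np.add.at(births, wsp, 1)

    new_lat = Lattice(new_occ, lat.mcs + 1)
    new_fields = relax_toxins(new_lat, fields, params)
    if return_stats:
        return new_lat, new_fields, SweepStats(births, deaths)
    return new_lat, new_fields


# ---------------------------------------------------------------------------
# Initial conditions and driver


def init_lattice(
    mode: str,
    L: int,
    n_species: int,
    fill_fraction: float = 0.5,
    patch_side: int | None = None,
    seed=None,
) -> Lattice:
    """Initial occupancy: ``patched`` places ``n_species`` disjoint
    monospecific square blocks (side ``patch_side``, default ``L // 10``)
    with centers evenly spaced on a ring of radius ``L / 4``; ``random``
    occupies each site independently with probability ``fill_fraction`` by
    a uniformly random species.
    """
    rng = np.random.default_rng(seed)
    occ = np.full((L, L), EMPTY, dtype=np.int64)
    if mode == "random":
        if not 0.0 <= fill_fraction <= 1.0:
            raise ValueError("fill_fraction must be in [0, 1]")
        filled = rng.random((L, L)) < fill_fraction
        species = rng.integers(0, n_species, size=(L, L))
        occ[filled] = species[filled]
    elif mode == "patched":
        side = patch_side if patch_side is not None else max(1, L // 10)
        if side < 1 or side > L:
            raise ValueError("patch_side out of range")
        c = (L - 1) / 2.0
        ring = L / 4.0
        half = side / 2.0
        blocks = []
        for i in range(n_species):
            ang = 2.0 * np.pi * i / n_species
            py = int(round(c + ring * np.sin(ang) - half))
            px = int(round(c + ring * np.cos(ang) - half))
            if py < 0 or px < 0 or py + side > L or px + side > L:
                raise ValueError(
                    f"patch {i} (side {side}) does not fit on an L={L} lattice"
                )
            blocks.append((py, px))
        for i, (py, px) in enumerate(blocks):
            if np.any(occ[py : py + side, px : px + side] != EMPTY):
                raise ValueError(f"patch {i} overlaps another patch")
            occ[py : py + side, px : px + side] = i
    else:
        raise ValueError(f"unknown init mode {mode!r}; expected 'patched' or 'random'")
    return Lattice(occ, 0)


def run_ca(
    lat: Lattice,
    fields: ToxinFields,
    params: CAParameters,
    net: InteractionNetwork,
    n_mcs: int,
    record_every: int = 1,
    rng: np.random.Generator | None = None,
) -> tuple[Lattice, ToxinFields, CountsRecord]:
    """Iterate ``mcs_step`` for ``n_mcs`` sweeps, recording per-species
    individual counts every ``record_every`` MCS (plus the initial state)."""
    if n_mcs < 1:
        raise ValueError("n_mcs must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    n = params.n_species
    times = [lat.mcs]
    counts = [lat.counts(n)]
    for k in range(1, n_mcs + 1):
        lat, fields = mcs_step(lat, fields, params, net, rng)
        if k % record_every == 0 or k == n_mcs:
            if lat.mcs > times[-1]:
                times.append(lat.mcs)
                counts.append(lat.counts(n))
    return lat, fields, CountsRecord(np.array(times), np.array(counts))
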