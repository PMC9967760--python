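"""Allelopathic interaction networks.

A community of ``n`` species is wired together by a binary *poison*
relation: ``poison[a, t] == 1`` means species ``a`` secretes a toxin that
suppresses species ``t``.  Both the continuous reaction-diffusion model and
the lattice cellular automaton consume the same network object; the scalar
interaction strengths (mortality ``mu``, uptake ``gamma``) live in the model
parameter objects and are multiplied onto this mask when the dynamical
equations are evaluated.

The matrix is stored attacker-to-target.  The classical notation for these
games writes the mask the other way around ("xi_ij = 1 if j poisons i"),
i.e. as the transpose; one orientation is used everywhere internally and
the transpose is taken only inside the dynamical right-hand sides.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "InteractionNetwork",
    "build_cycle",
    "build_from_matrix",
    "poisoners_of",
    "read_matrix_file",
    "write_matrix_file",
]


@dataclass(frozen=True)
class InteractionNetwork:
    """Binary who-poisons-whom structure.

    Attributes
    ----------
    n_species
        Number of interacting species.
    poison
        ``(n_species, n_species)`` array of {0, 1}; ``poison[a, t] = 1``
        means species ``a`` poisons species ``t``.  Zero diagonal (no
        self-poisoning).
    """

    n_species: int
    poison: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        mat = np.asarray(self.poison, dtype=np.int64)
        if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
            raise ValueError(f"poison matrix must be square, got shape {mat.shape}")
        if mat.shape[0] != self.n_species:
            raise ValueError(
                f"poison matrix is {mat.shape[0]}x{mat.shape[0]} "
                f"but n_species={self.n_species}"
            )
        bad = np.argwhere((mat != 0) & (mat != 1))
        if bad.size:
            a, t = bad[0]
            raise ValueError(
                f"poison matrix must be binary; entry [{a},{t}]={mat[a, t]}"
            )
        diag = np.flatnonzero(np.diagonal(mat))
        if diag.size:
            k = diag[0]
            raise ValueError(f"self-poisoning not allowed; entry [{k},{k}]=1")
        mat.setflags(write=False)
        object.__setattr__(self, "poison", mat)

    @property
    def victim_mask(self) -> np.ndarray:
        """Transposed mask: ``victim_mask[i, j] = 1`` iff ``j`` poisons ``i``.

        This is the orientation in which the dynamical equations sum over
        poisoners of a focal species.
        """
        return self.poison.T


def build_cycle(n: int, out_degree: int = 1) -> InteractionNetwork:
    """Cyclic (rock-paper-scissors-like) network: ``i`` poisons the next
    ``out_degree`` species modulo ``n``.

    ``build_cycle(3, 1)`` is the classic RPS game; ``build_cycle(5, 2)``
    the rock-paper-scissors-lizard-Spock structure in which every species
    beats two others.

    Raises
    ------
    ValueError
        If ``n < 3`` or ``out_degree`` is not in ``[1, n - 2]``.
    """
    if n < 3:
        raise ValueError(f"a cyclic game needs n >= 3 species, got n={n}")
    if not 1 <= out_degree <= n - 2:
        raise ValueError(
            f"out_degree must be in [1, {n - 2}] for n={n}, got {out_degree}"
        )
    mat = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        for off in range(1, out_degree + 1):
            mat[i, (i + off) % n] = 1
    return InteractionNetwork(n, mat)


def build_from_matrix(mask) -> InteractionNetwork:
    """Validate a user-supplied square binary matrix and wrap it.

    The entry convention is attacker-to-target: ``mask[a][t] = 1`` means
    species ``a`` poisons species ``t``.
    """
    mat = np.asarray(mask)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError(f"adjacency mask must be square, got shape {mat.shape}")
    return InteractionNetwork(mat.shape[0], mat)


def poisoners_of(net: InteractionNetwork, k: int) -> set[int]:
    """Indices of the species that poison species ``k``."""
    if not 0 <= k < net.n_species:
        raise IndexError(f"species index {k} out of range [0, {net.n_species})")
    return set(np.flatnonzero(net.poison[:, k]).tolist())


def read_matrix_file(path) -> InteractionNetwork:
    """Read a whitespace-delimited integer matrix file as a network."""
    mat = np.loadtxt(path, dtype=np.int64, ndmin=2)
    return build_from_matrix(mat)


def write_matrix_file(path, net: InteractionNetwork) -> None:
    """Write the poison matrix as plain-text integers (round-trips exactly)."""
    np.savetxt(path, net.poison, fmt="%d")
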