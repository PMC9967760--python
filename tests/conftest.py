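import numpy as np
import pytest

from allelloscape import CAParameters, ContinuousParameters, build_cycle


@pytest.fixture
def rps_net():
    """Three-species rock-paper-scissors cycle: 0->1->2->0."""
    return build_cycle(3, 1)


@pytest.fixture
def rpsls_net():
    """Five-species cycle with out-degree 2 (each species beats two)."""
    return build_cycle(5, 2)


@pytest.fixture
def fig_params():
    """Reference continuous parameter set used throughout: r=0.3, nu=0.5,
    mu=0.4, beta=0.5, delta=0.1, gamma=0.1, d=D=0.005, uptake response."""
    return ContinuousParameters.uniform(3)


@pytest.fixture
def ca_params():
    """Reference lattice parameter set: p0=q0=0.5, A=C=0.5, beta=0.7,
    gamma_deg=0.2, D=0.001."""
    return CAParameters(n_species=5, L=60)


def euler_ode_oracle(N0, B0, params, net, dt, n_steps):
    """Independent 0-D forward-Euler integration of the well-mixed limit.

    Plain Python loops over species; used as the oracle for the
    zero-diffusivity grid dynamics.
    """
    n = len(N0)
    N = [float(v) for v in N0]
    B = [float(v) for v in B0]
    victim = net.victim_mask
    traj = [list(N)]
    for _ in range(n_steps):
        dN, dB = [], []
        for i in range(n):
            comp = 0.0
            for j in range(n):
                comp += params.nu[i, j] * N[j]
            S = 0.0
            nsum = 0.0
            for j in range(n):
                if victim[i, j]:
                    S += B[j]
                    nsum += N[j]
            phi = S if params.response_kind == 1 else params.gamma * N[i] * S
            dN.append(params.r[i] * N[i] * (1.0 - comp) - params.mu * phi * N[i])
            dB.append(
                params.beta[i] * N[i]
                - params.delta[i] * B[i]
                - params.gamma * nsum * B[i]
            )
        for i in range(n):
            N[i] += dt * dN[i]
            B[i] += dt * dB[i]
        traj.append(list(N))
    return np.array(N), np.array(B), np.array(traj)


def periodic_laplacian_matrix(L):
    """Dense matrix of the 5-point Laplacian on an L x L periodic lattice."""
    M = np.zeros((L * L, L * L))
    for y in range(L):
        for x in range(L):
            i = y * L + x
            M[i, i] = -4.0
            for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                j = ((y + dy) % L) * L + (x + dx) % L
                M[i, j] += 1.0
    return M
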