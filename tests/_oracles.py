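"""Independent numerical oracles used by the tests.

The gradient-descent relaxer below is deliberately primitive (fixed
small step, no momentum, no line search) so that it shares nothing
with the package's minimizers beyond the energy kernel it consumes.
"""

import numba
import numpy as np

from fibernet._kernels import energy_gradient
from fibernet.network import FREE, NetworkState


@numba.njit(fastmath=True)
def _gd_loop(pos, free, edges, k, rest, grad, eta, threshold, max_iters):
    energy = 0.0
    for it in range(max_iters):
        energy, _deg = energy_gradient(pos, edges, k, rest, grad)
        worst = 0.0
        for m in range(free.shape[0]):
            b = free[m]
            f = (
                grad[b, 0] * grad[b, 0]
                + grad[b, 1] * grad[b, 1]
                + grad[b, 2] * grad[b, 2]
            )
            if f > worst:
                worst = f
        if np.sqrt(worst) <= threshold:
            return it, energy
        for m in range(free.shape[0]):
            b = free[m]
            pos[b, 0] -= eta * grad[b, 0]
            pos[b, 1] -= eta * grad[b, 1]
            pos[b, 2] -= eta * grad[b, 2]
    return -1, energy


def gradient_descent_relax(
    state: NetworkState,
    threshold: float,
    eta_factor: float = 0.5,
    max_iters: int = 25_000_000,
):
    """Fine-step steepest descent to a max-free-bead-force threshold.

    Returns (relaxed_state, iterations, final_energy); iterations is -1
    if the cap was reached first.
    """
    out = state.copy()
    free = np.flatnonzero(out.anchor_label == FREE).astype(np.int64)
    edges, k, rest = out.all_edges()
    grad = np.empty_like(out.positions)
    eta = eta_factor / k.max()
    iters, energy = _gd_loop(
        out.positions, free, edges, k, rest, grad, eta, threshold, max_iters
    )
    return out, iters, energy
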