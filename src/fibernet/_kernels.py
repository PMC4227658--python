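"""Numba-compiled inner loops for energy/gradient evaluation.

Kept separate from :mod:`fibernet.mechanics` so the compiled functions
stay free of Python object mode.  The gradient kernel returns the
index of the first degenerate (zero-length) spring it encounters, or
-1; the caller turns that into an exception.
"""

import numpy as np
from numba import njit

_TINY = 1e-12


@njit(cache=True, fastmath=True)
def energy_gradient(pos, edges, k, rest, grad):
    """Total spring energy and its gradient w.r.t. bead positions.

    Energy is sum over springs of 1/2 k (|r_j - r_i| - L0)^2.
    ``grad`` is overwritten in place.  Returns (energy, degenerate_index).
    """
    n = pos.shape[0]
    for b in range(n):
        grad[b, 0] = 0.0
        grad[b, 1] = 0.0
        grad[b, 2] = 0.0
    energy = 0.0
    degenerate = -1
    for e in range(edges.shape[0]):
        i = edges[e, 0]
        j = edges[e, 1]
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r < _TINY:
            if degenerate < 0:
                degenerate = e
            continue
        dl = r - rest[e]
        ke = k[e]
        energy += 0.5 * ke * dl * dl
        c = ke * dl / r
        gx = c * dx
        gy = c * dy
        gz = c * dz
        grad[i, 0] -= gx
        grad[i, 1] -= gy
        grad[i, 2] -= gz
        grad[j, 0] += gx
        grad[j, 1] += gy
        grad[j, 2] += gz
    return energy, degenerate


@njit(cache=True, fastmath=True)
def _scatter_free(pos, free, x):
    for a in range(free.shape[0]):
        b = free[a]
        pos[b, 0] = x[3 * a]
        pos[b, 1] = x[3 * a + 1]
        pos[b, 2] = x[3 * a + 2]


@njit(cache=True, fastmath=True)
def _gather_free(grad, free, gf):
    """Copy free-bead gradient into flat vector; return max bead force."""
    best = 0.0
    for a in range(free.shape[0]):
        b = free[a]
        g0 = grad[b, 0]
        g1 = grad[b, 1]
        g2 = grad[b, 2]
        gf[3 * a] = g0
        gf[3 * a + 1] = g1
        gf[3 * a + 2] = g2
        f = g0 * g0 + g1 * g1 + g2 * g2
        if f > best:
            best = f
    return np.sqrt(best)


@njit(cache=True, fastmath=True)
def lbfgs_relax(pos, free, edges, k, rest, threshold, max_iter, mem):
    """Limited-memory BFGS relaxation of the free beads, fully compiled.

    Minimizes the spring energy over free-bead coordinates until the
    maximum free-bead force drops below ``threshold`` (nN).  ``pos`` is
    updated in place.  Returns
    (iterations, converged, final_max_force, final_energy, n_evals,
    degenerate_spring_index).
    """
    nf = free.shape[0]
    ndof = nf * 3
    grad = np.empty_like(pos)
    x = np.empty(ndof)
    for a in range(nf):
        b = free[a]
        x[3 * a] = pos[b, 0]
        x[3 * a + 1] = pos[b, 1]
        x[3 * a + 2] = pos[b, 2]
    g = np.empty(ndof)
    g_new = np.empty(ndof)
    xt = np.empty(ndof)

    energy, degen = energy_gradient(pos, edges, k, rest, grad)
    n_evals = 1
    if degen >= 0:
        return 0, False, 0.0, energy, n_evals, degen
    maxf = _gather_free(grad, free, g)
    if maxf <= threshold:
        return 0, True, maxf, energy, n_evals, -1

    # ring buffers for the two-loop recursion
    S = np.zeros((mem, ndof))
    Y = np.zeros((mem, ndof))
    rho = np.zeros(mem)
    alpha_buf = np.zeros(mem)
    count = 0
    head = 0  # next slot to write
    gamma = 1.0 / max(k.max(), 1e-30)  # first-step scale ~ 1/k_max

    d = np.empty(ndof)
    iterations = 0
    converged = False

    while iterations < max_iter:
        iterations += 1
        # ---- two-loop recursion: d = -H g -------------------------
        for i in range(ndof):
            d[i] = g[i]
        for m in range(count):
            idx = (head - 1 - m) % mem
            sdot = 0.0
            for i in range(ndof):
                sdot += S[idx, i] * d[i]
            a_i = rho[idx] * sdot
            alpha_buf[idx] = a_i
            for i in range(ndof):
                d[i] -= a_i * Y[idx, i]
        for i in range(ndof):
            d[i] *= gamma
        for m in range(count - 1, -1, -1):
            idx = (head - 1 - m) % mem
            ydot = 0.0
            for i in range(ndof):
                ydot += Y[idx, i] * d[i]
            b_i = rho[idx] * ydot
            corr = alpha_buf[idx] - b_i
            for i in range(ndof):
                d[i] += corr * S[idx, i]
        dg = 0.0
        for i in range(ndof):
            d[i] = -d[i]
            dg += d[i] * g[i]
        if dg >= 0.0:  # not a descent direction: reset to scaled SD
            count = 0
            dg = 0.0
            for i in range(ndof):
                d[i] = -gamma * g[i]
                dg += d[i] * g[i]
            if dg >= 0.0:
                break

        # ---- Armijo backtracking from the quasi-Newton step --------
        step = 1.0
        accepted = False
        e_new = energy
        maxf_new = maxf
        for _bt in range(40):
            for i in range(ndof):
                xt[i] = x[i] + step * d[i]
            _scatter_free(pos, free, xt)
            e_new, degen = energy_gradient(pos, edges, k, rest, grad)
            n_evals += 1
            if degen >= 0:
                return iterations, False, maxf, energy, n_evals, degen
            if e_new <= energy + 1e-4 * step * dg:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            _scatter_free(pos, free, x)
            break

        maxf_new = _gather_free(grad, free, g_new)
        # ---- curvature update --------------------------------------
        sy = 0.0
        yy = 0.0
        ss = 0.0
        for i in range(ndof):
            si = step * d[i]
            yi = g_new[i] - g[i]
            S[head, i] = si
            Y[head, i] = yi
            sy += si * yi
            yy += yi * yi
            ss += si * si
        if sy > 1e-12 * np.sqrt(yy * ss):
            rho[head] = 1.0 / sy
            head = (head + 1) % mem
            if count < mem:
                count += 1
            gamma = sy / yy
        for i in range(ndof):
            x[i] = xt[i]
            g[i] = g_new[i]
        energy = e_new
        maxf = maxf_new
        if maxf <= threshold:
            converged = True
            break

    _scatter_free(pos, free, x)
    return iterations, converged, maxf, energy, n_evals, -1


@njit(cache=True, fastmath=True)
def max_bead_force(grad, idx):
    """Largest force-vector norm over the beads listed in ``idx``."""
    best = 0.0
    for m in range(idx.shape[0]):
        b = idx[m]
        f = (
            grad[b, 0] * grad[b, 0]
            + grad[b, 1] * grad[b, 1]
            + grad[b, 2] * grad[b, 2]
        )
        if f > best:
            best = f
    return np.sqrt(best)
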