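"""Numba-compiled inner loops.

Everything here is deliberately dumb: explicit Euler-Maruyama recursions and
per-particle event loops, with all model logic (parameter validation, region
geometry, switching policy) resolved by the callers into plain floats and
arrays.  Random numbers are either pre-generated by the caller (trajectory
kernels, so that noise streams can be shared across models) or drawn from a
``numpy.random.Generator`` passed in (experiment kernels, where the number of
draws is path-dependent).
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "cg_path",
    "fp_path",
    "msd_curve",
    "halfspace_kernel",
    "escape_kernel",
]


@njit(cache=True)
def cg_path(eta1, eta2, eta3, eta4, dt, noise, x0, v0, u0, z0):
    """Euler-Maruyama path of the CG model for one ion (3 components).

    ``noise`` has shape (n_steps, 3); the update uses the pre-step state on
    every right-hand side.  Returns (X, V, U, Z, bad_step); ``bad_step`` is the
    index of the first non-finite step, or -1.
    """
    n = noise.shape[0]
    X = np.empty((n + 1, 3))
    V = np.empty((n + 1, 3))
    U = np.empty((n + 1, 3))
    Z = np.empty((n + 1, 3))
    X[0] = x0
    V[0] = v0
    U[0] = u0
    Z[0] = z0
    amp = eta4 * np.sqrt(dt)
    for k in range(n):
        ok = True
        for i in range(3):
            x = X[k, i]
            v = V[k, i]
            u = U[k, i]
            z = Z[k, i]
            X[k + 1, i] = x + v * dt
            V[k + 1, i] = v + u * dt
            U[k + 1, i] = u + (-eta1 * v + z) * dt
            Z[k + 1, i] = z - (eta2 * z + eta3 * u) * dt + amp * noise[k, i]
            if not np.isfinite(Z[k + 1, i]) or not np.isfinite(X[k + 1, i]):
                ok = False
        if not ok:
            return X, V, U, Z, k + 1
    return X, V, U, Z, -1


@njit(cache=True)
def fp_path(alpha, dt, noise, x0, v0, ut0, zt0):
    """Euler-Maruyama path of the N-fictitious-particle model.

    State per component i: ion velocity V_i and per-particle auxiliaries
    (Ut_{j,i}, Zt_{j,i}).  ``alpha`` has shape (N, 4); ``noise`` has shape
    (n_steps, N, 3) and enters the Zt_j equation with coefficient
    alpha_{j,1} * alpha_{j,4}.  Returns (X, V, Ut, Zt, bad_step).
    """
    n = noise.shape[0]
    N = alpha.shape[0]
    X = np.empty((n + 1, 3))
    V = np.empty((n + 1, 3))
    Ut = np.empty((n + 1, N, 3))
    Zt = np.empty((n + 1, N, 3))
    X[0] = x0
    V[0] = v0
    Ut[0] = ut0
    Zt[0] = zt0
    sqdt = np.sqrt(dt)
    for k in range(n):
        ok = True
        for i in range(3):
            usum = 0.0
            for j in range(N):
                usum += Ut[k, j, i]
            X[k + 1, i] = X[k, i] + V[k, i] * dt
            V[k + 1, i] = V[k, i] + usum * dt
            for j in range(N):
                u = Ut[k, j, i]
                z = Zt[k, j, i]
                Ut[k + 1, j, i] = u + (z - alpha[j, 0] * V[k, i]) * dt
                Zt[k + 1, j, i] = (
                    z
                    - (alpha[j, 1] * z + alpha[j, 2] * u) * dt
                    + alpha[j, 0] * alpha[j, 3] * sqdt * noise[k, j, i]
                )
                if not np.isfinite(Zt[k + 1, j, i]):
                    ok = False
        if not ok:
            return X, V, Ut, Zt, k + 1
    return X, V, Ut, Zt, -1


@njit(cache=True)
def msd_curve(X, lags):
    """Time-origin-averaged, component-averaged mean square displacement.

    ``X`` has shape (n, 3); returns MSD summed over the three components
    (so that the free-diffusion asymptote of one component is 2*D*t after
    dividing by 3 -- the caller does the component averaging).
    """
    n = X.shape[0]
    out = np.empty(len(lags))
    for m in range(len(lags)):
        lag = lags[m]
        acc = 0.0
        for i in range(n - lag):
            for c in range(3):
                d = X[i + lag, c] - X[i, c]
                acc += d * d
        out[m] = acc / (3.0 * (n - lag))
    return out


@njit(cache=False)
def halfspace_kernel(
    eta1,
    eta2,
    eta3,
    eta4,
    D,
    h,
    dt,
    n_micro_per_bd,
    n_micro_total,
    n_particles,
    stationary_init,
    sig_v,
    sig_u,
    sig_z,
    rng,
):
    """Hybrid CG/BD half-space experiment; returns final x1 per particle.

    Geometry (first coordinate only; the CG first component is autonomous):
    the CG model is active for x1 > -h and hands over to BD once x1 <= -h;
    BD is active for x1 < h and hands back to CG once x1 >= h.  The overlap
    (-h, h) keeps the current description.  Time is counted in integer
    multiples of the CG timestep dt; one BD step spans ``n_micro_per_bd``
    of them, truncated at the final time if a switch has left the particle
    off the BD grid.

    The first half of the particles starts at +h under the CG description,
    the second half at -h under BD.
    """
    amp_cg = eta4 * np.sqrt(dt)
    out = np.empty(n_particles)
    n_half = n_particles // 2
    for p in range(n_particles):
        if p < n_half:
            tag_cg = True
            x = h
        else:
            tag_cg = False
            x = -h
        v = 0.0
        u = 0.0
        z = 0.0
        if tag_cg and stationary_init:
            v = sig_v * rng.standard_normal()
            u = sig_u * rng.standard_normal()
            z = sig_z * rng.standard_normal()
        k = 0  # elapsed time in micro (dt) units
        while k < n_micro_total:
            if tag_cg:
                xn = x + v * dt
                vn = v + u * dt
                un = u + (-eta1 * v + z) * dt
                zn = z - (eta2 * z + eta3 * u) * dt + amp_cg * rng.standard_normal()
                x, v, u, z = xn, vn, un, zn
                k += 1
                if x <= -h:
                    tag_cg = False
            else:
                span = n_micro_per_bd
                if k + span > n_micro_total:
                    span = n_micro_total - k
                x += np.sqrt(2.0 * D * span * dt) * rng.standard_normal()
                k += span
                if x >= h:
                    tag_cg = True
                    if stationary_init:
                        v = sig_v * rng.standard_normal()
                        u = sig_u * rng.standard_normal()
                        z = sig_z * rng.standard_normal()
                    else:
                        v = 0.0
                        u = 0.0
                        z = 0.0
        out[p] = x
    return out


@njit(cache=False)
def escape_kernel(
    eta1,
    eta2,
    eta3,
    eta4,
    D,
    r1,
    r2,
    r3,
    r4,
    dt,
    dT,
    r_grid,
    n_real,
    stationary_init,
    sig_v,
    sig_u,
    sig_z,
    max_steps,
    rng,
):
    """First-passage times through a grid of radii for the nested-box
    multiscale scheme with the CG model standing in for the fine-scale
    integrator.

    Region half-sides r1 < r2 < r3 < r4 delimit the nested boxes (sup-norm).
    Tags: 0 = fine (inner boxes), 1 = CG, 2 = BD.  The fine stand-in shares
    the CG dynamics, so fine<->CG handovers keep the full state; CG->BD drops
    the auxiliaries and BD->CG restores them per the initialization policy.
    Returns (T, tags_seen, truncated): T[real, m] is the first time the
    trajectory distance from the origin reached r_grid[m].
    """
    nr = len(r_grid)
    T = np.full((n_real, nr), np.nan)
    truncated = np.zeros(n_real, dtype=np.bool_)
    amp_cg = eta4 * np.sqrt(dt)
    amp_bd = np.sqrt(2.0 * D * dT)
    for real in range(n_real):
        x = np.zeros(3)
        v = np.empty(3)
        u = np.empty(3)
        z = np.empty(3)
        for i in range(3):
            v[i] = sig_v * rng.standard_normal()
            u[i] = sig_u * rng.standard_normal()
            z[i] = sig_z * rng.standard_normal()
        tag = 0  # start at origin under the fine description
        t = 0.0
        m = 0
        steps = 0
        while m < nr:
            steps += 1
            if steps > max_steps:
                truncated[real] = True
                break
            if tag <= 1:
                for i in range(3):
                    xi = x[i]
                    vi = v[i]
                    ui = u[i]
                    zi = z[i]
                    x[i] = xi + vi * dt
                    v[i] = vi + ui * dt
                    u[i] = ui + (-eta1 * vi + zi) * dt
                    z[i] = (
                        zi
                        - (eta2 * zi + eta3 * ui) * dt
                        + amp_cg * rng.standard_normal()
                    )
                t += dt
            else:
                for i in range(3):
                    x[i] += amp_bd * rng.standard_normal()
                t += dT
            # post-step region (sup-norm box classification, closed inner boxes)
            sup = abs(x[0])
            for i in range(1, 3):
                if abs(x[i]) > sup:
                    sup = abs(x[i])
            if sup <= r1:
                region = 1
            elif sup <= r2:
                region = 2
            elif sup <= r3:
                region = 3
            elif sup <= r4:
                region = 4
            else:
                region = 5
            if tag == 0:
                if region >= 3:
                    tag = 1
            elif tag == 1:
                if region == 1:
                    tag = 0
                elif region == 5:
                    tag = 2
            else:
                if region <= 3:
                    tag = 0 if region == 1 else 1
                    if stationary_init:
                        for i in range(3):
                            v[i] = sig_v * rng.standard_normal()
                            u[i] = sig_u * rng.standard_normal()
                            z[i] = sig_z * rng.standard_normal()
                    else:
                        for i in range(3):
                            v[i] = 0.0
                            u[i] = 0.0
                            z[i] = 0.0
            rho = np.sqrt(x[0] * x[0] + x[1] * x[1] + x[2] * x[2])
            while m < nr and rho >= r_grid[m]:
                T[real, m] = t
                m += 1
    return T, truncated


@njit(cache=True)
def linear_gaussian_path(A, L, noise, y0):
    """Exact linear-Gaussian recursion y_{k+1} = A y_k + L xi_k per component.

    ``y0`` has shape (d, 3); ``noise`` has shape (n_steps, d, 3).  Returns the
    full path with shape (n_steps + 1, d, 3).
    """
    n = noise.shape[0]
    d = A.shape[0]
    out = np.empty((n + 1, d, 3))
    out[0] = y0
    for k in range(n):
        for c in range(3):
            for i in range(d):
                acc = 0.0
                for j in range(d):
                    acc += A[i, j] * out[k, j, c] + L[i, j] * noise[k, j, c]
                out[k + 1, i, c] = acc
    return out
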