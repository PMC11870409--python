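"""Fixed-step RK4 kernels for the trafficking equations, with and without delay.

The dynamics are linear and non-stiff at biologically plausible rates, so a
classic fourth-order Runge-Kutta scheme on a uniform grid (step ~1 minute,
reduced further if any first-order rate would endanger stability) resolves
them far below the required tolerances.  The delayed variant integrates by
the method of steps: the step never exceeds the delay, so every delayed
lookup I(t - tau) falls in the already-computed part of the solution and is
read off by linear interpolation of the grid values.

Any small negative values produced by the scheme are clamped to zero at each
step.  Divergent trajectories (possible for extreme delay/rate combinations
where the delayed negative feedback is genuinely unstable) are detected and
reported through the returned status flag instead of raising inside the
compiled code.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_BLOWUP = 1e300


@njit(cache=True)
def _production(alpha, kappa, decay_mode, t):
    if decay_mode == 1:
        return alpha * np.exp(-kappa * t)
    return alpha


@njit(cache=True)
def _delayed(I, pos):
    k = int(np.floor(pos))
    frac = pos - k
    if frac < 1e-12:
        return I[k]
    return I[k] + frac * (I[k + 1] - I[k])


@njit(cache=True)
def rk4_delay(I, m, X, h, dd, alpha, kappa, decay_mode, beta, gamma, delta, eps):
    """Advance the delayed system over ``len(I) - m`` steps of size ``h``.

    ``I`` holds ``m`` history values (``I[m-1]`` is the state at local t=0)
    followed by uninitialized slots that this kernel fills.  ``X`` has the
    initial extracellular value in ``X[0]``.  ``dd = tau / h`` must be >= 1.
    Returns 0 on success, 1 on numerical blow-up.
    """
    n_steps = I.shape[0] - m
    c2 = beta + gamma
    dx_decay = delta + eps
    for i in range(n_steps):
        j = m - 1 + i
        t = i * h
        id0 = _delayed(I, j - dd)
        idh = _delayed(I, j + 0.5 - dd)
        id1 = _delayed(I, j + 1.0 - dd)
        p0 = _production(alpha, kappa, decay_mode, t)
        ph = _production(alpha, kappa, decay_mode, t + 0.5 * h)
        p1 = _production(alpha, kappa, decay_mode, t + h)
        x0 = X[i]

        k1i = p0 - c2 * id0 + eps * x0
        k1x = beta * id0 - dx_decay * x0
        x_half1 = x0 + 0.5 * h * k1x
        k2i = ph - c2 * idh + eps * x_half1
        k2x = beta * idh - dx_decay * x_half1
        x_half2 = x0 + 0.5 * h * k2x
        k3i = ph - c2 * idh + eps * x_half2
        k3x = beta * idh - dx_decay * x_half2
        x_full = x0 + h * k3x
        k4i = p1 - c2 * id1 + eps * x_full
        k4x = beta * id1 - dx_decay * x_full

        i_new = I[j] + h / 6.0 * (k1i + 2.0 * k2i + 2.0 * k3i + k4i)
        x_new = x0 + h / 6.0 * (k1x + 2.0 * k2x + 2.0 * k3x + k4x)
        if i_new < 0.0:
            i_new = 0.0
        if x_new < 0.0:
            x_new = 0.0
        if not (np.isfinite(i_new) and np.isfinite(x_new)) or i_new > _BLOWUP or x_new > _BLOWUP:
            return 1
        I[j + 1] = i_new
        X[i + 1] = x_new
    return 0


@njit(cache=True)
def rk4_ode(I, X, h, alpha, kappa, decay_mode, beta, gamma, delta, eps):
    """Advance the non-delayed system; ``I[0]``/``X[0]`` hold the initial state."""
    n_steps = I.shape[0] - 1
    c2 = beta + gamma
    dx_decay = delta + eps
    for i in range(n_steps):
        t = i * h
        p0 = _production(alpha, kappa, decay_mode, t)
        ph = _production(alpha, kappa, decay_mode, t + 0.5 * h)
        p1 = _production(alpha, kappa, decay_mode, t + h)
        i0 = I[i]
        x0 = X[i]

        k1i = p0 - c2 * i0 + eps * x0
        k1x = beta * i0 - dx_decay * x0
        i_a = i0 + 0.5 * h * k1i
        x_a = x0 + 0.5 * h * k1x
        k2i = ph - c2 * i_a + eps * x_a
        k2x = beta * i_a - dx_decay * x_a
        i_b = i0 + 0.5 * h * k2i
        x_b = x0 + 0.5 * h * k2x
        k3i = ph - c2 * i_b + eps * x_b
        k3x = beta * i_b - dx_decay * x_b
        i_c = i0 + h * k3i
        x_c = x0 + h * k3x
        k4i = p1 - c2 * i_c + eps * x_c
        k4x = beta * i_c - dx_decay * x_c

        i_new = i0 + h / 6.0 * (k1i + 2.0 * k2i + 2.0 * k3i + k4i)
        x_new = x0 + h / 6.0 * (k1x + 2.0 * k2x + 2.0 * k3x + k4x)
        if i_new < 0.0:
            i_new = 0.0
        if x_new < 0.0:
            x_new = 0.0
        if not (np.isfinite(i_new) and np.isfinite(x_new)) or i_new > _BLOWUP or x_new > _BLOWUP:
            return 1
        I[i + 1] = i_new
        X[i + 1] = x_new
    return 0
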