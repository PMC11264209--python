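"""Jitted propagation kernels for the bundled surrogate potentials.

Path sampling propagates millions of serial Langevin steps; for the bundled
systems a numba kernel evaluates the analytic gradient and the BAOAB update
in compiled code.  User-defined systems (plain callables) take the generic
numpy path in :mod:`tisdesign.dynamics`; results are deterministic on either
path given the seed, but the two paths use distinct noise streams.

Kernel contract: ``system.metadata["kernel"] = (kind, params, anchors)`` with
``kind`` one of the KIND_* integers.  An optional harmonic umbrella bias
``bias_k * (lambda - bias_c)**2`` (no 1/2 factor) is folded into the force.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit
    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*a, **k):
        def deco(f):
            return f
        return deco if not (a and callable(a[0])) else a[0]

KIND_DOUBLE_WELL = 0
KIND_MIGRATION_MIMIC = 1

STATUS_MAXSTEPS = 0
STATUS_STOPPED = 1
STATUS_BLOWUP = 2


@njit(cache=False)
def _grad_eval(kind, p, anchors, x, g, bias_k, bias_c):
    """Fill g with dV/dx (kcal/mol/A) including umbrella bias; return lambda."""
    for i in range(x.shape[0]):
        g[i] = 0.0
    if kind == KIND_DOUBLE_WELL:
        h, c, mid, coupling, k_env = p[0], p[1], p[2], p[3], p[4]
        u = x[0] - mid
        c4 = c ** 4
        lam = x[0]
        g[0] = 4.0 * h * u * (u * u - c * c) / c4
        for i in range(1, x.shape[0]):
            env = x[i] - coupling * u
            g[i] = k_env * env
            g[0] -= coupling * k_env * env
        if bias_k != 0.0:
            g[0] += 2.0 * bias_k * (lam - bias_c)
        return lam
    # migration mimic
    h = p[0]
    L = p[1]
    k_bond = p[2]
    gate_ref = p[4]
    gate_width = p[5]
    w2 = p[6]
    k_gate = p[7]
    k_center = p[9]
    k_env = p[10]
    n_gates = int(p[11])
    rDM = 0.0
    rMA = 0.0
    uDM = np.empty(3)
    uMA = np.empty(3)
    for a in range(3):
        uDM[a] = x[0 + a] - x[3 + a]
        uMA[a] = x[3 + a] - x[6 + a]
        rDM += uDM[a] * uDM[a]
        rMA += uMA[a] * uMA[a]
    rDM = np.sqrt(rDM)
    rMA = np.sqrt(rMA)
    for a in range(3):
        uDM[a] /= rDM
        uMA[a] /= rMA
    lam = rDM - rMA
    s = rDM + rMA - L
    bump = np.exp(-lam * lam / (2.0 * w2))
    dV_dlam = 4.0 * h * lam * (lam * lam - 1.0)
    # per-gate terms: strengths/rests at p[3]/p[8] (gate 1), p[12]/p[13]
    for gi in range(n_gates):
        strength = p[3] if gi == 0 else p[12]
        rest_g = p[8] if gi == 0 else p[13]
        base = 9 + 3 * gi
        gg = 0.0
        for a in range(3):
            gg += (x[base + a] - x[3 + a]) ** 2
        gdist = np.sqrt(gg)
        th = np.tanh((gdist - gate_ref) / gate_width)
        dV_dlam += strength * th * bump * (-lam / w2)
        dV_dg = strength * (1.0 - th * th) / gate_width * bump \
            + k_gate * (gdist - rest_g)
        for a in range(3):
            ug = (x[base + a] - x[3 + a]) / gdist
            g[base + a] += dV_dg * ug
            g[3 + a] -= dV_dg * ug
    if bias_k != 0.0:
        dV_dlam += 2.0 * bias_k * (lam - bias_c)
    dV_drDM = k_bond * s + dV_dlam
    dV_drMA = k_bond * s - dV_dlam
    for a in range(3):
        g[0 + a] += dV_drDM * uDM[a]
        g[3 + a] -= dV_drDM * uDM[a]
        g[3 + a] += dV_drMA * uMA[a]
        g[6 + a] -= dV_drMA * uMA[a]
        g[3 + a] += k_center * x[3 + a]
    n_distract = anchors.shape[0]
    for e in range(n_distract):
        base = 9 + 3 * n_gates + 3 * e
        r2 = 0.0
        for a in range(3):
            r2 += (x[base + a] - x[3 + a]) ** 2
        r = np.sqrt(r2)
        dV = k_env * (r - anchors[e]) / r
        for a in range(3):
            de = x[base + a] - x[3 + a]
            g[base + a] += dV * de
            g[3 + a] -= dV * de
    return lam


@njit(cache=False)
def propagate_kernel(kind, p, anchors, x0, v0, masses, dt, gamma_fs, kt_int,
                     f2a, lo, hi, max_steps, seed, bias_k, bias_c):
    """BAOAB propagation until lambda leaves (lo, hi) or max_steps.

    Returns (xs, vs, lams, n_frames, status).  Frame 0 is the initial state;
    the stop test is applied only to newly generated frames.
    """
    n = x0.shape[0]
    xs = np.empty((max_steps + 1, n))
    vs = np.empty((max_steps + 1, n))
    lams = np.empty(max_steps + 1)
    np.random.seed(seed)
    c1 = np.exp(-gamma_fs * dt)
    sigma = np.empty(n)
    inv_m = np.empty(n)
    for i in range(n):
        sigma[i] = np.sqrt((1.0 - c1 * c1) * kt_int / masses[i])
        inv_m[i] = f2a / masses[i]
    x = x0.copy()
    v = v0.copy()
    g = np.empty(n)
    lam = _grad_eval(kind, p, anchors, x, g, bias_k, bias_c)
    half = 0.5 * dt
    for i in range(n):
        xs[0, i] = x[i]
        vs[0, i] = v[i]
    lams[0] = lam
    nf = 1
    status = STATUS_MAXSTEPS
    stochastic = gamma_fs > 0.0
    for _ in range(max_steps):
        for i in range(n):
            v[i] += half * (-g[i]) * inv_m[i]
            x[i] += half * v[i]
        if stochastic:
            for i in range(n):
                v[i] = c1 * v[i] + sigma[i] * np.random.standard_normal()
        for i in range(n):
            x[i] += half * v[i]
        lam = _grad_eval(kind, p, anchors, x, g, bias_k, bias_c)
        for i in range(n):
            v[i] += half * (-g[i]) * inv_m[i]
        if not np.isfinite(lam):
            status = STATUS_BLOWUP
            break
        for i in range(n):
            xs[nf, i] = x[i]
            vs[nf, i] = v[i]
        lams[nf] = lam
        nf += 1
        if lam < lo or lam > hi:
            status = STATUS_STOPPED
            break
    return xs[:nf], vs[:nf], lams[:nf], nf, status


def kernel_params_double_well(barrier_height, well_centers, coupling, k_env):
    l1, l2 = well_centers
    mid = 0.5 * (l1 + l2)
    c = 0.5 * abs(l2 - l1)
    p = np.array([barrier_height, c, mid, coupling, k_env], dtype=float)
    return (KIND_DOUBLE_WELL, p, np.zeros(0))


def kernel_params_migration_mimic(barrier_height, bond_length_sum, k_bond,
                                  gate_strength, gate_ref, gate_width,
                                  gate_bump_width, k_gate, gate_rest,
                                  k_center, k_env, distractor_rests,
                                  n_gates=1, gate2_strength=0.0,
                                  gate2_rest=2.0):
    p = np.array([barrier_height, bond_length_sum, k_bond, gate_strength,
                  gate_ref, gate_width, gate_bump_width ** 2, k_gate,
                  gate_rest, k_center, k_env, float(n_gates),
                  gate2_strength, gate2_rest], dtype=float)
    # the aux array holds the distractor tether rest distances (to M)
    return (KIND_MIGRATION_MIMIC, p,
            np.ascontiguousarray(distractor_rests, dtype=float))
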