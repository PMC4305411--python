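"""Numerical inner loops, jit-compiled with numba when available.

The mechanics sub-step kernel integrates overdamped motion for one pathway
step.  It operates on flat arrays and a candidate pair list built with a
safety margin; it returns early once any cell has drifted far enough that
the candidate list may be stale, letting the caller rebuild it.
"""

from __future__ import annotations

import math

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap


@njit(cache=True)
def _seed_kernel_rng(seed):  # pragma: no cover - trivial
    np.random.seed(seed)


def seed_kernel_rng(seed: int) -> None:
    """Seed the RNG used inside the jit kernels (numba keeps its own)."""
    _seed_kernel_rng(np.int64(seed))


@njit(cache=True)
def colony_step_kernel(
    pos,  # (N,2) float64, updated in place
    radius,  # (N,) float64
    expr,  # (N,) float64
    E,  # (N,) float64, updated
    B,  # (N,) float64, updated
    EB,  # (N,) float64, updated
    C,  # (N,N) float64 bound complexes, updated
    area,  # (N,N) float64, updated
    prev,  # (N,N) float64, updated
    site,  # (N,N) bool, updated
    m_flag,  # (N,) bool: cell is in M phase
    sib_idx,  # (N,) int64 index of the M sibling, -1 otherwise
    pressure,  # (N,) float64 out: Σ|repulsive| at the last sub-step
    rho_u,
    nu_n,
    nu_p,
    rho_c,
    gamma_r,
    rho_d,
    model,  # int64 1/2/3
    dt,
    cap,
    sigma,
    emod,
    eta,
    noise_sigma2,  # 2*D, µm²/min
    collapse_thr,  # fraction of R_i+R_j; <=0 disables
):
    """One full physics step: bookkeeping → pathway → mechanics → collapse.

    Returns 1 if the world collapsed (some non-sibling pair closer than
    ``collapse_thr``·(R_i+R_j)), else 0.
    """
    n = pos.shape[0]
    eps_site = 1e-6

    # ---------------- bookkeeping
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            sib = m_flag[i] and m_flag[j] and sib_idx[i] == j
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            d = math.sqrt(dx * dx + dy * dy)
            Ri = radius[i]
            Rj = radius[j]
            a_new = 0.0
            if (not sib) and d < Ri + Rj:
                rs = Ri if Ri < Rj else Rj
                if d <= abs(Ri - Rj) or d < 1e-12:
                    a_sq = rs * rs
                else:
                    a_sq = (
                        4.0 * d * d * Ri * Ri
                        - (d * d - Rj * Rj + Ri * Ri) ** 2
                    ) / (4.0 * d * d)
                    if a_sq < 0.0:
                        a_sq = 0.0
                    if a_sq > rs * rs:
                        a_sq = rs * rs
                a_new = math.pi * a_sq
            if a_new > 0.0:
                if not site[i, j]:
                    site[i, j] = True
                    prev[i, j] = a_new
                    C[i, j] = 0.0
                area[i, j] = a_new
            elif site[i, j]:
                area[i, j] = 0.0
                if C[i, j] < eps_site:
                    EB[i] += C[i, j]
                    C[i, j] = 0.0
                    prev[i, j] = 0.0
                    site[i, j] = False

    # ---------------- pathway (forward Euler with conservative clipping)
    for i in range(n):
        surface = 4.0 * math.pi * radius[i] * radius[i]
        nsites = 0
        rowsum = 0.0
        for j in range(n):
            if site[i, j]:
                nsites += 1
                rowsum += C[i, j]
        m_bind = nu_p * E[i] * B[i] * dt
        if m_bind > E[i]:
            m_bind = E[i]
        if m_bind > B[i]:
            m_bind = B[i]
        m_diss = nu_n * EB[i] * dt

        gain_tot = 0.0
        for j in range(n):
            if not site[i, j]:
                continue
            if model == 1:
                cap_i = expr[i] / 6.0
                sat = 1.0 - C[i, j] / cap_i if cap_i > 0.0 else 0.0
            else:
                cap_i = 0.8 * expr[i]
                sat = 1.0 - rowsum / cap_i if cap_i > 0.0 else 0.0
            if sat < 0.0:
                sat = 0.0
            g = 0.0
            if area[i, j] > 0.0:
                # relative area change acts as a rate clamped at 1 min⁻¹
                a_c = (area[i, j] - prev[i, j]) / max(area[i, j], 1e-12)
                if a_c < 0.0:
                    a_c = 0.0
                elif a_c > dt:
                    a_c = dt
                g = (
                    rho_c * EB[i] * a_c
                    + rho_u * EB[i] * (area[i, j] / surface) * dt
                ) * sat
            gain_tot += g
        scale = 1.0
        out = m_diss + gain_tot
        if out > EB[i] and out > 0.0:
            scale = EB[i] / out
            if scale < 0.0:
                scale = 0.0
        m_diss *= scale

        drain_tot = 0.0
        gain_eff = 0.0
        headroom = 0.8 * expr[i] - rowsum  # shared cap of the dynamic models
        if headroom < 0.0:
            headroom = 0.0
        for j in range(n):
            if not site[i, j]:
                continue
            if model == 1:
                cap_i = expr[i] / 6.0
                sat = 1.0 - C[i, j] / cap_i if cap_i > 0.0 else 0.0
            else:
                cap_i = 0.8 * expr[i]
                sat = 1.0 - rowsum / cap_i if cap_i > 0.0 else 0.0
            if sat < 0.0:
                sat = 0.0
            g = 0.0
            dr = 0.0
            if area[i, j] > 0.0:
                a_c = (area[i, j] - prev[i, j]) / max(area[i, j], 1e-12)
                if a_c < 0.0:
                    a_c = 0.0
                elif a_c > dt:
                    a_c = dt
                a_d = (prev[i, j] - area[i, j]) / max(prev[i, j], 1e-12)
                if a_d < 0.0:
                    a_d = 0.0
                elif a_d > dt:
                    a_d = dt
                g = (
                    rho_c * EB[i] * a_c
                    + rho_u * EB[i] * (area[i, j] / surface) * dt
                ) * sat * scale
                dr = rho_d * C[i, j] * a_d
            else:
                dr = rho_d * C[i, j] * dt
            if dr > C[i, j]:
                dr = C[i, j]
            # a gain step may not overshoot the saturation cap
            if model == 1:
                room = expr[i] / 6.0 - C[i, j]
                if room < 0.0:
                    room = 0.0
                if g > room:
                    g = room
            else:
                if g > headroom:
                    g = headroom
                headroom -= g
            redis = 0.0
            if model != 1 and nsites > 1:
                # exact update of the linear redistribution subsystem
                # (unconditionally stable for any gamma)
                redis = (rowsum / nsites - C[i, j]) * (
                    1.0 - math.exp(-nsites * gamma_r * dt)
                )
            C[i, j] += g - dr + redis
            if C[i, j] < 0.0:
                EB[i] += C[i, j]
                C[i, j] = 0.0
            prev[i, j] = area[i, j]
            gain_eff += g
            drain_tot += dr
        E[i] += -m_bind + m_diss
        B[i] += -m_bind + m_diss
        EB[i] += m_bind - m_diss - gain_eff + drain_tot

    # ---------------- mechanics (candidate pairs, drift-aware rebuild)
    if n >= 1:
        margin = 2.0
        anchor = 15.0 if model == 1 else 80.0
        sep_force = 210000.0
        compliance = 0.75 * 2.0 * (1.0 - sigma * sigma) / emod
        max_pairs = n * (n - 1) // 2
        ii = np.empty(max_pairs, dtype=np.int64)
        jj = np.empty(max_pairs, dtype=np.int64)
        pref = np.empty(max_pairs)
        adh0 = np.empty(max_pairs)
        dnat = np.empty(max_pairs)
        fx = np.zeros(n)
        fy = np.zeros(n)
        nx = np.zeros(n)
        ny = np.zeros(n)
        x_ref = np.zeros(n)
        y_ref = np.zeros(n)
        drag = np.empty(n)
        for i in range(n):
            drag[i] = 6.0 * math.pi * (eta / 60.0) * radius[i]
        t = 0.0
        guard = 0
        while t < dt - 1e-12 and guard < 64:
            guard += 1
            npairs = 0
            for i in range(n):
                x_ref[i] = pos[i, 0]
                y_ref[i] = pos[i, 1]
                for j in range(i + 1, n):
                    if m_flag[i] and m_flag[j] and sib_idx[i] == j:
                        continue
                    dx = pos[i, 0] - pos[j, 0]
                    dy = pos[i, 1] - pos[j, 1]
                    d = math.sqrt(dx * dx + dy * dy)
                    near = d < radius[i] + radius[j] + margin
                    if not (near or site[i, j] or site[j, i]):
                        continue
                    ii[npairs] = i
                    jj[npairs] = j
                    pref[npairs] = (
                        math.sqrt(
                            radius[i] * radius[j] / (radius[i] + radius[j])
                        )
                        / compliance
                    )
                    m = C[i, j]
                    if C[j, i] < m:
                        m = C[j, i]
                    adh0[npairs] = m / anchor * sep_force
                    if model == 3:
                        a_nat = math.pi * (radius[i] + radius[j]) / 12.0
                        rs = radius[i] if radius[i] < radius[j] else radius[j]
                        if a_nat > rs:
                            a_nat = rs
                        dnat[npairs] = math.sqrt(
                            radius[i] * radius[i] - a_nat * a_nat
                        ) + math.sqrt(radius[j] * radius[j] - a_nat * a_nat)
                    else:
                        dnat[npairs] = 0.0
                    npairs += 1
            substeps = 0
            while t < dt - 1e-12 and substeps < 200000:
                substeps += 1
                for i in range(n):
                    fx[i] = 0.0
                    fy[i] = 0.0
                    pressure[i] = 0.0
                for k in range(npairs):
                    i = ii[k]
                    j = jj[k]
                    dx = pos[i, 0] - pos[j, 0]
                    dy = pos[i, 1] - pos[j, 1]
                    d = math.sqrt(dx * dx + dy * dy)
                    if d < 1e-9:
                        continue
                    h = radius[i] + radius[j] - d
                    rep = 0.0
                    if h > 0.0:
                        rep = pref[k] * h * math.sqrt(h)
                    adh = adh0[k]
                    if model == 3:
                        ramp = (d - dnat[k]) / 0.1
                        if ramp < 0.0:
                            ramp = 0.0
                        elif ramp > 1.0:
                            ramp = 1.0
                        adh *= ramp
                    f = (rep - adh) / d
                    fx[i] += f * dx
                    fy[i] += f * dy
                    fx[j] -= f * dx
                    fy[j] -= f * dy
                    pressure[i] += rep
                    pressure[j] += rep
                vmax = 0.0
                for i in range(n):
                    v = math.sqrt(fx[i] * fx[i] + fy[i] * fy[i]) / drag[i]
                    if v > vmax:
                        vmax = v
                if vmax <= 0.0 and noise_sigma2 <= 0.0:
                    t = dt
                    break
                sub = dt - t
                if vmax > 0.0 and cap / vmax < sub:
                    sub = cap / vmax
                sig = 0.0
                if noise_sigma2 > 0.0:
                    sig = math.sqrt(noise_sigma2 * sub)
                drift_hit = False
                for i in range(n):
                    ddx = fx[i] / drag[i] * sub
                    ddy = fy[i] / drag[i] * sub
                    if sig > 0.0:
                        # an M-phase dumb-bell is one body: both halves get
                        # the same noise realisation (no relative diffusion)
                        s = sib_idx[i] if (m_flag[i] and sib_idx[i] >= 0) else -1
                        if s >= 0 and s < i:
                            nx[i] = nx[s]
                            ny[i] = ny[s]
                        else:
                            nx[i] = sig * np.random.standard_normal()
                            ny[i] = sig * np.random.standard_normal()
                        ddx += nx[i]
                        ddy += ny[i]
                    pos[i, 0] += ddx
                    pos[i, 1] += ddy
                    ex = pos[i, 0] - x_ref[i]
                    ey = pos[i, 1] - y_ref[i]
                    if ex * ex + ey * ey > 0.64 * margin * margin:
                        drift_hit = True
                t += sub
                if model == 3:
                    # separation-force rule: inside the thin engagement band
                    # the pair's axial dynamics are stiff (force swings by
                    # the full bond strength over 0.1 µm) but have a stable
                    # equilibrium whose relaxation time is far below any
                    # sub-step; project bonded pairs onto it directly
                    for k in range(npairs):
                        i = ii[k]
                        j = jj[k]
                        if adh0[k] <= 0.0:
                            continue
                        dx = pos[i, 0] - pos[j, 0]
                        dy = pos[i, 1] - pos[j, 1]
                        d = math.sqrt(dx * dx + dy * dy)
                        if d <= dnat[k] or d >= dnat[k] + 0.1 or d < 1e-9:
                            continue
                        h = radius[i] + radius[j] - d
                        rep = pref[k] * h * math.sqrt(h) if h > 0.0 else 0.0
                        d_eq = dnat[k] + 0.1 * rep / adh0[k]
                        h2 = radius[i] + radius[j] - d_eq
                        rep2 = pref[k] * h2 * math.sqrt(h2) if h2 > 0.0 else 0.0
                        d_eq = dnat[k] + 0.1 * rep2 / adh0[k]
                        if d_eq >= dnat[k] + 0.1:
                            continue  # bond too weak: genuine separation
                        shift = d_eq - d
                        wi = drag[j] / (drag[i] + drag[j])
                        ux = dx / d
                        uy = dy / d
                        pos[i, 0] += shift * wi * ux
                        pos[i, 1] += shift * wi * uy
                        pos[j, 0] -= shift * (1.0 - wi) * ux
                        pos[j, 1] -= shift * (1.0 - wi) * uy
                # the M-phase dumb-bell is rigid: restore the fixed
                # inter-centre distance of the two halves (birth geometry)
                for i in range(n):
                    si = sib_idx[i]
                    if si <= i or not (m_flag[i] and si >= 0 and m_flag[si]):
                        continue
                    dx = pos[i, 0] - pos[si, 0]
                    dy = pos[i, 1] - pos[si, 1]
                    d = math.sqrt(dx * dx + dy * dy)
                    d_t = 0.5 * (radius[i] + radius[si]) * 2.0 ** (1.0 / 3.0)
                    if d < 1e-9:
                        dx, dy, d = 1.0, 0.0, 1.0
                    scale_s = 0.5 * (d_t - d) / d
                    pos[i, 0] += scale_s * dx
                    pos[i, 1] += scale_s * dy
                    pos[si, 0] -= scale_s * dx
                    pos[si, 1] -= scale_s * dy
                if drift_hit:
                    break

    # ---------------- collapse detection
    if collapse_thr > 0.0:
        for i in range(n):
            for j in range(i + 1, n):
                if m_flag[i] and m_flag[j] and sib_idx[i] == j:
                    continue
                dx = pos[i, 0] - pos[j, 0]
                dy = pos[i, 1] - pos[j, 1]
                d = math.sqrt(dx * dx + dy * dy)
                if d < collapse_thr * (radius[i] + radius[j]):
                    return 1
    return 0


@njit(cache=True)
def pipette_kernel(
    x0,  # (n,) float64 initial collinear positions
    active_step,  # (n,) int64 step at which each cell enters the assay
    anchor_idx,  # (n,) int64 arrival anchor (-1: x0 is absolute)
    offset,  # (n,) float64 arrival offset from the anchor position
    expr,  # (n,) float64 E-cadherin expression levels, %
    R,  # float64 cell radius, µm
    sigma,
    emod,
    eta,  # mech parameters (Pa·s for eta)
    rho_u,
    nu_n,
    nu_p,
    rho_c,
    gamma_r,
    rho_d,  # kinetic rates, min⁻¹
    model,  # int64: 1, 2 or 3
    n_steps,  # int64
    dt,  # float64, min
    cap,  # float64 displacement cap, µm
    record_every,  # int64 steps between force records
):
    """Fast dedicated integrator for the 2–3 cell pipette assays.

    Collinear geometry, no cycle, no noise, no collapse halt (the pipettes
    hold the cells).  A pair whose adhesion exceeds its repulsion inside
    0.2 µm is pinned at coincidence ("stuck"): past that point the model
    has no mechanical equilibrium and the overdamped dynamics would only
    jitter around the crushed state.  Records the *separation* force of
    each pair (the bond map evaluated at min of the two sides, ungated)
    every ``record_every`` steps.  Returns (rec_t, rec_F[:, 3], C) with
    pair columns (0-1), (0-2), (1-2).
    """
    n = x0.shape[0]
    x = x0.copy()
    E = np.zeros(n)
    B = np.zeros(n)
    EB = np.zeros(n)
    C = np.zeros((n, n))
    area = np.zeros((n, n))
    prev = np.zeros((n, n))
    site = np.zeros((n, n), dtype=np.bool_)
    active = np.zeros(n, dtype=np.bool_)

    anchor = 80.0
    if model == 1:
        anchor = 15.0
    sep_force = 210000.0
    surface = 4.0 * math.pi * R * R
    drag = 6.0 * math.pi * (eta / 60.0) * R
    compliance = 0.75 * 2.0 * (1.0 - sigma * sigma) / emod
    pref = math.sqrt(R * 0.5) / compliance
    # natural-state distance for equal spheres
    a_nat = math.pi * R / 6.0
    dnat = 2.0 * math.sqrt(R * R - a_nat * a_nat)
    eps_site = 1e-6

    n_rec = n_steps // record_every + 1
    rec_t = np.zeros(n_rec)
    rec_F = np.zeros((n_rec, 3))
    i_rec = 0

    for k in range(n_steps + 1):
        # --- activation
        for i in range(n):
            if not active[i] and k >= active_step[i]:
                active[i] = True
                if anchor_idx[i] >= 0:
                    x[i] = x[anchor_idx[i]] + offset[i]
                E[i] = expr[i]
                B[i] = 100.0
                EB[i] = 0.0

        # --- bookkeeping
        for i in range(n):
            for j in range(n):
                if i == j or not (active[i] and active[j]):
                    continue
                d = abs(x[i] - x[j])
                a_new = 0.0
                if d < 2.0 * R:
                    a_sq = R * R - 0.25 * d * d
                    if a_sq > 0.0:
                        a_new = math.pi * a_sq
                if a_new > 0.0:
                    if not site[i, j]:
                        site[i, j] = True
                        prev[i, j] = a_new
                        C[i, j] = 0.0
                    area[i, j] = a_new
                else:
                    if site[i, j]:
                        area[i, j] = 0.0
                        if C[i, j] < eps_site:
                            EB[i] += C[i, j]
                            C[i, j] = 0.0
                            prev[i, j] = 0.0
                            site[i, j] = False

        if k == n_steps:
            pass  # final record below, no further dynamics needed
        else:
            # --- pathway (forward Euler, conservative clipping)
            for i in range(n):
                if not active[i]:
                    continue
                nsites = 0
                rowsum = 0.0
                for j in range(n):
                    if site[i, j]:
                        nsites += 1
                        rowsum += C[i, j]
                m_bind = nu_p * E[i] * B[i] * dt
                if m_bind > E[i]:
                    m_bind = E[i]
                if m_bind > B[i]:
                    m_bind = B[i]
                m_diss = nu_n * EB[i] * dt

                gain_tot = 0.0
                gains = np.zeros(n)
                drains = np.zeros(n)
                for j in range(n):
                    if not site[i, j]:
                        continue
                    if model == 1:
                        cap_i = expr[i] / 6.0
                        sat = 1.0 - C[i, j] / cap_i if cap_i > 0 else 0.0
                    else:
                        cap_i = 0.8 * expr[i]
                        sat = 1.0 - rowsum / cap_i if cap_i > 0 else 0.0
                    if sat < 0.0:
                        sat = 0.0
                    if area[i, j] > 0.0:
                        # relative area change as a rate clamped at 1 min⁻¹
                        a_c = (area[i, j] - prev[i, j]) / max(area[i, j], 1e-12)
                        if a_c < 0.0:
                            a_c = 0.0
                        elif a_c > dt:
                            a_c = dt
                        a_d = (prev[i, j] - area[i, j]) / max(prev[i, j], 1e-12)
                        if a_d < 0.0:
                            a_d = 0.0
                        elif a_d > dt:
                            a_d = dt
                        g = (rho_c * EB[i] * a_c + rho_u * EB[i] * (area[i, j] / surface) * dt) * sat
                        dr = rho_d * C[i, j] * a_d
                    else:
                        g = 0.0
                        dr = rho_d * C[i, j] * dt
                    if dr > C[i, j]:
                        dr = C[i, j]
                    if model == 1:
                        room = expr[i] / 6.0 - C[i, j]
                    else:
                        room = 0.8 * expr[i] - rowsum - gain_tot
                    if room < 0.0:
                        room = 0.0
                    if g > room:
                        g = room
                    gains[j] = g
                    drains[j] = dr
                    gain_tot += g
                out = m_diss + gain_tot
                if out > EB[i] and out > 0.0:
                    sc = EB[i] / out
                    if sc < 0.0:
                        sc = 0.0
                    m_diss *= sc
                    for j in range(n):
                        gains[j] *= sc
                    gain_tot *= sc
                drain_tot = 0.0
                for j in range(n):
                    drain_tot += drains[j]
                E[i] += -m_bind + m_diss
                B[i] += -m_bind + m_diss
                EB[i] += m_bind - m_diss - gain_tot + drain_tot
                for j in range(n):
                    if site[i, j]:
                        redis = 0.0
                        if model != 1 and nsites > 1:
                            redis = (rowsum / nsites - C[i, j]) * (
                                1.0 - math.exp(-nsites * gamma_r * dt)
                            )
                        C[i, j] += gains[j] - drains[j] + redis
                        if C[i, j] < 0.0:
                            EB[i] += C[i, j]
                            C[i, j] = 0.0
                        prev[i, j] = area[i, j]

            # --- mechanics sub-steps
            t = 0.0
            while t < dt - 1e-12:
                fmax = 0.0
                f = np.zeros(n)
                for i in range(n):
                    if not active[i]:
                        continue
                    for j in range(n):
                        if j == i or not active[j]:
                            continue
                        dx = x[i] - x[j]
                        d = abs(dx)
                        if d < 1e-9:
                            continue
                        h = 2.0 * R - d
                        rep = 0.0
                        if h > 0.0:
                            rep = pref * h * math.sqrt(h)
                        m = C[i, j]
                        if C[j, i] < m:
                            m = C[j, i]
                        adh = m / anchor * sep_force
                        if model == 3:
                            ramp = (d - dnat) / 0.1
                            if ramp < 0.0:
                                ramp = 0.0
                            elif ramp > 1.0:
                                ramp = 1.0
                            adh *= ramp
                        f[i] += (rep - adh) * (dx / d)
                for i in range(n):
                    if abs(f[i]) > fmax:
                        fmax = abs(f[i])
                vmax = fmax / drag
                sub = dt - t
                if vmax > 0.0 and cap / vmax < sub:
                    sub = cap / vmax
                for i in range(n):
                    x[i] += f[i] / drag * sub
                t += sub
                # pin clusters past the point of no mechanical equilibrium:
                # cells bound more strongly than they repel at < 0.2 µm are
                # merged (transitively) onto their common centroid, where
                # the crushed state would otherwise only chatter
                label = np.full(n, -1, dtype=np.int64)
                nlab = 0
                for i in range(n):
                    if not active[i]:
                        continue
                    if label[i] < 0:
                        label[i] = nlab
                        nlab += 1
                    for j in range(i + 1, n):
                        if not active[j]:
                            continue
                        d = abs(x[i] - x[j])
                        if d >= 0.2:
                            continue
                        m = C[i, j]
                        if C[j, i] < m:
                            m = C[j, i]
                        adh = m / anchor * sep_force
                        h = 2.0 * R - d
                        rep = pref * h * math.sqrt(h) if h > 0.0 else 0.0
                        if model == 3:
                            ramp = (d - dnat) / 0.1
                            if ramp < 0.0:
                                ramp = 0.0
                            elif ramp > 1.0:
                                ramp = 1.0
                            adh *= ramp
                        if adh > rep:
                            if label[j] < 0:
                                label[j] = label[i]
                            elif label[j] != label[i]:
                                old_l = label[j]
                                for q in range(n):
                                    if label[q] == old_l:
                                        label[q] = label[i]
                for lab in range(nlab):
                    cnt = 0
                    cx = 0.0
                    for i in range(n):
                        if label[i] == lab:
                            cnt += 1
                            cx += x[i]
                    if cnt > 1:
                        cx /= cnt
                        for i in range(n):
                            if label[i] == lab:
                                x[i] = cx
                if vmax <= 0.0:
                    break

        if k % record_every == 0:
            rec_t[i_rec] = k * dt
            col = 0
            for i in range(n):
                for j in range(i + 1, n):
                    if col < 3:
                        m = C[i, j]
                        if C[j, i] < m:
                            m = C[j, i]
                        rec_F[i_rec, col] = m / anchor * sep_force
                    col += 1
            i_rec += 1

    return rec_t, rec_F, C
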