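"""Compiled single-trial simulation loop.

This is a performance twin of the object-level reference implementation in
:mod:`mothsim.plume` / :mod:`mothsim.navigators`: one navigator flown
against one wind + plume realization, step for step identical to the
reference (same update order, same prune rule, same state machine, same
random-sign consumption).  It covers the benchmark study conditions
(noise-free wind); noisy-wind runs fall back to the Python engine.

Mode codes: 0 waiting, 1 detecting, 2 surging, 3 casting, 4 sweeping,
5 done_success, 6 done_failed.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

WAITING, DETECTING, SURGING, CASTING, SWEEPING, SUCCESS, FAILED = range(7)


@njit(cache=True)
def run_trial_kernel(
    # wind
    A, B, omega, phase,
    # plume
    fr, r0sq, sigma, mp, C0, sx, sy,
    # domain
    xmin, xmax, ymin, ymax,
    # navigator
    x0, y0, speed, success_radius,
    # strategy: 0=A1, 1=A2, 2=B1, 3=B2
    strat, alpha, growth, lam_const, delta1_const, sweep_mult, n_half,
    # integration
    dt, n_steps,
    # pre-drawn uniforms for cast/sweep sign choices
    signs,
):
    """Simulate one trial; returns (mode, t0, t_end, released, pruned, active)."""
    cap = int(fr * dt * n_steps) + n_steps + 4
    dxb = np.empty(cap)
    dyb = np.empty(cap)
    tb = np.empty(cap)
    n_act = 0
    released = 0
    pruned = 0
    acc = 0.0
    Dx = 0.0
    Dy = 0.0
    clock = 0.0

    # max detection-disc radius over a puff lifetime (for the search window)
    s_death = mp / (2.0 * C0)
    rmax2 = 0.0
    s_star = s_death / math.e
    if s_star < r0sq:
        s_star = r0sq
    for s in (s_star, r0sq):
        if s < s_death:
            cand = 2.0 * s * math.log(mp / (2.0 * s * C0))
            if cand > rmax2:
                rmax2 = cand
    rmax = math.sqrt(rmax2) if rmax2 > 0.0 else 0.0

    # navigator state
    nx = x0
    ny = y0
    mode = WAITING
    t_c = 0.0
    mode_clock = 0.0
    lam = 0.0
    delta1 = 0.0
    delta2 = 0.0
    cast_k = 0
    cast_sign = 1.0
    sweep_sign = 1.0
    hx = -1.0
    hy = 0.0
    t0 = -1.0
    si = 0  # sign-draw cursor
    t_end = 0.0

    strategy_a = strat <= 1

    for _ in range(n_steps):
        # wind at step start, held constant over the step
        u = A
        v = B * math.sin(omega * clock + phase)

        # ---- plume step: advect, tick clock, release, prune
        Dx += u * dt
        Dy += v * dt
        clock += dt
        t = clock
        acc += fr * dt
        n_new = int(math.floor(acc))
        acc -= n_new
        for _k in range(n_new):
            dxb[n_act] = Dx
            dyb[n_act] = Dy
            tb[n_act] = clock
            n_act += 1
        released += n_new
        # prune (widths evaluated at the post-tick clock, as in the reference)
        w = 0
        for i in range(n_act):
            px = sx + (Dx - dxb[i])
            py = sy + (Dy - dyb[i])
            r = math.sqrt(r0sq + sigma * (clock - tb[i]))
            if (px <= xmax + r and px >= xmin - r
                    and py <= ymax + r and py >= ymin - r):
                dxb[w] = dxb[i]
                dyb[w] = dyb[i]
                tb[w] = tb[i]
                w += 1
            else:
                pruned += 1
        n_act = w

        # ---- navigator step
        # sense: windowed scan over puffs sorted by birth displacement
        detected = False
        if n_act > 0:
            lo_val = Dx - (nx - sx) - rmax
            hi_val = Dx - (nx - sx) + rmax
            lo = np.searchsorted(dxb[:n_act], lo_val)
            hi = np.searchsorted(dxb[:n_act], hi_val)
            for i in range(lo, hi):
                px = sx + (Dx - dxb[i])
                py = sy + (Dy - dyb[i])
                s = r0sq + sigma * (clock - tb[i])
                d2 = (px - nx) ** 2 + (py - ny) ** 2
                rdet2 = 2.0 * s * math.log(mp / (2.0 * s * C0))
                if d2 <= rdet2:
                    detected = True
                    break

        # transition
        if detected:
            if mode == WAITING:
                t0 = t - dt  # sensed at the pre-move position
            if mode != DETECTING:
                mode = DETECTING
                t_c = 0.0
                mode_clock = 0.0
            t_c += dt
            mode_clock += dt
        elif mode == DETECTING:
            mode = SURGING
            mode_clock = 0.0
            lam = t_c if strategy_a else lam_const
        elif mode != WAITING:
            mode_clock += dt
            if mode == SURGING:
                if mode_clock > lam:
                    mode = CASTING
                    mode_clock = 0.0
                    cast_k = 0
                    cast_sign = 1.0 if signs[si] < 0.5 else -1.0
                    si += 1
                    if strat == 0:
                        delta1 = alpha * t_c
                    elif strat == 1:
                        delta1 = alpha * t_c
                    else:
                        delta1 = delta1_const
            elif mode == CASTING:
                if mode_clock > delta1:
                    cast_k += 1
                    cast_sign = -cast_sign
                    mode_clock = 0.0
                    if strat == 0:
                        delta1 = alpha * t_c
                    elif strat == 1:
                        delta1 = alpha * growth ** cast_k * t_c
                    else:
                        delta1 = delta1_const
                    if (not strategy_a) and cast_k >= n_half:
                        mode = SWEEPING
                        delta2 = sweep_mult * delta1
                        sweep_sign = 1.0 if signs[si] < 0.5 else -1.0
                        si += 1
            elif mode == SWEEPING:
                if mode_clock > delta2:
                    mode = CASTING
                    mode_clock = 0.0
                    cast_k = 0

        # move
        if mode != WAITING:
            norm = math.hypot(u, v)
            if norm > 0.0:
                wu = u / norm
                wv = v / norm
                if mode == DETECTING or mode == SURGING:
                    hx = -wu
                    hy = -wv
                elif mode == CASTING:
                    hx = -wv * cast_sign
                    hy = wu * cast_sign
                elif mode == SWEEPING:
                    hx = -wv * sweep_sign
                    hy = wu * sweep_sign
            nx += hx * speed * dt
            ny += hy * speed * dt
            if math.hypot(nx - sx, ny - sy) <= success_radius:
                mode = SUCCESS
                t_end = t
                break
            if nx < xmin or nx > xmax or ny < ymin or ny > ymax:
                mode = FAILED
                t_end = t
                break
        t_end = t

    if mode < SUCCESS:
        mode = FAILED

    return mode, t0, t_end, released, pruned, n_act
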