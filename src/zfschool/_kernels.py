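"""Jitted inner loops shared by the simulator, the state integrator and
the surrogate-trajectory generator.

The world-stepping kernel advances all agents synchronously: perception
(occupancy + loom from the previous-step snapshot of everyone else and
the stimulus frame), integrator update, bout decision/execution, in
fixed agent order, with all randomness drawn from one
``numpy.random.Generator``.  The same arithmetic is exposed at the
Python level by :mod:`zfschool.retina`, :mod:`zfschool.policy` and
:mod:`zfschool.state`; an equivalence test ties the two routes together.
"""

from __future__ import annotations

import numpy as np
from numba import njit

DEG = 180.0 / np.pi

# parameter-vector layout (float64); see simulator.SimulationConfig.kernel_params
P_DT = 0          # s per step
P_ARENA_R = 1     # arena radius, cm
P_FISH_LEN = 2    # body length, cm
P_HALF_EXT = 3    # half-extent of a conspecific (fish height parameter), cm
P_BOUT_P = 4      # bout probability per step
P_BOUT_STEPS = 5  # bout duration in steps
P_BOUT_SIZE = 6   # displacement per bout, cm
P_A_BASE = 7      # baseline response slope, 1/deg
P_TAU = 8         # integrator time constant, s
P_RSCALE = 9      # integrator input scale
P_S_REST = 10
P_S_START = 11
P_D = 12
P_S_MIN = 13
P_S_MAX = 14
P_W_HALF = 15     # wall-policy half-max distance, body lengths
P_W_STEEP = 16    # wall-policy steepness, per body length
P_W_IGNORE = 17   # neighbors ignored below this wall distance, body lengths
P_TURN_FRAC = 18  # fraction of turn bouts (vs forward bouts)
P_FWD_SD = 19     # forward-bout angle sd, deg
P_TURN_MEAN = 20  # turn-bout angle mean, deg
P_TURN_SD = 21    # turn-bout angle sd, deg
P_FIELD = 22      # visual field half-span, deg
P_LOOM_RAW = 23   # 0: neighbor_induced, 1: raw
P_SOCIAL = 24     # 1: occupancy-driven turning on
P_INTEG = 25      # 1: integrator evolves; 0: state frozen (static model)
N_PARAMS = 26


@njit(cache=True)
def _wrap(a):
    """Wrap degrees to (-180, 180]."""
    return 180.0 - ((180.0 - a) % 360.0)


@njit(cache=True)
def leaky_trace(s0, inputs, dt, tau, r, s_rest, s_min, s_max, stride):
    """Forward-Euler integration of the loom integrator over an input series.

    Returns the clamped state after every ``stride``-th step.
    """
    n = inputs.shape[0]
    n_rec = n // stride
    out = np.empty(n_rec)
    s = s0
    k = 0
    for t in range(n):
        s = s + (dt / tau) * (s_rest - s + r * inputs[t])
        if s < s_min:
            s = s_min
        elif s > s_max:
            s = s_max
        if (t + 1) % stride == 0 and k < n_rec:
            out[k] = s
            k += 1
    return out


@njit(cache=True)
def run_world(
    x, y, h, s,
    prev_x, prev_y, prev_h,
    bout_left, bout_dx, bout_dy,
    dots, focal_frame, frame0,
    n_steps, step0,
    par, gen, rec_stride,
    rec_x, rec_y, rec_h, rec_s, rec_in, rec_ae, rec_bout,
    bl_agent, bl_onset, bl_turn, bl_docc, bl_wall, bl_ae, bl_s, bl_away, bl_social,
):
    """Advance ``n_steps`` of the world; see module docstring.

    ``dots`` is a (frames, k, 3) array of (x, y, radius); NaN x marks an
    absent dot.  ``focal_frame`` nonzero means dot coordinates are
    egocentric (x forward, y to the left of the heading) and re-anchored
    to the focal agent every step, as in closed-loop VR.  The stimulus
    frame for global step ``g = frame0 + t`` is ``g % frames`` (streams
    loop).  Records are written after every ``rec_stride``-th step; bout
    onsets append to the ``bl_*`` log arrays.  Returns
    ``(n_bouts_logged, n_records_written)``.
    """
    n = x.shape[0]
    n_frames = dots.shape[0]
    n_dots = dots.shape[1]
    R = par[P_ARENA_R]
    dt = par[P_DT]
    half_ext = par[P_HALF_EXT]
    field = par[P_FIELD]
    raw_loom = par[P_LOOM_RAW] > 0.5
    bout_steps = int(par[P_BOUT_STEPS])

    tmpx = np.empty(n)
    tmpy = np.empty(n)
    tmph = np.empty(n)
    cur_in = np.zeros(n)
    cur_ae = np.zeros(n)
    cur_bout = np.zeros(n)

    nb = 0
    nrec = 0
    cap = bl_agent.shape[0]
    n_rec_max = rec_x.shape[0]

    for t in range(n_steps):
        g = frame0 + t
        fidx = g % n_frames
        if g > 0 and n_frames > 1:
            pidx = (g - 1) % n_frames
        else:
            pidx = fidx
        for i in range(n):
            tmpx[i] = x[i]
            tmpy[i] = y[i]
            tmph[i] = h[i]
        for i in range(n):
            xi = tmpx[i]
            yi = tmpy[i]
            hi = tmph[i]
            sumv = 0.0
            sL = 0.0
            sR = 0.0
            loom = 0.0
            # conspecific agents as visual objects (per-object, no occlusion)
            for j in range(n):
                if j == i:
                    continue
                dxo = tmpx[j] - xi
                dyo = tmpy[j] - yi
                d = np.sqrt(dxo * dxo + dyo * dyo)
                if d <= 1e-9:
                    continue
                th = _wrap(np.arctan2(dyo, dxo) * DEG - hi)
                if np.abs(th) > field:
                    continue
                v = 2.0 * np.arctan(half_ext / d) * DEG
                if th > 0.0:
                    sL += v * v
                else:
                    sR += v * v
                sumv += v
                vp = 0.0
                if raw_loom:
                    dpx = prev_x[j] - prev_x[i]
                    dpy = prev_y[j] - prev_y[i]
                    dp = np.sqrt(dpx * dpx + dpy * dpy)
                    if dp > 1e-9:
                        thp = _wrap(np.arctan2(dpy, dpx) * DEG - prev_h[i])
                        if np.abs(thp) <= field:
                            vp = 2.0 * np.arctan(half_ext / dp) * DEG
                else:
                    dpx = prev_x[j] - xi
                    dpy = prev_y[j] - yi
                    dp = np.sqrt(dpx * dpx + dpy * dpy)
                    if dp > 1e-9:
                        vp = 2.0 * np.arctan(half_ext / dp) * DEG
                    else:
                        vp = 180.0
                inc = v - vp
                if inc > loom:
                    loom = inc
            # stimulus dots
            for k in range(n_dots):
                dx0 = dots[fidx, k, 0]
                dy0 = dots[fidx, k, 1]
                r0 = dots[fidx, k, 2]
                if not (np.isfinite(dx0) and r0 > 0.0):
                    continue
                if focal_frame != 0:
                    d = np.sqrt(dx0 * dx0 + dy0 * dy0)
                    th = np.arctan2(dy0, dx0) * DEG
                else:
                    ddx = dx0 - xi
                    ddy = dy0 - yi
                    d = np.sqrt(ddx * ddx + ddy * ddy)
                    th = _wrap(np.arctan2(ddy, ddx) * DEG - hi) if d > 1e-9 else 0.0
                if d <= 1e-9 or np.abs(th) > field:
                    continue
                v = 2.0 * np.arctan(r0 / d) * DEG
                if th > 0.0:
                    sL += v * v
                else:
                    sR += v * v
                sumv += v
                px0 = dots[pidx, k, 0]
                py0 = dots[pidx, k, 1]
                pr0 = dots[pidx, k, 2]
                vp = 0.0
                if np.isfinite(px0) and pr0 > 0.0:
                    if focal_frame != 0:
                        dp = np.sqrt(px0 * px0 + py0 * py0)
                        if dp > 1e-9:
                            vp = 2.0 * np.arctan(pr0 / dp) * DEG
                        else:
                            vp = 180.0
                    elif raw_loom:
                        dpx = px0 - prev_x[i]
                        dpy = py0 - prev_y[i]
                        dp = np.sqrt(dpx * dpx + dpy * dpy)
                        if dp > 1e-9:
                            thp = _wrap(np.arctan2(dpy, dpx) * DEG - prev_h[i])
                            if np.abs(thp) <= field:
                                vp = 2.0 * np.arctan(pr0 / dp) * DEG
                    else:
                        dpx = px0 - xi
                        dpy = py0 - yi
                        dp = np.sqrt(dpx * dpx + dpy * dpy)
                        if dp > 1e-9:
                            vp = 2.0 * np.arctan(pr0 / dp) * DEG
                        else:
                            vp = 180.0
                inc = v - vp
                if inc > loom:
                    loom = inc

            delta = 0.0
            if sumv > 0.0:
                delta = (sL - sR) / sumv

            if par[P_INTEG] > 0.5:
                si = s[i] + (dt / par[P_TAU]) * (
                    par[P_S_REST] - s[i] + par[P_RSCALE] * loom
                )
                if si < par[P_S_MIN]:
                    si = par[P_S_MIN]
                elif si > par[P_S_MAX]:
                    si = par[P_S_MAX]
                s[i] = si
            ae = par[P_A_BASE] * (1.0 - (s[i] - par[P_S_START]) / par[P_D])
            if ae < 0.0:
                ae = 0.0
            cur_in[i] = loom
            cur_ae[i] = ae

            if bout_left[i] <= 0 and gen.random() < par[P_BOUT_P]:
                # bout onset: choose direction and magnitude, rotate heading
                rad = np.sqrt(xi * xi + yi * yi)
                wall_bl = (R - rad) / par[P_FISH_LEN]
                p_wall = 1.0 / (1.0 + np.exp(par[P_W_STEEP] * (wall_bl - par[P_W_HALF])))
                is_wall = gen.random() < p_wall
                social_used = 0
                if is_wall:
                    if rad > 1e-9:
                        phi = _wrap(np.arctan2(yi, xi) * DEG - hi)
                        sign = -1.0 if phi > 0.0 else 1.0
                    else:
                        sign = -1.0 if gen.random() < 0.5 else 1.0
                    mag = np.abs(gen.normal(par[P_TURN_MEAN], par[P_TURN_SD]))
                else:
                    pr = 0.5
                    if par[P_SOCIAL] > 0.5 and wall_bl >= par[P_W_IGNORE] and sumv > 0.0:
                        pr = 0.5 + ae * delta
                        if pr < 0.0:
                            pr = 0.0
                        elif pr > 1.0:
                            pr = 1.0
                        social_used = 1
                    sign = -1.0 if gen.random() < pr else 1.0
                    if gen.random() < par[P_TURN_FRAC]:
                        mag = np.abs(gen.normal(par[P_TURN_MEAN], par[P_TURN_SD]))
                    else:
                        mag = np.abs(gen.normal(0.0, par[P_FWD_SD]))
                dh = sign * mag
                h[i] = _wrap(hi + dh)
                bout_left[i] = bout_steps
                step_d = par[P_BOUT_SIZE] / bout_steps
                bout_dx[i] = step_d * np.cos(h[i] / DEG)
                bout_dy[i] = step_d * np.sin(h[i] / DEG)
                if nb < cap:
                    bl_agent[nb] = i
                    bl_onset[nb] = step0 + t
                    bl_turn[nb] = dh
                    bl_docc[nb] = np.abs(delta)
                    bl_wall[nb] = wall_bl
                    bl_ae[nb] = ae
                    bl_s[nb] = s[i]
                    if delta == 0.0:
                        bl_away[nb] = -1
                    else:
                        bl_away[nb] = 1 if delta * dh < 0.0 else 0
                    bl_social[nb] = 0 if is_wall else (1 + social_used)
                    nb += 1

            if bout_left[i] > 0:
                # advance one displacement sub-step, truncated at the wall
                nx2 = x[i] + bout_dx[i]
                ny2 = y[i] + bout_dy[i]
                if nx2 * nx2 + ny2 * ny2 > R * R:
                    px = x[i]
                    py = y[i]
                    ddx = bout_dx[i]
                    ddy = bout_dy[i]
                    aq = ddx * ddx + ddy * ddy
                    bq = 2.0 * (px * ddx + py * ddy)
                    cq = px * px + py * py - R * R
                    tq = 0.0
                    if aq > 0.0:
                        disc = bq * bq - 4.0 * aq * cq
                        if disc > 0.0:
                            tq = (-bq + np.sqrt(disc)) / (2.0 * aq)
                            if tq < 0.0:
                                tq = 0.0
                            elif tq > 1.0:
                                tq = 1.0
                    x[i] = px + tq * ddx
                    y[i] = py + tq * ddy
                    bout_dx[i] = 0.0
                    bout_dy[i] = 0.0
                else:
                    x[i] = nx2
                    y[i] = ny2
                bout_left[i] -= 1
                cur_bout[i] = 1.0
            else:
                cur_bout[i] = 0.0

        for i in range(n):
            prev_x[i] = tmpx[i]
            prev_y[i] = tmpy[i]
            prev_h[i] = tmph[i]

        if rec_stride > 0 and (t + 1) % rec_stride == 0 and nrec < n_rec_max:
            for i in range(n):
                rec_x[nrec, i] = x[i]
                rec_y[nrec, i] = y[i]
                rec_h[nrec, i] = h[i]
                rec_s[nrec, i] = s[i]
                rec_in[nrec, i] = cur_in[i]
                rec_ae[nrec, i] = cur_ae[i]
                rec_bout[nrec, i] = cur_bout[i]
            nrec += 1

    return nb, nrec
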