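"""Fused daily water-balance kernel (numba).

Semantically identical to composing the operations in
:mod:`savhyd.hydrology` (`step_day`) for a flat landscape; the runner uses
it for speed and a regression test pins its equivalence to the modular
numpy path.  Non-flat terrain falls back to the numpy implementation, which
includes lateral routing.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def multi_day_flat(
    sw, theta_u, theta_l, cover,
    uptake_rate, wilting_point, rf_u, rf_l,
    du, dl,
    porosity, field_capacity, residual, ksat, evap_const, diffusion,
    c0, shading,
    precip_seg, pet_seg,
    bw_transp, accumulate_bw,
    stress_days, accumulate_stress,
    scratch_u, scratch_l,
    stress_margin=0.0,
):
    """Run ``day_step_flat`` over a segment of days with constant flags.

    Returns segment totals (t_up, t_low, evap) and the sum over days of the
    grid-mean upper moisture (callers divide by segment length).
    """
    t_up = 0.0
    t_low = 0.0
    ev = 0.0
    theta_mean_sum = 0.0
    for d in range(precip_seg.shape[0]):
        a, b, c, m = day_step_flat(
            sw, theta_u, theta_l, cover,
            uptake_rate, wilting_point, rf_u, rf_l,
            du, dl,
            porosity, field_capacity, residual, ksat, evap_const, diffusion,
            c0, shading,
            precip_seg[d], pet_seg[d],
            bw_transp, accumulate_bw,
            stress_days, accumulate_stress,
            scratch_u, scratch_l,
            stress_margin,
        )
        t_up += a
        t_low += b
        ev += c
        theta_mean_sum += m
    return t_up, t_low, ev, theta_mean_sum


@njit(cache=True)
def day_step_flat(
    sw,            # (n,) surface water, mm -- updated in place
    theta_u,       # (n,) upper-layer moisture -- updated in place
    theta_l,       # (n,) lower-layer moisture -- updated in place
    cover,         # (n, T) cover fractions
    uptake_rate,   # (T,)
    wilting_point, # (T,)
    rf_u,          # (T,)
    rf_l,          # (T,)
    du, dl,        # layer depths, mm
    porosity, field_capacity, residual, ksat, evap_const, diffusion,
    c0, shading,
    precip, pet_today,
    bw_transp,     # (n, T) biweekly transpiration accumulator (in place)
    accumulate_bw, # bool
    stress_days,   # (n, T) growing-season stress-day accumulator (in place)
    accumulate_stress,  # bool
    scratch_u,     # (T,) work array
    scratch_l,     # (T,) work array
    stress_margin=0.0,  # stress accrues below wilting_point + margin
):
    """Advance all cells one day; returns (t_up_sum, t_low_sum, evap_sum,
    mean_theta_u) with sums taken over the whole grid (mm)."""
    n, T = cover.shape
    wilt_floor = wilting_point[0]
    for t in range(1, T):
        if wilting_point[t] < wilt_floor:
            wilt_floor = wilting_point[t]
    inv_res = 1.0 / (field_capacity - residual)

    t_up_sum = 0.0
    t_low_sum = 0.0
    evap_sum = 0.0
    theta_sum = 0.0

    for i in range(n):
        tot_cov = 0.0
        for t in range(T):
            tot_cov += cover[i, t]

        s = sw[i] + precip
        thu = theta_u[i]
        thl = theta_l[i]

        if s > 0.0:
            # infiltration
            cap = (porosity - thu) * du
            if cap < 0.0:
                cap = 0.0
            keff = ksat * (c0 + (1.0 - c0) * tot_cov)
            inf = s
            if cap < inf:
                inf = cap
            if keff < inf:
                inf = keff
            s -= inf
            thu += inf / du

        # percolation: upper excess over field capacity -> lower
        if thu > field_capacity:
            perc = (thu - field_capacity) * du
            if perc > ksat:
                perc = ksat
            room = (porosity - thl) * dl
            if room < 0.0:
                room = 0.0
            if perc > room:
                perc = room
            thu -= perc / du
            thl += perc / dl

        # deep drainage: lower excess over field capacity leaves
        if thl > field_capacity:
            deep = (thl - field_capacity) * dl
            if deep > ksat:
                deep = ksat
            thl -= deep / dl

        # slow upper -> lower diffusion
        if thu > thl and diffusion > 0.0:
            dif = diffusion
            avail = (thu - residual) * du
            if avail < 0.0:
                avail = 0.0
            if dif > avail:
                dif = avail
            room2 = (porosity - thl) * dl
            if dif > room2:
                dif = room2
            thu -= dif / du
            thl += dif / dl

        # bare-soil evaporation (upper layer)
        wet = (thu - residual) * inv_res
        if wet < 0.0:
            wet = 0.0
        elif wet > 1.0:
            wet = 1.0
        shade = 1.0 - shading * tot_cov
        if shade < 0.0:
            shade = 0.0
        ev = pet_today * evap_const * wet * shade
        eavail = (thu - residual) * du
        if eavail < 0.0:
            eavail = 0.0
        if ev > eavail:
            ev = eavail
        thu -= ev / du
        evap_sum += ev

        # transpiration, proportionally rationed per layer
        dem_u = 0.0
        dem_l = 0.0
        for t in range(T):
            c = cover[i, t]
            if c <= 0.0:
                scratch_u[t] = 0.0
                scratch_l[t] = 0.0
                continue
            wp = wilting_point[t]
            inv = 1.0 / (field_capacity - wp)
            gu = (thu - wp) * inv
            if gu < 0.0:
                gu = 0.0
            elif gu > 1.0:
                gu = 1.0
            gl = (thl - wp) * inv
            if gl < 0.0:
                gl = 0.0
            elif gl > 1.0:
                gl = 1.0
            base = pet_today * c * uptake_rate[t]
            tu = base * rf_u[t] * gu
            tl = base * rf_l[t] * gl
            scratch_u[t] = tu
            scratch_l[t] = tl
            dem_u += tu
            dem_l += tl

        scale_u = 1.0
        if dem_u > 0.0:
            avail_u = (thu - wilt_floor) * du
            if avail_u < 0.0:
                avail_u = 0.0
            if dem_u > avail_u:
                scale_u = avail_u / dem_u
        scale_l = 1.0
        if dem_l > 0.0:
            avail_l = (thl - wilt_floor) * dl
            if avail_l < 0.0:
                avail_l = 0.0
            if dem_l > avail_l:
                scale_l = avail_l / dem_l

        t_up_sum += dem_u * scale_u
        t_low_sum += dem_l * scale_l
        thu -= dem_u * scale_u / du
        thl -= dem_l * scale_l / dl

        if accumulate_bw:
            for t in range(T):
                bw_transp[i, t] += scratch_u[t] * scale_u + scratch_l[t] * scale_l

        if accumulate_stress:
            for t in range(T):
                theta_eff = rf_u[t] * thu + rf_l[t] * thl
                if theta_eff < wilting_point[t] + stress_margin:
                    stress_days[i, t] += 1.0

        sw[i] = s
        theta_u[i] = thu
        theta_l[i] = thl
        theta_sum += thu

    return t_up_sum, t_low_sum, evap_sum, theta_sum / n
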