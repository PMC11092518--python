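"""Numba step-loop kernel for the simulation engine.

The engine flattens populations and synapse groups into plain arrays and
hands the whole time loop to ``run_steps``, which is resumable: it
returns when the requested step range is done or the event buffer is
nearly full, so the Python side can drain events and continue.  The
numerical scheme is identical to the module-level operations
(``izh_step``, ``tm_on_spike``, exact exponential decays); those remain
the reference implementation and the test oracle for this kernel.

Population drive roles are fixed by index: 0 = stellate (noise + settle
pulse), 1 = conjunctive (velocity-tuned), 2 = CA1 (place fields); any
further populations are interneurons driven only synaptically.
"""

from __future__ import annotations

import numpy as np
from numba import njit
from numba.typed import List

__all__ = ["run_steps", "seed_rng", "typed_list"]


def typed_list(arrays):
    out = List()
    for a in arrays:
        out.append(a)
    return out


@njit(cache=True)
def seed_rng(seed):
    np.random.seed(seed)


@njit(cache=True)
def run_steps(
    start_step,
    n_total,
    n_settle,
    dt,
    steps_per_ms,
    delay_steps,
    # populations (typed lists over pop index)
    v_list,
    u_list,
    pop_params,  # (P, 9): C,k,Vr,Vt,a,b,Vpeak,Vreset,d
    # groups (typed lists over group index)
    g_pre,
    g_post,
    g_w,
    g_indptr,
    g_u,
    g_x,
    g_sfast,
    g_sslow,
    g_buf_fast,  # each (delay_steps+1, n_post)
    g_buf_slow,
    g_decay,  # (G, 4): du, dx, dfast, dslow
    g_gfast,  # gain-scaled conductance gains
    g_gslow,
    g_U,
    g_inhib,  # (G,) uint8
    g_src,  # (G,) source population index
    g_tgt,
    # drive tables
    dir_code,  # (n_conj,) 0..3 direction class of each conjunctive cell
    dir_angle,  # (4,)
    conj_het,  # (n_conj,) per-cell drive heterogeneity factor
    speed_run,
    heading_run,
    pos_run,  # (n_run, 2)
    place_centers,  # (n_ca1, 2)
    place_cache,  # (n_ca1,) workspace
    sigma_place,
    A_place,
    I0,
    alpha,
    noise_sigma,
    pulse_pA,
    pulse_steps,
    start_x,
    start_y,
    place_update_steps,
    # receptor constants
    E_fx,
    E_sx,
    E_fi,
    E_si,
    # event output
    ev_pop,
    ev_idx,
    ev_t,
    n_events_in,
    # probes
    probe_pop,
    probe_idx,
    probe_v,  # (n_probes, n_ms)
    probe_s,  # (n_probes, G, 2, n_ms) conductances of groups onto the probe
    probe_is_target,  # (n_probes, G) uint8
):
    P = len(v_list)
    G = len(g_pre)
    n_events = n_events_in
    cap = ev_pop.size
    max_per_step = 0
    for p in range(P):
        max_per_step += v_list[p].size

    spiked_buf = []
    I_work = []
    for p in range(P):
        spiked_buf.append(np.empty(v_list[p].size, dtype=np.int64))
        I_work.append(np.zeros(v_list[p].size))

    step = start_step
    while step < n_total:
        if n_events + max_per_step > cap:
            break
        in_settle = step < n_settle
        k = step - n_settle

        # 1) decay
        for g in range(G):
            du = g_decay[g, 0]
            dx = g_decay[g, 1]
            df = g_decay[g, 2]
            ds = g_decay[g, 3]
            ug = g_u[g]
            xg = g_x[g]
            for i in range(ug.size):
                ug[i] *= du
                xg[i] = 1.0 - (1.0 - xg[i]) * dx
            sf = g_sfast[g]
            ss = g_sslow[g]
            for i in range(sf.size):
                sf[i] *= df
                ss[i] *= ds

        # 2) deliver delayed increments
        slot = step % (delay_steps + 1)
        for g in range(G):
            bf = g_buf_fast[g]
            bs = g_buf_slow[g]
            sf = g_sfast[g]
            ss = g_sslow[g]
            for i in range(sf.size):
                sf[i] += bf[slot, i]
                ss[i] += bs[slot, i]
                bf[slot, i] = 0.0
                bs[slot, i] = 0.0

        # 3) drive terms for this step
        if in_settle:
            speed = 0.0
            heading = 0.0
            px = start_x
            py = start_y
        else:
            speed = speed_run[k]
            heading = heading_run[k]
            px = pos_run[k, 0]
            py = pos_run[k, 1]
        fac0 = I0 + alpha * speed * 0.5 * (1.0 + np.cos(heading - dir_angle[0]))
        fac1 = I0 + alpha * speed * 0.5 * (1.0 + np.cos(heading - dir_angle[1]))
        fac2 = I0 + alpha * speed * 0.5 * (1.0 + np.cos(heading - dir_angle[2]))
        fac3 = I0 + alpha * speed * 0.5 * (1.0 + np.cos(heading - dir_angle[3]))
        if step % place_update_steps == 0 or step == start_step:
            inv2s2 = 1.0 / (2.0 * sigma_place * sigma_place)
            for j in range(place_centers.shape[0]):
                ddx = place_centers[j, 0] - px
                ddy = place_centers[j, 1] - py
                place_cache[j] = A_place * np.exp(-(ddx * ddx + ddy * ddy) * inv2s2)

        # 4a) external drive into per-population work arrays
        for p in range(P):
            I = I_work[p]
            if p == 0:
                if noise_sigma > 0.0:
                    for i in range(I.size):
                        I[i] = noise_sigma * np.random.normal()
                else:
                    for i in range(I.size):
                        I[i] = 0.0
                if in_settle and step < pulse_steps:
                    for i in range(I.size):
                        I[i] += pulse_pA
            elif p == 1:
                for i in range(I.size):
                    c = dir_code[i]
                    if c == 0:
                        I[i] = fac0
                    elif c == 1:
                        I[i] = fac1
                    elif c == 2:
                        I[i] = fac2
                    else:
                        I[i] = fac3
                    I[i] *= conj_het[i]
                    if noise_sigma > 0.0:
                        I[i] += noise_sigma * np.random.normal()
            elif p == 2:
                for i in range(I.size):
                    I[i] = place_cache[i]
            else:
                for i in range(I.size):
                    I[i] = 0.0

        # 4b) synaptic currents, accumulated group-major
        for g in range(G):
            p = g_tgt[g]
            I = I_work[p]
            v = v_list[p]
            sf = g_sfast[g]
            ss = g_sslow[g]
            if g_inhib[g] == 1:
                for i in range(I.size):
                    vi = v[i]
                    I[i] += sf[i] * (E_fi - vi) + ss[i] * (E_si - vi)
            else:
                for i in range(I.size):
                    vi = v[i]
                    z = (vi + 80.0) / 60.0
                    mg = z * z / (1.0 + z * z)
                    I[i] += sf[i] * (E_fx - vi) + ss[i] * (E_sx - vi) * mg

        # 4c) izhikevich update per population
        tgt_slot = (step + delay_steps) % (delay_steps + 1)
        for p in range(P):
            v = v_list[p]
            u = u_list[p]
            I_arr = I_work[p]
            n = v.size
            C = pop_params[p, 0]
            kk = pop_params[p, 1]
            Vr = pop_params[p, 2]
            Vt = pop_params[p, 3]
            a = pop_params[p, 4]
            b = pop_params[p, 5]
            Vpeak = pop_params[p, 6]
            Vreset = pop_params[p, 7]
            d = pop_params[p, 8]
            half = 0.5 * dt / C
            n_spk = 0
            for i in range(n):
                I = I_arr[i]
                vi = v[i]
                ui = u[i]
                if vi >= Vpeak:
                    # entry already at cutoff: immediate reset, no integration
                    v[i] = Vreset
                    u[i] = ui + d
                    spiked_buf[p][n_spk] = i
                    n_spk += 1
                    continue
                # two half-steps for v, one for u
                for _ in range(2):
                    dv = kk * (vi - Vr) * (vi - Vt) - ui + I
                    vi += half * dv
                    if vi > Vpeak:
                        vi = Vpeak
                    elif vi < -100.0:
                        vi = -100.0
                ui += dt * a * (b * (vi - Vr) - ui)
                if vi >= Vpeak:
                    vi = Vreset
                    ui += d
                    spiked_buf[p][n_spk] = i
                    n_spk += 1
                v[i] = vi
                u[i] = ui

            # 5) synaptic release for this population's spikes
            if n_spk > 0:
                for g in range(G):
                    if g_src[g] != p:
                        continue
                    U = g_U[g]
                    gf = g_gfast[g]
                    gs = g_gslow[g]
                    bf = g_buf_fast[g]
                    bs = g_buf_slow[g]
                    indptr = g_indptr[g]
                    posts = g_post[g]
                    ws = g_w[g]
                    ug = g_u[g]
                    xg = g_x[g]
                    for si in range(n_spk):
                        pre = spiked_buf[p][si]
                        uu = ug[pre] + U * (1.0 - ug[pre])
                        rel = uu * xg[pre]
                        ug[pre] = uu
                        xg[pre] -= rel
                        for e in range(indptr[pre], indptr[pre + 1]):
                            amt = rel * ws[e]
                            bf[tgt_slot, posts[e]] += gf * amt
                            bs[tgt_slot, posts[e]] += gs * amt
                # 6) record events (playback only)
                if not in_settle:
                    t_ms = k * dt
                    for si in range(n_spk):
                        ev_pop[n_events] = p
                        ev_idx[n_events] = spiked_buf[p][si]
                        ev_t[n_events] = t_ms
                        n_events += 1

        # 7) probes at 1-ms resolution
        if probe_pop.size > 0 and step % steps_per_ms == 0:
            ms = step // steps_per_ms
            for q in range(probe_pop.size):
                p = probe_pop[q]
                i = probe_idx[q]
                probe_v[q, ms] = v_list[p][i]
                for g in range(G):
                    if probe_is_target[q, g] == 1:
                        probe_s[q, g, 0, ms] = g_sfast[g][i]
                        probe_s[q, g, 1, ms] = g_sslow[g][i]
        step += 1

    return step, n_events
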