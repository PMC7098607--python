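"""Numba-compiled Gillespie kernel.

The exact event loop for a single cell.  Because all clocks are exponential,
propensities depend on the cell state only through the gene Boolean and the
counts of nascent, RNase-eligible and degrading molecules; channel selection
therefore draws a category first and then a uniformly chosen molecule within
it.  The Gillespie clock is restarted at each piecewise-constant change of
the scheduled activation rate, which is statistically exact for step
protocols.

The kernel mutates nothing outside its own buffers and draws randomness only
from the Generator handed in, so per-cell reproducibility is controlled
entirely by the caller's seeding scheme.
"""

import numpy as np
from numba import njit

STATUS_OK = 0
STATUS_EVENT_BUDGET = 1  # trial exceeded the per-cell event budget


@njit(cache=True, nogil=True)
def run_cell(
    g,                 # np.random.Generator
    t0,                # start time (min); negative for burn-in segments
    sched_t,           # schedule boundary times, sched_t[0] == t0
    sched_kon,         # activation rate on each schedule segment (1/min)
    k_off, k_ini, k_deg, r_step,  # rates (1/min)
    N,                 # elongation steps per transcript
    probe_prefix,      # int64[N+1] prefix sums of probe-covered steps
    sample_times,      # strictly increasing observation times >= t0
    gene_on0,          # initial gene state
    five0, three0, nasc0, degr0,  # initial molecule arrays (may be empty)
    max_events,        # event budget; exceeded -> STATUS_EVENT_BUDGET
    out_sig,           # float64[n_samples, 2]: nascent, mature signal
    out_cnt,           # int64[n_samples, 3]: n_molecules, n_degrading, n_nascent
):
    n = five0.size
    cap = 256
    while cap < 2 * n + 8:
        cap *= 2
    five = np.empty(cap, np.int64)
    three = np.empty(cap, np.int64)
    nasc = np.empty(cap, np.bool_)
    degr = np.empty(cap, np.bool_)
    five[:n] = five0
    three[:n] = three0
    nasc[:n] = nasc0
    degr[:n] = degr0

    n_nasc = 0
    n_degr = 0
    for i in range(n):
        if nasc[i]:
            n_nasc += 1
        if degr[i]:
            n_degr += 1

    gene_on = gene_on0
    probe_total = float(probe_prefix[N])
    t = t0
    n_seg = sched_t.size
    seg = 0
    while seg + 1 < n_seg and sched_t[seg + 1] <= t:
        seg += 1
    si = 0
    n_samp = sample_times.size
    events = 0

    while si < n_samp:
        kon_cur = sched_kon[seg]
        a_on = 0.0 if gene_on else kon_cur
        a_off = k_off if gene_on else 0.0
        a_ini = k_ini if gene_on else 0.0
        a_el = r_step * n_nasc
        a_bind = k_deg * (n - n_degr)
        a_deg = r_step * n_degr
        a0 = a_on + a_off + a_ini + a_el + a_bind + a_deg

        if a0 > 0.0:
            t_next = t - np.log(1.0 - g.random()) / a0
        else:
            t_next = np.inf
        boundary = sched_t[seg + 1] if seg + 1 < n_seg else np.inf
        t_stop = min(t_next, boundary)

        # record every sample time passed before the next event / boundary
        while si < n_samp and sample_times[si] <= t_stop:
            s_n = 0.0
            s_m = 0.0
            for i in range(n):
                s = (probe_prefix[three[i]] - probe_prefix[five[i] - 1]) / probe_total
                if nasc[i]:
                    s_n += s
                else:
                    s_m += s
            out_sig[si, 0] = s_n
            out_sig[si, 1] = s_m
            out_cnt[si, 0] = n
            out_cnt[si, 1] = n_degr
            out_cnt[si, 2] = n_nasc
            si += 1
        if si >= n_samp:
            break

        if boundary <= t_next:
            # schedule step: restart the clock under the new k_on
            t = boundary
            seg += 1
            continue

        t = t_next
        events += 1
        if events > max_events:
            return (STATUS_EVENT_BUDGET, gene_on,
                    five[:n].copy(), three[:n].copy(),
                    nasc[:n].copy(), degr[:n].copy())

        u = g.random() * a0
        if u < a_on:
            gene_on = True
        elif u < a_on + a_off:
            gene_on = False
        elif u < a_on + a_off + a_ini:
            if n == cap:
                cap *= 2
                nf = np.empty(cap, np.int64)
                nt = np.empty(cap, np.int64)
                nn = np.empty(cap, np.bool_)
                nd = np.empty(cap, np.bool_)
                nf[:n] = five[:n]
                nt[:n] = three[:n]
                nn[:n] = nasc[:n]
                nd[:n] = degr[:n]
                five, three, nasc, degr = nf, nt, nn, nd
            five[n] = 1
            three[n] = 1
            nasc[n] = True
            degr[n] = False
            n += 1
            n_nasc += 1
        elif u < a_on + a_off + a_ini + a_el:
            # k-th nascent molecule elongates (or is released at the end)
            k = int(g.random() * n_nasc)
            if k == n_nasc:
                k = n_nasc - 1
            idx = -1
            c = -1
            for i in range(n):
                if nasc[i]:
                    c += 1
                    if c == k:
                        idx = i
                        break
            if three[idx] < N:
                three[idx] += 1
            else:
                nasc[idx] = False  # release: polymerase leaves the locus
                n_nasc -= 1
        elif u < a_on + a_off + a_ini + a_el + a_bind:
            # RNase binds the k-th eligible (unbound) molecule
            k = int(g.random() * (n - n_degr))
            if k == n - n_degr:
                k = n - n_degr - 1
            idx = -1
            c = -1
            for i in range(n):
                if not degr[i]:
                    c += 1
                    if c == k:
                        idx = i
                        break
            degr[idx] = True
            n_degr += 1
        else:
            # degradation step on the k-th RNase-bound molecule
            k = int(g.random() * n_degr)
            if k == n_degr:
                k = n_degr - 1
            idx = -1
            c = -1
            for i in range(n):
                if degr[i]:
                    c += 1
                    if c == k:
                        idx = i
                        break
            if five[idx] < three[idx]:
                five[idx] += 1
            else:
                # last intact step consumed: remove the molecule entirely
                if nasc[idx]:
                    n_nasc -= 1
                n_degr -= 1
                n -= 1
                five[idx] = five[n]
                three[idx] = three[n]
                nasc[idx] = nasc[n]
                degr[idx] = degr[n]

    return (STATUS_OK, gene_on,
            five[:n].copy(), three[:n].copy(),
            nasc[:n].copy(), degr[:n].copy())
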