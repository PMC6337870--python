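"""JIT-compiled event loop of the lattice diffusion-collision simulator.

The loop exploits the structure of the propensity vector: every ternary
complex shares one travel propensity and one dissociation rate, so the
Gillespie direct-method channel choice factorises into (travel vs
dissociation) followed by a uniform complex choice — mathematically
identical to scanning the full cumulative propensity vector, but O(1)
per event.
"""

from __future__ import annotations

import numba
import numpy as np


@numba.njit(cache=True, fastmath=True)
def build_neighbors(n_side):
    """Neighbor table for a periodic cubic lattice, 6 directions per site."""
    n_sites = n_side * n_side * n_side
    nbr = np.empty((n_sites, 6), dtype=np.int32)
    for x in range(n_side):
        for y in range(n_side):
            for z in range(n_side):
                i = (x * n_side + y) * n_side + z
                xm = (x - 1) % n_side
                xp = (x + 1) % n_side
                ym = (y - 1) % n_side
                yp = (y + 1) % n_side
                zm = (z - 1) % n_side
                zp = (z + 1) % n_side
                nbr[i, 0] = (xm * n_side + y) * n_side + z
                nbr[i, 1] = (xp * n_side + y) * n_side + z
                nbr[i, 2] = (x * n_side + ym) * n_side + z
                nbr[i, 3] = (x * n_side + yp) * n_side + z
                nbr[i, 4] = (x * n_side + y) * n_side + zm
                nbr[i, 5] = (x * n_side + y) * n_side + zp
    return nbr


@numba.njit(cache=True, fastmath=True)
def _rebind(k, s, comp_sp, comp_pos, free_counts, free_total, n_sites, formation_t, t):
    """Release tRNA s to the pool; EFTu re-binds a uniformly chosen free
    tRNA molecule and the new complex is relocated to a random site.

    Adding the released molecule before drawing handles the empty-pool
    case (all tRNA complexed) uniformly: the released tRNA then re-binds
    immediately.
    """
    free_counts[s] += 1
    m = np.random.randint(0, free_total + 1)
    s2 = 0
    acc = free_counts[0]
    while acc <= m:
        s2 += 1
        acc += free_counts[s2]
    free_counts[s2] -= 1
    comp_sp[k] = s2
    comp_pos[k] = np.random.randint(0, n_sites)
    formation_t[k] = t


@numba.njit(cache=True, fastmath=True)
def run_kernel(
    seed,
    nbr,
    comp_pos,
    comp_sp,
    free_counts,
    site_rib_ptr,
    site_rib,
    rib_codon,
    rib_idle,
    seq_sp,
    jump_prop,
    k_diss,
    t_cat,
    t0,
    stop_steps,
    max_events,
    t_end,
    out_times,
    diss_lifetimes,
):
    """Run the SSA until ``stop_steps`` elongations, ``max_events`` SSA
    events, or time ``t_end``, whichever comes first.

    Returns (n_elong, n_events, t_final, n_diss_logged).  ``out_times``
    receives the absolute time of each successful elongation;
    ``diss_lifetimes`` (may be length 0) receives the lifetimes of the
    initial complex cohort at their first dissociation (an uncensored
    exponential sample provided the run outlives ~10/k_diss).
    """
    np.random.seed(seed)
    n_sites = nbr.shape[0]
    n_comp = comp_pos.shape[0]
    L = seq_sp.shape[0]
    free_total = 0
    for i in range(free_counts.shape[0]):
        free_total += free_counts[i]

    alpha0 = n_comp * (jump_prop + k_diss)
    inv_alpha0 = 1.0 / alpha0
    p_jump = jump_prop / (jump_prop + k_diss)
    t = t0
    n_elong = 0
    n_events = 0
    n_diss = 0
    log_cap = diss_lifetimes.shape[0]
    formation_t = np.full(n_comp, t0)
    n_comp6 = 6 * n_comp

    while n_elong < stop_steps and n_events < max_events and t < t_end:
        n_events += 1
        t += np.random.exponential() * inv_alpha0
        # one uniform selects the channel family AND (complex, direction):
        # conditional on v < p_jump, v/p_jump is again uniform(0,1)
        v = np.random.random()
        if v < p_jump:
            j = int(v / p_jump * n_comp6)
            if j >= n_comp6:
                j = n_comp6 - 1
            k = j // 6
            pos = nbr[comp_pos[k], j - 6 * k]
            comp_pos[k] = pos
            lo = site_rib_ptr[pos]
            hi = site_rib_ptr[pos + 1]
            if hi > lo:
                s = comp_sp[k]
                n_elig = 0
                chosen = -1
                for idx in range(lo, hi):
                    r = site_rib[idx]
                    if rib_idle[r] <= t and seq_sp[rib_codon[r]] == s:
                        # reservoir choice: uniform among eligible ribosomes
                        n_elig += 1
                        if n_elig == 1 or np.random.random() * n_elig < 1.0:
                            chosen = r
                if chosen >= 0:
                    out_times[n_elong] = t
                    n_elong += 1
                    c = rib_codon[chosen] + 1
                    rib_codon[chosen] = 0 if c == L else c
                    rib_idle[chosen] = t + t_cat
                    _rebind(k, s, comp_sp, comp_pos, free_counts, free_total,
                            n_sites, formation_t, t)
        else:
            k = int((v - p_jump) / (1.0 - p_jump) * n_comp)
            if k >= n_comp:
                k = n_comp - 1
            # log only first dissociations of the initial cohort: these are
            # uncensored Exp(k_diss) samples when t_end >> 1/k_diss
            if n_diss < log_cap and formation_t[k] == t0:
                diss_lifetimes[n_diss] = t - formation_t[k]
                n_diss += 1
            _rebind(k, comp_sp[k], comp_sp, comp_pos, free_counts, free_total,
                    n_sites, formation_t, t)
    return n_elong, n_events, t, n_diss
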