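"""Numba kernel: Newton continuation of Green-function poles along K.

Poles of G(K;p) with Im >= 0 (complex-conjugate pairs are represented by
their upper member) are carried from node to node on a fine K grid.  At
each node every pole is re-polished by Newton iteration on the reciprocal
continued fraction T(p) = 1/G(K;p) evaluated by backward recurrence;
residues are 1/T'(p).  Seeds get a small +i perturbation so that a pair
of real poles merging into a complex pair is picked up (both seeds then
converge to the upper member and are deduplicated).
"""

import numpy as np
from numba import njit

MAXP = 64


@njit(cache=True)
def _newton(K, p, l_max, max_iter):
    """Newton-polish one pole of G(K;p); returns (p, residue, ok)."""
    Ksq = K * K
    for _ in range(max_iter):
        t = p + l_max * (l_max + 1.0)
        dt = 1.0 + 0.0j
        for l in range(l_max, 0, -1):
            c = (l * l / (4.0 * l * l - 1.0)) * Ksq
            dt = 1.0 - c * dt / (t * t)
            t = (p + (l - 1.0) * l) + c / t
        if t == 0.0:
            return p, 1.0 / dt, True
        step = t / dt
        p = p - step
        if abs(step) <= 1e-13 * (1.0 + abs(p)):
            # one final derivative evaluation at the converged point
            t = p + l_max * (l_max + 1.0)
            dt = 1.0 + 0.0j
            for l in range(l_max, 0, -1):
                c = (l * l / (4.0 * l * l - 1.0)) * Ksq
                dt = 1.0 - c * dt / (t * t)
                t = (p + (l - 1.0) * l) + c / t
            return p, 1.0 / dt, True
    return p, 0.0j, False


ACT_THRESH = 1e-5


@njit(cache=True)
def march_block(K_vals, p_act, r_act, slope, n_arr, N, cut_re, f_out, g_out):
    """March the active pole set across K_vals; fill f(K) = K G(K;N).

    p_act/r_act/slope (length MAXP) and n_arr[0] are the running state,
    updated in place.  Poles with |residue| below ACT_THRESH are dormant:
    their zero of the reciprocal fraction nearly cancels against an
    adjacent pole of it, leaving a Newton basin smaller than any usable
    seed, so they are advanced by extrapolation only (their weight is
    negligible; periodic dense-eigendecomposition anchors resync them).
    Returns -1 on success or the index of the first node where Newton
    failed (caller reseeds densely).  g_out receives the leading-branch
    term K res e^{pN} for the analytic tail model.
    """
    n = n_arr[0]
    for i in range(K_vals.shape[0]):
        K = K_vals[i]
        l_max = 90 + int(0.55 * K)
        for j in range(n):
            if abs(r_act[j]) < ACT_THRESH:
                p_act[j] = p_act[j] + slope[j]
                continue
            seed = p_act[j] + slope[j]
            # the +i nudge lets a merging real pair be picked up as a
            # conjugate pair; only strong nearly-real poles merge
            if abs(r_act[j]) > 1e-2 and abs(p_act[j].imag) < 1e-3 * (1.0 + abs(p_act[j])):
                seed = seed + 1e-7j * (1.0 + abs(p_act[j]))
            p_new, res, ok = _newton(K, seed, l_max, 30)
            if not ok:
                n_arr[0] = n
                return i
            if p_new.imag < 0.0:
                p_new = np.conj(p_new)
                res = np.conj(res)
            slope[j] = p_new - p_act[j]
            p_act[j] = p_new
            r_act[j] = res
        # deduplicate merged pairs, drop decayed poles; dormant duplicates
        # are silently dropped, active real-axis duplicates signal a
        # basin-jump (caller reseeds densely)
        k = 0
        for j in range(n):
            dup = False
            fail_here = False
            for j2 in range(k):
                if abs(p_act[j] - p_act[j2]) < 1e-8 * (1.0 + abs(p_act[j])):
                    act_j = abs(r_act[j]) >= ACT_THRESH
                    act_j2 = abs(r_act[j2]) >= ACT_THRESH
                    if act_j and act_j2 and p_act[j].imag < 1e-4 * (1.0 + abs(p_act[j])):
                        fail_here = True
                    elif act_j and not act_j2:
                        # keep the freshly polished value over the stale one
                        p_act[j2] = p_act[j]
                        r_act[j2] = r_act[j]
                        slope[j2] = slope[j]
                    dup = True
                    break
            if fail_here:
                n_arr[0] = n
                return i
            if dup or p_act[j].real < -cut_re:
                continue
            p_act[k] = p_act[j]
            r_act[k] = r_act[j]
            slope[k] = slope[j]
            k += 1
        n = k
        # assemble G(K;N): real poles once, complex pairs twice (2 Re)
        G = 0.0
        lead = 0.0j
        lead_re = -1e300
        for j in range(n):
            term = r_act[j] * np.exp(p_act[j] * N)
            if p_act[j].imag > 1e-7 * (1.0 + abs(p_act[j])):
                G += 2.0 * term.real
                if p_act[j].real > lead_re:
                    lead_re = p_act[j].real
                    lead = K * term
            else:
                G += term.real
        f_out[i] = K * G
        g_out[i] = lead
    n_arr[0] = n
    return -1
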