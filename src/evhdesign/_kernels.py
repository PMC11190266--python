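"""Numba inner loops for the Gibbs and tempering samplers.

The kernels consume pre-generated random streams (member, position and
uniform arrays) so that runs are reproducible from a seed and so that
the pure-Python reference implementations in :mod:`evhdesign.design`
can replay the exact same trajectory for verification.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False)
def run_batch_gibbs(
    S, h, J, n_states, target, msa,
    lam_t, d_min, d_max, lam_d, d_div, lam_a, d_aln,
    betas, members, positions, unifs, counts,
):
    """Annealed batch Gibbs sampling on the penalized batch energy.

    S (M, L) is updated in place. ``betas`` has one inverse temperature
    per sweep; ``members``/``positions``/``unifs`` have one entry per
    single-site update (n_sweeps * M * L in total). If ``counts`` is
    non-empty (only sensible for M == 1 and small n_states**L), the
    visited-state histogram is accumulated after every update.

    Returns the per-sweep total batch energy trace.
    """
    M, L = S.shape
    N = msa.shape[0]
    n_sweeps = betas.shape[0]
    per_sweep = M * L
    do_count = counts.shape[0] > 0

    # incremental mismatch counters
    ct = np.zeros(M, dtype=np.int64)            # to target
    cb = np.zeros((M, M), dtype=np.int64)       # within batch
    ca = np.zeros((M, N), dtype=np.int64)       # to alignment rows
    for a in range(M):
        for i in range(L):
            if S[a, i] != target[i]:
                ct[a] += 1
        for b in range(M):
            if b != a:
                for i in range(L):
                    if S[a, i] != S[b, i]:
                        cb[a, b] += 1
        for n in range(N):
            for i in range(L):
                if S[a, i] != msa[n, i]:
                    ca[a, n] += 1

    # encoded state index for the M == 1 counting mode
    state_idx = 0
    pow_q = np.empty(L, dtype=np.int64)
    if do_count:
        p = 1
        for i in range(L - 1, -1, -1):
            pow_q[i] = p
            p *= n_states
        for i in range(L):
            state_idx += S[0, i] * pow_q[i]

    U_cand = np.empty(n_states, dtype=np.float64)
    trace = np.empty(n_sweeps, dtype=np.float64)

    t = 0
    for sweep in range(n_sweeps):
        beta = betas[sweep]
        for _ in range(per_sweep):
            a = members[t]
            i = positions[t]
            cur = S[a, i]
            for x in range(n_states):
                # negative EVH contribution of candidate x at (a, i)
                e = h[i, x]
                for j in range(L):
                    if j != i:
                        e += J[i, j, x, S[a, j]]
                u = -e
                if lam_t > 0.0:
                    c = ct[a]
                    if cur != target[i]:
                        c -= 1
                    if x != target[i]:
                        c += 1
                    d = c / L
                    if d < d_min or d > d_max:
                        u += lam_t * abs(d - d_min)
                if lam_d > 0.0:
                    for b in range(M):
                        if b != a:
                            c = cb[a, b]
                            if cur != S[b, i]:
                                c -= 1
                            if x != S[b, i]:
                                c += 1
                            if c / L < d_div:
                                # the indicator appears in both U(a) and U(b)
                                u += 2.0 * lam_d
                if lam_a > 0.0:
                    for n in range(N):
                        c = ca[a, n]
                        if cur != msa[n, i]:
                            c -= 1
                        if x != msa[n, i]:
                            c += 1
                        if c / L < d_aln:
                            u += lam_a
                U_cand[x] = u
            # softmin sampling: p(x) ∝ exp(-beta * U_cand[x])
            m = U_cand[0]
            for x in range(1, n_states):
                if U_cand[x] < m:
                    m = U_cand[x]
            total = 0.0
            for x in range(n_states):
                U_cand[x] = np.exp(-beta * (U_cand[x] - m))
                total += U_cand[x]
            r = unifs[t] * total
            acc = 0.0
            new = n_states - 1
            for x in range(n_states):
                acc += U_cand[x]
                if r < acc:
                    new = x
                    break
            if new != cur:
                if cur != target[i]:
                    ct[a] -= 1
                if new != target[i]:
                    ct[a] += 1
                for b in range(M):
                    if b != a:
                        delta = 0
                        if cur != S[b, i]:
                            delta -= 1
                        if new != S[b, i]:
                            delta += 1
                        cb[a, b] += delta
                        cb[b, a] += delta
                for n in range(N):
                    if cur != msa[n, i]:
                        ca[a, n] -= 1
                    if new != msa[n, i]:
                        ca[a, n] += 1
                S[a, i] = new
                if do_count:
                    state_idx += (new - cur) * pow_q[i]
            if do_count:
                counts[state_idx] += 1
            t += 1
        trace[sweep] = _total_batch_energy(
            S, h, J, target, msa, ct, cb, ca,
            lam_t, d_min, d_max, lam_d, d_div, lam_a, d_aln,
        )
    return trace


@njit(cache=False)
def _total_batch_energy(S, h, J, target, msa, ct, cb, ca,
                        lam_t, d_min, d_max, lam_d, d_div, lam_a, d_aln):
    M, L = S.shape
    N = msa.shape[0]
    total = 0.0
    for a in range(M):
        e = 0.0
        for i in range(L):
            e += h[i, S[a, i]]
            for j in range(i + 1, L):
                e += J[i, j, S[a, i], S[a, j]]
        u = -e
        d = ct[a] / L
        if d < d_min or d > d_max:
            u += lam_t * abs(d - d_min)
        for b in range(M):
            if b != a and cb[a, b] / L < d_div:
                u += lam_d
        for n in range(N):
            if ca[a, n] / L < d_aln:
                u += lam_a
        total += u
    return total


@njit(cache=False)
def run_tempering(S, h, J, n_states, beta0, growth, positions, unifs, swap_unifs):
    """Annealed parallel tempering on the plain statistical energy.

    S (R, L) holds one sequence per replica and is updated in place.
    During sweep ``i`` replica ``r`` samples at ``beta0[r] * growth**i``;
    after each sweep adjacent replicas attempt a Metropolis exchange in
    index order. Returns (best_seq, best_evh): the highest-EVH sequence
    ever visited by any replica.
    """
    R, L = S.shape
    n_sweeps = positions.shape[0]

    E = np.empty(R, dtype=np.float64)  # EVH per replica, kept incrementally
    for r in range(R):
        e = 0.0
        for i in range(L):
            e += h[i, S[r, i]]
            for j in range(i + 1, L):
                e += J[i, j, S[r, i], S[r, j]]
        E[r] = e

    best_E = E[0]
    best_seq = S[0].copy()
    for r in range(R):
        if E[r] > best_E:
            best_E = E[r]
            best_seq = S[r].copy()

    w = np.empty(n_states, dtype=np.float64)
    scale = 1.0
    for sweep in range(n_sweeps):
        for r in range(R):
            beta = beta0[r] * scale
            for k in range(L):
                i = positions[sweep, r, k]
                cur = S[r, i]
                mx = -1.0e300
                for x in range(n_states):
                    e = h[i, x]
                    for j in range(L):
                        if j != i:
                            e += J[i, j, x, S[r, j]]
                    w[x] = e
                    if e > mx:
                        mx = e
                total = 0.0
                for x in range(n_states):
                    w[x] = np.exp(beta * (w[x] - mx))
                    total += w[x]
                rnd = unifs[sweep, r, k] * total
                acc = 0.0
                new = n_states - 1
                for x in range(n_states):
                    acc += w[x]
                    if rnd < acc:
                        new = x
                        break
                if new != cur:
                    de = h[i, new] - h[i, cur]
                    for j in range(L):
                        if j != i:
                            de += J[i, j, new, S[r, j]] - J[i, j, cur, S[r, j]]
                    S[r, i] = new
                    E[r] += de
                    if E[r] > best_E:
                        best_E = E[r]
                        best_seq = S[r].copy()
        # adjacent replica exchange; U = -EVH
        for r in range(R - 1):
            db = beta0[r] * scale - beta0[r + 1] * scale
            du = E[r + 1] - E[r]
            if swap_unifs[sweep, r] < np.exp(db * du):
                for i in range(L):
                    tmp = S[r, i]
                    S[r, i] = S[r + 1, i]
                    S[r + 1, i] = tmp
                tmpE = E[r]
                E[r] = E[r + 1]
                E[r + 1] = tmpE
        scale *= growth
    return best_seq, best_E
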