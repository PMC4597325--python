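"""Numba kernels for collapsed Gibbs sampling over token-topic assignments.

Tokens are flattened into parallel arrays (document index, word index,
current topic). All randomness enters through pre-generated uniform
variates, so runs are bit-reproducible for a fixed numpy generator and
independent of numba's internal RNG state.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# sweeps drawn per chunk of pre-generated uniforms (bounds peak memory)
CHUNK = 200


@njit(cache=True)
def _sweep(z, doc_of, word_of, ndt, ntw, nt, alpha, beta, u, p):
    """One full sweep: resample every token from its collapsed conditional.

    p(z_i = t | z_-i, w) ∝ (n_dt^-i + alpha) * (n_tw^-i + beta) / (n_t^-i + V*beta)
    """
    n = z.shape[0]
    T = nt.shape[0]
    V = ntw.shape[1]
    vb = V * beta
    for i in range(n):
        d = doc_of[i]
        w = word_of[i]
        t0 = z[i]
        ndt[d, t0] -= 1
        ntw[t0, w] -= 1
        nt[t0] -= 1
        total = 0.0
        for t in range(T):
            total += (ndt[d, t] + alpha) * (ntw[t, w] + beta) / (nt[t] + vb)
            p[t] = total
        x = u[i] * total
        tnew = 0
        while p[tnew] < x and tnew < T - 1:
            tnew += 1
        z[i] = tnew
        ndt[d, tnew] += 1
        ntw[tnew, w] += 1
        nt[tnew] += 1


@njit(cache=True)
def _run_chunk(z, doc_of, word_of, ndt, ntw, nt, alpha, beta, uniforms,
               sweep0, burn_in, sample_every,
               phi_sum, theta_sum, n_samples, doc_len, p):
    """Run uniforms.shape[0] sweeps starting at global sweep index sweep0.

    When sample_every > 0, accumulates smoothed phi/theta point estimates at
    every sample_every-th post-burn-in sweep. Returns updated sample count.
    """
    T = nt.shape[0]
    V = ntw.shape[1]
    M = ndt.shape[0]
    for s in range(uniforms.shape[0]):
        _sweep(z, doc_of, word_of, ndt, ntw, nt, alpha, beta, uniforms[s], p)
        g = sweep0 + s
        if sample_every > 0 and g >= burn_in and (g - burn_in) % sample_every == 0:
            for t in range(T):
                denom = nt[t] + V * beta
                for w in range(V):
                    phi_sum[t, w] += (ntw[t, w] + beta) / denom
            for d in range(M):
                denom = doc_len[d] + T * alpha
                for t in range(T):
                    theta_sum[d, t] += (ndt[d, t] + alpha) / denom
            n_samples += 1
    return n_samples


@njit(cache=True)
def _init_sequential(z, doc_of, word_of, ndt, ntw, nt, alpha, beta, u, p):
    """Assign each token by sampling its collapsed conditional incrementally.

    Counts start empty and grow token by token, so early assignments are
    near-uniform and later ones already follow the emerging topic structure.
    Mixes far faster than uniform-random initialization at short sweep
    budgets; the stationary distribution is unchanged.
    """
    n = z.shape[0]
    T = nt.shape[0]
    V = ntw.shape[1]
    vb = V * beta
    for i in range(n):
        d = doc_of[i]
        w = word_of[i]
        total = 0.0
        for t in range(T):
            total += (ndt[d, t] + alpha) * (ntw[t, w] + beta) / (nt[t] + vb)
            p[t] = total
        x = u[i] * total
        tnew = 0
        while p[tnew] < x and tnew < T - 1:
            tnew += 1
        z[i] = tnew
        ndt[d, tnew] += 1
        ntw[tnew, w] += 1
        nt[tnew] += 1


@njit(cache=True)
def _run_chunk_record(z, doc_of, word_of, ndt, ntw, nt, alpha, beta, uniforms,
                      sweep0, burn_in, config_counts, T, p):
    """Sweeps that tally the full assignment configuration post-burn-in.

    Configurations are encoded base-T: code = sum_i z_i * T**i. Only usable
    when T ** n_tokens fits the counts array (tiny validation corpora).
    """
    n = z.shape[0]
    for s in range(uniforms.shape[0]):
        _sweep(z, doc_of, word_of, ndt, ntw, nt, alpha, beta, uniforms[s], p)
        if sweep0 + s >= burn_in:
            code = 0
            mult = 1
            for i in range(n):
                code += z[i] * mult
                mult *= T
            config_counts[code] += 1


@njit(cache=True)
def _foldin_doc(words, phi, alpha, u_init, uniforms, burn_in, p):
    """Fold in one held-out document with topic-word rows frozen.

    p(z_i = t | ·) ∝ (n_dt^-i + alpha) * phi[t, w_i]. Returns the smoothed
    theta estimate averaged over all post-burn-in sweeps (Rao-Blackwellised
    against single-sample noise). Documents are independent given phi, so
    the caller may stream per-document random variates.
    """
    T = phi.shape[0]
    L = words.shape[0]
    ndt = np.zeros(T, dtype=np.int64)
    z = np.empty(L, dtype=np.int64)
    for i in range(L):
        t = int(u_init[i] * T)
        if t >= T:
            t = T - 1
        z[i] = t
        ndt[t] += 1
    theta = np.zeros(T)
    n_samples = 0
    denom = L + T * alpha
    for s in range(uniforms.shape[0]):
        for i in range(L):
            w = words[i]
            t0 = z[i]
            ndt[t0] -= 1
            total = 0.0
            for t in range(T):
                total += (ndt[t] + alpha) * phi[t, w]
                p[t] = total
            x = uniforms[s, i] * total
            tnew = 0
            while p[tnew] < x and tnew < T - 1:
                tnew += 1
            z[i] = tnew
            ndt[tnew] += 1
        if s >= burn_in:
            for t in range(T):
                theta[t] += (ndt[t] + alpha) / denom
            n_samples += 1
    if n_samples == 0:
        for t in range(T):
            theta[t] = (ndt[t] + alpha) / denom
    else:
        for t in range(T):
            theta[t] /= n_samples
    return theta


def run_gibbs(z, doc_of, word_of, ndt, ntw, nt, alpha, beta,
              n_iter, burn_in, sample_every, rng, doc_len):
    """Drive the sweep kernel for n_iter sweeps with chunked uniforms.

    Mutates z and the count tables in place. Returns (phi_sum, theta_sum,
    n_samples); n_samples == 0 means the caller should use the final counts.
    """
    T = nt.shape[0]
    V = ntw.shape[1]
    M = ndt.shape[0]
    n = z.shape[0]
    phi_sum = np.zeros((T, V))
    theta_sum = np.zeros((M, T))
    p = np.empty(T)
    n_samples = 0
    done = 0
    while done < n_iter:
        k = min(CHUNK, n_iter - done)
        uniforms = rng.random((k, n))
        n_samples = _run_chunk(
            z, doc_of, word_of, ndt, ntw, nt, alpha, beta, uniforms,
            done, burn_in, sample_every, phi_sum, theta_sum, n_samples,
            doc_len, p,
        )
        done += k
    return phi_sum, theta_sum, n_samples
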