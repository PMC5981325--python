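"""Compiled inner loops for the evolutionary simulation.

Population state is held as flat arrays (struct-of-arrays): S as int8
with 0 = heuristic and 1 = context-dependent, T as float64, first moves
as an (N, 3) float64 block and response codes as an (N, 3) int8 block,
columns ordered H, C1, C2.  The mutation matrix enters as its (16, 4)
target table.

Perception concentrations kappa(m) are tabulated on a dense grid in the
mode m and linearly interpolated inside the kernel; the interpolation
error is far below the Monte-Carlo noise of any simulated quantity.

Randomness uses numba's implementation of the legacy numpy RNG, seeded
once per kernel call, so every trajectory is reproducible from its
integer seed.
"""

from __future__ import annotations

import numpy as np
from numba import njit

KAPPA_TABLE_SIZE = 4097


@njit(cache=False)
def _kappa_bisect(m, target):
    lo = 0.0
    hi = 1.0
    while True:
        a = 1.0 + hi * m
        b = 1.0 + hi * (1.0 - m)
        s = a + b
        if a * b / (s * s * (s + 1.0)) <= target:
            break
        hi *= 2.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        a = 1.0 + mid * m
        b = 1.0 + mid * (1.0 - m)
        s = a + b
        if a * b / (s * s * (s + 1.0)) > target:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-13:
            break
    return 0.5 * (lo + hi)


@njit(cache=False)
def build_kappa_table(u, n=KAPPA_TABLE_SIZE):
    """kappa(m) for m on a regular grid over [0, 1], variance target u/12."""
    tab = np.zeros(n)
    if u <= 0.0:
        return tab
    target = u / 12.0
    for i in range(n):
        tab[i] = _kappa_bisect(i / (n - 1), target)
    return tab


@njit(cache=False, inline="always")
def _draw_cp(c, u, kt):
    """One perceived consequence for true consequence c at uncertainty u."""
    if u <= 0.0:
        return c
    m = (c + 3.0) / 4.0
    x = m * (kt.shape[0] - 1)
    i0 = int(x)
    if i0 >= kt.shape[0] - 1:
        i0 = kt.shape[0] - 2
    w = x - i0
    kappa = kt[i0] * (1.0 - w) + kt[i0 + 1] * w
    a = 1.0 + kappa * m
    b = 1.0 + kappa * (1.0 - m)
    return -3.0 + 4.0 * np.random.beta(a, b)


@njit(cache=False)
def run_kernel(S, T, FM, CODE, targets, n_gens, n_inter, n_rounds,
               b, eps, mu, sigma, u, baseline, floor, seed, kt):
    """Full generation loop of the uncertainty model.

    Returns per-generation cooperation level, heuristic fraction and
    mean threshold, plus the final population arrays.
    """
    np.random.seed(seed)
    N = S.shape[0]
    coop_tr = np.empty(n_gens)
    heur_tr = np.empty(n_gens)
    meanT_tr = np.empty(n_gens)
    for g in range(n_gens):
        fitness = np.zeros(N)
        ncoop = 0
        for _ in range(n_inter):
            perm = np.random.permutation(N)
            for p in range(N // 2):
                i = perm[2 * p]
                j = perm[2 * p + 1]
                c = -3.0 + 4.0 * np.random.random()
                cpi = _draw_cp(c, u, kt)
                cpj = _draw_cp(c, u, kt)
                si = 0 if S[i] == 0 else (1 if cpi < T[i] else 2)
                sj = 0 if S[j] == 0 else (1 if cpj < T[j] else 2)
                ci = CODE[i, si]
                cj = CODE[j, sj]
                fi = FM[i, si]
                fj = FM[j, sj]
                oi = 0
                oj = 0
                for r in range(n_rounds):
                    if r == 0:
                        ai = 1 if np.random.random() < fi else 0
                        aj = 1 if np.random.random() < fj else 0
                    else:
                        ai = (ci >> (3 - oi)) & 1
                        aj = (cj >> (3 - oj)) & 1
                    if np.random.random() < eps:
                        ai = 1 - ai
                    if np.random.random() < eps:
                        aj = 1 - aj
                    oi = (1 - ai) * 2 + (1 - aj)
                    oj = (1 - aj) * 2 + (1 - ai)
                    fitness[i] += b * aj + c * ai
                    fitness[j] += b * ai + c * aj
                    ncoop += ai + aj
        coop_tr[g] = ncoop / (N * n_inter * n_rounds)
        nh = 0
        for i in range(N):
            if S[i] == 0:
                nh += 1
        heur_tr[g] = nh / N
        meanT_tr[g] = np.mean(T)
        if g < n_gens - 1:  # keep the last played generation as the final pop
            S, T, FM, CODE = _reproduce(S, T, FM, CODE, fitness, targets,
                                        baseline, floor, mu, sigma)
    return coop_tr, heur_tr, meanT_tr, S, T, FM, CODE


@njit(cache=False)
def _reproduce(S, T, FM, CODE, fitness, targets, baseline, floor, mu, sigma):
    """Roulette-wheel selection (fitness floored) + per-unit mutation."""
    N = S.shape[0]
    fit = np.empty(N)
    tot = 0.0
    for i in range(N):
        f = baseline + fitness[i]
        if f < floor:
            f = floor
        fit[i] = f
        tot += f
    cum = np.cumsum(fit)
    S2 = np.empty_like(S)
    T2 = np.empty_like(T)
    FM2 = np.empty_like(FM)
    CODE2 = np.empty_like(CODE)
    for k in range(N):
        if tot > 0.0:
            pr = np.searchsorted(cum, np.random.random() * tot, side="right")
            if pr >= N:
                pr = N - 1
        else:
            pr = np.random.randint(0, N)
        S2[k] = S[pr]
        T2[k] = T[pr]
        if np.random.random() < mu:
            S2[k] = 1 - S2[k]
        if np.random.random() < mu:
            T2[k] = T2[k] + np.random.normal(0.0, sigma)
        for s in range(3):
            fm = FM[pr, s]
            if np.random.random() < mu:
                fm = fm + np.random.normal(0.0, sigma)
                if fm < 0.0:
                    fm = 0.0
                if fm > 1.0:
                    fm = 1.0
            FM2[k, s] = fm
            cd = CODE[pr, s]
            if np.random.random() < mu:
                cd = targets[cd, np.random.randint(0, 4)]
            CODE2[k, s] = cd
    return S2, T2, FM2, CODE2


@njit(cache=False)
def run_fixed_c_kernel(FM, CODE, targets, n_gens, n_inter, n_rounds,
                       b, eps, mu, sigma, c, baseline, floor, seed):
    """Benchmark variant: constant consequence c, single-substrategy genotypes."""
    np.random.seed(seed)
    N = FM.shape[0]
    coop_tr = np.empty(n_gens)
    for g in range(n_gens):
        fitness = np.zeros(N)
        ncoop = 0
        for _ in range(n_inter):
            perm = np.random.permutation(N)
            for p in range(N // 2):
                i = perm[2 * p]
                j = perm[2 * p + 1]
                ci = CODE[i]
                cj = CODE[j]
                fi = FM[i]
                fj = FM[j]
                oi = 0
                oj = 0
                for r in range(n_rounds):
                    if r == 0:
                        ai = 1 if np.random.random() < fi else 0
                        aj = 1 if np.random.random() < fj else 0
                    else:
                        ai = (ci >> (3 - oi)) & 1
                        aj = (cj >> (3 - oj)) & 1
                    if np.random.random() < eps:
                        ai = 1 - ai
                    if np.random.random() < eps:
                        aj = 1 - aj
                    oi = (1 - ai) * 2 + (1 - aj)
                    oj = (1 - aj) * 2 + (1 - ai)
                    fitness[i] += b * aj + c * ai
                    fitness[j] += b * ai + c * aj
                    ncoop += ai + aj
        coop_tr[g] = ncoop / (N * n_inter * n_rounds)
        if g == n_gens - 1:
            break
        fit = np.empty(N)
        tot = 0.0
        for i in range(N):
            f = baseline + fitness[i]
            if f < floor:
                f = floor
            fit[i] = f
            tot += f
        cum = np.cumsum(fit)
        FM2 = np.empty_like(FM)
        CODE2 = np.empty_like(CODE)
        for k in range(N):
            if tot > 0.0:
                pr = np.searchsorted(cum, np.random.random() * tot, side="right")
                if pr >= N:
                    pr = N - 1
            else:
                pr = np.random.randint(0, N)
            fm = FM[pr]
            if np.random.random() < mu:
                fm = fm + np.random.normal(0.0, sigma)
                if fm < 0.0:
                    fm = 0.0
                if fm > 1.0:
                    fm = 1.0
            FM2[k] = fm
            cd = CODE[pr]
            if np.random.random() < mu:
                cd = targets[cd, np.random.randint(0, 4)]
            CODE2[k] = cd
        FM = FM2
        CODE = CODE2
    return coop_tr, FM, CODE
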