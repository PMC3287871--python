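"""Independent brute-force oracles used by the tests.

These deliberately avoid the code paths they check: kinship is computed by
exhaustive enumeration of inheritance vectors, REML by dense-matrix
inversion on a fine grid, IBS and collapsing by explicit double loops.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize_scalar

from famburden.pedigree import Pedigree

_LOG_2PI = float(np.log(2.0 * np.pi))


def kinship_by_enumeration(ped: Pedigree) -> np.ndarray:
    """Exact kinship by enumerating every inheritance vector.

    Founders carry distinct allele labels; every non-founder has two meiosis
    choices per parent, giving 2^(2 * n_nonfounders) equally likely
    configurations.  phi(i, j) is the average, over configurations and over
    the four allele pairings, of the probability that a random allele from i
    matches a random allele from j by descent.  Exact, exponential in the
    pedigree size; only usable on small pedigrees.
    """
    n = len(ped)
    parents = ped.parent_indices()
    order = ped._topological_order()
    nonfounders = [i for i in order if parents[i][0] >= 0 or parents[i][1] >= 0]
    nbits = 2 * len(nonfounders)
    if nbits > 22:
        raise ValueError("pedigree too large for exhaustive enumeration")
    bit_of = {i: 2 * k for k, i in enumerate(nonfounders)}
    n_cfg = 1 << nbits
    cfg = np.arange(n_cfg, dtype=np.int64)

    a1 = np.empty((n, n_cfg), dtype=np.int16)
    a2 = np.empty((n, n_cfg), dtype=np.int16)
    label = 0
    for i in order:
        fa, mo = parents[i]
        if fa < 0 and mo < 0:
            a1[i] = label
            a2[i] = label + 1
            label += 2
        else:
            bf = (cfg >> bit_of[i]) & 1
            bm = (cfg >> (bit_of[i] + 1)) & 1
            a1[i] = np.where(bf == 0, a1[fa], a2[fa])
            a2[i] = np.where(bm == 0, a1[mo], a2[mo])

    phi = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            share = (
                (a1[i] == a1[j]).mean()
                + (a1[i] == a2[j]).mean()
                + (a2[i] == a1[j]).mean()
                + (a2[i] == a2[j]).mean()
            )
            phi[i, j] = phi[j, i] = share / 4.0
    return phi


def reml_loglik_dense(y: np.ndarray, F: np.ndarray, K: np.ndarray, delta: float) -> float:
    """Profiled restricted log-likelihood by explicit dense inversion."""
    n, p = F.shape
    H = K + delta * np.eye(n)
    Hinv = np.linalg.inv(H)
    A = F.T @ Hinv @ F
    b = F.T @ Hinv @ y
    beta = np.linalg.solve(A, b)
    R = float(y @ Hinv @ y - b @ beta)
    _, logdetH = np.linalg.slogdet(H)
    _, logdetA = np.linalg.slogdet(A)
    nmp = n - p
    return -0.5 * (nmp * (_LOG_2PI + 1.0 + np.log(R / nmp)) + logdetH + logdetA)


def reml_fit_dense(y: np.ndarray, F: np.ndarray, K: np.ndarray) -> tuple[float, float]:
    """Direct REML optimiser: fine log10(delta) grid plus bounded refinement.

    Returns (delta, max restricted log-likelihood).  Every likelihood
    evaluation builds and inverts V explicitly; no spectral shortcut.
    """
    grid = np.linspace(-10.0, 10.0, 2001)
    ll = np.array([reml_loglik_dense(y, F, K, 10.0**g) for g in grid])
    i = int(np.argmax(ll))
    best_logd, best_ll = grid[i], float(ll[i])
    a, b = grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)]
    res = minimize_scalar(
        lambda g: -reml_loglik_dense(y, F, K, 10.0**g),
        bounds=(a, b), method="bounded", options={"xatol": 1e-8},
    )
    if -res.fun > best_ll:
        best_logd, best_ll = float(res.x), float(-res.fun)
    return 10.0**best_logd, best_ll


def ibs_double_loop(dosages: np.ndarray) -> np.ndarray:
    """IBS by explicit pair/variant loops with pairwise deletion (-1 missing)."""
    n, m = dosages.shape
    s = np.ones((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            num, cnt = 0.0, 0
            for v in range(m):
                gi, gj = dosages[i, v], dosages[j, v]
                if gi < 0 or gj < 0:
                    continue
                num += 1.0 - abs(float(gi) - float(gj)) / 2.0
                cnt += 1
            s[i, j] = num / cnt
    return s


def collapse_by_loops(dosages: np.ndarray, maf: np.ndarray, gene_mask: np.ndarray,
                      threshold: float) -> np.ndarray:
    """Per-subject any() over the gene's rare variants (-1 missing = non-carrier)."""
    n, m = dosages.shape
    out = np.zeros(n, dtype=int)
    for i in range(n):
        for v in range(m):
            if gene_mask[v] and maf[v] < threshold and dosages[i, v] >= 1:
                out[i] = 1
                break
    return out
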