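"""Independent reference implementations used only by the tests.

Each oracle deliberately takes a different computational route from the
package code it checks: a two-stage dense grid search (with a general,
non-symmetrized eigendecomposition) for ML distances, a plain Gotoh DP for
alignment scores, an exact combinatorial sum for hypergeometric tails, a
dense pH scan for the isoelectric point, and a naive edge-scanning shell
assigner.
"""

from __future__ import annotations

import math

import numpy as np
import scipy.linalg

from idrscape.evolution import AA_MODEL_ORDER, load_model
from idrscape.scales import (
    PKA_CTERMINAL,
    PKA_NEGATIVE_SIDE,
    PKA_NTERMINAL,
    PKA_NTERMINAL_DEFAULT,
    PKA_POSITIVE_SIDE,
)

_AA_IDX = {aa: i for i, aa in enumerate(AA_MODEL_ORDER)}


# ---------------------------------------------------------------------------
# grid-search ML distance

_eig_cache: dict[str, tuple] = {}


def _general_eig(model_name: str):
    if model_name not in _eig_cache:
        m = load_model(model_name)
        Q = m.exchangeability * m.pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        Q = Q / (-np.sum(m.pi * np.diag(Q)))
        w, V = scipy.linalg.eig(Q)
        _eig_cache[model_name] = (w, V, scipy.linalg.inv(V), np.log(m.pi))
    return _eig_cache[model_name]


def _loglik_grid(counts: np.ndarray, model_name: str, ts: np.ndarray) -> np.ndarray:
    w, V, Vinv, log_pi = _general_eig(model_name)
    # P(t) for all t at once: V diag(e^{w t}) V^-1
    expwt = np.exp(np.outer(ts, w))  # (T, 20)
    P = np.einsum("ik,tk,kj->tij", V, expwt, Vinv).real
    P = np.maximum(P, 1e-300)
    return np.einsum("ij,tij->t", counts, np.log(P) + log_pi[None, :, None])


def grid_ml_distance(a: str, b: str, model_name: str, cap: float = 10.0) -> float:
    """Two-stage dense grid search for the ML distance, final step 1e-4."""
    counts = np.zeros((20, 20))
    for x, y in zip(a, b):
        if x != "-" and y != "-":
            counts[_AA_IDX[x], _AA_IDX[y]] += 1.0
    if counts.sum() == 0:
        return float("nan")
    off = counts.sum() - np.trace(counts)
    if off == 0:
        return 0.0
    coarse = np.arange(1e-3, cap + 1e-3, 1e-3)
    ll = _loglik_grid(counts, model_name, coarse)
    t0 = coarse[int(np.argmax(ll))]
    fine = np.arange(max(t0 - 2e-3, 1e-4), min(t0 + 2e-3, cap) + 1e-9, 1e-4)
    ll = _loglik_grid(counts, model_name, fine)
    return float(fine[int(np.argmax(ll))])


# ---------------------------------------------------------------------------
# Gotoh global alignment score

def dp_align_score(a: str, b: str, matrix, gap_open: float, gap_extend: float) -> float:
    """Affine-gap global alignment score; a gap of length L costs
    gap_open + (L-1)*gap_extend. End gaps are penalized."""
    n, m = len(a), len(b)
    neg = -math.inf
    M = [[neg] * (m + 1) for _ in range(n + 1)]
    Ix = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in b (consume a)
    Iy = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in a (consume b)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        Ix[i][0] = gap_open + (i - 1) * gap_extend
    for j in range(1, m + 1):
        Iy[0][j] = gap_open + (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = matrix[a[i - 1], b[j - 1]]
            M[i][j] = max(M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1]) + s
            Ix[i][j] = max(M[i - 1][j] + gap_open, Ix[i - 1][j] + gap_extend,
                           Iy[i - 1][j] + gap_open)
            Iy[i][j] = max(M[i][j - 1] + gap_open, Iy[i][j - 1] + gap_extend,
                           Ix[i][j - 1] + gap_open)
    return max(M[n][m], Ix[n][m], Iy[n][m])


# ---------------------------------------------------------------------------
# exact hypergeometric upper tail

def exact_hypergeom_upper(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n) by exact combinatorial sums."""
    total = math.comb(N, n)
    acc = 0
    for x in range(max(k, 0), min(K, n) + 1):
        acc += math.comb(K, x) * math.comb(N - K, n - x)
    return acc / total


# ---------------------------------------------------------------------------
# dense pH-scan isoelectric point

def scan_pi(seq: str, include_termini: bool = True, step: float = 1e-4) -> float:
    phs = np.arange(0.0, 14.0 + step, step)
    charge = np.zeros_like(phs)
    for aa, pka in PKA_POSITIVE_SIDE.items():
        cnt = seq.count(aa)
        if cnt:
            charge += cnt / (1.0 + 10.0 ** (phs - pka))
    if include_termini:
        pka = PKA_NTERMINAL.get(seq[0], PKA_NTERMINAL_DEFAULT)
        charge += 1.0 / (1.0 + 10.0 ** (phs - pka))
    for aa, pka in PKA_NEGATIVE_SIDE.items():
        cnt = seq.count(aa)
        if cnt:
            charge -= cnt / (1.0 + 10.0 ** (pka - phs))
    if include_termini:
        charge -= 1.0 / (1.0 + 10.0 ** (PKA_CTERMINAL - phs))
    return float(phs[int(np.argmin(np.abs(charge)))])


# ---------------------------------------------------------------------------
# naive shell assigner

def brute_shells(edge_list, focus: str) -> dict[str, str]:
    """Shell levels by direct, repeated scans of the raw edge list."""
    def physical_partners(node):
        out = set()
        for e in edge_list:
            if e.etype == "physical" and e.a != e.b:
                if e.a == node:
                    out.add(e.b)
                if e.b == node:
                    out.add(e.a)
        return out

    genetic = set()
    for e in edge_list:
        if e.etype == "genetic" and e.a != e.b:
            if e.a == focus:
                genetic.add(e.b)
            if e.b == focus:
                genetic.add(e.a)

    level1 = physical_partners(focus)
    levels = {p: "1" for p in level1}
    for p in sorted(genetic - level1):
        if physical_partners(p) & level1:
            levels[p] = "2"
    level2 = {p for p, lv in levels.items() if lv == "2"}
    for p in sorted(genetic - level1 - level2):
        if physical_partners(p) & level2:
            levels[p] = "3"
    for p in sorted(genetic):
        if p not in levels:
            levels[p] = "outer"
    return levels
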