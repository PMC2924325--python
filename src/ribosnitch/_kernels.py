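"""Numba dynamic-programming kernels for the nested-structure ensemble.

Layout conventions (internal, 0-based):

* ``ptype[i, j]`` — pair-type id of (i, j) or -1 if the two residues cannot
  pair under the model.  Only ``i < j`` entries are consulted.
* Inside matrices over intervals [i..j]:
    ``QB`` — partition function given (i, j) paired,
    ``QM1`` — exactly one multiloop branch starting at i, the rest of
    [i..j] unpaired,
    ``QM`` — at least one multiloop branch inside [i..j],
    ``Q``  — unconstrained (exterior-style) partition function.
* All inside quantities are rescaled by ``q1`` per nucleotide (``q1 <= 1``)
  to keep values in double range for long sequences; probabilities are
  ratios in which the rescaling cancels exactly.
* Loop-weight arrays are Boltzmann factors indexed by loop size, with 0
  marking a disallowed size.

The outside pass computes, row by row in increasing i, the complement
weight ``OM[i, j]`` of each pair (everything outside the interval given
that (i, j) closes it), so that P(i,j) = QB*OM/Z.  The multiloop outside
contribution is accumulated with per-row helper sums to stay O(n^3).
"""

from __future__ import annotations

import numpy as np
from numba import njit

INF = 1e18


@njit(cache=True)
def fill_inside(ptype, h, maxloop, whp, wbu, wil, wstack, wml_c, wml_b, wml_u, q1pow):
    n = ptype.shape[0]
    QB = np.zeros((n, n))
    QM = np.zeros((n, n))
    QM1 = np.zeros((n, n))
    Q = np.zeros((n, n))
    q1 = q1pow[1]
    uq = wml_u * q1
    for i in range(n):
        Q[i, i] = q1
    for d in range(1, n):
        for i in range(n - d):
            j = i + d
            # --- QB: (i, j) paired -------------------------------------
            if ptype[i, j] >= 0 and d - 1 >= h:
                val = whp[d - 1] * q1pow[d + 1]
                # stack / bulge / internal closed by (i,j), inner pair (k,l)
                kmax = min(i + maxloop + 1, j - 1)
                for k in range(i + 1, kmax + 1):
                    g1 = k - i - 1
                    l_lo = j - 1 - (maxloop - g1)
                    if l_lo < k + h + 1:
                        l_lo = k + h + 1
                    for l in range(l_lo, j):
                        pt2 = ptype[k, l]
                        if pt2 >= 0 and QB[k, l] > 0.0:
                            g2 = j - l - 1
                            if g1 == 0 and g2 == 0:
                                w = wstack[ptype[i, j], pt2]
                            elif g1 == 0 or g2 == 0:
                                w = wbu[g1 + g2]
                            else:
                                w = wil[g1 + g2]
                            if w > 0.0:
                                val += w * QB[k, l] * q1pow[g1 + g2 + 2]
                # multiloop closure: >= 2 branches inside
                s = 0.0
                for k in range(i + 2, j):
                    s += QM[i + 1, k - 1] * QM1[k, j - 1]
                val += wml_c * q1pow[2] * s
                QB[i, j] = val
            # --- QM1 ----------------------------------------------------
            QM1[i, j] = QM1[i, j - 1] * uq + QB[i, j] * wml_b
            # --- QM -----------------------------------------------------
            acc = QM1[i, j]
            upow = uq
            for k in range(i + 1, j + 1):
                t = QM1[k, j]
                if t > 0.0:
                    acc += t * (upow + QM[i, k - 1])
                upow *= uq
            QM[i, j] = acc
            # --- Q ------------------------------------------------------
            accq = Q[i, j - 1] * q1
            for k in range(i, j - h):
                if ptype[k, j] >= 0 and QB[k, j] > 0.0:
                    left = 1.0 if k == i else Q[i, k - 1]
                    accq += left * QB[k, j]
            Q[i, j] = accq
    return QB, QM, QM1, Q


@njit(cache=True)
def fill_outside(ptype, h, maxloop, whp, wbu, wil, wstack, wml_c, wml_b, wml_u,
                 q1pow, QB, QM, Q):
    n = ptype.shape[0]
    OM = np.zeros((n, n))
    P = np.zeros((n, n))
    Z = Q[0, n - 1]
    q1 = q1pow[1]
    uq = wml_u * q1
    upow_tab = np.empty(n + 1)
    upow_tab[0] = 1.0
    for m in range(1, n + 1):
        upow_tab[m] = upow_tab[m - 1] * uq
    wml_cb = wml_c * wml_b
    A = np.zeros(n)
    B = np.zeros(n)
    for i in range(n):
        # helper sums over closing pairs (k, l) with k < i, for the
        # multiloop-outside term; rows k < i are already complete.
        if i >= 1:
            for l in range(i + 1, n):
                a_acc = 0.0
                b_acc = 0.0
                for k in range(0, i):
                    om = OM[k, l]
                    if om > 0.0:
                        if k + 1 <= i - 1:
                            a_acc += om * QM[k + 1, i - 1]
                        b_acc += om * upow_tab[i - 1 - k]
                A[l] = a_acc * q1
                B[l] = b_acc * q1
        for j in range(i + h + 1, n):
            if ptype[i, j] < 0 or QB[i, j] <= 0.0:
                continue
            # top-level pair in the exterior loop
            left = Q[0, i - 1] if i >= 1 else 1.0
            right = Q[j + 1, n - 1] if j + 1 <= n - 1 else 1.0
            val = left * right
            # (i, j) inner pair of a stack/bulge/internal closed by (k, l)
            k_lo = i - 1 - maxloop
            if k_lo < 0:
                k_lo = 0
            for k in range(k_lo, i):
                g1 = i - k - 1
                l_hi = j + 1 + (maxloop - g1)
                if l_hi > n - 1:
                    l_hi = n - 1
                for l in range(j + 1, l_hi + 1):
                    pt = ptype[k, l]
                    if pt >= 0 and OM[k, l] > 0.0:
                        g2 = l - j - 1
                        if g1 == 0 and g2 == 0:
                            w = wstack[pt, ptype[i, j]]
                        elif g1 == 0 or g2 == 0:
                            w = wbu[g1 + g2]
                        else:
                            w = wil[g1 + g2]
                        if w > 0.0:
                            val += OM[k, l] * w * q1pow[g1 + g2 + 2]
            # (i, j) a branch of a multiloop closed by some (k, l)
            if i >= 1 and j + 1 <= n - 1:
                s = 0.0
                for l in range(j + 1, n):
                    a_l = A[l]
                    b_l = B[l]
                    if a_l > 0.0 or b_l > 0.0:
                        qmr = QM[j + 1, l - 1] if j + 1 <= l - 1 else 0.0
                        s += a_l * (upow_tab[l - 1 - j] + qmr) + b_l * qmr
                val += wml_cb * q1 * s
            OM[i, j] = val
            p = QB[i, j] * val / Z
            P[i, j] = p
            P[j, i] = p
    return P


@njit(cache=True)
def fill_mfe(ptype, h, maxloop, ehp, ebu, eil, estack, ml_a, ml_b, ml_c):
    n = ptype.shape[0]
    V = np.full((n, n), INF)
    M = np.full((n, n), INF)
    M1 = np.full((n, n), INF)
    for d in range(1, n):
        for i in range(n - d):
            j = i + d
            if ptype[i, j] >= 0 and d - 1 >= h:
                best = ehp[d - 1]
                kmax = min(i + maxloop + 1, j - 1)
                for k in range(i + 1, kmax + 1):
                    g1 = k - i - 1
                    l_lo = j - 1 - (maxloop - g1)
                    if l_lo < k + h + 1:
                        l_lo = k + h + 1
                    for l in range(l_lo, j):
                        pt2 = ptype[k, l]
                        if pt2 >= 0 and V[k, l] < INF / 2:
                            g2 = j - l - 1
                            if g1 == 0 and g2 == 0:
                                e = estack[ptype[i, j], pt2]
                            elif g1 == 0 or g2 == 0:
                                e = ebu[g1 + g2]
                            else:
                                e = eil[g1 + g2]
                            if e < INF / 2 and e + V[k, l] < best:
                                best = e + V[k, l]
                for k in range(i + 2, j):
                    if M[i + 1, k - 1] < INF / 2 and M1[k, j - 1] < INF / 2:
                        e = ml_a + M[i + 1, k - 1] + M1[k, j - 1]
                        if e < best:
                            best = e
                V[i, j] = best
            m1 = M1[i, j - 1] + ml_c if M1[i, j - 1] < INF / 2 else INF
            if V[i, j] < INF / 2 and V[i, j] + ml_b < m1:
                m1 = V[i, j] + ml_b
            M1[i, j] = m1
            acc = M1[i, j]
            for k in range(i + 1, j + 1):
                t = M1[k, j]
                if t < INF / 2:
                    e = ml_c * (k - i) + t
                    if e < acc:
                        acc = e
                    if M[i, k - 1] < INF / 2 and M[i, k - 1] + t < acc:
                        acc = M[i, k - 1] + t
            M[i, j] = acc
    # exterior loop over prefixes: W[j+1] = best energy of residues 0..j
    W = np.zeros(n + 1)
    for j in range(n):
        best = W[j]
        for k in range(0, j - h):
            if V[k, j] < INF / 2 and W[k] + V[k, j] < best:
                best = W[k] + V[k, j]
        W[j + 1] = best
    return V, M, M1, W
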