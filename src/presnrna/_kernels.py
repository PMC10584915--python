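"""Numeric kernels: folding DP fill and ordered tree edit distance.

Both are plain array code so they can be JIT-compiled with numba; without
numba they run as ordinary (slow) Python, which keeps the package usable
in minimal environments.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def deco(f):
            return f

        return deco

INF = np.int64(1) << 40


@njit(cache=True)
def fill_matrices(pt_mat, must_pair, hairpin_tab, bulge_tab, internal_tab,
                  stack_tab, ml_init, ml_branch, ml_unpaired, maxloop):
    """Fill the folding matrices for one sequence under hard constraints.

    ``pt_mat[i, j]`` is the pair-type index of an admissible pair (i, j)
    (complementary, hairpin-size legal, allowed by the constraint) or -1.
    ``must_pair[i]`` marks positions carrying a forced-pair constraint.

    Returns ``V`` (energy given (i, j) paired), ``M`` (multiloop region
    with >= 1 branch), ``M2`` (>= 2 branches) and the exterior prefix
    array ``W`` (``W[j]`` = best energy of positions 0..j-1).  The
    decomposition grammar is unambiguous, so suboptimal enumeration visits
    every structure exactly once.
    """
    n = pt_mat.shape[0]
    V = np.full((n, n), INF, dtype=np.int64)
    M = np.full((n, n), INF, dtype=np.int64)
    M2 = np.full((n, n), INF, dtype=np.int64)
    W = np.full(n + 1, INF, dtype=np.int64)

    # forced_cum[i] = number of must-pair positions < i
    forced_cum = np.zeros(n + 1, dtype=np.int64)
    for i in range(n):
        forced_cum[i + 1] = forced_cum[i] + (1 if must_pair[i] else 0)

    for span in range(1, n):
        for i in range(0, n - span):
            j = i + span

            # ---- V: i pairs j -------------------------------------------
            if pt_mat[i, j] >= 0:
                best = INF
                # hairpin loop
                if forced_cum[j] - forced_cum[i + 1] == 0:
                    best = hairpin_tab[j - i - 1]
                # stack / bulge / interior loop
                for k in range(i + 1, j - 1):
                    l1 = k - i - 1
                    if l1 > maxloop:
                        break
                    if k > i + 1 and must_pair[k - 1]:
                        break
                    for l in range(j - 1, k, -1):
                        l2 = j - 1 - l
                        if l1 + l2 > maxloop:
                            break
                        if l < j - 1 and must_pair[l + 1]:
                            break
                        if V[k, l] >= INF:
                            continue
                        if l1 == 0 and l2 == 0:
                            e = stack_tab[pt_mat[i, j], pt_mat[k, l]]
                        elif l1 == 0 or l2 == 0:
                            e = bulge_tab[l1 + l2]
                        else:
                            e = internal_tab[l1 + l2]
                        tot = e + V[k, l]
                        if tot < best:
                            best = tot
                # multiloop closed by (i, j)
                if j - i - 1 >= 2 and M2[i + 1, j - 1] < INF:
                    tot = ml_init + ml_branch + M2[i + 1, j - 1]
                    if tot < best:
                        best = tot
                V[i, j] = best

            # ---- M: inside a multiloop, >= 1 branch ---------------------
            best = INF
            if not must_pair[j] and M[i, j - 1] < INF:
                tot = M[i, j - 1] + ml_unpaired
                if tot < best:
                    best = tot
            for k in range(i, j):
                if V[k, j] >= INF:
                    continue
                base = V[k, j] + ml_branch
                if k == i:
                    if base < best:
                        best = base
                else:
                    # first branch: i..k-1 all unpaired
                    if forced_cum[k] - forced_cum[i] == 0:
                        tot = base + ml_unpaired * (k - i)
                        if tot < best:
                            best = tot
                    if M[i, k - 1] < INF:
                        tot = base + M[i, k - 1]
                        if tot < best:
                            best = tot
            M[i, j] = best

            # ---- M2: >= 2 branches --------------------------------------
            best = INF
            if not must_pair[j] and M2[i, j - 1] < INF:
                tot = M2[i, j - 1] + ml_unpaired
                if tot < best:
                    best = tot
            for k in range(i + 1, j):
                if V[k, j] >= INF or M[i, k - 1] >= INF:
                    continue
                tot = M[i, k - 1] + V[k, j] + ml_branch
                if tot < best:
                    best = tot
            M2[i, j] = best

    # ---- exterior ----------------------------------------------------
    W[0] = 0
    for j in range(1, n + 1):
        last = j - 1
        best = INF
        if not must_pair[last] and W[last] < INF:
            best = W[last]
        for k in range(0, last):
            if V[k, last] < INF and W[k] < INF:
                tot = W[k] + V[k, last]
                if tot < best:
                    best = tot
        W[j] = best

    return V, M, M2, W


@njit(cache=True)
def tree_edit_distance_kernel(lml1, kr1, lab1, lml2, kr2, lab2):
    """Zhang-Shasha ordered tree edit distance with unit costs.

    Trees are given in postorder: ``lml`` maps each node to its leftmost
    leaf descendant, ``kr`` lists keyroots in increasing order, ``lab``
    holds integer node labels.  Insert/delete cost 1; relabel costs 1 for
    differing labels and 0 otherwise.
    """
    n1 = lab1.shape[0]
    n2 = lab2.shape[0]
    td = np.zeros((n1, n2), dtype=np.int64)
    fd = np.zeros((n1 + 1, n2 + 1), dtype=np.int64)
    for xi in range(kr1.shape[0]):
        x = kr1[xi]
        i0 = lml1[x]
        m = x - i0 + 1
        for yi in range(kr2.shape[0]):
            y = kr2[yi]
            j0 = lml2[y]
            nn = y - j0 + 1
            fd[0, 0] = 0
            for di in range(1, m + 1):
                fd[di, 0] = fd[di - 1, 0] + 1
            for dj in range(1, nn + 1):
                fd[0, dj] = fd[0, dj - 1] + 1
            for di in range(1, m + 1):
                i = i0 + di - 1
                for dj in range(1, nn + 1):
                    j = j0 + dj - 1
                    a = fd[di - 1, dj] + 1
                    b = fd[di, dj - 1] + 1
                    if lml1[i] == i0 and lml2[j] == j0:
                        cost = 0 if lab1[i] == lab2[j] else 1
                        c = fd[di - 1, dj - 1] + cost
                        best = a if a < b else b
                        if c < best:
                            best = c
                        fd[di, dj] = best
                        td[i, j] = best
                    else:
                        c = fd[lml1[i] - i0, lml2[j] - j0] + td[i, j]
                        best = a if a < b else b
                        if c < best:
                            best = c
                        fd[di, dj] = best
    return td[n1 - 1, n2 - 1]
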