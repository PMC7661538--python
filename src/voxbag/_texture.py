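"""Numba kernels for sliding-window gray-level texture feature maps.

The per-voxel 5x5x5-window co-occurrence / run-length computations are the
hot loop of the whole pipeline (|ROI| windows x 26 offsets x 125 voxel pairs
per patient and modality), so they are compiled with numba. The pure-Python
single-window operations in :mod:`voxbag.feature_maps` define the reference
semantics; the test suite checks this compiled path against a naive
enumeration voxel by voxel.

Conventions shared with feature_maps:
- quantized levels are 1..L inside the ROI, 0 (sentinel) outside;
- GLCM pairs require both endpoints inside window, volume and ROI, and are
  accumulated symmetrically;
- GLRLM counts maximal runs of equal level along each direction, broken by
  the window border, the volume border and sentinel voxels.
"""

from __future__ import annotations

import numpy as np
from numba import njit

N_GLCM = 8
N_GLRLM = 10


@njit(cache=True)
def _glcm_scalars(C, out):
    """8 Haralick-type statistics from a symmetric count matrix C (in place).

    Order: energy, inverse difference moment, entropy (bits), Haralick
    correlation, cluster shade, cluster prominence, inertia, correlation.
    Degenerate (no pairs): point-mass conventions (1, 1, 0, 0, 0, 0, 0, 0).
    Returns the total pair count.
    """
    L = C.shape[0]
    total = 0.0
    for i in range(L):
        for j in range(L):
            total += C[i, j]
    if total <= 0.0:
        out[0] = 1.0
        out[1] = 1.0
        for m in range(2, N_GLCM):
            out[m] = 0.0
        return 0.0
    mu = 0.0
    for i in range(L):
        s = 0.0
        for j in range(L):
            s += C[i, j]
        mu += (i + 1.0) * s / total
    var = 0.0
    for i in range(L):
        s = 0.0
        for j in range(L):
            s += C[i, j]
        var += (i + 1.0 - mu) ** 2 * s / total
    energy = 0.0
    idm = 0.0
    ent = 0.0
    sxy = 0.0
    shade = 0.0
    prom = 0.0
    inertia = 0.0
    ccent = 0.0
    for i in range(L):
        for j in range(L):
            c = C[i, j]
            if c <= 0.0:
                continue
            p = c / total
            d = float(i - j)
            energy += p * p
            idm += p / (1.0 + d * d)
            ent -= p * np.log2(p)
            inertia += d * d * p
            sxy += (i + 1.0) * (j + 1.0) * p
            t = (i + 1.0 - mu) + (j + 1.0 - mu)
            t3 = t * t * t
            shade += t3 * p
            prom += t3 * t * p
            ccent += (i + 1.0 - mu) * (j + 1.0 - mu) * p
    if var > 1e-12:
        hcorr = (sxy - mu * mu) / var
        corr = ccent / var
    else:
        hcorr = 0.0
        corr = 0.0
    out[0] = energy
    out[1] = idm
    out[2] = ent
    out[3] = hcorr
    out[4] = shade
    out[5] = prom
    out[6] = inertia
    out[7] = corr
    return total


@njit(cache=True)
def _glrlm_scalars(R, out):
    """10 run-length statistics from a count matrix R (levels x lengths).

    Order: SRE, LRE, GLN, RLN, LGLRE, HGLRE, SRLGLE, SRHGLE, LRLGLE, LRHGLE.
    Degenerate (no runs): all zero. Returns the total run count.
    """
    L = R.shape[0]
    W = R.shape[1]
    nr = 0.0
    for i in range(L):
        for l in range(W):
            nr += R[i, l]
    if nr <= 0.0:
        for m in range(N_GLRLM):
            out[m] = 0.0
        return 0.0
    sre = lre = lglre = hglre = 0.0
    srlgle = srhgle = lrlgle = lrhgle = 0.0
    gln = rln = 0.0
    for i in range(L):
        lvl = (i + 1.0) ** 2
        row = 0.0
        for l in range(W):
            r = R[i, l]
            if r <= 0.0:
                continue
            row += r
            ln = (l + 1.0) ** 2
            sre += r / ln
            lre += r * ln
            lglre += r / lvl
            hglre += r * lvl
            srlgle += r / (ln * lvl)
            srhgle += r * lvl / ln
            lrlgle += r * ln / lvl
            lrhgle += r * ln * lvl
        gln += row * row
    for l in range(W):
        col = 0.0
        for i in range(L):
            col += R[i, l]
        rln += col * col
    out[0] = sre / nr
    out[1] = lre / nr
    out[2] = gln / nr
    out[3] = rln / nr
    out[4] = lglre / nr
    out[5] = hglre / nr
    out[6] = srlgle / nr
    out[7] = srhgle / nr
    out[8] = lrlgle / nr
    out[9] = lrhgle / nr
    return nr


@njit(cache=True)
def glcm_window_counts(levels, c0, c1, c2, offsets, num_levels, half, C):
    """Accumulate symmetric pair counts for one window into C (zeroed here)."""
    d0, d1, d2 = levels.shape
    lo0 = max(0, c0 - half)
    hi0 = min(d0, c0 + half + 1)
    lo1 = max(0, c1 - half)
    hi1 = min(d1, c1 + half + 1)
    lo2 = max(0, c2 - half)
    hi2 = min(d2, c2 + half + 1)
    C[:, :] = 0.0
    for o in range(offsets.shape[0]):
        o0 = offsets[o, 0]
        o1 = offsets[o, 1]
        o2 = offsets[o, 2]
        for a0 in range(lo0, hi0):
            b0 = a0 + o0
            if b0 < lo0 or b0 >= hi0:
                continue
            for a1 in range(lo1, hi1):
                b1 = a1 + o1
                if b1 < lo1 or b1 >= hi1:
                    continue
                for a2 in range(lo2, hi2):
                    b2 = a2 + o2
                    if b2 < lo2 or b2 >= hi2:
                        continue
                    la = levels[a0, a1, a2]
                    if la == 0:
                        continue
                    lb = levels[b0, b1, b2]
                    if lb == 0:
                        continue
                    C[la - 1, lb - 1] += 1.0
                    C[lb - 1, la - 1] += 1.0


@njit(cache=True)
def glrlm_window_counts(levels, c0, c1, c2, directions, num_levels, half, R):
    """Accumulate maximal-run counts for one window into R (zeroed here)."""
    d0, d1, d2 = levels.shape
    lo0 = max(0, c0 - half)
    hi0 = min(d0, c0 + half + 1)
    lo1 = max(0, c1 - half)
    hi1 = min(d1, c1 + half + 1)
    lo2 = max(0, c2 - half)
    hi2 = min(d2, c2 + half + 1)
    W = R.shape[1]
    R[:, :] = 0.0
    for o in range(directions.shape[0]):
        v0 = directions[o, 0]
        v1 = directions[o, 1]
        v2 = directions[o, 2]
        for s0 in range(lo0, hi0):
            for s1 in range(lo1, hi1):
                for s2 in range(lo2, hi2):
                    lv = levels[s0, s1, s2]
                    if lv == 0:
                        continue
                    p0 = s0 - v0
                    p1 = s1 - v1
                    p2 = s2 - v2
                    if (
                        lo0 <= p0 < hi0
                        and lo1 <= p1 < hi1
                        and lo2 <= p2 < hi2
                        and levels[p0, p1, p2] == lv
                    ):
                        continue  # not a run start
                    ln = 1
                    q0 = s0 + v0
                    q1 = s1 + v1
                    q2 = s2 + v2
                    while (
                        lo0 <= q0 < hi0
                        and lo1 <= q1 < hi1
                        and lo2 <= q2 < hi2
                        and levels[q0, q1, q2] == lv
                    ):
                        ln += 1
                        q0 += v0
                        q1 += v1
                        q2 += v2
                    if ln > W:
                        ln = W
                    R[lv - 1, ln - 1] += 1.0


@njit(cache=True)
def texture_feature_maps(levels, idx, offsets, directions, num_levels, window):
    """Windowed GLCM+GLRLM features at each ROI voxel.

    Returns (features (N, 18), n_degenerate) where columns 0..7 are the GLCM
    scalars and 8..17 the GLRLM scalars; a window is degenerate when it has
    no valid co-occurrence pair.
    """
    half = window // 2
    N = idx.shape[0]
    feats = np.zeros((N, N_GLCM + N_GLRLM))
    C = np.zeros((num_levels, num_levels))
    R = np.zeros((num_levels, window))
    gout = np.zeros(N_GLCM)
    rout = np.zeros(N_GLRLM)
    n_degenerate = 0
    for n in range(N):
        c0 = idx[n, 0]
        c1 = idx[n, 1]
        c2 = idx[n, 2]
        glcm_window_counts(levels, c0, c1, c2, offsets, num_levels, half, C)
        npairs = _glcm_scalars(C, gout)
        glrlm_window_counts(levels, c0, c1, c2, directions, num_levels, half, R)
        _glrlm_scalars(R, rout)
        if npairs <= 0.0:
            n_degenerate += 1
        for m in range(N_GLCM):
            feats[n, m] = gout[m]
        for m in range(N_GLRLM):
            feats[n, N_GLCM + m] = rout[m]
    return feats, n_degenerate


@njit(cache=True)
def glrlm_volume_counts(levels, directions, num_levels, max_len):
    """Whole-volume maximal-run counts (used by classical aggregation)."""
    d0, d1, d2 = levels.shape
    R = np.zeros((num_levels, max_len))
    for o in range(directions.shape[0]):
        v0 = directions[o, 0]
        v1 = directions[o, 1]
        v2 = directions[o, 2]
        for s0 in range(d0):
            for s1 in range(d1):
                for s2 in range(d2):
                    lv = levels[s0, s1, s2]
                    if lv == 0:
                        continue
                    p0 = s0 - v0
                    p1 = s1 - v1
                    p2 = s2 - v2
                    if (
                        0 <= p0 < d0
                        and 0 <= p1 < d1
                        and 0 <= p2 < d2
                        and levels[p0, p1, p2] == lv
                    ):
                        continue
                    ln = 1
                    q0 = s0 + v0
                    q1 = s1 + v1
                    q2 = s2 + v2
                    while (
                        0 <= q0 < d0
                        and 0 <= q1 < d1
                        and 0 <= q2 < d2
                        and levels[q0, q1, q2] == lv
                    ):
                        ln += 1
                        q0 += v0
                        q1 += v1
                        q2 += v2
                    if ln > max_len:
                        ln = max_len
                    R[lv - 1, ln - 1] += 1.0
    return R
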