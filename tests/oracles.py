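"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's vectorised code paths: per-voxel
Python loops, full permutation enumeration, and index arithmetic only.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def pervoxel_voisets(ct, psma, naf, hu_skeleton=150.0, hu_sclerosis=600.0, suv_psma=3.0, suv_naf=10.0):
    """Build all eight VOI masks by evaluating the predicates voxel by voxel."""
    shape = ct.shape
    masks = {
        name: np.zeros(shape, dtype=bool)
        for name in (
            "Skeleton", "Skeleton600", "PSMA_PET_3", "NaF_PET_10",
            "NaF10_PSMA3", "Scl_PSMA3", "Scl_NaF10", "Scl_NaF10_PSMA3",
        )
    }
    for i in range(shape[0]):
        for j in range(shape[1]):
            for k in range(shape[2]):
                skel = ct[i, j, k] > hu_skeleton
                scl = ct[i, j, k] > hu_sclerosis
                pp = skel and psma[i, j, k] > suv_psma
                nf = skel and naf[i, j, k] > suv_naf
                masks["Skeleton"][i, j, k] = skel
                masks["Skeleton600"][i, j, k] = scl
                masks["PSMA_PET_3"][i, j, k] = pp
                masks["NaF_PET_10"][i, j, k] = nf
                masks["NaF10_PSMA3"][i, j, k] = pp and nf
                masks["Scl_PSMA3"][i, j, k] = pp and scl
                masks["Scl_NaF10"][i, j, k] = nf and scl
                masks["Scl_NaF10_PSMA3"][i, j, k] = pp and nf and scl
    return masks


def sum_form_burden(pet_values, mask, spacing):
    """Burden score as the per-voxel sum of SUV x voxel volume (L)."""
    voxel_l = spacing[0] * spacing[1] * spacing[2] / 1e6
    total = 0.0
    for v, m in zip(pet_values.ravel(), mask.ravel()):
        if m:
            total += float(v) * voxel_l
    return total


def count_volume_ml(mask, spacing):
    n = 0
    for m in mask.ravel():
        if m:
            n += 1
    return n * spacing[0] * spacing[1] * spacing[2] / 1000.0


def mannwhitney_enumeration(a, b):
    """Exact two-sided Mann-Whitney p by enumerating all group labelings."""
    a, b = list(map(float, a)), list(map(float, b))
    pool = a + b
    n1 = len(a)

    def ustat(sel: set) -> float:
        aa = [pool[i] for i in sel]
        bb = [pool[i] for i in range(len(pool)) if i not in sel]
        gt = sum(1.0 for x in aa for y in bb if x > y)
        eq = sum(0.5 for x in aa for y in bb if x == y)
        return gt + eq

    u_obs = ustat(set(range(n1)))
    us = [ustat(set(c)) for c in combinations(range(len(pool)), n1)]
    ge = sum(1 for u in us if u >= u_obs) / len(us)
    le = sum(1 for u in us if u <= u_obs) / len(us)
    return u_obs, min(1.0, 2.0 * min(ge, le))


def shifted_nearest(values, shift_vox, fill):
    """Index-shift resampling oracle: out[i] = values[i + shift] or fill."""
    out = np.full_like(values, fill, dtype=float)
    nx, ny, nz = values.shape
    sx, sy, sz = shift_vox
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                ii, jj, kk = i + sx, j + sy, k + sz
                if 0 <= ii < nx and 0 <= jj < ny and 0 <= kk < nz:
                    out[i, j, k] = values[ii, jj, kk]
    return out
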