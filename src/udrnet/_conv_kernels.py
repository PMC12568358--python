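"""Numba kernels for stride-1 3D cross-correlation and its gradients.

The loop nest keeps the K*K*Ci input rows needed for one output row in L1
and vectorizes over the contiguous last axis, so DRAM traffic stays near
"read input once, write output once" instead of the 27x blow-up of an
im2col materialization.  ``fastmath`` only fixes a (deterministic) SIMD
reduction order; results are reproducible run to run.

The input-gradient of a correlation is itself a correlation of the padded
upstream gradient with the spatially flipped, channel-transposed kernel, so
``corr3_fwd`` serves both directions (see :mod:`udrnet._autodiff`).
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False, fastmath=True)
def corr3_fwd(xp: np.ndarray, w: np.ndarray, out: np.ndarray) -> None:
    """out[n,co,z,y,x] = sum_{ci,kz,ky,kx} w[co,ci,kz,ky,kx] *
    xp[n,ci,z+kz,y+ky,x+kx]; ``xp`` is pre-padded, ``out`` pre-allocated."""
    n_batch = xp.shape[0]
    ci_n = xp.shape[1]
    co_n = w.shape[0]
    k = w.shape[2]
    d, h, wd = out.shape[2], out.shape[3], out.shape[4]
    acc = np.empty(wd, dtype=np.float32)
    for n in range(n_batch):
        for z in range(d):
            for y in range(h):
                for co in range(co_n):
                    acc[:] = 0.0
                    for ci in range(ci_n):
                        for kz in range(k):
                            for ky in range(k):
                                row = xp[n, ci, z + kz, y + ky]
                                for kx in range(k):
                                    wv = w[co, ci, kz, ky, kx]
                                    for x in range(wd):
                                        acc[x] += wv * row[kx + x]
                    out[n, co, z, y, :] = acc


@njit(cache=False, fastmath=True)
def corr3_grad_w(xp: np.ndarray, go: np.ndarray, gw: np.ndarray) -> None:
    """gw[co,ci,kz,ky,kx] += sum_{n,z,y,x} go[n,co,z,y,x] *
    xp[n,ci,z+kz,y+ky,x+kx]; ``gw`` pre-zeroed."""
    n_batch = xp.shape[0]
    ci_n = xp.shape[1]
    co_n = go.shape[1]
    k = gw.shape[2]
    d, h, wd = go.shape[2], go.shape[3], go.shape[4]
    for n in range(n_batch):
        for z in range(d):
            for y in range(h):
                for co in range(co_n):
                    grow = go[n, co, z, y]
                    for ci in range(ci_n):
                        for kz in range(k):
                            for ky in range(k):
                                row = xp[n, ci, z + kz, y + ky]
                                for kx in range(k):
                                    s = np.float32(0.0)
                                    for x in range(wd):
                                        s += grow[x] * row[kx + x]
                                    gw[co, ci, kz, ky, kx] += s
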