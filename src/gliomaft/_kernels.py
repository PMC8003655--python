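"""JIT-compiled 3x3x3 convolution kernels.

Single-threaded direct convolutions (numba, ``cache=True``) used by the
network engine. All kernels take the *padded* input (1 voxel of zero
padding per spatial side) and float32 arrays; they are deterministic
run-to-run because no threading or atomics are involved.
"""
from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, fastmath=True)
def conv3d_forward(xp, w, b):
    """Direct 3x3x3 convolution.

    xp : (cin, D+2, H+2, W+2) zero-padded input
    w  : (cout, cin, 3, 3, 3)
    b  : (cout,)
    returns (cout, D, H, W)
    """
    cin, dp, hp, wp = xp.shape
    d, h, wd = dp - 2, hp - 2, wp - 2
    cout = w.shape[0]
    out = np.empty((cout, d, h, wd), dtype=np.float32)
    for co in range(cout):
        for z in range(d):
            for y in range(h):
                acc = np.full(wd, b[co], dtype=np.float32)
                for ci in range(cin):
                    for dz in range(3):
                        for dy in range(3):
                            row = xp[ci, z + dz, y + dy]
                            w0 = w[co, ci, dz, dy, 0]
                            w1 = w[co, ci, dz, dy, 1]
                            w2 = w[co, ci, dz, dy, 2]
                            for x in range(wd):
                                acc[x] += w0 * row[x] + w1 * row[x + 1] + w2 * row[x + 2]
                out[co, z, y] = acc
    return out


@njit(cache=True, fastmath=True)
def conv3d_grad_weights(xp, gy):
    """Weight/bias gradients of :func:`conv3d_forward`.

    xp : (cin, D+2, H+2, W+2) the padded forward input
    gy : (cout, D, H, W) gradient w.r.t. the output
    returns (dw (cout, cin, 3, 3, 3), db (cout,))
    """
    cin = xp.shape[0]
    cout, d, h, wd = gy.shape
    dw = np.zeros((cout, cin, 3, 3, 3), dtype=np.float32)
    db = np.zeros(cout, dtype=np.float32)
    for co in range(cout):
        s = np.float32(0.0)
        for z in range(d):
            for y in range(h):
                g = gy[co, z, y]
                for x in range(wd):
                    s += g[x]
                for ci in range(cin):
                    for dz in range(3):
                        for dy in range(3):
                            row = xp[ci, z + dz, y + dy]
                            a0 = np.float32(0.0)
                            a1 = np.float32(0.0)
                            a2 = np.float32(0.0)
                            for x in range(wd):
                                gv = g[x]
                                a0 += gv * row[x]
                                a1 += gv * row[x + 1]
                                a2 += gv * row[x + 2]
                            dw[co, ci, dz, dy, 0] += a0
                            dw[co, ci, dz, dy, 1] += a1
                            dw[co, ci, dz, dy, 2] += a2
        db[co] = s
    return dw, db


def conv3d_grad_input(gy, w):
    """Input gradient: full correlation of gy with the flipped kernel.

    Implemented by re-using :func:`conv3d_forward` with the kernel
    transposed over the channel axes and flipped spatially.
    """
    cout = w.shape[0]
    wt = np.ascontiguousarray(w.transpose(1, 0, 2, 3, 4)[:, :, ::-1, ::-1, ::-1])
    c, d, h, wd = gy.shape
    gyp = np.zeros((c, d + 2, h + 2, wd + 2), dtype=np.float32)
    gyp[:, 1:-1, 1:-1, 1:-1] = gy
    zb = np.zeros(w.shape[1], dtype=np.float32)
    return conv3d_forward(gyp, wt, zb)
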