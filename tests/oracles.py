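"""Independent brute-force recomputations used as oracles.

Everything here is deliberately naive (explicit python loops over output
pixels, no shared code with mcrn.nn) and is only run on tiny inputs.
Arrays are plain numpy; activations NCHW with N == 1 dropped to (C, H, W).
"""

import numpy as np


def np_prelu(x, alpha):
    out = np.array(x, dtype=float)
    for c in range(out.shape[0]):
        neg = out[c] < 0
        out[c][neg] *= alpha[c]
    return out


def np_sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def np_conv(x, w, b, stride=1, pad=0, dilation=1):
    """x (C,H,W), w (O,C,kh,kw) -> (O,Ho,Wo), loop-based cross-correlation."""
    c, h, wid = x.shape
    o, _, kh, kw = w.shape
    xp = np.zeros((c, h + 2 * pad, wid + 2 * pad))
    xp[:, pad : pad + h, pad : pad + wid] = x
    ho = (h + 2 * pad - dilation * (kh - 1) - 1) // stride + 1
    wo = (wid + 2 * pad - dilation * (kw - 1) - 1) // stride + 1
    out = np.zeros((o, ho, wo))
    for oc in range(o):
        for i in range(ho):
            for j in range(wo):
                acc = b[oc]
                for ic in range(c):
                    for ki in range(kh):
                        for kj in range(kw):
                            acc += (
                                w[oc, ic, ki, kj]
                                * xp[ic, i * stride + ki * dilation, j * stride + kj * dilation]
                            )
                out[oc, i, j] = acc
    return out


def np_deconv(x, w, b, stride, pad):
    """x (C,H,W), w (C_in,C_out,kh,kw) -> (C_out, (H-1)s-2p+kh, ...), scatter-based."""
    c_in, h, wid = x.shape
    _, c_out, kh, kw = w.shape
    hf = (h - 1) * stride + kh
    wf = (wid - 1) * stride + kw
    full = np.zeros((c_out, hf, wf))
    for ic in range(c_in):
        for i in range(h):
            for j in range(wid):
                v = x[ic, i, j]
                for oc in range(c_out):
                    for ki in range(kh):
                        for kj in range(kw):
                            full[oc, i * stride + ki, j * stride + kj] += v * w[ic, oc, ki, kj]
    out = full[:, pad : hf - pad, pad : wf - pad]
    return out + np.asarray(b, dtype=float)[:, None, None]


def np_channel_attention(x, w_down, b_down, w_up, b_up):
    """GAP -> 1x1 reduce -> ReLU -> 1x1 expand -> sigmoid -> per-channel scale."""
    c = x.shape[0]
    desc = np.array([x[i].mean() for i in range(c)])
    hidden = np.maximum(w_down[:, :, 0, 0] @ desc + b_down, 0.0)
    gate = np_sigmoid(w_up[:, :, 0, 0] @ hidden + b_up)
    out = np.array(x, dtype=float)
    for i in range(c):
        out[i] *= gate[i]
    return out


def np_pixel_shuffle(x, r):
    crr, h, w = x.shape
    c = crr // (r * r)
    out = np.zeros((c, h * r, w * r))
    for oc in range(c):
        for i in range(h):
            for j in range(w):
                for di in range(r):
                    for dj in range(r):
                        out[oc, i * r + di, j * r + dj] = x[oc * r * r + di * r + dj, i, j]
    return out


def _cw(cw):
    """Unpack mcrn ConvWeights into plain arrays."""
    alpha = None if cw.alpha is None else np.array(cw.alpha.data)
    return np.array(cw.w.data), np.array(cw.b.data), alpha


def _act(x, alpha):
    return x if alpha is None else np_prelu(x, alpha)


def np_conv_cw(x, cw, stride=1, pad=0, dilation=1):
    w, b, alpha = _cw(cw)
    return _act(np_conv(x, w, b, stride, pad, dilation), alpha)


def np_deconv_cw(x, cw, stride, pad):
    w, b, alpha = _cw(cw)
    return _act(np_deconv(x, w, b, stride, pad), alpha)


def np_forward_one_stage(x, model):
    """Brute-force forward of a 1-up/down-stage model on x (H,W)."""
    cfg = model.config
    spec = cfg.scale_spec
    f = np_conv_cw(x[None, :, :], model.init, pad=1)
    # dilated multichannel residual block
    branches = [
        np_conv_cw(f, cw, pad=r, dilation=r)
        for cw, r in zip(model.dil_branches, cfg.dilation_rates)
    ]
    fused = np_conv_cw(np.concatenate(branches, axis=0), model.dil_fuse)
    l0 = fused + f
    # up-block
    st = model.stages[0]
    l_prev = np_conv_cw(l0, st.reduce_1x1)
    h0 = np_deconv_cw(l_prev, st.p, spec.stride, spec.pad)
    l0p = np_conv_cw(h0, st.g, stride=spec.stride, pad=spec.pad)
    e_l = l0p - l_prev
    h1 = np_deconv_cw(e_l, st.q, spec.stride, spec.pad)
    h = h0 + h1
    # down-block
    h2 = np_conv_cw(h, st.k)
    l1 = np_conv_cw(h2, st.g, stride=spec.stride, pad=spec.pad)
    h3 = np_deconv_cw(l1, st.p, spec.stride, spec.pad)
    e_h = h3 - h2
    l2 = np_conv_cw(e_h, st.g, stride=spec.stride, pad=spec.pad)
    l_out = l1 + l2
    # cascade reduction + residual attention module
    t = np_conv_cw(l_out, model.cascade_reduce)
    y = t
    for rab in model.rabs:
        z = np_conv_cw(y, rab.conv, pad=1)
        wd, bd, _ = _cw(rab.att_down)
        wu, bu, _ = _cw(rab.att_up)
        z = np_channel_attention(z, wd, bd, wu, bu)
        y = z + y
    y = np_conv_cw(y, model.ra_tail, pad=1) + t
    # reconstruction
    pre = np_conv_cw(y, model.recon.pre, pad=1)
    shuffled = np_pixel_shuffle(pre, cfg.scale)
    return np_conv_cw(shuffled, model.recon.post, pad=1)[0]
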