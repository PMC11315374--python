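"""Independent explicit-loop reference implementations of the fusion blocks.

These are deliberately written as straight-line numpy loops over plain
arrays — no Tensor graph, no shared helpers with the package — so that
agreement with the vectorised implementations is a genuine cross-check.
Parameters are read off the blocks as raw arrays.
"""

import numpy as np


def softmax_1d(v):
    e = np.exp(v - v.max())
    return e / e.sum()


def conv2d_loops(x, w, b, stride=1, padding=0):
    """Direct quadruple-loop cross-correlation; x: (C,H,W), w: (O,C,kh,kw)."""
    C, H, W = x.shape
    O, _, kh, kw = w.shape
    xp = np.zeros((C, H + 2 * padding, W + 2 * padding))
    xp[:, padding:padding + H, padding:padding + W] = x
    Ho = (xp.shape[1] - kh) // stride + 1
    Wo = (xp.shape[2] - kw) // stride + 1
    out = np.zeros((O, Ho, Wo))
    for o in range(O):
        for i in range(Ho):
            for j in range(Wo):
                acc = 0.0
                for c in range(C):
                    for a in range(kh):
                        for bb in range(kw):
                            acc += xp[c, i * stride + a, j * stride + bb] * w[o, c, a, bb]
                out[o, i, j] = acc + (b[o] if b is not None else 0.0)
    return out


def aff_loops(x_l, x_g, conv_w, conv_b):
    """Per-pixel evaluation of concat -> 3x3 conv -> 2-way softmax -> blend."""
    C, H, W = x_l.shape
    y = np.concatenate([x_l, x_g], axis=0)
    logits = conv2d_loops(y, conv_w, conv_b, stride=1, padding=1)  # (2,H,W)
    out = np.zeros_like(x_l)
    weights = np.zeros((2, H, W))
    for i in range(H):
        for j in range(W):
            wl, wg = softmax_1d(logits[:, i, j])
            weights[0, i, j], weights[1, i, j] = wl, wg
            for c in range(C):
                out[c, i, j] = x_l[c, i, j] * wl + x_g[c, i, j] * wg
    return out, weights


def batchnorm_eval_loops(x, gamma, beta, mean, var, eps):
    out = np.zeros_like(x)
    for c in range(x.shape[0]):
        out[c] = (x[c] - mean[c]) / np.sqrt(var[c] + eps) * gamma[c] + beta[c]
    return out


def hmu_loops(x, hmu):
    """Unrolled single-image evaluation of the staged HMU computation.

    Reads parameters directly from an eval-mode `lgnet.fusion.HMU`.
    x: (C, H, W).
    """
    cfg = hmu.cfg
    y = conv2d_loops(x, hmu.expand.weight.data, hmu.expand.bias.data,
                     padding=cfg.kernel_size // 2)
    w, p = hmu.group_width, hmu.part_width
    carry = None
    parts2, parts3 = [], []
    for j in range(cfg.groups):
        gj = y[j * w:(j + 1) * w]
        inp = gj if carry is None else np.concatenate([carry, gj], axis=0)
        conv = hmu.group_convs[j]
        out = conv2d_loops(inp, conv.weight.data, conv.bias.data,
                           padding=cfg.kernel_size // 2)
        carry = out[0:p]
        parts2.append(out[p:2 * p])
        parts3.append(out[2 * p:3 * p])
    cat2 = np.concatenate(parts2, axis=0)
    logits = conv2d_loops(cat2, hmu.modulate.weight.data, hmu.modulate.bias.data)
    if cfg.modulation_activation == "sigmoid":
        alpha = 1.0 / (1.0 + np.exp(-logits))
    else:
        alpha = (np.tanh(logits) + 1.0) / 2.0
    content = alpha * np.concatenate(parts3, axis=0)
    t_out = conv2d_loops(content, hmu.proj_out.weight.data, hmu.proj_out.bias.data,
                         padding=cfg.kernel_size // 2)
    n_out = batchnorm_eval_loops(t_out, hmu.norm.gamma.data, hmu.norm.beta.data,
                                 hmu.norm.running_mean, hmu.norm.running_var,
                                 hmu.norm.eps)
    residual = np.maximum(x, 0) if cfg.residual_activation == "relu" else x
    return residual + n_out


def hmuff_loops(x1, x2, hmuff):
    """Explicit loop over every (s1, s2) position pair of the fusion math.

    Reads its two HMU submodules from an eval-mode `lgnet.fusion.HMUFF`.
    x1: (C, H1, W1), x2: (C, H2, W2).
    """
    C, H1, W1 = x1.shape
    _, H2, W2 = x2.shape
    h1 = hmu_loops(x1, hmuff.hmu1)
    h2 = hmu_loops(x2, hmuff.hmu2)
    S1, S2 = H1 * W1, H2 * W2
    fh1 = h1.reshape(C, S1)
    fh2 = h2.reshape(C, S2)
    E = np.zeros((S1, S2))
    for s1 in range(S1):
        for s2 in range(S2):
            E[s1, s2] = sum(fh1[c, s1] * fh2[c, s2] for c in range(C))
    E = E / hmuff.temperature
    md_rows = np.zeros_like(E)
    for s1 in range(S1):
        md_rows[s1, :] = softmax_1d(-E[s1, :])
    md_cols = np.zeros_like(E)
    for s2 in range(S2):
        md_cols[:, s2] = softmax_1d(-E[:, s2])
    f12 = np.zeros((C, S1))
    for s1 in range(S1):
        for c in range(C):
            f12[c, s1] = sum(md_rows[s1, s2] * fh2[c, s2] for s2 in range(S2))
    f21 = np.zeros((C, S2))
    for s2 in range(S2):
        for c in range(C):
            f21[c, s2] = sum(md_cols[s1, s2] * fh1[c, s1] for s1 in range(S1))
    x12 = x1 + f12.reshape(C, H1, W1)
    x21 = x2 + f21.reshape(C, H2, W2)
    return x12, x21


def cross_entropy_loops(logits, labels):
    """Scalar softmax + negative log-likelihood, averaged over the batch."""
    total = 0.0
    for row, lab in zip(logits, labels):
        p = softmax_1d(row)
        total += -np.log(p[lab])
    return total / len(labels)
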