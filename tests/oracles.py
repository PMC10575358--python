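"""Independent loop-based reference implementations used by the tests.

Everything here is written as a literal, scalar-by-scalar transcription of
the attention equations and evaluation formulas, deliberately sharing no
code with the package's vectorised implementations.
"""

import numpy as np

BN_EPS = 1e-3  # batchnorm epsilon used by the detector's conv blocks


def sigmoid(z):
    return 1.0 / (1.0 + np.exp(-np.asarray(z, dtype=np.float64)))


def silu_scalar(z):
    return z * (1.0 / (1.0 + np.exp(-z)))


def channel_attention_oracle(fmap, w0, w1):
    """Mc = sigma(W1 relu(W0 avg) + W1 relu(W0 max)), scalar loops."""
    c, h, w = fmap.shape
    avg = np.zeros(c)
    mx = np.full(c, -np.inf)
    for ci in range(c):
        for y in range(h):
            for x in range(w):
                avg[ci] += fmap[ci, y, x]
                mx[ci] = max(mx[ci], fmap[ci, y, x])
        avg[ci] /= h * w

    def mlp(vec):
        hidden = np.zeros(w0.shape[0])
        for j in range(w0.shape[0]):
            s = 0.0
            for ci in range(c):
                s += w0[j, ci] * vec[ci]
            hidden[j] = max(s, 0.0)
        out = np.zeros(c)
        for ci in range(c):
            s = 0.0
            for j in range(w0.shape[0]):
                s += w1[ci, j] * hidden[j]
            out[ci] = s
        return out

    return sigmoid(mlp(avg) + mlp(mx))


def spatial_attention_oracle(fmap, kernel):
    """Ms = sigma(conv7x7([mean_c; max_c])), naive sliding window, zero pad."""
    c, h, w = fmap.shape
    k = kernel.shape[-1]
    pad = k // 2
    avg = np.zeros((h, w))
    mx = np.full((h, w), -np.inf)
    for y in range(h):
        for x in range(w):
            for ci in range(c):
                avg[y, x] += fmap[ci, y, x]
                mx[y, x] = max(mx[y, x], fmap[ci, y, x])
            avg[y, x] /= c
    stacked = [avg, mx]
    out = np.zeros((h, w))
    for y in range(h):
        for x in range(w):
            s = 0.0
            for ch in range(2):
                for dy in range(k):
                    for dx in range(k):
                        yy, xx = y + dy - pad, x + dx - pad
                        if 0 <= yy < h and 0 <= xx < w:
                            s += kernel[0, ch, dy, dx] * stacked[ch][yy, xx]
            out[y, x] = sigmoid(s)
    return out


def cbam_oracle(fmap, ca_w0, ca_w1, sa_kernel):
    """F'' = Ms(F') (x) F' with F' = Mc(F) (x) F."""
    mc = channel_attention_oracle(fmap, ca_w0, ca_w1)
    fprime = np.empty_like(fmap, dtype=np.float64)
    for ci in range(fmap.shape[0]):
        fprime[ci] = fmap[ci] * mc[ci]
    ms = spatial_attention_oracle(fprime, sa_kernel)
    return fprime * ms[None, :, :]


def naive_conv_bn_silu(x, weight, stride=1, pad=0):
    """One detector conv block at identity BN statistics, scalar loops."""
    cout, cin, kh, kw = weight.shape
    c, h, w = x.shape
    assert c == cin
    ho = (h + 2 * pad - kh) // stride + 1
    wo = (w + 2 * pad - kw) // stride + 1
    out = np.zeros((cout, ho, wo))
    bn_scale = 1.0 / np.sqrt(1.0 + BN_EPS)   # (v - 0) / sqrt(1 + eps)
    for co in range(cout):
        for y in range(ho):
            for x0 in range(wo):
                s = 0.0
                for ci in range(cin):
                    for dy in range(kh):
                        for dx in range(kw):
                            yy = y * stride + dy - pad
                            xx = x0 * stride + dx - pad
                            if 0 <= yy < h and 0 <= xx < w:
                                s += weight[co, ci, dy, dx] * x[ci, yy, xx]
                out[co, y, x0] = silu_scalar(s * bn_scale)
    return out


def res2net_cbam_oracle(x, params):
    """Literal hierarchy: Y1 = X1; Y2 = K2(X2); Yi = Ki(Xi + Y(i-1)); then
    Y = exit_conv(concat), F1 = Mc(Y) (x) Y, F2 = Ms(F1) (x) F1, F = F2 + X."""
    s = params.scale
    z = naive_conv_bn_silu(x, params.entry)
    width = z.shape[0] // s
    groups = [z[i * width:(i + 1) * width] for i in range(s)]
    ys = [groups[0]]
    for i in range(2, s + 1):
        inp = groups[i - 1] if i == 2 else groups[i - 1] + ys[-1]
        ys.append(naive_conv_bn_silu(inp, params.groups[i - 2], pad=1))
    y = naive_conv_bn_silu(np.concatenate(ys, axis=0), params.exit)
    ca, sa = params.cbam
    f2 = cbam_oracle(y, ca.w0, ca.w1, sa.kernel)
    return f2 + x


def average_precision_oracle(tp_flags, n_gt):
    """Hand-summed all-point interpolated AP from a ranked TP/FP list."""
    recalls, precisions = [], []
    tp = fp = 0
    for flag in tp_flags:
        tp += bool(flag)
        fp += not flag
        recalls.append(tp / n_gt)
        precisions.append(tp / (tp + fp))
    ap = 0.0
    prev_r = 0.0
    for i, r in enumerate(recalls):
        p_inter = max(p for p, rr in zip(precisions, recalls) if rr >= r)
        ap += (r - prev_r) * p_inter
        prev_r = r
    return ap


def nms_oracle(records, iou_threshold):
    """Exhaustive suppression: for each class/image group, keep a record iff
    no kept higher-priority record overlaps it at or above the threshold."""
    from birdparts.metrics import box_iou

    keep = []
    groups = {}
    for r in records:
        groups.setdefault((r.image_id, r.class_id), []).append(r)
    for group in groups.values():
        order = sorted(group, key=lambda r: (-r.confidence, r.box))
        kept = []
        for cand in order:
            if not any(box_iou(cand.box, k.box) >= iou_threshold for k in kept):
                kept.append(cand)
        keep.extend(kept)
    return keep


def weight_vectors_oracle(step):
    """Exhaustive 4-nested-loop enumeration of the weight grid."""
    out = []
    for a in range(0, 101, step):
        for b in range(0, 101, step):
            for c in range(0, 101, step):
                for d in range(0, 101, step):
                    if a + b + c + d == 100:
                        out.append((a, b, c, d))
    return out
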