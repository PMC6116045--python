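"""Independent brute-force oracles: literal double-loop implementations of
the feature and metric formulas, kept deliberately naive and separate from
the package code paths they check."""

import math

import numpy as np


def brute_local_dpp(values, n, lam):
    values = np.asarray(values, dtype=float)
    length = values.shape[0]
    width = length // n
    bounds = [(k * width, (k + 1) * width) for k in range(n - 1)]
    bounds.append(((n - 1) * width, length))
    out = []
    for start, end in bounds:
        seg = values[start:end]
        seg_len = end - start
        for j in range(20):
            total = 0.0
            for i in range(seg_len):
                total += seg[i, j]
            out.append(total / seg_len)
        for j in range(20):
            for xi in range(1, lam + 1):
                total = 0.0
                for i in range(seg_len - xi):
                    total += (seg[i, j] - seg[i + xi, j]) ** 2
                out.append(total / (seg_len - xi))
    return np.array(out)


def brute_ac_struct(probs, l_min):
    probs = np.asarray(probs, dtype=float)
    length = probs.shape[0]
    out = []
    means = [sum(probs[i, j] for i in range(length)) / length for j in range(3)]
    for j in range(3):
        for lag in range(1, l_min):
            total = 0.0
            for i in range(length - lag):
                total += (probs[i, j] - means[j]) * (probs[i + lag, j] - means[j])
            out.append(total / (length - lag))
    out.extend(means)
    for j in range(3):
        var = sum((probs[i, j] - means[j]) ** 2 for i in range(length)) / length
        out.append(math.sqrt(var))
    return np.array(out)


def brute_ctd(seq, classes):
    length = len(seq)
    lookup = {}
    for c, members in enumerate(classes):
        for res in members:
            lookup[res] = c
    codes = [lookup[ch] for ch in seq]
    out = [codes.count(c) / length for c in range(3)]
    for a, b in ((0, 1), (0, 2), (1, 2)):
        count = 0
        for i in range(length - 1):
            pair = {codes[i], codes[i + 1]}
            if pair == {a, b}:
                count += 1
        out.append(count / (length - 1) if length > 1 else 0.0)
    for c in range(3):
        positions = [i + 1 for i in range(length) if codes[i] == c]
        if not positions:
            out.extend([0.0] * 5)
            continue
        total = len(positions)
        picks = [
            1,
            math.ceil(0.25 * total),
            math.ceil(0.5 * total),
            math.ceil(0.75 * total),
            total,
        ]
        out.extend(positions[p - 1] / length for p in picks)
    return np.array(out)


def brute_metrics(tp, fp, tn, fn):
    sn = tp / (tp + fn) if tp + fn > 0 else 0.0
    sp = tn / (tn + fp) if tn + fp > 0 else 0.0
    acc = (tp + tn) / (tp + fp + tn + fn)
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom > 0 else 0.0
    return sn, sp, acc, mcc
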