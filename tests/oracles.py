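"""Independent reference implementations used only as test oracles.

Everything here is written against integer decisecond endpoints so interval
arithmetic (including the strict 1.5 s gap rule) is exact, and deliberately
uses naive loops rather than the package's vectorized code paths.
"""

from fractions import Fraction


def brute_force_window_count(n_samples: int, length_n: int, step_n: int):
    """Enumerate every valid fully-contained window start."""
    starts = []
    s = 0
    while s + length_n <= n_samples:
        starts.append(s)
        s += step_n
    return starts


def two_pass_mean_sd(values):
    n = len(values)
    mean = sum(values) / n
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    return mean, var ** 0.5


def sort_percentile(values, q):
    """Linear-interpolation percentile computed from first principles."""
    xs = sorted(values)
    rank = Fraction(q, 100) * (len(xs) - 1)
    lo = int(rank)
    frac = rank - lo
    if lo + 1 < len(xs):
        return float(xs[lo] + frac * (xs[lo + 1] - xs[lo]))
    return float(xs[lo])


# --------------------------------------------------------------------------
# interval algebra in integer deciseconds


def union_ds(intervals):
    ivs = sorted(iv for iv in intervals if iv[1] > iv[0])
    out = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def concat_ds(intervals, gap_ds=15):
    """Merge consecutive intervals with gap strictly below ``gap_ds``."""
    ivs = union_ds(intervals)
    out = []
    for s, e in ivs:
        if out and s - out[-1][1] < gap_ds:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def majority_segment_ds(interval, segments):
    s, e = interval
    best, best_ov = None, 0
    for i, (gs, ge) in enumerate(segments):
        ov = max(0, min(e, ge) - max(s, gs))
        if ov > best_ov:
            best, best_ov = i, ov
    return best


def merge_sit_phases_ds(sit, trans, segments, gap_ds=15):
    """Naive reference for the four merge rules, in deciseconds."""
    segments = union_ds(segments)
    sit = concat_ds(sit, gap_ds)
    trans = concat_ds(trans, gap_ds)
    surviving = set()
    for iv in trans:
        g = majority_segment_ds(iv, segments)
        if g is not None:
            surviving.add(g)
    pieces = {}
    for s, e in sit:
        for g, (gs, ge) in enumerate(segments):
            cs, ce = max(s, gs), min(e, ge)
            if ce > cs and g in surviving:
                pieces.setdefault(g, []).append((cs, ce))
    return [(min(p[0] for p in ps), max(p[1] for p in ps))
            for g, ps in sorted(pieces.items())]
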