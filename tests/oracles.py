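"""Independent reference implementations used only to check the package.

Everything here is written as plainly as possible — nested Python loops, no
numpy — so that agreement with the vectorized implementations is meaningful.
"""

import math


def naive_distance(u, v, metric):
    if metric == "identity":
        return 0.0 if u == v else math.inf
    ds = [abs(a - b) for a, b in zip(u, v)]
    if metric == "taxi":
        return sum(ds)
    if metric == "euclid":
        return math.sqrt(sum(d * d for d in ds))
    if metric == "sup":
        return max(ds)
    raise ValueError(metric)


def naive_plot(data, metric, radius, m):
    tuples = [tuple(data[i:i + m]) for i in range(len(data) - m + 1)]
    n = len(tuples)
    return [[naive_distance(tuples[i], tuples[j], metric) <= radius
             for j in range(n)] for i in range(n)]


def _cyclic_run_cells(line, min_len):
    """Cells in maximal True runs of length >= min_len on a cyclic line."""
    n = len(line)
    if all(line):
        return n if n >= min_len else 0
    start = line.index(False)
    rotated = line[start:] + line[:start]
    total = run = 0
    for v in rotated + [False]:
        if v:
            run += 1
        else:
            if run >= min_len:
                total += run
            run = 0
    return total


def naive_rqa(data, metric, radius, m, min_len=2):
    """(RR, DET, PAL) by triple-loop plot construction and direct run scans."""
    plot = naive_plot(data, metric, radius, m)
    n = len(plot)
    true_cells = sum(plot[i][j] for i in range(n) for j in range(n))
    off_true = true_cells - n
    rr = off_true / (n * n - n)
    det_num = 0
    for o in range(1, n):
        line = [plot[i][(i + o) % n] for i in range(n)]
        det_num += _cyclic_run_cells(line, min_len)
    det = det_num / off_true if off_true else 0.0
    pal_num = 0
    for s in range(n):
        line = [plot[i][(s - i) % n] for i in range(n)]
        pal_num += _cyclic_run_cells(line, min_len)
    pal = pal_num / true_cells if true_cells else 0.0
    return rr, det, pal


def naive_match_positions(data, pattern):
    """Exact gap-free pattern positions by substring scan."""
    m = len(pattern)
    return [i for i in range(len(data) - m + 1)
            if list(data[i:i + m]) == list(pattern)]


def best_two_partition_1d(values):
    """Optimal 2-clustering of sorted 1-D values by exhaustive split search."""
    values = sorted(values)

    def ss(chunk):
        mu = sum(chunk) / len(chunk)
        return sum((v - mu) ** 2 for v in chunk)

    best = None
    for cut in range(1, len(values)):
        left, right = values[:cut], values[cut:]
        cost = ss(left) + ss(right)
        if best is None or cost < best[0]:
            best = (cost, set(left), set(right))
    return best[1], best[2]
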