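"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written without reference to the package's
own algorithms: path enumeration instead of dynamic programming, full
excursion-interval scans instead of early-stopping walks, explicit
geometry instead of vectorized shortcuts.
"""

import numpy as np
from scipy.special import logsumexp
from scipy.stats import gamma as gamma_dist


def enumerate_hmm(init, trans, means, shapes, obs):
    """All-path enumeration: returns (best path, best log-prob, total log-prob).

    The best path is the argmax over every state sequence; numpy's argmax
    keeps the first (lexicographically smallest) maximizer, matching a
    lower-state-index tie-break.
    """
    S = len(init)
    T, C = obs.shape
    logb = np.zeros((T, S))
    for s in range(S):
        for c in range(C):
            logb[:, s] += gamma_dist.logpdf(obs[:, c], a=shapes[s, c], scale=means[s, c] / shapes[s, c])
    paths = np.stack(
        np.meshgrid(*[np.arange(S)] * T, indexing="ij"), axis=-1
    ).reshape(-1, T)  # (S^T, T), lexicographic order
    lp = np.log(init)[paths[:, 0]] + logb[0, paths[:, 0]]
    for t in range(1, T):
        lp = lp + np.log(trans)[paths[:, t - 1], paths[:, t]] + logb[t, paths[:, t]]
    best = int(np.argmax(lp))
    return paths[best], float(lp[best]), float(logsumexp(lp))


def residence_time_bruteforce(x, y, t_h, i, radius, max_gap_h):
    """Residence time at fix i by scanning ALL inside/outside intervals.

    Builds the full list of circle-crossing times of the linearly
    interpolated distance-to-centre series, then reads off the first
    disqualifying excursion (> max_gap_h outside) on each side of t_i.
    Returns hours (forward + backward), truncation treated exactly as the
    spec of the metric: an unresolved track-end excursion stops at its exit
    time; ending inside accumulates to the track end.
    """
    d = np.hypot(np.asarray(x) - x[i], np.asarray(y) - y[i])
    n = len(d)

    # Outside excursions as (exit_time, entry_time_or_None) pairs, full track.
    excursions = []
    # An excursion touching a data boundary has an unknown true extent; mark
    # the unknown end None (accumulation stops at the known crossing).
    t_exit = None
    for j in range(n - 1):
        a, b = d[j], d[j + 1]
        if a <= radius < b:
            t_exit = t_h[j] + (radius - a) / (b - a) * (t_h[j + 1] - t_h[j])
        elif a > radius >= b:
            excursions.append((t_exit, t_h[j] + (radius - a) / (b - a) * (t_h[j + 1] - t_h[j])))
            t_exit = None
    if t_exit is not None:
        excursions.append((t_exit, None))

    ti = t_h[i]

    def side_time(forward):
        if forward:
            cand = [e for e in excursions if e[0] is not None and e[0] >= ti]
            cand.sort(key=lambda e: e[0])
        else:
            cand = [e for e in excursions if e[1] is not None and e[1] <= ti]
            cand.sort(key=lambda e: -e[1])
        for exit_t, entry_t in cand:
            if forward:
                end_of_data = entry_t is None
                duration = (t_h[-1] - exit_t) if end_of_data else (entry_t - exit_t)
                if end_of_data:
                    return abs(exit_t - ti)  # truncated or resolved: stop at exit
                if duration > max_gap_h:
                    return abs(exit_t - ti)
            else:
                start_of_data = exit_t is None
                duration = (entry_t - t_h[0]) if start_of_data else (entry_t - exit_t)
                if start_of_data:
                    return abs(ti - entry_t)
                if duration > max_gap_h:
                    return abs(ti - entry_t)
        return (t_h[-1] - ti) if forward else (ti - t_h[0])

    return side_time(True) + side_time(False)


def point_segment_distance(px, py, ax, ay, bx, by):
    """Plain Euclidean distance from a point to a segment."""
    vx, vy = bx - ax, by - ay
    L2 = vx * vx + vy * vy
    if L2 == 0:
        return np.hypot(px - ax, py - ay)
    s = np.clip(((px - ax) * vx + (py - ay) * vy) / L2, 0.0, 1.0)
    return np.hypot(px - (ax + s * vx), py - (ay + s * vy))
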