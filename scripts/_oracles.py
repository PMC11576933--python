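"""Brute-force oracles used by the acceptance script (independent of the
package's implementations)."""

import itertools

import numpy as np


def brute_dsc(a, b):
    a, b = a.astype(bool), b.astype(bool)
    if a.sum() + b.sum() == 0:
        return 1.0
    return 2.0 * np.logical_and(a, b).sum() / (a.sum() + b.sum())


def brute_asd(a, b, spacing):
    def surface(mask):
        pts = []
        for p in np.argwhere(mask):
            for ax in range(mask.ndim):
                for d in (-1, 1):
                    q = p.copy()
                    q[ax] += d
                    if (q < 0).any() or (q >= np.array(mask.shape)).any() or not mask[tuple(q)]:
                        pts.append(p)
                        break
                else:
                    continue
                break
        return np.array(pts) * np.asarray(spacing)

    sa, sb = surface(a), surface(b)
    d_ab = [min(np.linalg.norm(p - q) for q in sb) for p in sa]
    d_ba = [min(np.linalg.norm(p - q) for q in sa) for p in sb]
    return float(np.mean(d_ab + d_ba))


def exhaustive_wilcoxon_p(diff):
    diff = np.asarray(diff, dtype=float)
    ranks = np.argsort(np.argsort(np.abs(diff))) + 1.0
    w_obs = ranks[diff > 0].sum()
    total = ranks.sum()
    stats = []
    for signs in itertools.product([0, 1], repeat=len(diff)):
        stats.append(sum(r for s, r in zip(signs, ranks) if s))
    stats = np.asarray(stats, dtype=float)
    m = total / 2
    p = np.mean(np.abs(stats - m) >= abs(w_obs - m) - 1e-12)
    return min(1.0, p), min(w_obs, total - w_obs)
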