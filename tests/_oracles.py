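"""Independent brute-force transcription of the PU ensemble scoring rule.

Used by the unit and acceptance suites; shares no code with the package
implementation (explicit loops over attribute subsets and value tuples).
"""

import itertools

import numpy as np


def pande_brute_force(dataset, alpha, n, x, m=1.0):
    """Returns ((score0, score1), fallback_depth) for instance x."""
    X, s = dataset.X, dataset.s
    N = X.shape[0]
    n_lab = int(s.sum())
    k = X.shape[1]
    arities = X.max(axis=0)
    r = alpha * N / n_lab

    def count(attrs, vals, labelled_only=False):
        mask = np.ones(N, bool)
        for a, v in zip(attrs, vals):
            mask &= X[:, a] == v
        if labelled_only:
            mask &= s == 1
        return int(mask.sum())

    def neg_count(attrs, vals):
        return max(count(attrs, vals) - r * count(attrs, vals, True), 0.0)

    def level_scores(t):
        score = {0: 0.0, 1: 0.0}
        any_delta = False
        for S in itertools.combinations(range(k), t):
            vS = tuple(x[a] for a in S)
            if count(S, vS) == 0:
                continue  # delta(x_S) = 0
            any_delta = True
            ncells = int(np.prod([arities[a] for a in S])) if S else 1
            p1 = alpha * (count(S, vS, True) + m / ncells) / (n_lab + m)
            neg_total = 0.0
            value_space = (itertools.product(*[range(1, arities[a] + 1) for a in S])
                           if S else [()])
            for cell in value_space:
                neg_total += neg_count(S, cell)
            p0 = (1 - alpha) * (neg_count(S, vS) + m / ncells) / (neg_total + m)
            t1, t0 = p1, p0
            for child in range(k):
                if child in S:
                    continue
                v = arities[child]
                attrs = S + (child,)
                vals = vS + (x[child],)
                t1 *= (count(attrs, vals, True) + m / v) / (count(S, vS, True) + m)
                ctx = sum(neg_count(attrs, vS + (vv,)) for vv in range(1, v + 1))
                t0 *= (neg_count(attrs, vals) + m / v) / (ctx + m)
            score[1] += t1
            score[0] += t0
        return score, any_delta

    t = n
    while True:
        sc, ok = level_scores(t)
        if ok or t == 0:
            return sc, n - t
        t -= 1
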