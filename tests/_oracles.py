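"""Independent brute-force oracles, written with direct loops and no shared
code with the package implementation, for cross-checking the i-KNN scores."""

import math

import numpy as np


def brute_sbar(x, labels, k_values=(3, 5, 7, 10), bandwidth=None, standardize=True):
    """Mean informativeness score s-bar per point, by direct enumeration.

    Follows the scoring definition literally: Gaussian similarity
    d = exp(-||dx||^2 / h), eta = fraction of the reference point's k
    neighbors sharing the candidate's label, Lambda = product over the
    neighborhood of (1 - d * opposite-class indicator), normalized
    informativeness, top-M majority vote with ties going to the most
    informative neighbor, binary disagreement score averaged over all
    (k, M) settings.
    """
    x = np.asarray(x, float).copy()
    labels = list(labels)
    n = len(x)
    if standardize:
        for col in range(x.shape[1]):
            mu = x[:, col].mean()
            sd = x[:, col].std()
            x[:, col] = (x[:, col] - mu) / (sd if sd > 0 else 1.0)

    def sqdist(a, b):
        return sum((ai - bi) ** 2 for ai, bi in zip(x[a], x[b]))

    if bandwidth is None:
        ds = [sqdist(i, j) for i in range(n) for j in range(i + 1, n)]
        ds.sort()
        m = len(ds)
        bandwidth = (ds[m // 2] if m % 2 else (ds[m // 2 - 1] + ds[m // 2]) / 2) or 1.0

    def sim(a, b):
        return math.exp(-sqdist(a, b) / bandwidth)

    pairs = [(k, m) for k in k_values for m in range(1, k + 1)]
    sbar = np.zeros(n)
    for i in range(n):
        scores = []
        for k in k_values:
            others = sorted((j for j in range(n) if j != i), key=lambda j: (sqdist(i, j), j))
            nbrs = others[:k]
            mass = []
            for j in nbrs:
                eta = sum(labels[nn] == labels[j] for nn in nbrs) / k
                lam = 1.0
                for nn in nbrs:
                    if labels[nn] != labels[j]:
                        lam *= 1.0 - sim(j, nn)
                mass.append(sim(i, j) ** eta * lam ** (1.0 - eta))
            total = sum(mass)
            probs = [v / total for v in mass] if total > 0 else [1.0 / k] * k
            ranked = sorted(range(k), key=lambda t: (-probs[t], t))
            for m in range(1, k + 1):
                top = [labels[nbrs[t]] for t in ranked[:m]]
                counts = {}
                for lab in top:
                    counts[lab] = counts.get(lab, 0) + 1
                best = max(counts.values())
                leaders = [lab for lab in counts if counts[lab] == best]
                vote = leaders[0] if len(leaders) == 1 else labels[nbrs[ranked[0]]]
                scores.append(0.0 if vote == labels[i] else 1.0)
        sbar[i] = sum(scores) / len(pairs)
    return sbar
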