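"""Independent brute-force oracle for Scott-Knott means grouping.

Recomputes the recursive partition from raw data with its own arithmetic:
the best ordered binary split is found by exhaustive enumeration, the error
mean square comes from a fresh one-way decomposition, and the acceptance rule
is applied with scipy's chi-square quantile.  Used only to cross-check the
package implementation on small fixtures.
"""

import itertools
import math
import string

import numpy as np
from scipy import stats


def scott_knott_oracle(groups: dict, alpha: float = 0.05) -> dict:
    data = {k: np.asarray(v, float) for k, v in groups.items()}
    labels = list(data)
    k_total = len(labels)
    all_vals = np.concatenate(list(data.values()))
    # fresh one-way error mean square
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in data.values())
    nu = len(all_vals) - k_total
    mse = ss_within / nu
    s2_mean = mse * np.mean([1.0 / len(v) for v in data.values()])

    means = {l: float(v.mean()) for l, v in data.items()}
    ordered = sorted(labels, key=lambda l: means[l], reverse=True)

    scale = math.pi / (2 * (math.pi - 2))

    def partition(block: list) -> list:
        if len(block) < 2:
            return [block]
        m = np.array([means[l] for l in block])
        # exhaustive enumeration of every ordered binary split
        candidates = []
        for j in range(1, len(block)):
            g1, g2 = m[:j], m[j:]
            b0 = len(g1) * (g1.mean() - m.mean()) ** 2 + len(g2) * (g2.mean() - m.mean()) ** 2
            candidates.append((b0, j))
        b0, j = max(candidates)
        sigma0 = (((m - m.mean()) ** 2).sum() + nu * s2_mean) / (len(block) + nu)
        lam = scale * b0 / sigma0
        crit = stats.chi2.ppf(1 - alpha, len(block) / (math.pi - 2))
        if lam > crit:
            return partition(block[:j]) + partition(block[j:])
        return [block]

    blocks = partition(ordered)
    letters = {}
    for letter, block in zip(string.ascii_lowercase, blocks):
        for l in block:
            letters[l] = letter
    return letters
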