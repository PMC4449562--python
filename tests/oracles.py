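"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the package's vectorized code paths: the encoder
oracle is a dictionary-based double loop over position pairs, the t-test
oracle evaluates the pooled-variance formula term by term, and the AUC
oracle counts concordant pairs directly.
"""

import math

import numpy as np
from scipy.stats import t as t_dist

STANDARD = "ACDEFGHIKLMNPQRSTVWY"


def brute_force_encode(sequence: str, max_gap: int, alphabet: str = STANDARD) -> np.ndarray:
    l = len(sequence)
    counts: dict[tuple[str, int, str], int] = {}
    for p in range(l):
        for q in range(p + 1, l):
            gap = q - p - 1
            if gap > max_gap:
                continue
            a, b = sequence[p], sequence[q]
            if a in alphabet and b in alphabet:
                counts[(a, gap, b)] = counts.get((a, gap, b), 0) + 1
    vec = np.zeros(400 * (max_gap + 1))
    for (a, gap, b), k in counts.items():
        denom = l - gap - 1
        idx = gap * 400 + alphabet.index(a) * 20 + alphabet.index(b)
        vec[idx] = k / denom
    return vec


def pooled_t_p_value(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided pooled-variance two-sample t-test, evaluated term by term."""
    n1, n2 = len(x), len(y)
    s2 = ((n1 - 1) * np.var(x, ddof=1) + (n2 - 1) * np.var(y, ddof=1)) / (n1 + n2 - 2)
    if s2 == 0.0:
        return 1.0 if np.mean(x) == np.mean(y) else 0.0
    t = (np.mean(x) - np.mean(y)) / math.sqrt(s2 * (1 / n1 + 1 / n2))
    return 2 * t_dist.sf(abs(t), df=n1 + n2 - 2)


def concordant_pair_auc(labels, scores) -> float:
    """AUC as the fraction of (positive, negative) pairs where the positive
    outscores the negative, ties counting 1/2."""
    pos = [s for y, s in zip(labels, scores) if y == 1]
    neg = [s for y, s in zip(labels, scores) if y == -1]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))
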