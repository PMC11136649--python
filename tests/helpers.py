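"""Independent brute-force oracles used by the tests."""

import numpy as np


def brute_force_r2(a, b):
    """Squared Pearson correlation straight from the definition."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.std() == 0 or b.std() == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1] ** 2)


def brute_force_ld_scores(panel, window_bp=100_000):
    """All-pairs LD scores: O(L^2) loop over every variant pair."""
    pos = panel.variants["pos"].to_numpy()
    chrom = panel.variants["chrom"].to_numpy()
    L = panel.n_sites
    scores = np.zeros(L)
    for i in range(L):
        for j in range(L):
            if i == j or chrom[i] != chrom[j]:
                continue
            if abs(int(pos[i]) - int(pos[j])) > window_bp:
                continue
            r2 = brute_force_r2(panel.matrix[i], panel.matrix[j])
            if not np.isnan(r2):
                scores[i] += r2
    return scores
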