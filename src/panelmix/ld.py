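"""Linkage-disequilibrium preservation metrics.

The LD score of a variant is the sum of squared Pearson correlations (r^2)
between its haplotype allele column and every other variant within a
physical window (default +/- 100 kb, inclusive) on the same chromosome.
Comparing per-variant LD scores between an original and a resampled panel
summarises how much local haplotype structure the transform destroyed:

* rho  — Pearson correlation between the two LD-score vectors (pattern
  preservation; 1.0 means the LD landscape is intact up to scale);
* beta — OLS slope of synthetic scores regressed on original scores (with
  intercept), so beta < 1 means a global loss of LD and beta = 1 none.

r^2 is computed on haplotype (not genotype) columns since the panels are
phased.  Monomorphic columns have undefined correlation: they contribute to
nobody's score and are dropped from rho/beta comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .panel import HaplotypePanel

__all__ = [
    "LDProfile",
    "pairwise_r2",
    "ld_scores",
    "ld_score_correlation",
    "ld_score_slope",
    "pairwise_r2_matrix",
    "plot_r2_comparison",
]

DEFAULT_WINDOW_BP = 100_000


@dataclass(frozen=True)
class LDProfile:
    """Per-variant LD scores for one panel.

    ``table`` has columns ``chrom, pos, ld_score, n_neighbors, polymorphic``.
    """

    table: pd.DataFrame
    window_bp: int = DEFAULT_WINDOW_BP

    @property
    def ld_score(self) -> np.ndarray:
        return self.table["ld_score"].to_numpy()

    def polymorphic_scores(self) -> np.ndarray:
        return self.table.loc[self.table["polymorphic"], "ld_score"].to_numpy()

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")

    def __len__(self) -> int:
        return len(self.table)


def pairwise_r2(col_a, col_b) -> float:
    """Squared Pearson correlation of two 0/1 haplotype allele columns.

    Returns NaN when either column is monomorphic (zero variance).
    """
    a = np.asarray(col_a, dtype=np.float64)
    b = np.asarray(col_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("columns must be 1-D and of equal length")
    va = a.var()
    vb = b.var()
    if va == 0.0 or vb == 0.0:
        return float("nan")
    cov = ((a - a.mean()) * (b - b.mean())).mean()
    return float(cov * cov / (va * vb))


def ld_scores(panel: HaplotypePanel, window_bp: int = DEFAULT_WINDOW_BP) -> LDProfile:
    """Per-variant sum of r^2 with all neighbors within ``+/- window_bp``.

    The window bound is inclusive; self is excluded; each pair contributes
    to both endpoints' scores.  Multiallelic sites are treated through the
    0-vs-nonzero allele coding of the matrix.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    chroms = panel.variants["chrom"].to_numpy()
    positions = panel.variants["pos"].to_numpy()
    X = panel.matrix.astype(np.float64)
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.sqrt((Xc * Xc).sum(axis=1))
    poly = norms > 0
    scores = np.zeros(panel.n_sites)
    nnb = np.zeros(panel.n_sites, dtype=np.int64)
    for chrom in pd.unique(chroms):
        idx = np.nonzero(chroms == chrom)[0]
        pos = positions[idx]
        if np.any(np.diff(pos) < 0):
            raise ValueError(f"positions not sorted within {chrom}")
        lo = np.searchsorted(pos, pos - window_bp, side="left")
        hi = np.searchsorted(pos, pos + window_bp, side="right")
        for k, gi in enumerate(idx):
            nb_local = np.arange(lo[k], hi[k])
            nb = idx[nb_local[nb_local != k]]
            nnb[gi] = nb.size
            if not poly[gi] or nb.size == 0:
                continue
            nb = nb[poly[nb]]
            if nb.size == 0:
                continue
            r = (Xc[nb] @ Xc[gi]) / (norms[nb] * norms[gi])
            scores[gi] = float(np.sum(r * r))
    table = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": positions,
            "ld_score": scores,
            "n_neighbors": nnb,
            "polymorphic": poly,
        }
    )
    return LDProfile(table=table, window_bp=int(window_bp))


def _aligned_scores(a: LDProfile, b: LDProfile) -> tuple[np.ndarray, np.ndarray]:
    ka = a.table[["chrom", "pos"]]
    kb = b.table[["chrom", "pos"]]
    if len(ka) != len(kb) or not ka.reset_index(drop=True).equals(
        kb.reset_index(drop=True)
    ):
        raise ValueError("LD profiles cover different variant sets")
    keep = (a.table["polymorphic"] & b.table["polymorphic"]).to_numpy()
    return a.ld_score[keep], b.ld_score[keep]


def ld_score_correlation(profile_a: LDProfile, profile_b: LDProfile) -> float:
    """Pearson rho between two panels' LD-score vectors (shared variants)."""
    x, y = _aligned_scores(profile_a, profile_b)
    if x.size < 2:
        raise ValueError("need at least 2 shared polymorphic variants")
    if np.std(x) == 0 and np.std(y) == 0 and np.allclose(x, y):
        return 1.0
    return float(stats.pearsonr(x, y).statistic)


def ld_score_slope(profile_original: LDProfile, profile_synthetic: LDProfile) -> float:
    """OLS slope beta of synthetic LD scores on original LD scores.

    Fitted with an intercept; beta < 1 reads as a global LD decrease in the
    synthetic panel, beta = 1 as exact preservation up to noise.
    """
    x, y = _aligned_scores(profile_original, profile_synthetic)
    if x.size < 2:
        raise ValueError("need at least 2 shared polymorphic variants")
    if np.var(x) == 0:
        raise ValueError("original LD scores have zero variance; slope undefined")
    return float(stats.linregress(x, y).slope)


def pairwise_r2_matrix(
    panel: HaplotypePanel, start_bp: int | None = None, end_bp: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs r^2 matrix for one region; returns (matrix, positions).

    Monomorphic sites give NaN rows/columns; the diagonal is 1 for
    polymorphic sites.
    """
    pos = panel.variants["pos"].to_numpy()
    mask = np.ones(panel.n_sites, dtype=bool)
    if start_bp is not None:
        mask &= pos >= start_bp
    if end_bp is not None:
        mask &= pos <= end_bp
    X = panel.matrix[mask].astype(np.float64)
    sd = X.std(axis=1)
    Xc = X - X.mean(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc @ Xc.T) / X.shape[1] / np.outer(sd, sd)
    return r * r, pos[mask]


def plot_r2_comparison(panel_a: HaplotypePanel, panel_b: HaplotypePanel,
                       start_bp=None, end_bp=None, ax=None):
    """Triangular r^2 heatmap: panel_a above the diagonal, panel_b below.

    Requires matplotlib (the ``plot`` extra); both panels must cover the
    same variants in the region.
    """
    import matplotlib.pyplot as plt

    ra, pos = pairwise_r2_matrix(panel_a, start_bp, end_bp)
    rb, pos_b = pairwise_r2_matrix(panel_b, start_bp, end_bp)
    if not np.array_equal(pos, pos_b):
        raise ValueError("panels cover different variants in the region")
    combined = np.triu(ra, k=1) + np.tril(rb, k=-1) + np.eye(len(pos))
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    im = ax.imshow(combined, vmin=0, vmax=1, cmap="viridis", origin="upper")
    ax.figure.colorbar(im, ax=ax, label=r"$r^2$")
    ax.set_xlabel("variant index")
    ax.set_ylabel("variant index")
    return ax
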