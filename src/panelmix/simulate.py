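"""Synthetic fixture generation: mosaic panels with tunable LD and toy maps.

Panels come from a founder-mosaic model rather than a full coalescent:
``n_founders`` haplotypes are drawn i.i.d. per site, and each panel
haplotype copies a founder, switching to a uniformly chosen founder between
consecutive sites with probability ``1 - exp(-switch_rate * dbp)``.  A low
switch rate gives long shared founder tracts and hence strong local LD; a
high rate destroys it — exactly the dial the LD-preservation tests need.
Everything is seed-deterministic and valid phased biallelic VCF material.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genetic_map import GeneticMap
from .panel import HaplotypePanel

__all__ = [
    "FixtureSpec",
    "simulate_mosaic_panel",
    "make_toy_map",
    "plant_duplicate_haplotype",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the founder-mosaic panel generator.

    Defaults give a 100-haplotype, 500-site, 1-Mb panel with pronounced
    block LD (mean founder tract ~ 1/switch_rate = 100 kb).
    """

    n_haplotypes: int = 100
    n_sites: int = 500
    span_bp: tuple[int, int] = (1, 1_000_000)
    n_founders: int = 8
    founder_alt_prob: float = 0.3
    switch_rate: float = 1e-5  # per bp
    seed: int = 0
    chromosome: str = "1"

    def __post_init__(self) -> None:
        if self.n_haplotypes < 2 or self.n_haplotypes % 2 != 0:
            raise ValueError("n_haplotypes must be even and >= 2")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if not (1 <= self.n_founders <= self.n_haplotypes):
            raise ValueError("n_founders must be in [1, n_haplotypes]")
        if not (0.0 <= self.founder_alt_prob <= 1.0):
            raise ValueError("founder_alt_prob must be a probability")
        if self.switch_rate < 0:
            raise ValueError("switch_rate must be >= 0")
        if self.span_bp[1] <= self.span_bp[0]:
            raise ValueError("span_bp must be a non-empty range")


def simulate_mosaic_panel(spec: FixtureSpec) -> HaplotypePanel:
    """Generate a phased biallelic panel under the founder-mosaic model."""
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.span_bp
    pos = np.unique(rng.integers(lo, hi + 1, size=spec.n_sites))
    while pos.size < spec.n_sites:  # rare collision top-up keeps L exact
        extra = rng.integers(lo, hi + 1, size=spec.n_sites - pos.size)
        pos = np.unique(np.concatenate([pos, extra]))
    L = pos.size
    founders = (
        rng.random((L, spec.n_founders)) < spec.founder_alt_prob
    ).astype(np.int8)
    gaps = np.diff(pos).astype(np.float64)
    p_switch = -np.expm1(-spec.switch_rate * gaps)
    N = spec.n_haplotypes
    choice = np.empty((L, N), dtype=np.int64)
    choice[0] = rng.integers(0, spec.n_founders, size=N)
    for s in range(1, L):
        switch = rng.random(N) < p_switch[s - 1]
        new = rng.integers(0, spec.n_founders, size=N)
        choice[s] = np.where(switch, new, choice[s - 1])
    matrix = founders[np.arange(L)[:, None], choice]
    variants = pd.DataFrame(
        {
            "chrom": spec.chromosome,
            "pos": pos.astype(np.int64),
            "ref": "A",
            "alt": "C",
        }
    )
    sample_ids = [f"S{i + 1:04d}" for i in range(N // 2)]
    return HaplotypePanel(variants=variants, matrix=matrix, sample_ids=sample_ids)


def make_toy_map(
    span_bp: tuple[int, int],
    total_cM: float,
    shape: str = "constant",
    chromosome: str = "1",
) -> GeneticMap:
    """Toy genetic map over ``span_bp`` with exact total length.

    ``constant``: cM linear in bp.  ``hotspot``: 90% of the genetic length
    packed into the central 10% of the physical span, the rest spread
    evenly — a caricature of a recombination hotspot flanked by coldspots.
    """
    if total_cM < 0:
        raise ValueError("total_cM must be >= 0")
    lo, hi = int(span_bp[0]), int(span_bp[1])
    if hi <= lo:
        raise ValueError("span must be non-empty")
    if shape == "constant":
        bp = np.array([lo, hi], dtype=np.int64)
        cm = np.array([0.0, total_cM])
    elif shape == "hotspot":
        width = hi - lo
        h0 = lo + int(round(0.45 * width))
        h1 = lo + int(round(0.55 * width))
        bp = np.array([lo, h0, h1, hi], dtype=np.int64)
        cm = np.array([0.0, 0.05 * total_cM, 0.95 * total_cM, total_cM])
    else:
        raise ValueError(f"unknown map shape {shape!r}")
    return GeneticMap(chromosome=chromosome, positions_bp=bp, positions_cM=cm)


def plant_duplicate_haplotype(
    panel: HaplotypePanel, source: int, target: int
) -> HaplotypePanel:
    """Copy haplotype column ``source`` over ``target`` (IBD-tracing plant)."""
    n = panel.n_haplotypes
    if not (0 <= source < n and 0 <= target < n):
        raise IndexError("haplotype index out of range")
    out = panel.copy()
    out.matrix[:, target] = out.matrix[:, source]
    return out
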