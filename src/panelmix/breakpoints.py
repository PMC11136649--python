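"""Poisson sampling of recombination breakpoints along a chromosome.

The number of crossover events accumulated when a panel of N haplotypes is
pushed through K generations of meiosis is modelled as a homogeneous Poisson
process on the genetic (cM) scale with expected count

    lambda = L_Morgans * (N/2) * K

where L_Morgans is the chromosome's genetic length in Morgans (cM/100):
each of the N/2 diploid individuals undergoes one meiosis per generation,
and a Morgan is one expected crossover per meiosis.  Sampling is realised as
M ~ Poisson(lambda) followed by M i.i.d. Uniform(0, total_cM) positions,
which has the same law as drawing exponential inter-arrival distances and is
replayable with a fixed RNG draw order.  Genetic positions are converted to
bp through the genetic map, so events concentrate in hotspots.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genetic_map import GeneticMap

__all__ = [
    "SamplerParams",
    "BreakpointSet",
    "sample_breakpoints",
    "recombination_probability",
    "probability_curve",
    "write_breakpoints_bed",
]


@dataclass(frozen=True)
class SamplerParams:
    """Number of simulated generations K, panel haplotype count N, RNG seed."""

    K: int
    N: int
    seed: int

    def __post_init__(self) -> None:
        if self.K < 0:
            raise ValueError("K must be >= 0")
        if self.N < 2:
            raise ValueError("N must be >= 2")
        if self.N % 2 != 0:
            raise ValueError("N must be even (haplotypes come in diploid pairs)")


@dataclass(frozen=True)
class BreakpointSet:
    """Ordered recombination positions plus the parameters that generated them."""

    positions_bp: np.ndarray
    positions_cM: np.ndarray  # on the shifted scale (map start = 0)
    params: SamplerParams
    lam: float

    @property
    def count(self) -> int:
        return int(self.positions_bp.size)

    def __len__(self) -> int:
        return self.count


def expected_events(gmap: GeneticMap, params: SamplerParams) -> float:
    """lambda = total Morgans x (N/2) x K."""
    return (gmap.total_cM / 100.0) * (params.N / 2.0) * params.K


def sample_breakpoints(
    gmap: GeneticMap, params: SamplerParams, rng: np.random.Generator
) -> BreakpointSet:
    """Draw breakpoint positions from the Poisson process on the map.

    RNG draw order (part of the replay contract): (1) one Poisson draw for
    the event count M, (2) M uniform genetic positions.  Positions are then
    sorted; sorting consumes no randomness.
    """
    lam = expected_events(gmap, params)
    m = int(rng.poisson(lam))
    g = np.sort(rng.uniform(0.0, gmap.total_cM, size=m))
    bp = gmap.cM_to_bp(g) if m else np.empty(0, dtype=np.float64)
    return BreakpointSet(
        positions_bp=np.atleast_1d(np.asarray(bp, dtype=np.float64)),
        positions_cM=g,
        params=params,
        lam=lam,
    )


def recombination_probability(length_cM: float, K: int, N=None) -> float:
    """Probability that one given haplotype recombines at least once.

    Each of the Poisson(lambda) events swaps two haplotype slots drawn
    uniformly with replacement, so a given haplotype is involved in one
    event with probability 1 - ((N-1)/N)^2 = (2N-1)/N^2.  Thinning the
    process leaves a Poisson with per-haplotype rate

        lambda_h = (length_cM / 100) * K * (2N - 1) / (2N)

    and the hit probability is 1 - exp(-lambda_h).  Pass ``N=None`` (or
    ``"infinite"``/``inf``) for the large-panel limit (length/100) * K.
    """
    if length_cM < 0 or K < 0:
        raise ValueError("length_cM and K must be non-negative")
    morgans = length_cM / 100.0
    if N is None or N == "infinite" or (isinstance(N, float) and np.isinf(N)):
        rate = morgans * K
    else:
        if N < 2:
            raise ValueError("N must be >= 2")
        rate = morgans * K * (2 * N - 1) / (2 * N)
    return float(-np.expm1(-rate))


def probability_curve(map_lengths_cM, K_values, N=None) -> pd.DataFrame:
    """Grid of per-haplotype recombination probabilities.

    Rows are chromosome genetic lengths (sorted ascending), columns are K
    values; suitable for plotting one curve per chromosome.
    """
    lengths = sorted(float(x) for x in map_lengths_cM)
    ks = list(K_values)
    if not lengths or not ks:
        raise ValueError("map_lengths_cM and K_values must be non-empty")
    data = {
        k: [recombination_probability(L, k, N) for L in lengths] for k in ks
    }
    df = pd.DataFrame(data, index=pd.Index(lengths, name="length_cM"))
    df.columns.name = "K"
    return df


def write_breakpoints_bed(bset: BreakpointSet, chromosome: str, path) -> None:
    """Export breakpoints as 3-column text (chrom, bp, cM) for inspection."""
    df = pd.DataFrame(
        {
            "chrom": chromosome,
            "position_bp": bset.positions_bp,
            "position_cM": bset.positions_cM,
        }
    )
    df.to_csv(path, sep="\t", index=False, header=False, float_format="%.6f")
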