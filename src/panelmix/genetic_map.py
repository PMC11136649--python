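"""Genetic maps: bidirectional interpolation between physical (bp) and genetic (cM) coordinates.

A genetic map is a monotone lookup table relating physical position along a
chromosome (base pairs) to cumulative genetic position (centimorgans, cM).
Recombination events are uniform on the genetic scale, so the map is what
turns a homogeneous Poisson process in cM-space into realistic, hotspot-aware
breakpoint positions in bp-space.

The on-disk dialect is the whitespace-delimited HapMap style: a one-line
header followed by rows of either

    position  rate(cM/Mb)  map(cM)                  (3 columns)
    chromosome  position  rate(cM/Mb)  map(cM)      (4 columns)

The rate column is carried for readability but interpolation uses only the
(position, cumulative cM) pairs.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GeneticMap",
    "GeneticMapError",
    "read_genetic_map",
    "write_genetic_map",
    "make_constant_rate_map",
]


class GeneticMapError(ValueError):
    """Raised for malformed or non-monotone genetic map input."""


@dataclass(frozen=True)
class GeneticMap:
    """Monotone bp <-> cM lookup table for one chromosome.

    Parameters
    ----------
    chromosome
        Chromosome label (e.g. ``"20"`` or ``"chr20"``).
    positions_bp
        Strictly increasing 1-based physical positions.
    positions_cM
        Non-decreasing cumulative genetic positions, same length.
    """

    chromosome: str
    positions_bp: np.ndarray
    positions_cM: np.ndarray

    def __post_init__(self) -> None:
        bp = np.asarray(self.positions_bp, dtype=np.int64)
        cm = np.asarray(self.positions_cM, dtype=np.float64)
        if bp.ndim != 1 or cm.ndim != 1 or bp.shape != cm.shape:
            raise GeneticMapError("positions_bp and positions_cM must be 1-D and equal length")
        if bp.size < 2:
            raise GeneticMapError("a genetic map needs at least 2 entries")
        if np.any(np.diff(bp) <= 0):
            raise GeneticMapError("physical positions must be strictly increasing")
        if np.any(np.diff(cm) < 0):
            raise GeneticMapError("genetic positions must be non-decreasing")
        if not np.all(np.isfinite(cm)):
            raise GeneticMapError("genetic positions must be finite")
        object.__setattr__(self, "positions_bp", bp)
        object.__setattr__(self, "positions_cM", cm)

    @property
    def total_cM(self) -> float:
        """Total genetic length (last cM minus first cM)."""
        return float(self.positions_cM[-1] - self.positions_cM[0])

    @property
    def span_bp(self) -> tuple[int, int]:
        return int(self.positions_bp[0]), int(self.positions_bp[-1])

    def bp_to_cM(self, pos):
        """Map physical position(s) to cumulative cM by linear interpolation.

        Exact at knots; positions outside the mapped interval are clamped to
        the boundary cM value (zero recombination rate off the map).
        """
        return np.interp(pos, self.positions_bp, self.positions_cM)

    def cM_to_bp(self, g):
        """Map genetic position(s) on the shifted scale (map start = 0 cM) to bp.

        Inverse of ``bp_to_cM`` on strictly increasing segments.  On flat
        (zero-rate) segments the leftmost bp with that cM value is returned,
        a deterministic tie-break; breakpoints land there with probability 0.

        Raises
        ------
        GeneticMapError
            If any ``g`` is outside ``[0, total_cM]``.
        """
        g = np.asarray(g, dtype=np.float64)
        scalar = g.ndim == 0
        g = np.atleast_1d(g)
        if np.any(g < 0) or np.any(g > self.total_cM):
            raise GeneticMapError(
                f"genetic position outside [0, {self.total_cM}] cM"
            )
        cm = self.positions_cM - self.positions_cM[0]
        bp = self.positions_bp.astype(np.float64)
        # first knot with cm >= g: exact hits resolve to the leftmost bp of
        # any flat run; otherwise interpolate on the segment [idx-1, idx]
        idx = np.searchsorted(cm, g, side="left")
        idx = np.clip(idx, 0, cm.size - 1)
        out = np.empty_like(g)
        exact = cm[idx] == g
        out[exact] = bp[idx[exact]]
        seg = ~exact
        if np.any(seg):
            hi = idx[seg]
            lo = hi - 1
            frac = (g[seg] - cm[lo]) / (cm[hi] - cm[lo])
            out[seg] = bp[lo] + frac * (bp[hi] - bp[lo])
        return float(out[0]) if scalar else out

    def fingerprint(self) -> str:
        """SHA-256 over the canonical table; identifies the map in metadata."""
        h = hashlib.sha256()
        h.update(self.chromosome.encode())
        h.update(self.positions_bp.tobytes())
        h.update(self.positions_cM.tobytes())
        return h.hexdigest()

    def __len__(self) -> int:
        return int(self.positions_bp.size)


def read_genetic_map(path, chromosome: str | None = None) -> GeneticMap:
    """Parse a HapMap-style genetic map text file.

    Accepts the 3-column (position, rate, cM) and 4-column
    (chromosome, position, rate, cM) dialects, whitespace-delimited with a
    one-line header.  With 4 columns, rows are filtered to ``chromosome``
    (matched with or without a ``chr`` prefix).
    """
    df = pd.read_csv(path, sep=r"\s+", header=0, dtype=str)
    if df.shape[1] not in (3, 4):
        raise GeneticMapError(
            f"expected 3 or 4 whitespace-delimited columns, got {df.shape[1]}"
        )
    if df.shape[1] == 4:
        chrom_col = df.iloc[:, 0].astype(str)
        if chromosome is not None:
            wanted = {chromosome, chromosome.removeprefix("chr"), f"chr{chromosome}"}
            df = df[chrom_col.isin(wanted)]
            label = chromosome
        else:
            labels = chrom_col.unique()
            if len(labels) > 1:
                raise GeneticMapError(
                    "map file covers multiple chromosomes; pass chromosome="
                )
            label = str(labels[0]) if len(labels) else "unknown"
        pos_col, cm_col = 1, 3
    else:
        label = chromosome if chromosome is not None else "unknown"
        pos_col, cm_col = 0, 2
    if len(df) < 2:
        raise GeneticMapError("fewer than 2 usable map rows")
    bp = pd.to_numeric(df.iloc[:, pos_col]).to_numpy(dtype=np.int64)
    cm = pd.to_numeric(df.iloc[:, cm_col]).to_numpy(dtype=np.float64)
    return GeneticMap(chromosome=label, positions_bp=bp, positions_cM=cm)


def write_genetic_map(gmap: GeneticMap, path) -> None:
    """Write a map in the 4-column HapMap dialect (rate recomputed from cM)."""
    bp = gmap.positions_bp
    cm = gmap.positions_cM
    rate = np.zeros_like(cm)
    # rate over the interval starting at each knot, in cM/Mb; last row 0
    dbp = np.diff(bp) / 1e6
    rate[:-1] = np.diff(cm) / dbp
    df = pd.DataFrame(
        {
            "chromosome": gmap.chromosome,
            "position": bp,
            "rate_cM_Mb": rate,
            "map_cM": cm,
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def make_constant_rate_map(gmap: GeneticMap) -> GeneticMap:
    """Constant-rate null map: same bp span, same total cM, linear cM in bp.

    Used to contrast hotspot-aware resampling against a uniform-rate
    assumption; by construction the total genetic length is preserved to
    machine precision (the endpoints are copied, not recomputed).
    """
    first_bp, last_bp = gmap.span_bp
    return GeneticMap(
        chromosome=gmap.chromosome,
        positions_bp=np.array([first_bp, last_bp], dtype=np.int64),
        positions_cM=np.array(
            [gmap.positions_cM[0], gmap.positions_cM[-1]], dtype=np.float64
        ),
    )
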