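"""Forward and reverse haplotype-panel transforms.

The forward transform simulates K generations of descent: breakpoints are
drawn from the Poisson process on the genetic map, the haplotype columns
get one initial random relabelling, and at each breakpoint (walking the
chromosome left to right) two haplotype slots drawn uniformly with
replacement are swapped.  Each emitted site row is the input row re-indexed
by the current slot order, so every output haplotype is a mosaic of input
haplotypes — the allele multiset at every site is exactly preserved while
genome-to-individual links are broken.

The whole event sequence is a pure function of (seed, K, N, genetic map),
so the transform is exactly invertible: the reverse replays the events and
applies the inverse permutation per segment, restoring the original
genotype matrix bit for bit.

RNG contract (per chromosome, and the basis of reversibility):
a fresh numpy PCG64 generator is seeded from ``(seed, crc32(chromosome))``
and consumed in this fixed order:

1. one Poisson draw for the event count M;
2. M uniform genetic positions (sorted afterwards; sorting draws nothing);
3. one Fisher-Yates permutation of the N slots (``Generator.permutation``);
4. an (M, 2) block of uniform slot indices, row m being the swap for the
   m-th breakpoint in ascending position order.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import __version__
from .breakpoints import BreakpointSet, SamplerParams, sample_breakpoints
from .genetic_map import GeneticMap
from .panel import HaplotypePanel, PanelError

__all__ = [
    "FingerprintMismatchError",
    "PermutationState",
    "TransformMetadata",
    "ChromosomeRecord",
    "initial_shuffle",
    "apply_event",
    "forward_transform",
    "reverse_transform",
    "chromosome_rng",
]

RNG_ID = "numpy-pcg64/seedseq(seed,crc32(chrom))"


class FingerprintMismatchError(PanelError):
    """Metadata does not match the supplied genetic map; reversal refused."""


@dataclass
class PermutationState:
    """Bijection of slots {0..N-1}: output slot -> current source haplotype."""

    order: np.ndarray

    def __post_init__(self) -> None:
        self.order = np.asarray(self.order, dtype=np.int64)
        n = self.order.size
        if not np.array_equal(np.sort(self.order), np.arange(n)):
            raise ValueError("order must be a permutation of 0..N-1")

    @property
    def n(self) -> int:
        return int(self.order.size)


def initial_shuffle(N: int, rng: np.random.Generator) -> PermutationState:
    """Uniform random slot order (numpy's Fisher-Yates), deterministic per rng state."""
    if N < 2:
        raise ValueError("N must be >= 2")
    return PermutationState(order=rng.permutation(N))


def apply_event(state: PermutationState, i: int, j: int) -> PermutationState:
    """Swap slots i and j in place; i == j is a legal no-op (with-replacement draw)."""
    n = state.n
    if not (0 <= i < n and 0 <= j < n):
        raise IndexError(f"slot index out of range for N={n}")
    state.order[[i, j]] = state.order[[j, i]]
    return state


def chromosome_rng(seed: int, chromosome: str) -> np.random.Generator:
    """Deterministic per-chromosome RNG substream."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(str(chromosome).encode())])
    )


@dataclass(frozen=True)
class ChromosomeRecord:
    chromosome: str
    map_sha256: str
    n_breakpoints: int


@dataclass(frozen=True)
class TransformMetadata:
    """Everything needed to replay (and hence reverse) a transform exactly."""

    seed: int
    K: int
    N: int
    rng: str = RNG_ID
    version: str = __version__
    chromosomes: tuple[ChromosomeRecord, ...] = ()

    def to_json(self, path=None) -> str:
        payload = {
            "seed": self.seed,
            "K": self.K,
            "N": self.N,
            "rng": self.rng,
            "version": self.version,
            "chromosomes": [asdict(c) for c in self.chromosomes],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "TransformMetadata":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        return cls(
            seed=int(payload["seed"]),
            K=int(payload["K"]),
            N=int(payload["N"]),
            rng=payload.get("rng", RNG_ID),
            version=payload.get("version", __version__),
            chromosomes=tuple(
                ChromosomeRecord(**c) for c in payload.get("chromosomes", [])
            ),
        )

    def header_lines(self, prefix: str = "panelmix") -> list[str]:
        """VCF ## header lines making the output self-describing."""
        lines = [
            f"##{prefix}_seed={self.seed}",
            f"##{prefix}_K={self.K}",
            f"##{prefix}_N={self.N}",
            f"##{prefix}_rng={self.rng}",
            f"##{prefix}_version={self.version}",
        ]
        for rec in self.chromosomes:
            lines.append(
                f"##{prefix}_chrom={rec.chromosome}:sha256={rec.map_sha256}"
                f":M={rec.n_breakpoints}"
            )
        return lines

    @classmethod
    def from_header_lines(cls, lines, prefix: str = "panelmix") -> "TransformMetadata":
        fields: dict[str, str] = {}
        chroms: list[ChromosomeRecord] = []
        for line in lines:
            line = line.strip().lstrip("#")
            if not line.startswith(prefix + "_"):
                continue
            key, _, value = line[len(prefix) + 1 :].partition("=")
            if key == "chrom":
                label, _, rest = value.partition(":sha256=")
                sha, _, m = rest.partition(":M=")
                chroms.append(ChromosomeRecord(label, sha, int(m)))
            else:
                fields[key] = value
        if not {"seed", "K", "N"} <= fields.keys():
            raise PanelError("transform metadata not found in header")
        return cls(
            seed=int(fields["seed"]),
            K=int(fields["K"]),
            N=int(fields["N"]),
            rng=fields.get("rng", RNG_ID),
            version=fields.get("version", __version__),
            chromosomes=tuple(chroms),
        )


def _resolve_map(maps, chromosome: str) -> GeneticMap:
    if isinstance(maps, GeneticMap):
        return maps
    for key in (chromosome, chromosome.removeprefix("chr"), f"chr{chromosome}"):
        if key in maps:
            return maps[key]
    raise PanelError(f"no genetic map supplied for chromosome {chromosome!r}")


def transform_rows(rows, gmap: GeneticMap, params: SamplerParams, chromosome: str,
                   invert: bool = False):
    """Stream one chromosome's site rows through the (inverse) transform.

    ``rows`` yields ``(variant, allele_row)`` in position order.  Memory is
    O(N + M) regardless of the number of sites.  Returns a generator; the
    breakpoint count is exposed on the generator's ``.n_breakpoints``
    attribute via the companion :func:`replay_events`.
    """
    order, bset, pairs = replay_events(gmap, params, chromosome)
    yield from _apply_to_rows(rows, order, bset, pairs, invert)


def replay_events(gmap: GeneticMap, params: SamplerParams, chromosome: str):
    """Regenerate (initial order, breakpoints, swap pairs) from the seed."""
    rng = chromosome_rng(params.seed, chromosome)
    bset = sample_breakpoints(gmap, params, rng)
    state = initial_shuffle(params.N, rng)
    pairs = rng.integers(0, params.N, size=(bset.count, 2))
    return state, bset, pairs


def _apply_to_rows(rows, state: PermutationState, bset: BreakpointSet,
                   pairs: np.ndarray, invert: bool):
    order = state.order
    positions = bset.positions_bp
    m_total = bset.count
    bidx = 0
    last_pos = -np.inf
    for var, row in rows:
        pos = var.pos
        if pos < last_pos:
            raise PanelError("input variant positions are not sorted")
        last_pos = pos
        # half-open boundary rule: an event at real position r takes effect
        # before the first variant with position > r
        while bidx < m_total and positions[bidx] < pos:
            i, j = pairs[bidx]
            order[[i, j]] = order[[j, i]]
            bidx += 1
        if invert:
            out = np.empty_like(row)
            out[order] = row
        else:
            out = row[order]
        yield var, out
    # events beyond the last variant: replayed so the final state matches
    # the full event sequence (keeps replay/reversal bookkeeping exact)
    while bidx < m_total:
        i, j = pairs[bidx]
        order[[i, j]] = order[[j, i]]
        bidx += 1


def _run_panel(panel: HaplotypePanel, maps, params_factory, invert: bool):
    out = np.empty_like(panel.matrix)
    records = []
    chrom_order = panel.variants["chrom"].drop_duplicates().tolist()
    for chrom in chrom_order:
        mask = (panel.variants["chrom"] == chrom).to_numpy()
        idx = np.nonzero(mask)[0]
        gmap = _resolve_map(maps, str(chrom))
        params = params_factory(str(chrom), gmap)
        sub = panel.variants.iloc[idx]
        rows = zip(sub.itertuples(index=False), panel.matrix[idx])
        state, bset, pairs = replay_events(gmap, params, str(chrom))
        for k, (_, row_out) in zip(idx, _apply_to_rows(rows, state, bset, pairs, invert)):
            out[k] = row_out
        records.append(ChromosomeRecord(str(chrom), gmap.fingerprint(), bset.count))
    return out, records


def forward_transform(
    panel: HaplotypePanel, maps, params: SamplerParams
) -> tuple[HaplotypePanel, TransformMetadata]:
    """Transform a panel into synthetic descendant haplotypes.

    ``maps`` is a :class:`GeneticMap` (single-chromosome panel) or a mapping
    from chromosome label to map.  Output variants are identical; sample
    identity is replaced by SYN labels; per-site allele counts are invariant.
    """
    if params.N != panel.n_haplotypes:
        raise PanelError(
            f"params.N={params.N} does not match panel N={panel.n_haplotypes}"
        )
    out, records = _run_panel(panel, maps, lambda c, g: params, invert=False)
    meta = TransformMetadata(
        seed=params.seed, K=params.K, N=params.N, chromosomes=tuple(records)
    )
    syn_ids = [f"SYN{i + 1:04d}" for i in range(panel.n_haplotypes // 2)]
    return (
        HaplotypePanel(variants=panel.variants.copy(), matrix=out, sample_ids=syn_ids),
        meta,
    )


def reverse_transform(
    panel_syn: HaplotypePanel, maps, meta: TransformMetadata,
    original_sample_ids: list[str] | None = None,
) -> HaplotypePanel:
    """Exactly restore the panel that produced ``panel_syn``.

    The per-chromosome map fingerprint recorded in ``meta`` is verified
    against ``maps`` before anything is replayed; a mismatch means the
    event sequence cannot be reproduced and is a hard error.
    """
    if meta.N != panel_syn.n_haplotypes:
        raise PanelError(
            f"metadata N={meta.N} does not match panel N={panel_syn.n_haplotypes}"
        )
    recorded = {r.chromosome: r for r in meta.chromosomes}
    for chrom in panel_syn.variants["chrom"].drop_duplicates():
        gmap = _resolve_map(maps, str(chrom))
        rec = recorded.get(str(chrom))
        if rec is not None and rec.map_sha256 != gmap.fingerprint():
            raise FingerprintMismatchError(
                f"genetic map fingerprint mismatch for chromosome {chrom}: "
                "reversal would not reproduce the event sequence"
            )
    params = SamplerParams(K=meta.K, N=meta.N, seed=meta.seed)
    out, _ = _run_panel(panel_syn, maps, lambda c, g: params, invert=True)
    ids = original_sample_ids or [
        f"S{i + 1:04d}" for i in range(panel_syn.n_haplotypes // 2)
    ]
    return HaplotypePanel(
        variants=panel_syn.variants.copy(), matrix=out, sample_ids=ids
    )
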