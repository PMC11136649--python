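"""In-memory phased haplotype panel and validation.

A panel is L variant sites by N haplotypes of allele indices; haplotypes
2i and 2i+1 form diploid sample i.  The container keeps the whole matrix
(fine at fixture scale); the transform itself consumes any row stream, so
large panels can go straight from VCF to VCF without materialising here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["HaplotypePanel", "ValidationReport", "PanelError", "validate_panel"]

MISSING = np.int8(-1)  # encodes '.' alleles internally


class PanelError(ValueError):
    """Raised for structurally invalid panels."""


@dataclass
class HaplotypePanel:
    """Phased haplotype matrix with variant metadata.

    Parameters
    ----------
    variants
        DataFrame with columns ``chrom, pos, ref, alt`` (pos 1-based,
        non-decreasing within chromosome; ``alt`` comma-joined for
        multiallelic sites).
    matrix
        ``(L, N)`` int8 array of allele indices; ``-1`` marks missing.
    sample_ids
        N/2 labels; haplotypes ``(2i, 2i+1)`` belong to sample i.
    unphased
        Optional ``(L, N/2)`` bool mask of unphased genotypes (from VCF
        input); all-phased if omitted.
    """

    variants: pd.DataFrame
    matrix: np.ndarray
    sample_ids: list[str]
    unphased: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int8)
        if self.matrix.ndim != 2:
            raise PanelError("matrix must be 2-D (sites x haplotypes)")
        L, N = self.matrix.shape
        if len(self.variants) != L:
            raise PanelError("variants table and matrix row count differ")
        if N % 2 != 0 or N < 2:
            raise PanelError("haplotype count must be even and >= 2")
        if len(self.sample_ids) != N // 2:
            raise PanelError("need one sample id per haplotype pair")
        for chrom, grp in self.variants.groupby("chrom", sort=False):
            if np.any(np.diff(grp["pos"].to_numpy()) < 0):
                raise PanelError(f"positions not sorted within {chrom}")

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_haplotypes(self) -> int:
        return self.matrix.shape[1]

    def iter_rows(self):
        """Yield ``(variant_namedtuple, allele_row)`` one site at a time."""
        for var, row in zip(self.variants.itertuples(index=False), self.matrix):
            yield var, row

    def allele_frequencies(self) -> np.ndarray:
        """Per-site alternate-allele frequency (any non-reference allele)."""
        return (self.matrix > 0).mean(axis=1)

    def copy(self) -> "HaplotypePanel":
        return HaplotypePanel(
            variants=self.variants.copy(),
            matrix=self.matrix.copy(),
            sample_ids=list(self.sample_ids),
            unphased=None if self.unphased is None else self.unphased.copy(),
        )

    def equals(self, other: "HaplotypePanel") -> bool:
        """Genotype-exact equality: same variants and identical allele matrix."""
        return (
            self.matrix.shape == other.matrix.shape
            and bool(np.array_equal(self.matrix, other.matrix))
            and self.variants[["chrom", "pos", "ref", "alt"]].reset_index(drop=True).equals(
                other.variants[["chrom", "pos", "ref", "alt"]].reset_index(drop=True)
            )
        )


@dataclass(frozen=True)
class ValidationReport:
    n_sites: int
    n_haplotypes: int
    n_monomorphic: int
    n_multiallelic: int
    n_missing_sites: int
    n_unphased_sites: int

    @property
    def clean(self) -> bool:
        return self.n_missing_sites == 0 and self.n_unphased_sites == 0


def validate_panel(panel: HaplotypePanel, strict: bool = True) -> ValidationReport:
    """Count problem sites; in strict mode missing/unphased genotypes are fatal.

    Monomorphic and multiallelic sites are reported but never fatal: the
    transform permutes whole columns and is allele-agnostic, so such sites
    pass through unchanged in distribution.
    """
    mono = int(np.sum([len(np.unique(row[row >= 0])) <= 1 for row in panel.matrix]))
    multi = int(panel.variants["alt"].astype(str).str.contains(",").sum())
    missing_rows = np.any(panel.matrix == MISSING, axis=1)
    n_missing = int(missing_rows.sum())
    if panel.unphased is not None:
        unphased_rows = np.any(panel.unphased, axis=1)
        n_unphased = int(unphased_rows.sum())
    else:
        n_unphased = 0
    report = ValidationReport(
        n_sites=panel.n_sites,
        n_haplotypes=panel.n_haplotypes,
        n_monomorphic=mono,
        n_multiallelic=multi,
        n_missing_sites=n_missing,
        n_unphased_sites=n_unphased,
    )
    if strict and not report.clean:
        raise PanelError(
            f"strict validation failed: {n_missing} site(s) with missing "
            f"genotypes, {n_unphased} with unphased genotypes"
        )
    return report
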