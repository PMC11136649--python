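"""VCF/BCF adapters for haplotype panels (pysam-backed).

Reads phased GT fields into the in-memory panel container and writes panels
back out as VCF (``.vcf``), bgzipped VCF (``.vcf.gz``) or BCF (``.bcf``),
chosen by file extension.  Transform metadata travels as ``##panelmix_*``
header lines so outputs are self-describing; a sidecar JSON can carry the
same fields for users who strip headers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pysam

from .panel import HaplotypePanel, PanelError
from .transform import TransformMetadata

__all__ = ["read_panel_vcf", "write_panel_vcf", "read_metadata_vcf"]


def _open_mode(path: str) -> str:
    p = str(path)
    if p.endswith(".bcf"):
        return "wb"
    if p.endswith(".vcf.gz"):
        return "wz"
    return "w"


def read_panel_vcf(path) -> HaplotypePanel:
    """Load a phased diploid panel from VCF/BCF.

    Missing alleles are stored as -1 and unphased genotypes flagged, so
    strict validation downstream can reject them with counts attached.
    """
    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    if not samples:
        raise PanelError("VCF has no samples")
    n_hap = 2 * len(samples)
    chroms: list[str] = []
    positions: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    rows: list[np.ndarray] = []
    unphased: list[np.ndarray] = []
    for rec in vf:
        row = np.empty(n_hap, dtype=np.int8)
        unph = np.zeros(len(samples), dtype=bool)
        for i, s in enumerate(samples):
            sd = rec.samples[s]
            gt = sd["GT"]
            if len(gt) != 2:
                raise PanelError(
                    f"non-diploid genotype at {rec.chrom}:{rec.pos} sample {s}"
                )
            row[2 * i] = -1 if gt[0] is None else gt[0]
            row[2 * i + 1] = -1 if gt[1] is None else gt[1]
            unph[i] = not sd.phased
        chroms.append(rec.chrom)
        positions.append(rec.pos)
        refs.append(rec.ref or "N")
        alts.append(",".join(rec.alts) if rec.alts else ".")
        rows.append(row)
        unphased.append(unph)
    vf.close()
    if not rows:
        raise PanelError("VCF contains no variant records")
    variants = pd.DataFrame(
        {"chrom": chroms, "pos": positions, "ref": refs, "alt": alts}
    )
    return HaplotypePanel(
        variants=variants,
        matrix=np.vstack(rows),
        sample_ids=samples,
        unphased=np.vstack(unphased),
    )


def read_metadata_vcf(path, prefix: str = "panelmix") -> TransformMetadata:
    """Recover transform metadata from ``##panelmix_*`` header lines."""
    vf = pysam.VariantFile(str(path))
    lines = [str(rec).strip() for rec in vf.header.records]
    vf.close()
    return TransformMetadata.from_header_lines(lines, prefix=prefix)


def write_panel_vcf(
    panel: HaplotypePanel, path, metadata: TransformMetadata | None = None
) -> None:
    """Write a panel as phased VCF/BCF (format picked from the extension)."""
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    contig_end = panel.variants.groupby("chrom", sort=False)["pos"].max()
    for chrom, end in contig_end.items():
        header.contigs.add(str(chrom), length=int(end) + 1)
    if metadata is not None:
        for line in metadata.header_lines():
            header.add_line(line)
    for s in panel.sample_ids:
        header.add_sample(s)
    vf = pysam.VariantFile(str(path), _open_mode(path), header=header)
    try:
        for var, row in panel.iter_rows():
            alleles = (var.ref,) if var.alt == "." else (var.ref, *var.alt.split(","))
            rec = vf.new_record(
                contig=str(var.chrom), start=int(var.pos) - 1, alleles=alleles
            )
            for i, s in enumerate(panel.sample_ids):
                a, b = int(row[2 * i]), int(row[2 * i + 1])
                rec.samples[s]["GT"] = (None if a < 0 else a, None if b < 0 else b)
                rec.samples[s].phased = True
            vf.write(rec)
    finally:
        vf.close()
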