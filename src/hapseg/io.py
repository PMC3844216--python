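"""Reading and writing haplotype matrices and block partitions.

Two plain-text matrix dialects are supported:

``simple``
    One haplotype per line, one character per site, no separators;
    ``#``-prefixed comment lines are ignored.  Canonical on output.
``tsv``
    Tab-separated with a header row of site ids; one haplotype row per line,
    first column the sample id.

Partitions are written as TSV mirroring the usual "(start, end) / tags used"
block-table layout, with one row per block.

An optional VCF ingestion path (phased GT fields split into haplotype rows)
is provided through :func:`read_vcf`; it requires ``cyvcf2``.
"""

from __future__ import annotations

import os

import numpy as np

from .errors import ConsistencyError, FormatError
from .matrix import (
    MISSING,
    Block,
    HaplotypeMatrix,
    Segmentation,
    decode_symbol,
    encode_code,
)

PARTITION_COLUMNS = ["block_id", "start", "end", "n_snps", "diversity", "n_tags", "tag_loci"]


def _decode_row(symbols: list[str], row_no: int) -> list[int]:
    out = []
    for pos, ch in enumerate(symbols, start=1):
        try:
            out.append(decode_symbol(ch))
        except KeyError:
            raise FormatError(
                f"unknown allele symbol {ch!r} at row {row_no}, site {pos}"
            ) from None
    return out


def read_matrix(path: str | os.PathLike, dialect: str = "simple") -> HaplotypeMatrix:
    """Read a haplotype matrix from ``path``.

    Symbols '0'->MAJOR, '1'->MINOR and any of '?', '2', 'N', 'n'->MISSING.
    Raises :class:`FormatError` on ragged rows or unknown symbols.
    """
    if dialect not in ("simple", "tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path, "rt", encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh]

    site_ids: list[str] = []
    sample_ids: list[str] = []
    rows: list[list[int]] = []
    if dialect == "simple":
        data_no = 0
        for ln in lines:
            if not ln.strip() or ln.lstrip().startswith("#"):
                continue
            data_no += 1
            rows.append(_decode_row(list(ln.strip()), data_no))
    else:
        body = [ln for ln in lines if ln.strip() and not ln.startswith("#")]
        if not body:
            raise FormatError("tsv matrix file has no header row")
        header = body[0].split("\t")
        if len(header) < 2:
            raise FormatError("tsv header must name at least one site")
        site_ids = header[1:]
        for data_no, ln in enumerate(body[1:], start=1):
            fields = ln.split("\t")
            sample_ids.append(fields[0])
            rows.append(_decode_row(fields[1:], data_no))

    if not rows:
        raise FormatError(f"no haplotype rows found in {path}")
    width = len(rows[0])
    for r, row in enumerate(rows, start=1):
        if len(row) != width:
            raise FormatError(f"ragged row {r}: expected {width} sites, got {len(row)}")
    return HaplotypeMatrix(
        np.array(rows, dtype=np.int8), site_ids=site_ids, sample_ids=sample_ids
    )


def write_matrix(mat: HaplotypeMatrix, path: str | os.PathLike) -> None:
    """Write ``mat`` in the ``simple`` dialect ('?' for missing entries)."""
    with open(path, "wt", encoding="utf-8") as fh:
        for row in mat.alleles:
            fh.write("".join(encode_code(a) for a in row) + "\n")


def write_partition(seg: Segmentation, mat: HaplotypeMatrix, path: str | os.PathLike) -> None:
    """Write a block partition as TSV (one row per block, header always present)."""
    for b in seg.blocks:
        if not (1 <= b.start <= b.end <= mat.n):
            raise ConsistencyError(
                f"block [{b.start}, {b.end}] lies outside the matrix range 1..{mat.n}"
            )
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("\t".join(PARTITION_COLUMNS) + "\n")
        for bid, b in enumerate(seg.blocks, start=1):
            loci = ",".join(mat.site_ids[t - 1] for t in b.tag_loci)
            fh.write(
                f"{bid}\t{b.start}\t{b.end}\t{b.length}\t{b.diversity:.10g}\t{b.n_tags}\t{loci}\n"
            )


def read_partition(path: str | os.PathLike, mat: HaplotypeMatrix) -> Segmentation:
    """Re-parse a partition TSV written by :func:`write_partition`."""
    label_to_site = {lab: c + 1 for c, lab in enumerate(mat.site_ids)}
    blocks: list[Block] = []
    with open(path, "rt", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != PARTITION_COLUMNS:
            raise FormatError(f"unexpected partition header {header!r}")
        for ln in fh:
            if not ln.strip():
                continue
            _, start, end, _, div, n_tags, loci = ln.rstrip("\n").split("\t")
            tag_loci = [label_to_site[lab] for lab in loci.split(",")] if loci else []
            blocks.append(
                Block(
                    start=int(start),
                    end=int(end),
                    diversity=float(div),
                    n_tags=int(n_tags),
                    tag_loci=tag_loci,
                )
            )
    return Segmentation(blocks)


def read_vcf(path: str | os.PathLike) -> HaplotypeMatrix:
    """Ingest phased genotypes from a VCF 4.x file as haplotype rows.

    Each diploid sample contributes two rows; '.' alleles map to MISSING.
    Multi-allelic sites and unphased records are rejected.
    """
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise ImportError("VCF ingestion requires the optional cyvcf2 dependency") from exc

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    columns: list[list[int]] = []
    site_ids: list[str] = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise FormatError(f"multi-allelic site at {rec.CHROM}:{rec.POS} rejected")
        col: list[int] = []
        for g in rec.genotypes:  # [allele_a, allele_b, phased]
            if not g[2]:
                raise FormatError(f"unphased genotype at {rec.CHROM}:{rec.POS}")
            for allele in g[:2]:
                col.append(MISSING if allele < 0 else int(allele))
        columns.append(col)
        site_ids.append(rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}")
    if not columns:
        raise FormatError(f"no variant records found in {path}")
    alleles = np.array(columns, dtype=np.int8).T
    sample_ids = [f"{s}_{h}" for s in samples for h in (1, 2)]
    return HaplotypeMatrix(alleles, site_ids=site_ids, sample_ids=sample_ids)
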