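"""Reading and writing genotype/haplotype panels and pruning reports.

Supported inputs: PLINK 1.9 binary BED/BIM/FAM triplets (SNP-major), phased
VCF with pipe-separated GT fields, and plain whitespace-delimited integer
matrices.  Real-valued dosages on [0, 2] can be rounded to hard calls with
:func:`round_dosages`.  Missing genotypes are a hard error everywhere (the
algorithms require complete data); for BED input an opt-in flag drops the
offending loci instead.

Outputs follow the PLINK convention: ``<prefix>.prune.in`` /
``<prefix>.prune.out`` with one locus id per line in input order, plus a TSV
pair report with the removal reason, partner and r2 of every pruned locus.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .panel import (
    GenotypePanel,
    HaplotypePanel,
    LocusMeta,
    PruneResult,
    default_loci,
)

__all__ = [
    "read_plink_bed",
    "write_plink_bed",
    "read_vcf_phased",
    "write_vcf_phased",
    "read_matrix_txt",
    "write_matrix_txt",
    "read_dosage_matrix",
    "round_dosages",
    "write_prune_lists",
]

logger = logging.getLogger("ldprune")

_BED_MAGIC = b"\x6c\x1b"
_BED_SNP_MAJOR = b"\x01"
# 2-bit codes (low bits = first sample) -> count of the .bim A2 allele;
# 0b01 is the missing-genotype code.
_BED_CODE_TO_COUNT = {0b00: 0, 0b10: 1, 0b11: 2}
_COUNT_TO_BED_CODE = {0: 0b00, 1: 0b10, 2: 0b11}


class FormatError(ValueError):
    """Malformed input file."""


def _read_bim(path: Path) -> list[LocusMeta]:
    loci = []
    for idx, line in enumerate(path.read_text().splitlines()):
        fields = line.split()
        if len(fields) < 6:
            raise FormatError(f"{path}: line {idx + 1}: expected 6 .bim columns")
        chrom, snp_id, _cm, pos = fields[0], fields[1], fields[2], fields[3]
        loci.append(LocusMeta(snp_id, idx, chromosome=chrom, position=int(pos)))
    return loci


def _read_fam(path: Path) -> list[str]:
    ids = []
    for line in path.read_text().splitlines():
        fields = line.split()
        if len(fields) < 2:
            raise FormatError(f"{path}: expected at least 2 .fam columns")
        ids.append(fields[1])
    return ids


def read_plink_bed(path_prefix: Union[str, Path], drop_missing_loci: bool = False) -> GenotypePanel:
    """Read a PLINK ``.bed/.bim/.fam`` triplet into a genotype panel.

    Decoded counts are counts of the .bim A2 allele (PLINK 1.9 convention);
    r2 and pruning are invariant to this orientation, which only affects
    reporting.  A missing-genotype code raises an error naming the first
    offending locus unless ``drop_missing_loci`` is set, in which case the
    affected loci are removed with a logged count.
    """
    prefix = Path(path_prefix)
    bed = Path(str(prefix) + ".bed")
    loci = _read_bim(Path(str(prefix) + ".bim"))
    individual_ids = _read_fam(Path(str(prefix) + ".fam"))
    n, m = len(individual_ids), len(loci)

    data = bed.read_bytes()
    if data[:2] != _BED_MAGIC:
        raise FormatError(f"{bed}: not a PLINK .bed file (bad magic bytes)")
    if data[2:3] != _BED_SNP_MAJOR:
        raise FormatError(f"{bed}: only SNP-major mode (0x01) is supported")
    bytes_per_locus = (n + 3) // 4
    expected = 3 + bytes_per_locus * m
    if len(data) != expected:
        raise FormatError(f"{bed}: expected {expected} bytes, found {len(data)}")

    raw = np.frombuffer(data, dtype=np.uint8, offset=3).reshape(m, bytes_per_locus)
    # unpack 2-bit codes, low bits first
    codes = np.empty((m, bytes_per_locus * 4), dtype=np.uint8)
    for shift in range(4):
        codes[:, shift::4] = (raw >> (2 * shift)) & 0b11
    codes = codes[:, :n]  # drop padding samples

    missing = codes == 0b01
    missing_loci = np.flatnonzero(missing.any(axis=1))
    if missing_loci.size:
        if not drop_missing_loci:
            first = loci[int(missing_loci[0])].locus_id
            raise FormatError(
                f"{bed}: missing genotypes are not supported "
                f"(first offending locus: {first})"
            )
        logger.warning(
            "dropping %d loci with missing genotypes", missing_loci.size
        )
        keep = np.setdiff1d(np.arange(m), missing_loci)
        codes = codes[keep]
        loci = [
            LocusMeta(loci[j].locus_id, rank, loci[j].chromosome, loci[j].position)
            for rank, j in enumerate(keep)
        ]
    counts = np.zeros_like(codes, dtype=np.int8)
    counts[codes == 0b10] = 1
    counts[codes == 0b11] = 2
    return GenotypePanel(counts=counts.T, loci=loci, individual_ids=individual_ids)


def write_plink_bed(panel: GenotypePanel, path_prefix: Union[str, Path]) -> None:
    """Write a genotype panel as a PLINK ``.bed/.bim/.fam`` triplet."""
    prefix = Path(path_prefix)
    n, m = panel.n_individuals, panel.n_loci
    with Path(str(prefix) + ".bim").open("w") as fh:
        for lm in panel.loci:
            chrom = lm.chromosome if lm.chromosome is not None else "0"
            pos = lm.position if lm.position is not None else lm.input_index + 1
            fh.write(f"{chrom}\t{lm.locus_id}\t0\t{pos}\tA\tB\n")
    with Path(str(prefix) + ".fam").open("w") as fh:
        for iid in panel.individual_ids:
            fh.write(f"{iid}\t{iid}\t0\t0\t0\t-9\n")
    bytes_per_locus = (n + 3) // 4
    out = bytearray(_BED_MAGIC + _BED_SNP_MAJOR)
    counts = panel.counts.T  # locus-major
    for j in range(m):
        row = bytearray(bytes_per_locus)
        for i in range(n):
            row[i // 4] |= _COUNT_TO_BED_CODE[int(counts[j, i])] << (2 * (i % 4))
        out.extend(row)
    Path(str(prefix) + ".bed").write_bytes(bytes(out))


def read_vcf_phased(path: Union[str, Path]) -> tuple[HaplotypePanel, int]:
    """Read phased GT fields from a VCF into a haplotype panel.

    Returns ``(panel, n_skipped)`` where ``n_skipped`` counts multi-allelic
    records, which are skipped with a logged warning.  Unphased or missing
    genotypes are errors.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    individual_ids = list(vcf.samples)
    columns: list[np.ndarray] = []
    loci: list[LocusMeta] = []
    n_skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_skipped += 1
            logger.warning(
                "skipping multi-allelic record %s:%d", rec.CHROM, rec.POS
            )
            continue
        gts = rec.genotypes  # [hap1, hap2, phased_flag] per sample
        col = np.empty((len(individual_ids), 2), dtype=np.int8)
        for i, gt in enumerate(gts):
            if len(gt) < 3:
                raise FormatError(
                    f"{path}: record {rec.CHROM}:{rec.POS}: haploid genotype"
                )
            a1, a2, phased = gt[0], gt[1], gt[-1]
            if a1 < 0 or a2 < 0:
                raise FormatError(
                    f"{path}: record {rec.CHROM}:{rec.POS}: missing allele"
                )
            if not phased:
                raise FormatError(
                    f"{path}: record {rec.CHROM}:{rec.POS}: genotype is not "
                    "phased (found '/' separator; phased '|' GT required)"
                )
            col[i, 0], col[i, 1] = a1, a2
        rec_id = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}"
        loci.append(LocusMeta(rec_id, len(loci), chromosome=rec.CHROM, position=rec.POS))
        columns.append(col)
    if columns:
        alleles = np.stack(columns, axis=1)
    else:
        alleles = np.empty((len(individual_ids), 0, 2), dtype=np.int8)
    panel = HaplotypePanel(alleles=alleles, loci=loci, individual_ids=individual_ids)
    return panel, n_skipped


def write_vcf_phased(panel: HaplotypePanel, path: Union[str, Path]) -> None:
    """Write a haplotype panel as a minimal phased VCF (alleles A/B)."""
    chroms: dict[str, None] = {}
    for lm in panel.loci:
        chroms[lm.chromosome if lm.chromosome is not None else "1"] = None
    with Path(path).open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.individual_ids)
            + "\n"
        )
        for j, lm in enumerate(panel.loci):
            chrom = lm.chromosome if lm.chromosome is not None else "1"
            pos = lm.position if lm.position is not None else j + 1
            gts = "\t".join(
                f"{panel.alleles[i, j, 0]}|{panel.alleles[i, j, 1]}"
                for i in range(panel.n_individuals)
            )
            fh.write(f"{chrom}\t{pos}\t{lm.locus_id}\tA\tB\t.\tPASS\t.\tGT\t{gts}\n")


def read_matrix_txt(
    path: Union[str, Path],
    orientation: str = "rows-are-loci",
) -> GenotypePanel:
    """Read a whitespace-delimited integer matrix of allele counts.

    ``orientation`` is ``"rows-are-loci"`` (default: sequence-scale panels
    have far more loci than individuals) or ``"rows-are-individuals"``.
    Locus ids are generated as ``snp<k>``, individual ids as ``ind<k>``.
    """
    if orientation not in ("rows-are-loci", "rows-are-individuals"):
        raise ValueError(f"unknown orientation {orientation!r}")
    rows: list[list[int]] = []
    width: Optional[int] = None
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            row = []
            for colno, tok in enumerate(tokens, start=1):
                if tok not in ("0", "1", "2"):
                    raise FormatError(
                        f"{path}: line {lineno}, column {colno}: expected an "
                        f"integer allele count in {{0,1,2}}, got {tok!r}"
                    )
                row.append(int(tok))
            if width is None:
                width = len(row)
            elif len(row) != width:
                raise FormatError(
                    f"{path}: line {lineno}: ragged row ({len(row)} values, "
                    f"expected {width})"
                )
            rows.append(row)
    mat = np.array(rows, dtype=np.int8)
    if mat.size == 0:
        raise FormatError(f"{path}: empty matrix")
    if orientation == "rows-are-loci":
        mat = mat.T
    n, m = mat.shape
    return GenotypePanel(
        counts=mat,
        loci=default_loci(m),
        individual_ids=[f"ind{i + 1}" for i in range(n)],
    )


def write_matrix_txt(
    panel: GenotypePanel,
    path: Union[str, Path],
    orientation: str = "rows-are-loci",
) -> None:
    mat = panel.counts.T if orientation == "rows-are-loci" else panel.counts
    with Path(path).open("w") as fh:
        for row in mat:
            fh.write(" ".join(str(int(v)) for v in row) + "\n")


def round_dosages(values: np.ndarray) -> np.ndarray:
    """Round real-valued dosages on [0, 2] to hard allele counts.

    Values <= 0.5 become 0, values >= 1.5 become 2, everything else 1.
    """
    values = np.asarray(values, dtype=float)
    if values.size and (values.min() < 0.0 or values.max() > 2.0):
        bad = values[(values < 0.0) | (values > 2.0)].flat[0]
        raise ValueError(f"dosage {bad} outside [0, 2]")
    out = np.ones(values.shape, dtype=np.int8)
    out[values <= 0.5] = 0
    out[values >= 1.5] = 2
    return out


def read_dosage_matrix(
    path: Union[str, Path],
    orientation: str = "rows-are-loci",
) -> GenotypePanel:
    """Read a real-valued dosage matrix on [0, 2] and round to hard calls."""
    if orientation not in ("rows-are-loci", "rows-are-individuals"):
        raise ValueError(f"unknown orientation {orientation!r}")
    try:
        mat = np.loadtxt(Path(path), dtype=float, ndmin=2)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    counts = round_dosages(mat)
    if orientation == "rows-are-loci":
        counts = counts.T
    n, m = counts.shape
    return GenotypePanel(
        counts=counts,
        loci=default_loci(m),
        individual_ids=[f"ind{i + 1}" for i in range(n)],
    )


def write_prune_lists(result: PruneResult, out_prefix: Union[str, Path]) -> None:
    """Write ``prune.in`` / ``prune.out`` lists and the TSV pair report.

    Kept and removed ids are listed one per line in input order; the pair
    report has one row per removal with the reason (complete|high), the
    surviving partner, the r2 with it, and — when map positions are known —
    whether the pair shares a chromosome and its base-pair distance.
    """
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    ids = {lm.input_index: lm for lm in result.loci}
    removed = {r.removed_index: r for r in result.removals}

    with open(f"{prefix}.prune.in", "w") as fh:
        for idx in sorted(result.kept_indices):
            fh.write(ids[idx].locus_id + "\n")
    with open(f"{prefix}.prune.out", "w") as fh:
        for idx in sorted(removed):
            fh.write(ids[idx].locus_id + "\n")

    with open(f"{prefix}.pairs.tsv", "w") as fh:
        fh.write("locus_removed\tpartner\treason\tr2\tsame_chromosome\tdistance\n")
        for idx in sorted(removed):
            r = removed[idx]
            a, b = ids[r.removed_index], ids[r.partner_index]
            if a.chromosome is not None and b.chromosome is not None:
                same = str(a.chromosome == b.chromosome).lower()
                dist = (
                    str(abs(a.position - b.position))
                    if a.chromosome == b.chromosome
                    else ""
                )
            else:
                same, dist = "", ""
            fh.write(
                f"{a.locus_id}\t{b.locus_id}\t{r.reason}\t{r.r2:.6g}\t{same}\t{dist}\n"
            )
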