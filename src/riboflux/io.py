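"""Format boundaries: GFF3, SAM, BED12, TSV alignments, count matrices, sample sheets.

GFF3 and SAM are 1-based inclusive on disk and converted to the package's
0-based half-open convention here; BED is native.  SAM text is parsed with
pysam.  Only reading/writing lives in this module -- no coverage or
statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd
import pysam

from .intervals import AlignedRead, GenomicInterval, TranscriptModel

MIN_READ_LEN = 15
MAX_READ_LEN = 60


class AnnotationWarning(UserWarning):
    """A gene was skipped or modified while assembling transcript models."""


class GFF3ParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def _parse_attributes(text: str) -> dict[str, str]:
    out = {}
    for item in text.strip().rstrip(";").split(";"):
        if not item:
            continue
        if "=" not in item:
            raise ValueError(f"malformed attribute {item!r}")
        k, v = item.split("=", 1)
        out[k.strip()] = v.strip()
    return out


def _gene_of(attrs: dict[str, str]) -> str | None:
    for key in ("Parent", "gene_id", "ID", "locus_tag"):
        if key in attrs:
            return attrs[key].split(",")[0]
    return None


def read_gff3(path, default_utr5: int = 120, default_utr3: int = 200) -> list[TranscriptModel]:
    """Assemble transcript models from a GFF3 annotation.

    Measured ``five_prime_UTR``/``three_prime_UTR`` rows are used when
    present (the longest row wins; ties keep the first encountered);
    otherwise UTRs of exactly ``default_utr5``/``default_utr3`` nt are
    extended from the CDS in transcript orientation and flagged
    ``utr5_source='default'``.  Default extensions never cross a chromosome
    boundary; genes that would be truncated to nothing are skipped, shorter
    truncations are flagged.  Genes whose CDS length is not a multiple of 3
    are skipped with a warning.
    """
    cds_parts: dict[str, list[GenomicInterval]] = {}
    utr5_rows: dict[str, list[GenomicInterval]] = {}
    utr3_rows: dict[str, list[GenomicInterval]] = {}
    uorf_rows: dict[str, list[GenomicInterval]] = {}
    order: list[str] = []
    chrom_len: dict[str, int] = {}

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) >= 4:
                    chrom_len[parts[1]] = int(parts[3])
                continue
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise GFF3ParseError(f"{path}:{lineno}: expected 9 columns, got {len(cols)}")
            chrom, _src, ftype, start_s, end_s, _score, strand, _frame, attr_s = cols
            try:
                start1, end1 = int(start_s), int(end_s)
                attrs = _parse_attributes(attr_s)
            except ValueError as exc:
                raise GFF3ParseError(f"{path}:{lineno}: {exc}") from exc
            if strand not in ("+", "-") or end1 < start1 or start1 < 1:
                raise GFF3ParseError(f"{path}:{lineno}: bad coordinates/strand")
            gene = _gene_of(attrs)
            if gene is None:
                continue
            iv = GenomicInterval(chrom, start1 - 1, end1, strand)  # to half-open
            bucket = {
                "CDS": cds_parts,
                "five_prime_UTR": utr5_rows,
                "three_prime_UTR": utr3_rows,
                "uORF": uorf_rows,
            }.get(ftype)
            if bucket is None:
                continue
            if gene not in cds_parts and bucket is cds_parts:
                order.append(gene)
            bucket.setdefault(gene, []).append(iv)

    models: list[TranscriptModel] = []
    for gene in order:
        parts = sorted(cds_parts[gene], key=lambda p: p.start)
        chrom, strand = parts[0].chrom, parts[0].strand
        cds = GenomicInterval(chrom, parts[0].start, parts[-1].end, strand)
        introns = [
            GenomicInterval(chrom, a.end, b.start, strand)
            for a, b in zip(parts, parts[1:])
            if a.end < b.start
        ]
        cds_len = sum(len(p) for p in parts)
        if cds_len % 3 != 0:
            warnings.warn(f"{gene}: CDS length {cds_len} not a multiple of 3; skipped",
                          AnnotationWarning, stacklevel=2)
            continue

        def longest(rows: list[GenomicInterval]) -> GenomicInterval:
            return max(rows, key=len)  # max keeps the first on ties

        truncated = False
        utr5_source = "measured" if gene in utr5_rows else "default"
        limit = chrom_len.get(chrom)

        if gene in utr5_rows:
            utr5 = longest(utr5_rows[gene])
        else:
            if strand == "+":
                lo = max(0, cds.start - default_utr5)
                truncated |= lo > cds.start - default_utr5
                if lo == cds.start:
                    warnings.warn(f"{gene}: no room for a default 5'UTR; skipped",
                                  AnnotationWarning, stacklevel=2)
                    continue
                utr5 = GenomicInterval(chrom, lo, cds.start, strand)
            else:
                hi = cds.end + default_utr5
                if limit is not None and hi > limit:
                    hi, truncated = limit, True
                if hi == cds.end:
                    warnings.warn(f"{gene}: no room for a default 5'UTR; skipped",
                                  AnnotationWarning, stacklevel=2)
                    continue
                utr5 = GenomicInterval(chrom, cds.end, hi, strand)

        if gene in utr3_rows:
            utr3 = longest(utr3_rows[gene])
        else:
            if strand == "+":
                hi = cds.end + default_utr3
                if limit is not None and hi > limit:
                    hi, truncated = limit, True
                if hi == cds.end:
                    warnings.warn(f"{gene}: no room for a default 3'UTR; skipped",
                                  AnnotationWarning, stacklevel=2)
                    continue
                utr3 = GenomicInterval(chrom, cds.end, hi, strand)
            else:
                lo = max(0, cds.start - default_utr3)
                truncated |= lo > cds.start - default_utr3
                if lo == cds.start:
                    warnings.warn(f"{gene}: no room for a default 3'UTR; skipped",
                                  AnnotationWarning, stacklevel=2)
                    continue
                utr3 = GenomicInterval(chrom, lo, cds.start, strand)

        try:
            model = TranscriptModel(
                gene_id=gene, utr5=utr5, cds=cds, utr3=utr3,
                uorfs=uorf_rows.get(gene, []),
                utr5_source=utr5_source, truncated_utr=truncated, introns=introns,
            )
        except ValueError as exc:
            warnings.warn(f"{gene}: {exc}; skipped", AnnotationWarning, stacklevel=2)
            continue
        models.append(model)
    return models


def write_gff3(models: list[TranscriptModel], path, chrom_lengths: dict[str, int] | None = None) -> None:
    """Write transcript models back to GFF3 (1-based inclusive)."""

    def row(chrom, ftype, iv: GenomicInterval, attrs: str) -> str:
        return f"{chrom}\triboflux\t{ftype}\t{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\t{attrs}"

    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, n in (chrom_lengths or {}).items():
            fh.write(f"##sequence-region {chrom} 1 {n}\n")
        for m in models:
            fh.write(row(m.chrom, "gene", m.span, f"ID={m.gene_id}") + "\n")
            if m.utr5_source == "measured":
                fh.write(row(m.chrom, "five_prime_UTR", m.utr5, f"Parent={m.gene_id}") + "\n")
                fh.write(row(m.chrom, "three_prime_UTR", m.utr3, f"Parent={m.gene_id}") + "\n")
            fh.write(row(m.chrom, "CDS", m.cds, f"Parent={m.gene_id}") + "\n")
            for i, u in enumerate(m.uorfs, 1):
                fh.write(row(m.chrom, "uORF", u, f"Parent={m.gene_id};ID={m.gene_id}.uORF{i}") + "\n")


# ---------------------------------------------------------------------------
# Alignments
# ---------------------------------------------------------------------------

@dataclass
class AlignmentReadResult:
    """Reads accepted by the length filter plus rejection tallies."""

    reads: list[AlignedRead] = field(default_factory=list)
    n_dropped_length: int = 0
    n_skipped_cigar: int = 0

    def __iter__(self):
        return iter(self.reads)

    def __len__(self):
        return len(self.reads)


_CONSUME_REF_IN_BLOCK = {0, 2, 7, 8}  # M, D, =, X
_QUERY_ONLY = {1, 4, 5}               # I, S, H


def _sam_blocks(rec) -> list[tuple[int, int]] | None:
    """Reference blocks split only at N operators; None if unsupported CIGAR."""
    pos = rec.reference_start
    blocks: list[tuple[int, int]] = []
    cur = pos
    for op, n in rec.cigartuples:
        if op in _CONSUME_REF_IN_BLOCK:
            pos += n
        elif op == 3:  # N: splice
            if pos > cur:
                blocks.append((cur, pos))
            pos += n
            cur = pos
        elif op in _QUERY_ONLY:
            continue
        else:
            return None
    if pos > cur:
        blocks.append((cur, pos))
    return blocks


def read_alignments(path, format: str, sample_id: str | None = None) -> AlignmentReadResult:
    """Read aligned fragments from SAM text, BED12, or a simple TSV.

    The TSV dialect is ``chrom  start  end  strand  sample_id`` (0-based
    half-open, single block).  Records outside [15, 60] aligned nt are
    dropped and counted; SAM records with unsupported CIGAR operators are
    skipped and counted.
    """
    if format == "sam":
        return _read_sam(path, sample_id)
    if format == "bed12":
        return _read_bed12(path, sample_id)
    if format == "tsv":
        return _read_tsv(path, sample_id)
    raise ValueError(f"unknown alignment format {format!r} (expected sam, bed12, or tsv)")


def _accept(result: AlignmentReadResult, read: AlignedRead) -> None:
    if MIN_READ_LEN <= read.read_length <= MAX_READ_LEN:
        result.reads.append(read)
    else:
        result.n_dropped_length += 1


def _read_sam(path, sample_id: str | None) -> AlignmentReadResult:
    result = AlignmentReadResult()
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.cigartuples is None:
                continue
            raw = _sam_blocks(rec)
            if raw is None:
                result.n_skipped_cigar += 1
                continue
            strand = "-" if rec.is_reverse else "+"
            sid = sample_id
            if sid is None:
                sid = rec.get_tag("RG") if rec.has_tag("RG") else ""
            blocks = [GenomicInterval(rec.reference_name, s, e, strand) for s, e in raw]
            _accept(result, AlignedRead(blocks=blocks, sample_id=sid))
    return result


def _read_bed12(path, sample_id: str | None) -> AlignmentReadResult:
    result = AlignmentReadResult()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise ValueError(f"{path}:{lineno}: BED12 needs 12 columns")
            chrom, start, _end, name, _score, strand = cols[0], int(cols[1]), int(cols[2]), cols[3], cols[4], cols[5]
            sizes = [int(x) for x in cols[10].rstrip(",").split(",")]
            offsets = [int(x) for x in cols[11].rstrip(",").split(",")]
            if len(sizes) != int(cols[9]) or len(offsets) != int(cols[9]):
                raise ValueError(f"{path}:{lineno}: block count mismatch")
            blocks = [
                GenomicInterval(chrom, start + off, start + off + size, strand)
                for off, size in zip(offsets, sizes)
            ]
            _accept(result, AlignedRead(blocks=blocks, sample_id=sample_id or name))
    return result


def _read_tsv(path, sample_id: str | None) -> AlignmentReadResult:
    result = AlignmentReadResult()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if cols[0] == "chrom":  # header row
                continue
            if len(cols) < 4:
                raise ValueError(f"{path}:{lineno}: need chrom, start, end, strand[, sample_id]")
            try:
                iv = GenomicInterval(cols[0], int(cols[1]), int(cols[2]), cols[3])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            sid = cols[4] if len(cols) > 4 else (sample_id or "")
            _accept(result, AlignedRead(blocks=[iv], sample_id=sid))
    return result


def write_sam(reads: list[AlignedRead], path, chrom_lengths: dict[str, int]) -> None:
    """Write reads as SAM text (header included; splices become N operators)."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for chrom, n in chrom_lengths.items():
            fh.write(f"@SQ\tSN:{chrom}\tLN:{n}\n")
        for i, r in enumerate(reads):
            flag = 16 if r.strand == "-" else 0
            cigar = ""
            for a, b in zip(r.blocks, r.blocks[1:]):
                cigar += f"{len(a)}M{b.start - a.end}N"
            cigar += f"{len(r.blocks[-1])}M"
            rg = f"\tRG:Z:{r.sample_id}" if r.sample_id else ""
            fh.write(
                f"read{i}\t{flag}\t{r.chrom}\t{r.start + 1}\t255\t{cigar}\t*\t0\t0\t*\t*{rg}\n"
            )


# ---------------------------------------------------------------------------
# Count matrices and sample sheets
# ---------------------------------------------------------------------------

def validate_counts(matrix: pd.DataFrame) -> pd.DataFrame:
    arr = matrix.to_numpy()
    if matrix.size:
        if not pd.api.types.is_integer_dtype(matrix.dtypes.iloc[0]) or any(
            not pd.api.types.is_integer_dtype(t) for t in matrix.dtypes
        ):
            raise ValueError("count matrix cells must be integers")
        if (arr < 0).any():
            raise ValueError("count matrix cells must be non-negative")
    return matrix


def write_counts(matrix: pd.DataFrame, path) -> None:
    """Write a genes x samples integer count matrix as TSV."""
    validate_counts(matrix)
    matrix.to_csv(path, sep="\t", index_label="gene_id")


def read_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    for col in df.columns:
        as_int = pd.to_numeric(df[col], errors="raise")
        if not (as_int == as_int.astype("int64")).all():
            raise ValueError(f"non-integer count in column {col}")
        df[col] = as_int.astype("int64")
    return validate_counts(df)


SHEET_COLUMNS = ["sample_id", "assay", "strain", "temperature", "replicate"]


def validate_sample_sheet(sheet: pd.DataFrame, require_full_design: bool = False) -> pd.DataFrame:
    """Check sample-sheet invariants; optionally require every design cell filled."""
    df = sheet.rename(columns={"sample": "sample_id"}).copy()
    missing = [c for c in SHEET_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sample sheet missing columns: {missing}")
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in sample sheet")
    if not df["assay"].isin(["RPF", "RNA"]).all():
        raise ValueError("assay must be RPF or RNA")
    if not df["strain"].isin(["WT", "MUT"]).all():
        raise ValueError("strain must be WT or MUT")
    df["temperature"] = df["temperature"].astype(int)
    if not df["temperature"].isin([25, 37]).all():
        raise ValueError("temperature must be 25 or 37")
    if require_full_design:
        for assay in df["assay"].unique():
            sub = df[df["assay"] == assay]
            cells = {(s, t) for s, t in zip(sub["strain"], sub["temperature"])}
            want = {(s, t) for s in ("WT", "MUT") for t in (25, 37)}
            if cells != want:
                raise ValueError(f"assay {assay}: missing design cells {sorted(want - cells)}")
    return df[SHEET_COLUMNS + [c for c in df.columns if c not in SHEET_COLUMNS]]


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    validate_sample_sheet(sheet).to_csv(path, sep="\t", index=False)


def read_sample_sheet(path) -> pd.DataFrame:
    return validate_sample_sheet(pd.read_csv(path, sep="\t"))
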