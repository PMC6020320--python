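"""Readers and writers for every external format the pipeline touches.

Internal conventions used everywhere in this package:

* coordinates are 1-based inclusive; only BED I/O converts (BED is 0-based
  half-open on disk);
* dosage matrices are samples x variants DataFrames with values in {0, 1, 2}
  (minor-allele counts) and NaN for missing calls;
* expression matrices are genes x samples DataFrames;
* chromosome names are taken verbatim from the files — no "chr" stripping.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "RegionSet",
    "read_genotypes",
    "write_vcf",
    "write_dosage_tsv",
    "read_regions_bed",
    "write_regions_bed",
    "read_gene_table_gff3",
    "write_gene_table_gff3",
    "write_gene_table_bed",
    "read_pfm_jaspar",
    "write_pfm_jaspar",
    "read_gmt",
    "write_gmt",
    "read_expression",
    "write_expression",
    "read_table",
    "write_table",
    "read_fasta",
    "write_fasta",
    "read_chrom_sizes",
    "write_chrom_sizes",
]

BASES = "ACGT"

_DOSAGE_META = ["variant_id", "chromosome", "position", "ref", "alt"]


@dataclass
class RegionSet:
    """A labelled set of genomic intervals, 1-based inclusive.

    Intervals may overlap; nothing is merged on read.
    """

    label: str
    intervals: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["chromosome", "start", "end"])
    )

    def __post_init__(self) -> None:
        iv = self.intervals
        if len(iv) and (iv["start"] > iv["end"]).any():
            raise ValueError("region start must be <= end (1-based inclusive)")

    def __len__(self) -> int:
        return len(self.intervals)


def _finalize_variant_table(variant_table: pd.DataFrame, dosage: pd.DataFrame) -> pd.DataFrame:
    """Fill maf/call_rate columns from the dosage matrix (non-missing calls)."""
    vt = variant_table.copy()
    n_called = dosage.notna().sum(axis=0).to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        freq = dosage.sum(axis=0, skipna=True).to_numpy(dtype=float) / (2.0 * n_called)
    maf = np.minimum(freq, 1.0 - freq)
    vt["maf"] = maf
    vt["call_rate"] = n_called / len(dosage)
    return vt


def read_genotypes(path, fmt: str | None = None):
    """Read genotypes as ``(variant_table, dosage)``.

    Parameters
    ----------
    path : str or Path
        VCF (v4.x, GT field) or dosage TSV as written by :func:`write_dosage_tsv`.
    fmt : {"vcf", "dosage-tsv"}, optional
        Inferred from the file suffix when omitted.
    """
    path = Path(path)
    if fmt is None:
        fmt = "vcf" if path.suffix.lower() == ".vcf" else "dosage-tsv"
    if fmt == "vcf":
        return _read_vcf(path)
    if fmt == "dosage-tsv":
        return _read_dosage_tsv(path)
    raise ValueError(f"unknown genotype format {fmt!r}")


def _read_vcf(path: Path):
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if len(set(samples)) != len(samples):
        raise ValueError("duplicate sample ids in VCF header")
    gt_map = np.array([0.0, 1.0, np.nan, 2.0])  # HOM_REF, HET, UNKNOWN, HOM_ALT
    rows, dosages = [], []
    for v in vcf:
        if v.ALT is None or len(v.ALT) != 1:
            raise ValueError(
                f"multi-allelic record at {v.CHROM}:{v.POS} — split or drop it first; "
                "this pipeline expects biallelic chip-style sites"
            )
        vid = v.ID if v.ID not in (None, ".") else f"{v.CHROM}_{v.POS}"
        rows.append((vid, str(v.CHROM), int(v.POS), v.REF, v.ALT[0]))
        dosages.append(gt_map[np.asarray(v.gt_types)])
    if not rows:
        raise ValueError(f"no variant records in {path}")
    variant_table = pd.DataFrame(rows, columns=_DOSAGE_META)
    if variant_table["variant_id"].duplicated().any():
        raise ValueError("duplicate variant ids in VCF")
    dosage = pd.DataFrame(
        np.asarray(dosages).T, index=samples, columns=variant_table["variant_id"]
    )
    return _finalize_variant_table(variant_table, dosage), dosage


def _read_dosage_tsv(path: Path):
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _DOSAGE_META if c not in df.columns]
    if missing:
        raise ValueError(f"dosage TSV missing required columns: {missing}")
    samples = [c for c in df.columns if c not in _DOSAGE_META]
    if len(set(samples)) != len(samples):
        raise ValueError("duplicate sample ids in dosage TSV header")
    variant_table = df[_DOSAGE_META].copy()
    if variant_table["variant_id"].duplicated().any():
        raise ValueError("duplicate variant ids in dosage TSV")
    dosage = pd.DataFrame(
        df[samples].to_numpy(dtype=float).T,
        index=samples,
        columns=variant_table["variant_id"],
    )
    return _finalize_variant_table(variant_table, dosage), dosage


_GT_STRINGS = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_vcf(variant_table, dosage, path, chrom_lengths=None) -> None:
    """Write a minimal VCF v4.2 with GT-only genotypes."""
    path = Path(path)
    samples = list(dosage.index)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if chrom_lengths:
            for chrom, length in chrom_lengths.items():
                fh.write(f"##contig=<ID={chrom},length={int(length)}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples) + "\n"
        )
        for row in variant_table.itertuples(index=False):
            d = dosage[row.variant_id].to_numpy(dtype=float)
            gts = "\t".join(_GT_STRINGS.get(x, "./.") for x in d)
            fh.write(
                f"{row.chromosome}\t{int(row.position)}\t{row.variant_id}\t"
                f"{row.ref}\t{row.alt}\t.\t.\t.\tGT\t{gts}\n"
            )


def write_dosage_tsv(variant_table, dosage, path) -> None:
    out = variant_table[_DOSAGE_META].copy()
    block = pd.DataFrame(
        dosage.to_numpy(dtype=float).T, columns=list(dosage.index), index=out.index
    )
    pd.concat([out, block], axis=1).to_csv(path, sep="\t", index=False, na_rep="NA")


def read_regions_bed(path, label: str | None = None) -> RegionSet:
    """Read a BED3+ file; converts 0-based half-open to 1-based inclusive."""
    path = Path(path)
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: BED line needs >=3 columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if end <= start:
                raise ValueError(f"{path}:{ln}: BED end must be > start, got {start}..{end}")
            rows.append((chrom, start + 1, end))
    intervals = pd.DataFrame(rows, columns=["chromosome", "start", "end"])
    return RegionSet(label=label or path.stem, intervals=intervals)


def write_regions_bed(regions: RegionSet, path) -> None:
    with open(path, "w") as fh:
        for row in regions.intervals.itertuples(index=False):
            fh.write(f"{row.chromosome}\t{int(row.start) - 1}\t{int(row.end)}\n")


def read_gene_table_gff3(path) -> pd.DataFrame:
    """Read gene features from a GFF3 file into the internal gene table."""
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True, merge_strategy="error"
    )
    rows = []
    for feat in db.features_of_type("gene"):
        gid = feat.attributes.get("ID", [feat.id])[0]
        rows.append((gid, feat.seqid, feat.start, feat.end, feat.strand))
    if not rows:
        raise ValueError(f"no gene features found in {path}")
    gt = pd.DataFrame(rows, columns=["gene_id", "chromosome", "start", "end", "strand"])
    if gt["gene_id"].duplicated().any():
        raise ValueError("duplicate gene ids in GFF3")
    return gt


def write_gene_table_gff3(gene_table, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in gene_table.itertuples(index=False):
            fh.write(
                f"{row.chromosome}\teqtlnet\tgene\t{int(row.start)}\t{int(row.end)}\t"
                f".\t{row.strand}\t.\tID={row.gene_id}\n"
            )


def write_gene_table_bed(gene_table, path) -> None:
    with open(path, "w") as fh:
        for row in gene_table.itertuples(index=False):
            fh.write(f"{row.chromosome}\t{int(row.start) - 1}\t{int(row.end)}\t{row.gene_id}\n")


def read_pfm_jaspar(path) -> np.ndarray:
    """Read a position frequency matrix (JASPAR text or raw 4-row format).

    Returns a 4 x L count matrix in A, C, G, T row order. Column sums may
    differ across positions; normalization happens later (PSSM construction).
    """
    text = Path(path).read_text()
    if not text.strip():
        raise ValueError(f"empty PFM file: {path}")
    try:
        if text.lstrip().startswith(">"):
            motif = motifs.read(_io.StringIO(text), "jaspar")
        else:
            motif = motifs.read(_io.StringIO(text), "pfm")
    except Exception as exc:  # Bio raises assorted parse errors
        raise ValueError(f"could not parse PFM {path}: {exc}") from exc
    counts = np.array([motif.counts[b] for b in BASES], dtype=float)
    if counts.ndim != 2 or counts.shape[0] != 4 or counts.shape[1] == 0:
        raise ValueError("PFM must have four equal-length rows (A, C, G, T)")
    if (counts < 0).any():
        raise ValueError("PFM counts must be non-negative")
    return counts


def write_pfm_jaspar(counts: np.ndarray, path, name: str = "MOTIF1") -> None:
    counts = np.asarray(counts, dtype=float)
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for base, row in zip(BASES, counts):
            vals = " ".join(f"{v:g}" for v in row)
            fh.write(f"{base} [ {vals} ]\n")


def read_gmt(path) -> dict[str, set[str]]:
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: GMT line needs name, description, >=1 gene")
            name = parts[0]
            if name in sets:
                raise ValueError(f"{path}:{ln}: duplicate gene-set name {name!r}")
            sets[name] = {g for g in parts[2:] if g}
    return sets


def write_gmt(gene_sets: dict[str, set[str]], path) -> None:
    with open(path, "w") as fh:
        for name, members in gene_sets.items():
            fh.write(name + "\tna\t" + "\t".join(sorted(members)) + "\n")


def read_expression(path) -> pd.DataFrame:
    """Genes x samples expression TSV with a gene_id index column."""
    df = read_table(path)
    if df.index.duplicated().any():
        raise ValueError("duplicate gene ids in expression matrix")
    return df


def write_expression(expression: pd.DataFrame, path) -> None:
    expression.to_csv(path, sep="\t", index_label="gene_id")


def read_table(path) -> pd.DataFrame:
    """Generic TSV with a header row and an id index column."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    # a header of raw numbers means the file has no header row at all
    if all(_looks_numeric(c) for c in df.columns) and len(df.columns):
        raise ValueError(f"{path}: missing header row")
    return df


def _looks_numeric(value) -> bool:
    try:
        float(value)
    except (TypeError, ValueError):
        return False
    return True


def write_table(df: pd.DataFrame, path, index_label: str = "id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def read_fasta(path) -> dict[str, str]:
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not seqs:
        raise ValueError(f"no sequences in {path}")
    return seqs


def write_fasta(seqs: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_chrom_sizes(path) -> dict[str, int]:
    sizes = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            name, length = line.split()[:2]
            sizes[name] = int(length)
    return sizes


def write_chrom_sizes(sizes: dict[str, int], path) -> None:
    with open(path, "w") as fh:
        for name, length in sizes.items():
            fh.write(f"{name}\t{int(length)}\n")


def check_same_chromosomes(names_a, names_b, what_a: str = "A", what_b: str = "B") -> None:
    """Hard error (with a diff summary) when two inputs disagree on naming."""
    a, b = set(names_a), set(names_b)
    if not a & b:
        raise ValueError(
            f"chromosome naming mismatch between {what_a} and {what_b}: "
            f"{what_a} has {sorted(a)[:5]}, {what_b} has {sorted(b)[:5]}"
        )
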