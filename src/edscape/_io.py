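"""Shared table schemas, readers/writers, and checksum helpers.

All tabular interchange is plain TSV so that runs are reproducible and
diff-able.  Column sets are validated on read; a missing column raises
:class:`SchemaError` naming the offending column(s).
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import pandas as pd

__all__ = [
    "SchemaError",
    "EVIDENCE_COLUMNS",
    "read_evidence",
    "read_design",
    "read_sites",
    "read_exon_counts",
    "read_bed",
    "read_snp_catalog",
    "read_genotypes",
    "write_tsv",
    "sha256_file",
]


class SchemaError(ValueError):
    """A TSV did not carry the columns its consumer requires."""


#: Column order of the read-evidence table (one row per read per site).
EVIDENCE_COLUMNS = [
    "chrom",
    "pos_1based",
    "sample_id",
    "stage",
    "read_id",
    "allele",
    "base_qual",
    "map_qual",
    "read_len",
    "pos_in_read_1based",
    "strand",
    "best_hit_score",
    "second_hit_score",
    "best_hit_overlaps_site",
]

DESIGN_COLUMNS = ["sample_id", "stage"]

EXON_COUNT_COLUMNS = [
    "exon_id",
    "transcript_class",
    "sample_id",
    "inclusion_reads",
    "exclusion_reads",
    "inclusion_len",
    "exclusion_len",
]

GENOTYPE_COLUMNS = ["chrom", "pos", "genotype"]


def _require(df: pd.DataFrame, columns, what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{what}: missing column(s): {', '.join(missing)}"
        )


def read_evidence(path) -> pd.DataFrame:
    """Read a read-evidence TSV and normalize column names.

    ``pos_1based``/``pos_in_read_1based`` are renamed to ``pos`` and
    ``pos_in_read`` internally; the boolean hit-overlap flag is coerced
    to 0/1 integers.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample_id": str})
    _require(df, EVIDENCE_COLUMNS, f"evidence table {path}")
    df = df.rename(
        columns={"pos_1based": "pos", "pos_in_read_1based": "pos_in_read"}
    )
    df["best_hit_overlaps_site"] = df["best_hit_overlaps_site"].astype(int)
    return df


def read_design(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require(df, DESIGN_COLUMNS, f"design table {path}")
    return df


def read_sites(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    _require(df, ["chrom", "pos", "ref", "alt"], f"sites table {path}")
    return df


def read_exon_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"exon_id": str, "sample_id": str})
    _require(df, EXON_COUNT_COLUMNS, f"exon counts table {path}")
    return df


def read_genotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "genotype": str})
    _require(df, GENOTYPE_COLUMNS, f"genotype table {path}")
    return df


def read_bed(path) -> pd.DataFrame:
    """Read a BED file (0-based, half-open). Name column optional."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 3:
        raise SchemaError(f"BED file {path}: expected >=3 columns")
    df = df.iloc[:, :4] if df.shape[1] >= 4 else df.assign(name=".")
    df.columns = ["chrom", "start", "end", "name"][: df.shape[1]]
    if "name" not in df.columns:
        df["name"] = "."
    df["chrom"] = df["chrom"].astype(str)
    return df


def read_snp_catalog(path) -> pd.DataFrame:
    """Read a known-SNP VCF into a (chrom, pos, is_cdna) frame.

    The cDNA molecular-type flag is read from the ``MOLTYPE`` INFO key.
    """
    import pysam

    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            moltype = rec.info.get("MOLTYPE", None)
            if isinstance(moltype, tuple):
                moltype = moltype[0] if moltype else None
            rows.append(
                {
                    "chrom": rec.chrom,
                    "pos": rec.pos,
                    "is_cdna": (moltype == "cDNA"),
                }
            )
    return pd.DataFrame(rows, columns=["chrom", "pos", "is_cdna"])


def write_tsv(df: pd.DataFrame, path, float_format: str = "%.10g") -> None:
    """Deterministic TSV writer (fixed float formatting, no index)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format=float_format)


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
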