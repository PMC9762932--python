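"""Reading and writing the pipeline's table formats.

The per-person variant table travels either as a TSV with one row per
person-variant call, or as a VCF dialect in which each record is one
person-variant call with the annotation subfields in INFO (documented in
``INFO_FIELDS``).  Numeric annotation fields are encoded as decimal strings
in INFO so that a write/read cycle preserves values exactly (VCF Float is
single precision).

TSV outputs written by the pipeline carry ``#``-prefixed header comments
recording the seed and config hash; readers skip comment lines.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd
import pysam


class SchemaError(ValueError):
    """An input table does not conform to the documented schema."""


REQUIRED_VARIANT_COLUMNS = (
    "person_id", "gene", "chrom", "pos", "ref", "alt", "variant_class",
    "consequence_terms", "site_quality", "genotype_quality", "missingness",
    "af_reference", "af_internal", "zygosity",
)
OPTIONAL_VARIANT_COLUMNS = (
    "insilico_score", "clinvar_plp", "alsod_publications", "alsod_patients",
)

#: INFO subfields of the VCF dialect, in column order.
INFO_FIELDS = {
    "PID": ("person_id", str),
    "GENE": ("gene", str),
    "VCLASS": ("variant_class", str),
    "CSQ": ("consequence_terms", str),
    "SQ": ("site_quality", float),
    "GQI": ("genotype_quality", float),
    "MISS": ("missingness", float),
    "AFR": ("af_reference", float),
    "AFI": ("af_internal", float),
    "ZYG": ("zygosity", str),
    "SCORE": ("insilico_score", float),
    "CVPLP": ("clinvar_plp", bool),
    "APUB": ("alsod_publications", int),
    "APAT": ("alsod_patients", int),
}


def validate_variants(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a variant frame against the schema; returns the frame."""
    for col in REQUIRED_VARIANT_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"variant table is missing required column {col!r}")
    for col in ("af_reference", "af_internal", "missingness"):
        vals = df[col].to_numpy(float)
        bad = np.flatnonzero((vals < 0) | (vals > 1) | np.isnan(vals))
        if len(bad):
            raise SchemaError(
                f"column {col!r} must be a fraction in [0, 1]; offending value"
                f" {vals[bad[0]]!r} at row {bad[0] + 1}"
            )
    empty = df["consequence_terms"].astype(str).str.strip() == ""
    if empty.any():
        row = int(np.flatnonzero(empty.to_numpy())[0])
        raise SchemaError(f"column 'consequence_terms' is empty at row {row + 1}")
    return df


def _comment_header(meta: dict | None) -> str:
    if not meta:
        return ""
    return "".join(f"# {k}={v}\n" for k, v in meta.items())


def write_tsv(df: pd.DataFrame, path: str | Path, meta: dict | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_comment_header(meta))
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_variant_table(
    df: pd.DataFrame, path: str | Path, meta: dict | None = None
) -> None:
    """Write a variant table in the dialect implied by the file suffix."""
    if str(path).endswith(".vcf"):
        _write_variant_vcf(df, path)
    else:
        write_tsv(df, path, meta=meta)


def read_variant_table(path: str | Path, dialect: str | None = None) -> pd.DataFrame:
    """Read a variant table (``dialect`` "vcf" or "tsv"; inferred from suffix)."""
    if dialect is None:
        dialect = "vcf" if str(path).endswith(".vcf") else "tsv"
    if dialect == "vcf":
        df = _read_variant_vcf(path)
    elif dialect == "tsv":
        df = read_tsv(path)
        df["chrom"] = df["chrom"].astype(str)
    else:
        raise ValueError(f"unknown variant table dialect: {dialect!r}")
    return validate_variants(df)


def _encode(value, typ) -> str:
    if typ is bool:
        return "1" if value else "0"
    if typ is float:
        return "." if value is None or (isinstance(value, float) and math.isnan(value)) else repr(float(value))
    return str(value)


def _decode(raw: str, typ):
    if typ is bool:
        return raw == "1"
    if typ is float:
        return float("nan") if raw == "." else float(raw)
    if typ is int:
        return int(raw)
    return raw


def _write_variant_vcf(df: pd.DataFrame, path: str | Path) -> None:
    header = pysam.VariantHeader()
    for contig in pd.unique(df["chrom"].astype(str)):
        header.contigs.add(contig)
    if len(df) == 0:
        header.contigs.add("1")
    for key in INFO_FIELDS:
        header.info.add(key, 1, "String", f"alsact annotation field {key}")
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for _, row in df.iterrows():
            rec = vf.new_record(
                contig=str(row["chrom"]),
                start=int(row["pos"]) - 1,
                alleles=(str(row["ref"]), str(row["alt"])),
            )
            rec.qual = float(row["site_quality"])
            for key, (col, typ) in INFO_FIELDS.items():
                if col in df.columns:
                    rec.info[key] = _encode(row[col], typ)
            vf.write(rec)


def _read_variant_vcf(path: str | Path) -> pd.DataFrame:
    rows = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            row = {
                "chrom": rec.contig,
                "pos": rec.pos,
                "ref": rec.ref,
                "alt": rec.alts[0] if rec.alts else "",
            }
            for key, (col, typ) in INFO_FIELDS.items():
                if key in rec.info:
                    row[col] = _decode(rec.info[key], typ)
            rows.append(row)
    columns = ["person_id", "gene", "chrom", "pos", "ref", "alt", "variant_class",
               "consequence_terms", "site_quality", "genotype_quality",
               "missingness", "af_reference", "af_internal", "zygosity",
               "insilico_score", "clinvar_plp", "alsod_publications",
               "alsod_patients"]
    if not rows:
        return pd.DataFrame(columns=columns)
    df = pd.DataFrame(rows)
    return df[[c for c in columns if c in df.columns]]


def read_sample_metrics(path: str | Path) -> pd.DataFrame:
    df = read_tsv(path)
    for col in ("person_id", "titv", "n_snv", "n_indel", "n_singleton",
                "inferred_sex", "reported_sex", "age_onset"):
        if col not in df.columns:
            raise SchemaError(f"sample metrics table is missing column {col!r}")
    return df


def read_repeat_calls(path: str | Path) -> pd.DataFrame:
    df = read_tsv(path)
    for col in ("person_id", "gene", "repeat_count"):
        if col not in df.columns:
            raise SchemaError(f"repeat call table is missing column {col!r}")
    return df


def read_register(path: str | Path) -> pd.DataFrame:
    df = read_tsv(path)
    for col in ("age_group", "sex", "cases", "person_years"):
        if col not in df.columns:
            raise SchemaError(f"register table is missing column {col!r}")
    return df


def read_probabilities(path: str | Path) -> dict:
    """Read an age-group actionable-probability table (columns
    ``age_group``, optional ``sex``, ``p``)."""
    df = read_tsv(path)
    for col in ("age_group", "p"):
        if col not in df.columns:
            raise SchemaError(f"probability table is missing column {col!r}")
    if "sex" in df.columns and df["sex"].notna().any():
        return {
            (r["age_group"], r["sex"]): float(r["p"]) for _, r in df.iterrows()
        }
    return {r["age_group"]: float(r["p"]) for _, r in df.iterrows()}
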