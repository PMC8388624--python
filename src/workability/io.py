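"""Readers and writers for the pipeline's plain-text formats.

All tabular artifacts are UTF-8 CSV (dates ISO-8601, unknown parent = 0),
genotype dosages are TSV with animals as rows, and relationship kernels go
to MatrixMarket files with a sidecar id-map CSV.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.io as sio

from .pedigree import Pedigree
from .relationship import GenotypeMatrix, RelationshipKernel

__all__ = [
    "PHENOTYPE_COLUMNS",
    "ValidationError",
    "read_phenotypes",
    "write_phenotypes",
    "read_pedigree",
    "write_pedigree",
    "read_dosages",
    "write_dosages",
    "read_vcf",
    "write_kernel",
    "write_chain",
    "file_sha256",
]

PHENOTYPE_COLUMNS = [
    "cow_id",
    "sire_id",
    "dam_id",
    "birth_date",
    "calving_date",
    "eval_date",
    "first_test_date",
    "herd_id",
    "hf_percent",
    "ms_score",
    "mt_score",
]

_DATE_COLUMNS = ["birth_date", "calving_date", "eval_date", "first_test_date"]


class ValidationError(ValueError):
    """Fatal input problem (bad schema, unreadable file)."""


def _validate_row(row: pd.Series) -> str | None:
    """Reason the row is rejected, or None if it is valid."""
    for col in _DATE_COLUMNS:
        if pd.isna(row[col]):
            return f"unparseable or missing {col}"
    if not 1 <= row["ms_score"] <= 5 or row["ms_score"] != int(row["ms_score"]):
        return "score out of 1-5 scale"
    if not 1 <= row["mt_score"] <= 3 or row["mt_score"] != int(row["mt_score"]):
        return "score out of 1-3 scale"
    if not 0 <= row["hf_percent"] <= 100:
        return "hf_percent outside 0-100"
    if row["eval_date"] < row["calving_date"]:
        return "evaluation before calving"
    if row["birth_date"] >= row["calving_date"]:
        return "birth not before calving"
    return None


def read_phenotypes(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Validated phenotype records plus an error report.

    Returns ``(records, errors)`` where ``errors`` has columns
    ``line`` (1-based file line number) and ``reason``. A missing
    mandatory column is fatal.
    """
    try:
        raw = pd.read_csv(path, dtype={"cow_id": str, "sire_id": str, "dam_id": str, "herd_id": str})
    except (OSError, pd.errors.ParserError) as exc:
        raise ValidationError(f"cannot read phenotype CSV {path}: {exc}") from exc
    missing = [c for c in PHENOTYPE_COLUMNS if c not in raw.columns]
    if missing:
        raise ValidationError(f"phenotype CSV missing columns: {missing}")
    for col in _DATE_COLUMNS:
        raw[col] = pd.to_datetime(raw[col], errors="coerce")
    for col in ("hf_percent", "ms_score", "mt_score"):
        raw[col] = pd.to_numeric(raw[col], errors="coerce")

    reasons = raw.apply(_validate_row, axis=1) if len(raw) else pd.Series(dtype=object)
    bad = reasons.notna() if len(raw) else pd.Series(dtype=bool)
    errors = pd.DataFrame(
        {
            "line": (raw.index[bad] + 2) if len(raw) else [],  # +1 header, +1 1-based
            "reason": reasons[bad] if len(raw) else [],
        }
    ).reset_index(drop=True)
    kept = raw[~bad].reset_index(drop=True) if len(raw) else raw
    return kept, errors


def write_phenotypes(records: pd.DataFrame, path) -> None:
    df = records[PHENOTYPE_COLUMNS].copy()
    for col in _DATE_COLUMNS:
        df[col] = pd.to_datetime(df[col]).dt.strftime("%Y-%m-%d")
    df.to_csv(path, index=False)


def read_pedigree(path) -> Pedigree:
    frame = pd.read_csv(path, dtype=str).fillna("0")
    missing = [c for c in ("animal", "sire", "dam") if c not in frame.columns]
    if missing:
        raise ValidationError(f"pedigree CSV missing columns: {missing}")
    return Pedigree.from_frame(frame)


def write_pedigree(pedigree: Pedigree, path) -> None:
    pedigree.to_frame().to_csv(path, index=False)


def read_dosages(path) -> GenotypeMatrix:
    """Genotype dosage TSV: rows animals, columns SNPs, entries 0/1/2."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return GenotypeMatrix(
        ids=[str(i) for i in frame.index],
        snp_ids=[str(c) for c in frame.columns],
        dosages=frame.to_numpy(dtype=np.int8),
    )


def write_dosages(genotypes: GenotypeMatrix, path) -> None:
    genotypes.to_frame().to_csv(path, sep="\t", index_label="animal")


def read_vcf(path) -> GenotypeMatrix:
    """Dosages (count of ALT alleles) from a VCF; requires cyvcf2."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    ids = list(vcf.samples)
    snp_ids, rows = [], []
    for variant in vcf:
        snp_ids.append(variant.ID or f"{variant.CHROM}:{variant.POS}")
        gts = np.asarray(variant.genotype.array())[:, :2]
        if (gts < 0).any():
            raise ValidationError(
                f"missing genotype at {snp_ids[-1]}; impute before import"
            )
        rows.append(gts.sum(axis=1))
    dosages = (
        np.column_stack(rows).astype(np.int8)
        if rows
        else np.zeros((len(ids), 0), dtype=np.int8)
    )
    return GenotypeMatrix(ids=ids, snp_ids=snp_ids, dosages=dosages)


def write_kernel(kernel: RelationshipKernel, stem) -> None:
    """MatrixMarket matrix at <stem>.mtx plus <stem>.ids.csv index map."""
    stem = Path(stem)
    m = kernel.matrix if sp.issparse(kernel.matrix) else sp.coo_matrix(kernel.matrix)
    sio.mmwrite(str(stem.with_suffix(".mtx")), m, symmetry="symmetric")
    pd.DataFrame({"index": range(kernel.n), "animal": kernel.ids}).to_csv(
        stem.with_suffix(".ids.csv"), index=False
    )


def write_chain(chain: pd.DataFrame, path) -> None:
    chain.to_csv(path, index=False)


def file_sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_provenance(manifest: dict, path) -> None:
    def default(obj):
        if dataclasses.is_dataclass(obj):
            return dataclasses.asdict(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        return str(obj)

    Path(path).write_text(json.dumps(manifest, indent=2, default=default, sort_keys=True))
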