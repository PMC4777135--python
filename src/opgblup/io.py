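"""Readers and writers for the plain-text dialects used throughout.

* genotype TSV — header ``id<TAB>locus1<TAB>...``; dosages 0/1/2 or NA;
* VCF — biallelic SNP records, GT parsed to alternative-allele counts
  (multi-allelic records skipped, count reported);
* pedigree CSV — ``id,dam,sire`` with empty = unknown parent;
* phenotype CSV — ``id,family,block,<trait>...``;
* kernel TSV — square matrix with sample ids on both axes;
* YAML pipeline configuration.

All writers are deterministic (fixed column order, fixed float format)
so reruns of a seeded pipeline are diff-clean.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .kernels import GenotypeMatrix, PedigreeTable, RelationshipKernel

__all__ = [
    "read_genotypes_tsv",
    "write_genotypes_tsv",
    "read_vcf",
    "read_pedigree_csv",
    "write_pedigree_csv",
    "read_phenotypes_csv",
    "write_phenotypes_csv",
    "read_kernel_tsv",
    "write_kernel_tsv",
    "load_config",
    "dump_config",
]

_FLOAT_FMT = "%.10g"


class FileFormatError(ValueError):
    """A file does not conform to the expected dialect."""


# ---------------------------------------------------------------------------
# genotypes

def read_genotypes_tsv(path: str | Path) -> GenotypeMatrix:
    frame = pd.read_csv(path, sep="\t", dtype={0: str}, na_values=["NA", ""])
    if frame.columns[0] != "id":
        raise FileFormatError(f"{path}: first column must be 'id'")
    ids = frame["id"].tolist()
    loci = list(frame.columns[1:])
    values = frame[loci].to_numpy(float)
    bad = np.isfinite(values) & ~np.isin(values, (0.0, 1.0, 2.0))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise FileFormatError(
            f"{path}: unknown genotype code {values[r, c]!r} at row id "
            f"{ids[r]!r}, locus {loci[c]!r}"
        )
    try:
        return GenotypeMatrix(ids, loci, values)
    except ValueError as err:
        raise FileFormatError(f"{path}: {err}") from err


def write_genotypes_tsv(g: GenotypeMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(g.locus_ids) + "\n")
        for sid, row in zip(g.sample_ids, g.dosages):
            cells = ["NA" if not np.isfinite(v) else str(int(v)) for v in row]
            fh.write(sid + "\t" + "\t".join(cells) + "\n")


def read_vcf(path: str | Path) -> tuple[GenotypeMatrix, int]:
    """Dosages from a VCF; returns the matrix and the skipped-record count.

    Only biallelic SNP records are used; the dosage counts the ALT
    allele.  Missing genotypes become NaN.
    """
    try:
        from cyvcf2 import VCF
    except ImportError as err:  # pragma: no cover
        raise ImportError("reading VCF requires the cyvcf2 package") from err
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    loci: list[str] = []
    rows: list[np.ndarray] = []
    skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1 or not rec.is_snp:
            skipped += 1
            continue
        # gt_types: 0=hom-ref, 1=het, 2=hom-alt(cyvcf2: 3), 2=unknown
        gts = np.array(rec.gt_types, dtype=float)
        dos = np.where(gts == 0, 0.0, np.where(gts == 1, 1.0, np.where(gts == 3, 2.0, np.nan)))
        loci.append(rec.ID or f"{rec.CHROM}:{rec.POS}")
        rows.append(dos)
    if not rows:
        raise FileFormatError(f"{path}: no usable biallelic SNP records")
    return GenotypeMatrix(samples, loci, np.column_stack(rows)), skipped


# ---------------------------------------------------------------------------
# pedigree

def read_pedigree_csv(path: str | Path) -> PedigreeTable:
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    needed = {"id", "dam", "sire"}
    if not needed.issubset(frame.columns):
        raise FileFormatError(f"{path}: pedigree CSV needs columns id,dam,sire")
    rows = [
        (r["id"], r["dam"] or None, r["sire"] or None) for _, r in frame.iterrows()
    ]
    try:
        return PedigreeTable(rows)
    except ValueError as err:
        raise FileFormatError(f"{path}: {err}") from err


def write_pedigree_csv(ped: PedigreeTable | pd.DataFrame, path: str | Path) -> None:
    frame = ped.to_frame() if isinstance(ped, PedigreeTable) else ped
    frame = frame.fillna("")
    frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# phenotypes

def read_phenotypes_csv(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, dtype={"id": str, "family": str, "block": str})
    needed = {"id", "family", "block"}
    if not needed.issubset(frame.columns):
        raise FileFormatError(f"{path}: phenotype CSV needs columns id,family,block")
    traits = [c for c in frame.columns if c not in needed]
    if not traits:
        raise FileFormatError(f"{path}: no trait columns")
    if frame["id"].duplicated().any():
        dup = frame.loc[frame["id"].duplicated(), "id"].iloc[0]
        raise FileFormatError(f"{path}: duplicate id {dup!r}")
    for col in ("family", "block"):
        empty = frame[col].isna() | (frame[col].astype(str).str.strip() == "")
        if empty.any():
            row = int(np.flatnonzero(empty)[0]) + 2  # 1-based incl. header
            raise FileFormatError(f"{path}: empty {col!r} label at line {row}")
    for t in traits:
        if frame[t].notna().sum() == 0:
            warnings.warn(f"{path}: trait {t!r} has no non-missing values")
    return frame


def write_phenotypes_csv(phen: pd.DataFrame, path: str | Path) -> None:
    phen.to_csv(path, index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# kernels

def read_kernel_tsv(path: str | Path, label: str = "") -> RelationshipKernel:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    if list(frame.index) != list(frame.columns):
        raise FileFormatError(f"{path}: kernel row/column ids differ")
    return RelationshipKernel(
        label or Path(path).stem, list(frame.index), frame.to_numpy(float)
    )


def write_kernel_tsv(k: RelationshipKernel, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(k.sample_ids) + "\n")
        for sid, row in zip(k.sample_ids, k.matrix):
            fh.write(sid + "\t" + "\t".join(_FLOAT_FMT % v for v in row) + "\n")


# ---------------------------------------------------------------------------
# configuration

def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise FileFormatError(f"{path}: configuration must be a YAML mapping")
    return cfg


def dump_config(cfg: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
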