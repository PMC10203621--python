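"""Readers and writers for the plain-text formats the pipeline consumes.

Datasets travel as TSV with columns ``id, x, y, partition``; scoring weights
use the PGS Catalog scoring-file layout ('#'-prefixed header lines, then a
tab-separated table with ``rsID``, ``effect_allele``, ``other_allele``,
``effect_weight``); genotypes come from a samples-by-variants dosage TSV or,
optionally, a VCF (GT or DS fields) via cyvcf2.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .cohort import GenotypeMatrix, WeightTable
from .scenarios import LabeledDataset

__all__ = [
    "write_dataset",
    "read_dataset",
    "read_pgs_scoring_file",
    "write_pgs_scoring_file",
    "read_dosage_tsv",
    "write_dosage_tsv",
    "read_vcf",
]

PathLike = Union[str, Path]


def write_dataset(ds: LabeledDataset, path: PathLike) -> None:
    """Write a dataset as TSV with columns id, x, y, partition."""
    df = pd.DataFrame(
        {
            "id": np.arange(1, ds.n + 1),
            "x": ds.x,
            "y": ds.y,
            "partition": ds.partition if ds.partition is not None else "",
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_dataset(path: PathLike) -> LabeledDataset:
    """Read a dataset TSV written by :func:`write_dataset`.

    The ``partition`` column is optional; empty or absent means
    unpartitioned.
    """
    df = pd.read_csv(path, sep="\t")
    for col in ("x", "y"):
        if col not in df.columns:
            raise ValueError(f"dataset {path} is missing required column {col!r}")
    partition = None
    if "partition" in df.columns and df["partition"].notna().any():
        partition = df["partition"].to_numpy(dtype=object)
    return LabeledDataset(
        df["x"].to_numpy(dtype=float), df["y"].to_numpy(dtype=float), partition=partition
    )


# -- PGS Catalog scoring files -------------------------------------------------

_ID_COLUMNS = ("rsID", "rsid", "variant_id", "ID")
_OTHER_COLUMNS = ("other_allele", "reference_allele", "A2")


def read_pgs_scoring_file(path: PathLike) -> WeightTable:
    """Parse a PGS Catalog scoring file into a :class:`WeightTable`.

    Skips '#'-prefixed metadata lines; requires an id column (``rsID`` or a
    recognised alias, else ``chr_name:chr_position`` is synthesised),
    ``effect_allele``, an other/reference-allele column and
    ``effect_weight``.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    cols = set(df.columns)
    if "effect_allele" not in cols or "effect_weight" not in cols:
        raise ValueError(
            f"{path}: a scoring file needs 'effect_allele' and 'effect_weight' "
            f"columns; found {sorted(cols)}"
        )
    id_col = next((c for c in _ID_COLUMNS if c in cols), None)
    if id_col is not None:
        ids = df[id_col].to_numpy(dtype=object)
    elif {"chr_name", "chr_position"} <= cols:
        ids = (df["chr_name"].astype(str) + ":" + df["chr_position"].astype(str)).to_numpy(
            dtype=object
        )
    else:
        raise ValueError(f"{path}: no variant id column (rsID or chr_name/chr_position)")
    other_col = next((c for c in _OTHER_COLUMNS if c in cols), None)
    if other_col is None:
        raise ValueError(f"{path}: no other/reference allele column")
    return WeightTable(
        ids,
        df["effect_allele"].to_numpy(dtype=object),
        df[other_col].to_numpy(dtype=object),
        df["effect_weight"].to_numpy(dtype=float),
    )


def write_pgs_scoring_file(w: WeightTable, path: PathLike, name: str = "synthetic") -> None:
    """Write a weight table in PGS Catalog scoring-file layout."""
    with open(path, "w") as fh:
        fh.write("### PGS CATALOG SCORING FILE\n")
        fh.write(f"#pgs_name={name}\n")
        fh.write(f"#variants_number={w.m}\n")
        w.to_frame().to_csv(fh, sep="\t", index=False)


# -- dosage matrices -----------------------------------------------------------


def write_dosage_tsv(g: GenotypeMatrix, path: PathLike) -> None:
    """Write a samples x variants dosage TSV; first column is sample_id."""
    df = pd.DataFrame(g.dosages, columns=list(g.variant_id))
    df.insert(0, "sample_id", g.sample_id)
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_dosage_tsv(path: PathLike) -> GenotypeMatrix:
    """Read a samples x variants dosage TSV (first column sample_id).

    The TSV carries no allele metadata; the returned matrix has
    ``counted_allele=None`` and scoring assumes columns already count the
    weight table's effect alleles.
    """
    df = pd.read_csv(path, sep="\t", na_values=["NA", ""])
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected a sample_id column plus >=1 variant column")
    sample_id = df.iloc[:, 0].to_numpy(dtype=object)
    variant_id = np.array(df.columns[1:], dtype=object)
    dosages = df.iloc[:, 1:].to_numpy(dtype=float)
    return GenotypeMatrix(dosages, variant_id, sample_id=sample_id)


def read_vcf(path: PathLike, field: str = "GT") -> GenotypeMatrix:
    """Read genotypes from a VCF via cyvcf2; counts the ALT allele.

    ``field="GT"`` counts hard genotype calls; ``field="DS"`` reads the
    dosage FORMAT field.  Requires the optional cyvcf2 dependency.
    """
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("reading VCF requires the optional dependency cyvcf2") from exc
    if field not in ("GT", "DS"):
        raise ValueError(f"field must be 'GT' or 'DS'; got {field!r}")
    vcf = VCF(str(path))
    samples = np.array(vcf.samples, dtype=object)
    ids, counted, other, cols = [], [], [], []
    for var in vcf:
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        counted.append(var.ALT[0] if var.ALT else ".")
        other.append(var.REF)
        if field == "DS":
            ds = np.asarray(var.format("DS"), dtype=float).reshape(-1)
        else:
            # cyvcf2 gt_types: 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
            gt = np.asarray(var.gt_types, dtype=float)
            ds = np.where(gt == 2, np.nan, np.where(gt == 3, 2.0, gt))
        cols.append(ds)
    if not cols:
        raise ValueError(f"{path}: no variants found")
    return GenotypeMatrix(
        np.column_stack(cols),
        np.array(ids, dtype=object),
        counted_allele=np.array(counted, dtype=object),
        other_allele=np.array(other, dtype=object),
        sample_id=samples,
    )
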