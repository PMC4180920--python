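"""Readers and writers for the plain-text interchange formats.

Genotypes travel either as plain TSV (id, line, one column per SNP) or as
PLINK ``.raw`` additive coding (FID IID PAT MAT SEX PHENOTYPE SNP...);
pedigrees and phenotypes as TSV; relationship matrices as TSV with an id
header plus a JSON sidecar holding the kind tag and parameters.  Simulator
configs load from YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datatypes import MISSING, GenotypeMatrix, Pedigree
from .kinship import RelationshipMatrix
from .simdata import LineSpec, SimConfig

__all__ = [
    "write_genotypes_tsv", "read_genotypes_tsv",
    "write_genotypes_plink_raw", "read_genotypes_plink_raw",
    "write_pedigree_tsv", "read_pedigree_tsv",
    "write_phenotypes_tsv", "read_phenotypes_tsv",
    "write_relationship_matrix", "read_relationship_matrix",
    "load_sim_config",
]


def write_genotypes_tsv(geno: GenotypeMatrix, path) -> None:
    geno.to_frame().to_csv(path, sep="\t", index=False)


def read_genotypes_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "line": str})
    snp_cols = [c for c in df.columns if c not in ("id", "line")]
    codes = df[snp_cols].to_numpy()
    codes = np.where(np.isnan(codes.astype(float)), MISSING, codes).astype(np.int8)
    return GenotypeMatrix(
        ids=df["id"].to_numpy(dtype=object),
        lines=df["line"].to_numpy(dtype=object),
        snp_ids=np.array(snp_cols, dtype=object),
        codes=codes,
    )


def write_genotypes_plink_raw(geno: GenotypeMatrix, path) -> None:
    """PLINK additive-coding export; the line label becomes the family id."""
    df = pd.DataFrame(geno.codes.astype(object))
    df = df.where(df != MISSING, "NA")
    df.columns = [f"{s}_A" for s in geno.snp_ids]
    header = pd.DataFrame({
        "FID": geno.lines, "IID": geno.ids,
        "PAT": "0", "MAT": "0", "SEX": "0", "PHENOTYPE": "-9",
    })
    pd.concat([header, df], axis=1).to_csv(path, sep=" ", index=False)


def read_genotypes_plink_raw(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep=r"\s+", dtype={"FID": str, "IID": str})
    snp_cols = [c for c in df.columns
                if c not in ("FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE")]
    codes = df[snp_cols].apply(pd.to_numeric, errors="coerce").to_numpy()
    codes = np.where(np.isnan(codes), MISSING, codes).astype(np.int8)
    snp_ids = [c[:-2] if c.endswith(("_A", "_C", "_G", "_T")) else c
               for c in snp_cols]
    return GenotypeMatrix(
        ids=df["IID"].to_numpy(dtype=object),
        lines=df["FID"].to_numpy(dtype=object),
        snp_ids=np.array(snp_ids, dtype=object),
        codes=codes,
    )


def write_pedigree_tsv(ped: Pedigree, path) -> None:
    ped.table.to_csv(path, sep="\t", index=False)


def read_pedigree_tsv(path) -> Pedigree:
    return Pedigree(pd.read_csv(
        path, sep="\t", dtype={"id": str, "sire": str, "dam": str, "line": str}))


def write_phenotypes_tsv(pheno: pd.DataFrame, path) -> None:
    pheno.to_csv(path, sep="\t", index=False)


def read_phenotypes_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"id": str, "line": str})


def write_relationship_matrix(mat: RelationshipMatrix, path) -> None:
    path = Path(path)
    mat.to_frame().to_csv(path, sep="\t")
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(
        {"kind": mat.kind, "metadata": mat.metadata}, indent=2))


def read_relationship_matrix(path) -> RelationshipMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    sidecar = path.with_suffix(path.suffix + ".json")
    info = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return RelationshipMatrix(
        ids=df.index.to_numpy(dtype=object),
        values=df.to_numpy(dtype=float),
        kind=info.get("kind", "G_vanraden"),
        metadata=info.get("metadata", {}),
    )


def load_sim_config(path) -> SimConfig:
    """Build a :class:`SimConfig` from a YAML file.

    Expected layout::

        n_snps: 4000
        seed: 11
        lines:
          - {name: B1, generations_since_split: 20, effective_size: 50,
             n_train: 1000, n_validation: 240}
          - ...
        heritability: {B1: 0.41, B2: 0.41, W1: 0.51}
        qtl_effect_correlation: [[1.0, 0.8, 0.3], ...]
    """
    raw = yaml.safe_load(Path(path).read_text())
    lines = tuple(LineSpec(**spec) for spec in raw.pop("lines"))
    corr = raw.pop("qtl_effect_correlation", None)
    if corr is not None:
        corr = np.asarray(corr, dtype=float)
    return SimConfig(lines=lines, qtl_effect_correlation=corr, **raw)
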