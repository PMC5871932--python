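"""Delimited-text readers/writers and the run manifest.

Dialect: comma-separated, UTF-8, "NA" missing token, mandatory headers.
Genotype matrices are individual-major (rows = individuals, header = marker
ids); map positions are real-valued cM with 1-based linkage groups.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import GeneticMap, GenotypeMatrix, Population

NA = "NA"

__all__ = [
    "write_genotypes", "read_genotypes",
    "write_map", "read_map",
    "write_phenotypes", "read_phenotypes",
    "write_pedigree",
    "write_manifest", "read_manifest",
    "read_vcf_dosages",
    "sha256_of",
]


def write_genotypes(geno: GenotypeMatrix, path) -> None:
    df = geno.to_frame()
    df.index.name = "individual_id"
    df.to_csv(path, na_rep=NA, float_format="%.10g")
    # sidecar with marker modes so dominant/codominant coding round-trips
    modes = pd.DataFrame({"marker_id": geno.marker_ids, "mode": geno.modes})
    modes.to_csv(Path(path).with_suffix(".modes.csv"), index=False)


def read_genotypes(path) -> GenotypeMatrix:
    path = Path(path)
    try:
        df = pd.read_csv(path, index_col=0, na_values=[NA])
    except Exception as exc:  # pragma: no cover - message formatting
        raise ValueError(f"malformed genotype file {path}: {exc}") from exc
    vals = df.to_numpy(dtype=float)
    bad = ~(np.isnan(vals) | np.isin(vals, [0.0, 1.0, 2.0]))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValueError(
            f"invalid genotype value {vals[r, c]!r} at row {df.index[r]!r}, "
            f"column {df.columns[c]!r} in {path}"
        )
    modes_path = path.with_suffix(".modes.csv")
    if modes_path.exists():
        modes = pd.read_csv(modes_path)["mode"].to_numpy(dtype=object)
    else:
        # infer: columns containing a 2 are codominant
        modes = np.where((vals == 2).any(axis=0), "codominant", "dominant").astype(object)
    return GenotypeMatrix(df.index.to_numpy(dtype=object),
                          df.columns.to_numpy(dtype=object), vals, modes)


def write_map(gmap: GeneticMap, path) -> None:
    gmap.to_frame().to_csv(path, index=False, float_format="%.10g")


def read_map(path) -> GeneticMap:
    df = pd.read_csv(path)
    required = {"marker_id", "linkage_group", "position_cM", "mode"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"map file {path} missing columns {sorted(missing)}")
    return GeneticMap.from_frame(df)


def write_phenotypes(phenos: pd.DataFrame, path) -> None:
    out = phenos.copy()
    out.index.name = "individual_id"
    out.to_csv(path, na_rep=NA, float_format="%.12g")


def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0, na_values=[NA])


def write_pedigree(pop: Population, path) -> None:
    pop.pedigree_frame().to_csv(path, index=False)


def sha256_of(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(path, config: dict, master_seed: int, stage_seeds: dict,
                   files: list | None = None, extra: dict | None = None) -> None:
    manifest = {
        "config": config,
        "master_seed": master_seed,
        "stage_seeds": stage_seeds,
        "files": {str(f): sha256_of(f) for f in (files or [])},
    }
    if extra:
        manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=2, default=str))


def read_manifest(path) -> dict:
    return json.loads(Path(path).read_text())


def read_vcf_dosages(path) -> GenotypeMatrix:
    """Optional VCF reader: biallelic GT fields mapped to dosage {0,1,2}."""
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise ImportError("cyvcf2 is required for VCF input") from exc
    vcf = VCF(str(path))
    samples = np.array(vcf.samples, dtype=object)
    ids, cols = [], []
    for var in vcf:
        if len(var.ALT) != 1:
            continue
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        g = np.array(var.gt_types, dtype=float)  # 0=hom_ref,1=het,2=unknown,3=hom_alt
        dosage = np.where(g == 0, 0.0, np.where(g == 1, 1.0, np.where(g == 3, 2.0, np.nan)))
        cols.append(dosage)
    if not cols:
        raise ValueError(f"no biallelic variants in {path}")
    vals = np.column_stack(cols)
    modes = np.array(["codominant"] * len(ids), dtype=object)
    return GenotypeMatrix(samples, np.array(ids, dtype=object), vals, modes)
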