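"""Serialization of pipeline artifacts: TSV, VCF, JSON.

Every stage writes plain-text artifacts so runs are diffable and the CLI
subcommands composable.  VCF export writes GT-only records (0/0, 0/1, 1/1,
./.) with the risk allele as ALT; reading back through the VCF reader
recovers the identical count matrix.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    MISSING,
    GenotypeMatrix,
    IncidenceMatrix,
    specs_from_frame,
    specs_to_frame,
)

_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_genotypes_tsv(G: GenotypeMatrix, path: str | Path) -> None:
    df = G.to_frame()
    df.to_csv(path, sep="\t", na_rep="NA", float_format="%.0f")


def write_variant_specs(G: GenotypeMatrix, path: str | Path) -> None:
    specs_to_frame(G.variant_specs).to_csv(path, sep="\t", index=False)


def read_variant_specs(path: str | Path):
    return specs_from_frame(pd.read_csv(path, sep="\t"))


def write_vcf(G: GenotypeMatrix, path: str | Path) -> None:
    """Minimal GT-only VCF 4.2 export, risk allele as ALT."""
    contigs = []
    for s in G.variant_specs:
        chrom = s.chromosome or "1"
        if chrom not in contigs:
            contigs.append(chrom)
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        *[f"##contig=<ID={c}>" for c in contigs],
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(G.subject_ids),
    ]
    for j, s in enumerate(G.variant_specs):
        alt = s.risk_allele or "A"
        ref = "G" if alt != "G" else "C"
        chrom = s.chromosome or "1"
        pos = s.position or (j + 1) * 1000
        gts = "\t".join(_GT[int(c)] for c in G.counts[:, j])
        lines.append(
            f"{chrom}\t{pos}\t{s.variant_id}\t{ref}\t{alt}\t.\t.\t.\tGT\t{gts}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_phenotype_tsv(subject_ids, phenotype, path: str | Path) -> None:
    pd.DataFrame(
        {"subject_id": subject_ids, "phenotype": np.asarray(phenotype).astype(int)}
    ).to_csv(path, sep="\t", index=False)


def read_phenotype_tsv(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    return df.set_index("subject_id")["phenotype"]


def write_covariates_tsv(subject_ids, covariates, path: str | Path) -> None:
    C = np.asarray(covariates)
    df = pd.DataFrame(
        C, index=pd.Index(subject_ids, name="subject_id"),
        columns=[f"mds{k + 1}" for k in range(C.shape[1])],
    )
    df.to_csv(path, sep="\t")


def read_covariates_tsv(path: str | Path) -> np.ndarray:
    return pd.read_csv(path, sep="\t", index_col=0).to_numpy(dtype=float)


def write_incidence_tsv(I: IncidenceMatrix, path: str | Path) -> None:
    I.to_frame().to_csv(path, sep="\t")


def read_incidence_tsv(path: str | Path, phenotype_item: str = "MS") -> IncidenceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return IncidenceMatrix.from_frame(df.astype(bool), phenotype_item)


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonify) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())


def _jsonify(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, tuple):
        return list(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
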