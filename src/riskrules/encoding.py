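"""Genotype ingestion, imputation, dominant-model encoding and substructure.

The encoding step turns risk-allele counts into the binary incidence matrix
that rule mining consumes: one item per variant under the dominant model
(carrier of >=1 risk allele, or zero copies for absence-mode variants) plus
one phenotype item.  Substructure covariates are the principal coordinates
(classical MDS) of the pairwise identity-by-state distance matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    MISSING,
    GenotypeMatrix,
    IncidenceMatrix,
    VariantSpec,
)


@dataclass
class ReadReport:
    """Structured account of spec variants that could not be read verbatim."""

    absent_variants: list[str] = field(default_factory=list)
    flipped_variants: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.absent_variants


class AlleleMismatchError(ValueError):
    pass


def _counts_from_tsv(path: Path, spec: list[VariantSpec]) -> tuple[pd.DataFrame, ReadReport]:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA", "./."])
    report = ReadReport(absent_variants=[s.variant_id for s in spec if s.variant_id not in df.columns])
    return df, report


def _counts_from_plink_raw(path: Path, spec: list[VariantSpec]) -> tuple[pd.DataFrame, ReadReport]:
    # PLINK .raw: FID IID PAT MAT SEX PHENOTYPE then <variant>_<countedallele> columns
    df = pd.read_csv(path, sep=r"\s+")
    meta_cols = {"FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"}
    df = df.set_index("IID")
    geno = df[[c for c in df.columns if c not in meta_cols]]
    col_by_variant: dict[str, tuple[str, str]] = {}
    for col in geno.columns:
        vid, _, allele = col.rpartition("_")
        col_by_variant[vid] = (col, allele)

    report = ReadReport()
    out = {}
    for s in spec:
        if s.variant_id not in col_by_variant:
            report.absent_variants.append(s.variant_id)
            continue
        col, counted = col_by_variant[s.variant_id]
        vals = geno[col].astype(float)
        if s.risk_allele and counted != s.risk_allele:
            vals = 2.0 - vals
            report.flipped_variants.append(s.variant_id)
        out[s.variant_id] = vals
    return pd.DataFrame(out, index=geno.index), report


def _counts_from_vcf(path: Path, spec: list[VariantSpec]) -> tuple[pd.DataFrame, ReadReport]:
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    subjects = list(vcf.samples)
    by_id: dict[str, np.ndarray] = {}
    alleles: dict[str, tuple[str, str]] = {}
    for rec in vcf:
        vid = rec.ID or f"{rec.CHROM}:{rec.POS}"
        # gt_types with gts012: 0=hom-ref, 1=het, 2=hom-alt, 3=unknown
        alt_counts = rec.gt_types.astype(float)
        alt_counts[alt_counts == 3] = np.nan
        by_id[vid] = alt_counts
        by_id.setdefault(f"{rec.CHROM}:{rec.POS}", alt_counts)
        alts = rec.ALT[0] if rec.ALT else ""
        alleles[vid] = (rec.REF, alts)
        alleles.setdefault(f"{rec.CHROM}:{rec.POS}", (rec.REF, alts))
    vcf.close()

    report = ReadReport()
    out = {}
    for s in spec:
        key = s.variant_id if s.variant_id in by_id else f"{s.chromosome}:{s.position}"
        if key not in by_id:
            report.absent_variants.append(s.variant_id)
            continue
        ref, alt = alleles[key]
        vals = by_id[key]
        if s.risk_allele:
            if s.risk_allele == alt:
                pass
            elif s.risk_allele == ref:
                vals = 2.0 - vals
                report.flipped_variants.append(s.variant_id)
            else:
                raise AlleleMismatchError(
                    f"variant {s.variant_id!r}: risk allele {s.risk_allele!r} is "
                    f"neither REF ({ref!r}) nor ALT ({alt!r})"
                )
        out[s.variant_id] = vals
    return pd.DataFrame(out, index=subjects), report


def read_genotypes(
    path: str | Path,
    format: str,
    spec: list[VariantSpec] | pd.DataFrame,
) -> GenotypeMatrix:
    """Read genotypes in one of three dialects, oriented to the risk allele.

    Parameters
    ----------
    path : file path
    format : "vcf" | "plink_raw" | "tsv"
        ``vcf`` reads GT fields via cyvcf2 (0/0, 0/1, 1/1, ./.) and flips
        counts when the spec's risk allele is the REF allele.  ``plink_raw``
        reads the PLINK additive-dosage text export (counted allele in the
        column header).  ``tsv`` expects rows = subjects, columns = variant
        ids, values 0/1/2/NA already oriented to the risk allele.
    spec : variant specification table

    Returns a :class:`GenotypeMatrix` whose ``read_report`` attribute lists
    spec variants absent from the file (never silently dropped) and variants
    whose counts were flipped.  A risk allele matching neither file allele is
    a hard error.
    """
    from .containers import specs_from_frame

    if isinstance(spec, pd.DataFrame):
        spec = specs_from_frame(spec)
    path = Path(path)
    readers = {
        "tsv": _counts_from_tsv,
        "plink_raw": _counts_from_plink_raw,
        "vcf": _counts_from_vcf,
    }
    if format not in readers:
        raise ValueError(f"unknown genotype format {format!r}; expected one of {sorted(readers)}")
    df, report = readers[format](path, spec)

    present = [s for s in spec if s.variant_id in df.columns]
    vals = df[[s.variant_id for s in present]].to_numpy(dtype=float)
    counts = np.where(np.isnan(vals), MISSING, vals).astype(np.int8)
    G = GenotypeMatrix(
        subject_ids=[str(i) for i in df.index],
        variant_specs=present,
        counts=counts,
    )
    G.read_report = report  # type: ignore[attr-defined]
    return G


def impute_missing(
    G: GenotypeMatrix,
    method: str = "mode",
    seed: int = 0,
    max_missing_fraction: float = 0.05,
    max_iter: int = 10,
) -> GenotypeMatrix:
    """Fill residual missing genotype codes.

    method="mode" replaces missing calls with the variant's most frequent
    observed code (ties broken toward the smaller code) — deterministic.
    method="iterative_forest" initialises with the mode fill and then
    iteratively re-predicts each incomplete variant from all other variants
    with a random-forest classifier until assignments stabilise.
    """
    if not G.has_missing():
        return G.copy()
    counts = G.counts.copy()
    miss = counts == MISSING

    frac = miss.mean(axis=0)
    over = np.flatnonzero(frac > max_missing_fraction)
    if over.size:
        names = [G.variant_ids[j] for j in over]
        raise ValueError(
            f"per-variant missingness exceeds ceiling {max_missing_fraction:.0%} "
            f"for: {names}"
        )
    all_missing = np.flatnonzero(miss.all(axis=0))
    if all_missing.size:
        names = [G.variant_ids[j] for j in all_missing]
        raise ValueError(f"variants with all values missing: {names}")

    def mode_fill(c: np.ndarray, m: np.ndarray) -> np.ndarray:
        c = c.copy()
        for j in np.flatnonzero(m.any(axis=0)):
            obs = c[~m[:, j], j]
            vals, freq = np.unique(obs, return_counts=True)
            c[m[:, j], j] = vals[np.argmax(freq)]
        return c

    if method == "mode":
        filled = mode_fill(counts, miss)
    elif method == "iterative_forest":
        from sklearn.ensemble import RandomForestClassifier

        filled = mode_fill(counts, miss)
        incomplete = np.flatnonzero(miss.any(axis=0))
        rng = np.random.default_rng(seed)
        for _ in range(max_iter):
            changed = 0
            for j in incomplete:
                rows = miss[:, j]
                X = np.delete(filled, j, axis=1)
                clf = RandomForestClassifier(
                    n_estimators=50,
                    random_state=int(rng.integers(2**31 - 1)),
                    n_jobs=1,
                )
                clf.fit(X[~rows], filled[~rows, j])
                pred = clf.predict(X[rows]).astype(np.int8)
                changed += int((pred != filled[rows, j]).sum())
                filled[rows, j] = pred
            if changed == 0:
                break
    else:
        raise ValueError(f"unknown imputation method {method!r}")

    return GenotypeMatrix(
        subject_ids=list(G.subject_ids),
        variant_specs=list(G.variant_specs),
        counts=filled,
    )


def encode_incidence(
    G: GenotypeMatrix,
    phenotype: np.ndarray,
    phenotype_item: str = "MS",
) -> IncidenceMatrix:
    """Build the binary incidence matrix (dominant model + phenotype item).

    Presence-mode items are true when the subject carries >=1 risk allele;
    absence-mode items are true when the subject carries zero copies.  The
    phenotype is appended as the final item.  Missing genotype codes are a
    hard error: impute first.
    """
    phenotype = np.asarray(phenotype).astype(int)
    if phenotype.shape[0] != G.n_subjects:
        raise ValueError("phenotype length != number of subjects")
    if not np.isin(phenotype, (0, 1)).all():
        raise ValueError("phenotype must be binary 0/1")
    if G.has_missing():
        raise ValueError(
            "genotype matrix contains missing codes; run impute_missing first"
        )
    if phenotype_item in G.variant_ids:
        raise ValueError(f"phenotype item {phenotype_item!r} collides with a variant id")

    cols = np.empty((G.n_subjects, G.n_variants + 1), dtype=bool)
    for j, s in enumerate(G.variant_specs):
        if s.mode == "presence":
            cols[:, j] = G.counts[:, j] >= 1
        else:
            cols[:, j] = G.counts[:, j] == 0
    cols[:, -1] = phenotype == 1
    return IncidenceMatrix(
        subject_ids=list(G.subject_ids),
        item_ids=G.variant_ids + [phenotype_item],
        cells=cols,
        phenotype_item=phenotype_item,
    )


def ibs_distance(G: GenotypeMatrix) -> np.ndarray:
    """Pairwise allele-sharing distance: 1 - proportion of alleles IBS.

    For diploid counts g, the proportion of alleles identical by state between
    two subjects at one variant is 1 - |g_i - g_j| / 2; the distance averages
    its complement over variants.
    """
    if G.has_missing():
        raise ValueError("IBS distance requires a complete genotype matrix")
    X = G.counts
    # sum_j |g_i - g_j| via indicator matmuls: |a-b| is 1 for {0,1} or {1,2}
    # pairs and 2 for {0,2} pairs
    A0 = (X == 0).astype(np.float64)
    A1 = (X == 1).astype(np.float64)
    A2 = (X == 2).astype(np.float64)
    one_step = A0 @ A1.T + A1 @ A2.T
    two_step = A0 @ A2.T
    absdiff = one_step + one_step.T + 2.0 * (two_step + two_step.T)
    return absdiff / (2.0 * G.n_variants)


def compute_substructure(G: GenotypeMatrix, k: int = 3) -> np.ndarray:
    """Classical metric MDS (principal coordinates) of the IBS distance.

    Returns the first ``k`` coordinate columns, with each column's sign fixed
    so its largest-magnitude loading is positive.  Used downstream as
    population-substructure covariates in adjusted logistic models.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n = G.n_subjects
    if k >= n:
        raise ValueError(f"k = {k} must be smaller than the subject count {n}")
    D = ibs_distance(G)
    # double-centred Gower matrix
    D2 = D**2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1][:k]
    coords = vecs[:, order] * np.sqrt(np.clip(vals[order], 0.0, None))
    for j in range(coords.shape[1]):
        i = np.argmax(np.abs(coords[:, j]))
        if coords[i, j] < 0:
            coords[:, j] = -coords[:, j]
    return coords
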