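"""Core data containers shared across the pipeline.

Genotypes are stored as risk-allele counts (0, 1, 2) with ``MISSING`` (-1)
marking unobserved calls.  The binary incidence matrix holds one dominant-model
item per variant plus a single phenotype item (the disease consequent).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

MISSING: int = -1

VALID_MODES = ("presence", "absence")


@dataclass(frozen=True)
class VariantSpec:
    """Metadata for one variant: identity, genomic location and encoding mode.

    ``mode`` controls the dominant-model item: ``presence`` items are true for
    carriers of >=1 risk allele; ``absence`` items are true for subjects with
    zero copies (used e.g. for protective HLA class I alleles whose *absence*
    confers risk).  Positions are 1-based metadata and never enter computation.
    """

    variant_id: str
    chromosome: str = ""
    position: int = 0
    gene: str = ""
    risk_allele: str = ""
    mode: str = "presence"

    def __post_init__(self) -> None:
        if self.mode not in VALID_MODES:
            raise ValueError(
                f"variant {self.variant_id!r}: mode must be one of {VALID_MODES}, "
                f"got {self.mode!r}"
            )


def specs_to_frame(specs: list[VariantSpec]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "variant_id": [s.variant_id for s in specs],
            "chromosome": [s.chromosome for s in specs],
            "position": [s.position for s in specs],
            "gene": [s.gene for s in specs],
            "risk_allele": [s.risk_allele for s in specs],
            "mode": [s.mode for s in specs],
        }
    )


def specs_from_frame(df: pd.DataFrame) -> list[VariantSpec]:
    required = {"variant_id", "mode"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"variant spec table missing columns: {sorted(missing)}")
    specs = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        specs.append(
            VariantSpec(
                variant_id=str(d["variant_id"]),
                chromosome=str(d.get("chromosome", "")),
                position=int(d.get("position", 0) or 0),
                gene="" if pd.isna(d.get("gene", "")) else str(d.get("gene", "")),
                risk_allele=str(d.get("risk_allele", "")),
                mode=str(d["mode"]),
            )
        )
    ids = [s.variant_id for s in specs]
    if len(set(ids)) != len(ids):
        dupes = sorted({v for v in ids if ids.count(v) > 1})
        raise ValueError(f"duplicate variant_id in spec table: {dupes}")
    return specs


@dataclass
class GenotypeMatrix:
    """Subjects x variants risk-allele counts with variant metadata."""

    subject_ids: list[str]
    variant_specs: list[VariantSpec]
    counts: np.ndarray  # int8, values in {0, 1, 2, MISSING}

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int8)
        n, m = self.counts.shape
        if n != len(self.subject_ids):
            raise ValueError(
                f"counts has {n} rows but {len(self.subject_ids)} subject ids"
            )
        if m != len(self.variant_specs):
            raise ValueError(
                f"counts has {m} columns but {len(self.variant_specs)} variant specs"
            )
        bad = ~np.isin(self.counts, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError(
                f"genotype counts contain invalid codes: "
                f"{sorted(np.unique(self.counts[bad]).tolist())}"
            )

    @property
    def variant_ids(self) -> list[str]:
        return [s.variant_id for s in self.variant_specs]

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variant_specs)

    def has_missing(self) -> bool:
        return bool((self.counts == MISSING).any())

    def missing_fraction(self) -> float:
        return float((self.counts == MISSING).mean())

    def copy(self) -> "GenotypeMatrix":
        return replace(self, counts=self.counts.copy())

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.counts.astype(float),
            index=pd.Index(self.subject_ids, name="subject_id"),
            columns=self.variant_ids,
        )
        return df.where(df != MISSING, other=np.nan)

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, specs: list[VariantSpec] | None = None
    ) -> "GenotypeMatrix":
        if specs is None:
            specs = [VariantSpec(variant_id=str(c)) for c in df.columns]
        else:
            df = df[[s.variant_id for s in specs]]
        vals = df.to_numpy(dtype=float)
        counts = np.where(np.isnan(vals), MISSING, vals).astype(np.int8)
        return cls(
            subject_ids=[str(i) for i in df.index],
            variant_specs=specs,
            counts=counts,
        )


@dataclass
class IncidenceMatrix:
    """Subjects x binary items, the transaction table mined for rules.

    Exactly one item is the phenotype (disease) item; all other items are
    dominant-model variant indicators.
    """

    subject_ids: list[str]
    item_ids: list[str]
    cells: np.ndarray  # bool, subjects x items
    phenotype_item: str

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=bool)
        n, m = self.cells.shape
        if n != len(self.subject_ids):
            raise ValueError("cells row count != number of subjects")
        if m != len(self.item_ids):
            raise ValueError("cells column count != number of items")
        if len(set(self.item_ids)) != len(self.item_ids):
            raise ValueError("item ids are not unique")
        if self.phenotype_item not in self.item_ids:
            raise ValueError(
                f"phenotype item {self.phenotype_item!r} not among items"
            )

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_items(self) -> int:
        return len(self.item_ids)

    def item_index(self, item: str) -> int:
        try:
            return self.item_ids.index(item)
        except ValueError:
            raise KeyError(f"unknown item id: {item!r}") from None

    def columns(self, items) -> np.ndarray:
        idx = [self.item_index(i) for i in items]
        return self.cells[:, idx]

    @property
    def phenotype(self) -> np.ndarray:
        """Binary phenotype vector (1 = case) recovered from the phenotype item."""
        return self.cells[:, self.item_index(self.phenotype_item)].astype(np.int8)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.cells.astype(int),
            index=pd.Index(self.subject_ids, name="subject_id"),
            columns=self.item_ids,
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, phenotype_item: str) -> "IncidenceMatrix":
        return cls(
            subject_ids=[str(i) for i in df.index],
            item_ids=[str(c) for c in df.columns],
            cells=df.to_numpy(dtype=bool),
            phenotype_item=phenotype_item,
        )
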