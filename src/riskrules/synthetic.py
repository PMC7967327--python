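"""Synthetic case-control cohorts with planted higher-order risk patterns.

The generator emulates a modestly sized candidate-variant study: a few
hundred biallelic variants drawn from Hardy-Weinberg proportions, a binary
disease assigned by a logistic liability with weak per-variant marginal
effects and a large joint effect for carriers of every item of a planted
pattern, mild two-group population substructure, and a trace of missingness
on a handful of variants.  Everything is reproducible from one integer seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .containers import MISSING, GenotypeMatrix, IncidenceMatrix, VariantSpec


class InfeasibleCohortError(RuntimeError):
    """The liability model cannot yield the requested group size at the cap."""


@dataclass(frozen=True)
class PlantedPattern:
    """A set of variants whose joint carriage multiplies the disease odds.

    ``joint_odds_ratio`` applies when a subject carries >=1 risk allele at
    every item; ``marginal_odds_ratios`` apply per carried item regardless.
    """

    items: tuple[str, ...]
    joint_odds_ratio: float
    marginal_odds_ratios: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if len(set(self.items)) != len(self.items):
            raise ValueError("pattern items must be distinct")
        if not 2 <= len(self.items) <= 4:
            raise ValueError("pattern size must be 2-4 items")
        if self.joint_odds_ratio <= 0:
            raise ValueError("joint_odds_ratio must be positive")
        if self.marginal_odds_ratios is not None:
            if len(self.marginal_odds_ratios) != len(self.items):
                raise ValueError("one marginal OR per item required")
            if any(m <= 0 for m in self.marginal_odds_ratios):
                raise ValueError("marginal odds ratios must be positive")

    def marginals(self) -> tuple[float, ...]:
        if self.marginal_odds_ratios is None:
            return tuple(1.1 for _ in self.items)
        return tuple(self.marginal_odds_ratios)


@dataclass
class SyntheticCohortConfig:
    n_cases: int = 207
    n_controls: int = 179
    n_variants: int = 196
    maf_range: tuple[float, float] = (0.05, 0.22)
    baseline_prevalence: float = 0.2
    patterns: list[PlantedPattern] = field(default_factory=list)
    n_substructure_dims: int = 3
    substructure_effect: float = 0.3
    substructure_maf_shift: float = 0.05
    missing_rate: float = 0.0
    n_missing_variants: int = 7
    pattern_item_maf: float | None = 0.20
    seed: int = 0
    oversample_cap: int = 200  # max draws, as a multiple of the cohort size

    def __post_init__(self) -> None:
        if self.n_cases + self.n_controls < 2:
            raise ValueError("cohort must contain at least 2 subjects")
        lo, hi = self.maf_range
        if not 0 < lo <= hi <= 0.5:
            raise ValueError("maf_range must lie in (0, 0.5] with lo <= hi")
        if not 0 < self.baseline_prevalence < 1:
            raise ValueError("baseline_prevalence must be a probability in (0,1)")
        if not 0 <= self.missing_rate <= 0.05:
            raise ValueError("missing_rate must be <= 0.05")
        ids = set(self.variant_ids)
        for p in self.patterns:
            extra = set(p.items) - ids
            if extra:
                raise ValueError(f"pattern items not among cohort variants: {sorted(extra)}")

    @property
    def variant_ids(self) -> list[str]:
        width = len(str(self.n_variants))
        return [f"v{j + 1:0{width}d}" for j in range(self.n_variants)]


@dataclass
class SyntheticCohort:
    genotypes: GenotypeMatrix
    phenotype: np.ndarray  # int8, 1 = case
    covariates: np.ndarray  # subjects x n_substructure_dims
    truth: dict

    @property
    def n_subjects(self) -> int:
        return self.genotypes.n_subjects


def default_study_config(seed: int = 0, **overrides) -> SyntheticCohortConfig:
    """Study-scale defaults: 207 cases / 179 controls, 196 variants, two
    planted triads (joint OR 20 and 8) with weak (1.1) marginal effects."""
    cfg = SyntheticCohortConfig(seed=seed, **overrides)
    if "patterns" not in overrides:
        ids = cfg.variant_ids
        cfg.patterns = [
            PlantedPattern(items=tuple(ids[0:3]), joint_odds_ratio=20.0),
            PlantedPattern(items=tuple(ids[3:6]), joint_odds_ratio=8.0),
        ]
    return cfg


def _pattern_carrier_counts(
    carriers: np.ndarray, phenotype: np.ndarray, cfg: SyntheticCohortConfig
) -> list[dict]:
    id_to_col = {v: j for j, v in enumerate(cfg.variant_ids)}
    out = []
    for p in cfg.patterns:
        joint = carriers[:, [id_to_col[i] for i in p.items]].all(axis=1)
        out.append(
            {
                "items": list(p.items),
                "joint_odds_ratio": p.joint_odds_ratio,
                "carriers_cases": int(joint[phenotype == 1].sum()),
                "carriers_controls": int(joint[phenotype == 0].sum()),
            }
        )
    return out


def simulate_cohort(config: SyntheticCohortConfig) -> SyntheticCohort:
    """Draw a case-control cohort from the logistic liability model.

    Genotypes come from Hardy-Weinberg proportions at per-variant MAFs
    sampled uniformly from ``maf_range`` (pattern items optionally pinned to
    ``pattern_item_maf`` so planted patterns are frequent enough to mine).
    Substructure is a latent two-group mixture shifting allele frequencies
    and adding a group term to the liability.  Subjects are drawn in batches
    and the first ``n_cases`` cases / ``n_controls`` controls retained, so
    group sizes are hit exactly; an infeasible demand fails at the
    oversampling cap with the offending group named.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n_needed = cfg.n_cases + cfg.n_controls
    m = cfg.n_variants
    ids = cfg.variant_ids
    id_to_col = {v: j for j, v in enumerate(ids)}

    mafs = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=m)
    pattern_cols: set[int] = set()
    for p in cfg.patterns:
        pattern_cols.update(id_to_col[i] for i in p.items)
    if cfg.pattern_item_maf is not None and pattern_cols:
        mafs[sorted(pattern_cols)] = cfg.pattern_item_maf

    two_groups = cfg.n_substructure_dims > 0
    shift = rng.choice([-1.0, 1.0], size=m) * cfg.substructure_maf_shift
    maf_by_group = np.stack(
        [mafs, np.clip(mafs + shift, 0.01, 0.99)] if two_groups else [mafs, mafs]
    )

    # per-variant marginal log-OR (dominant carrier), summed across patterns
    marg_logor = np.zeros(m)
    for p in cfg.patterns:
        for item, mo in zip(p.items, p.marginals()):
            marg_logor[id_to_col[item]] += math.log(mo)

    base_logit = math.log(cfg.baseline_prevalence / (1 - cfg.baseline_prevalence))

    geno_parts, pheno_parts, group_parts = [], [], []
    n_cases_kept = n_controls_kept = 0
    drawn = 0
    cap = cfg.oversample_cap * n_needed
    batch = max(1024, 4 * n_needed)
    while n_cases_kept < cfg.n_cases or n_controls_kept < cfg.n_controls:
        if drawn >= cap:
            short = "n_cases" if n_cases_kept < cfg.n_cases else "n_controls"
            raise InfeasibleCohortError(
                f"drew {drawn} subjects without filling {short} "
                f"({n_cases_kept}/{cfg.n_cases} cases, "
                f"{n_controls_kept}/{cfg.n_controls} controls); "
                f"{short} is infeasible under baseline_prevalence="
                f"{cfg.baseline_prevalence} at oversample_cap={cfg.oversample_cap}"
            )
        b = min(batch, cap - drawn)
        drawn += b
        grp = rng.integers(0, 2, size=b) if two_groups else np.zeros(b, dtype=int)
        p_mat = maf_by_group[grp]  # b x m
        geno = rng.binomial(2, p_mat).astype(np.int8)
        carrier = geno >= 1
        logit = base_logit + carrier @ marg_logor
        for p in cfg.patterns:
            cols = [id_to_col[i] for i in p.items]
            logit = logit + carrier[:, cols].all(axis=1) * math.log(p.joint_odds_ratio)
        if two_groups:
            logit = logit + cfg.substructure_effect * (grp - 0.5)
        y = rng.random(b) < 1.0 / (1.0 + np.exp(-logit))

        want_case = min(cfg.n_cases - n_cases_kept, int(y.sum()))
        want_ctrl = min(cfg.n_controls - n_controls_kept, int((~y).sum()))
        keep = np.concatenate(
            [np.flatnonzero(y)[:want_case], np.flatnonzero(~y)[:want_ctrl]]
        )
        n_cases_kept += want_case
        n_controls_kept += want_ctrl
        geno_parts.append(geno[keep])
        pheno_parts.append(y[keep].astype(np.int8))
        group_parts.append(grp[keep])

    geno = np.concatenate(geno_parts)
    pheno = np.concatenate(pheno_parts)
    group = np.concatenate(group_parts)
    order = rng.permutation(len(pheno))
    geno, pheno, group = geno[order], pheno[order], group[order]

    truth_counts = _pattern_carrier_counts(geno >= 1, pheno, cfg)

    if cfg.missing_rate > 0 and cfg.n_missing_variants > 0:
        cols = rng.choice(m, size=min(cfg.n_missing_variants, m), replace=False)
        mask = rng.random((len(pheno), len(cols))) < cfg.missing_rate
        for jj, col in enumerate(cols):
            geno[mask[:, jj], col] = MISSING

    k = cfg.n_substructure_dims
    if k > 0:
        cov = rng.normal(0.0, 0.25, size=(len(pheno), k))
        cov[:, 0] += group - 0.5
    else:
        cov = np.empty((len(pheno), 0))

    width = len(str(n_needed))
    specs = [VariantSpec(variant_id=v, risk_allele="A") for v in ids]
    G = GenotypeMatrix(
        subject_ids=[f"S{i + 1:0{width}d}" for i in range(len(pheno))],
        variant_specs=specs,
        counts=geno,
    )
    truth = {
        "config": {
            "n_cases": cfg.n_cases,
            "n_controls": cfg.n_controls,
            "n_variants": cfg.n_variants,
            "maf_range": list(cfg.maf_range),
            "baseline_prevalence": cfg.baseline_prevalence,
            "n_substructure_dims": cfg.n_substructure_dims,
            "substructure_effect": cfg.substructure_effect,
            "missing_rate": cfg.missing_rate,
            "pattern_item_maf": cfg.pattern_item_maf,
            "seed": cfg.seed,
        },
        "patterns": truth_counts,
        "n_drawn": drawn,
    }
    return SyntheticCohort(genotypes=G, phenotype=pheno, covariates=cov, truth=truth)


def inject_missing(G: GenotypeMatrix, rate: float, seed: int = 0) -> GenotypeMatrix:
    """Set each genotype independently to missing with probability ``rate``."""
    if not 0 <= rate <= 1:
        raise ValueError("rate must be a probability")
    out = G.copy()
    if rate == 0:
        return out
    rng = np.random.default_rng(seed)
    mask = rng.random(out.counts.shape) < rate
    out.counts[mask] = MISSING
    return out


def exact_fixture(
    n_cases: int,
    n_controls: int,
    cell_counts: dict,
    items: list[str] | None = None,
    phenotype_item: str = "MS",
) -> IncidenceMatrix:
    """Deterministic incidence matrix with prescribed itemset cell counts.

    ``cell_counts`` maps ``(item_profile, group)`` to a subject count, where
    ``item_profile`` is an iterable of item ids the subjects carry (empty for
    the none-profile) and ``group`` is ``"case"`` or ``"control"``.  Subjects
    not covered by an explicit profile carry no items.  Counts exceeding the
    group size fail, naming the offending profile.
    """
    norm: dict[tuple[tuple[str, ...], str], int] = {}
    vocab: set[str] = set(items or [])
    for (profile, group), cnt in cell_counts.items():
        if group not in ("case", "control"):
            raise ValueError(f"group must be 'case' or 'control', got {group!r}")
        key = (tuple(sorted(profile)), group)
        if cnt < 0:
            raise ValueError(f"negative count for profile {key}")
        norm[key] = norm.get(key, 0) + cnt
        vocab.update(key[0])
    if phenotype_item in vocab:
        raise ValueError(f"phenotype item {phenotype_item!r} may not appear in profiles")

    totals = {"case": n_cases, "control": n_controls}
    for group, total in totals.items():
        s = sum(c for (prof, g), c in norm.items() if g == group)
        if s > total:
            offending = [prof for (prof, g) in norm if g == group]
            raise ValueError(
                f"{group} profile counts sum to {s} > {total}; profiles: {offending}"
            )
        remainder = total - s
        if remainder:
            norm[((), group)] = norm.get(((), group), 0) + remainder

    item_ids = sorted(vocab) + [phenotype_item]
    col = {v: j for j, v in enumerate(item_ids)}
    rows, subject_ids, k = [], [], {"case": 0, "control": 0}
    for (profile, group) in sorted(norm):
        cnt = norm[(profile, group)]
        row = np.zeros(len(item_ids), dtype=bool)
        for it in profile:
            row[col[it]] = True
        row[col[phenotype_item]] = group == "case"
        for _ in range(cnt):
            k[group] += 1
            subject_ids.append(f"{group}{k[group]:04d}")
            rows.append(row.copy())
    return IncidenceMatrix(
        subject_ids=subject_ids,
        item_ids=item_ids,
        cells=np.array(rows, dtype=bool),
        phenotype_item=phenotype_item,
    )
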