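"""End-to-end orchestration: genotypes (real or simulated) to summarized rules.

A run executes simulate|read -> impute -> encode -> mine -> associate ->
interactions -> summaries, writing every artifact plus a JSON run report and
a MANIFEST.  Any stage failure aborts with the stage name and cause; partial
outputs are retained and the MANIFEST marks the run incomplete.  All
randomness flows from the single ``seed`` field.
"""

from __future__ import annotations

import dataclasses
import platform
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io
from .containers import GenotypeMatrix, IncidenceMatrix
from .encoding import compute_substructure, encode_incidence, impute_missing, read_genotypes
from .mining import MiningConfig, Rule, mine_rules, rules_to_frame
from .stats import RuleAssociation, associate_rules, interaction_decomposition
from .summaries import (
    cooccurrence,
    item_frequency,
    item_frequency_frame,
    rank_rules,
    rules_network,
)
from .synthetic import default_study_config, simulate_cohort

CONFIG_SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Fully serializable pipeline configuration (YAML, versioned schema)."""

    # input: synthetic by default, or paths to real data
    simulate: bool = True
    synthetic: dict = field(default_factory=dict)  # overrides for the generator
    genotypes_path: str | None = None
    genotypes_format: str = "tsv"
    variant_spec_path: str | None = None
    phenotype_path: str | None = None
    covariates_path: str | None = None
    # encoding
    imputation: str = "mode"
    phenotype_item: str = "MS"
    n_mds: int = 3
    # mining
    min_support: float = 0.05
    min_confidence: float = 0.80
    max_rule_length: int = 5
    # statistics
    n_boot: int = 5000
    alpha: float = 0.05
    n_covariates: int = 3
    assoc_top_k: int | None = None  # bootstrap only the top-k rules (None = all)
    interact_top_k: int = 1
    interaction_n_boot: int = 2000
    # summaries
    top_k: int = 15
    # run
    out_dir: str = "results/run"
    seed: int = 0

    def __post_init__(self) -> None:
        # delegates threshold validation; raises for e.g. min_confidence > 1
        self.mining_config()
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    def mining_config(self) -> MiningConfig:
        return MiningConfig(
            min_support=self.min_support,
            min_confidence=self.min_confidence,
            max_rule_length=self.max_rule_length,
            consequent=self.phenotype_item,
        )

    def to_yaml(self, path: str | Path) -> None:
        d = {"schema_version": CONFIG_SCHEMA_VERSION, **dataclasses.asdict(self)}
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        version = d.pop("schema_version", CONFIG_SCHEMA_VERSION)
        if version != CONFIG_SCHEMA_VERSION:
            raise ValueError(f"unsupported config schema version {version}")
        return cls(**d)


def associations_to_frame(assocs: list[RuleAssociation]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "lhs": [";".join(a.rule.lhs) for a in assocs],
            "rhs": [a.rule.rhs for a in assocs],
            "support": [a.rule.support for a in assocs],
            "confidence": [a.rule.confidence for a in assocs],
            "or_crude": [a.or_crude for a in assocs],
            "or_adjusted": [a.or_adjusted for a in assocs],
            "ci_low": [a.ci_low for a in assocs],
            "ci_high": [a.ci_high for a in assocs],
            "p_value": [a.p_value for a in assocs],
            "n_boot": [a.n_boot for a in assocs],
            "n_dropped": [a.n_dropped for a in assocs],
            "unstable": [a.unstable for a in assocs],
            "separated": [a.separated for a in assocs],
            "significant_bonferroni": [a.significant_bonferroni for a in assocs],
        }
    )


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline and return the run report (also written as
    JSON next to the artifacts)."""
    cfg = config
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    manifest: list[str] = []
    counts: dict[str, int] = {}
    stage = "init"

    def emit(name: str) -> Path:
        manifest.append(name)
        return out / name

    try:
        # ---- input -------------------------------------------------------
        stage = "simulate" if cfg.simulate else "read"
        if cfg.simulate:
            syn_cfg = default_study_config(seed=cfg.seed, **cfg.synthetic)
            cohort = simulate_cohort(syn_cfg)
            G, phenotype, covariates = cohort.genotypes, cohort.phenotype, cohort.covariates
            io.write_genotypes_tsv(G, emit("genotypes.tsv"))
            io.write_vcf(G, emit("genotypes.vcf"))
            io.write_variant_specs(G, emit("variant_specs.tsv"))
            io.write_phenotype_tsv(G.subject_ids, phenotype, emit("phenotype.tsv"))
            io.write_json(cohort.truth, emit("truth.json"))
        else:
            if not (cfg.genotypes_path and cfg.variant_spec_path and cfg.phenotype_path):
                raise ValueError(
                    "non-simulated runs need genotypes_path, variant_spec_path "
                    "and phenotype_path"
                )
            spec = io.read_variant_specs(cfg.variant_spec_path)
            G = read_genotypes(cfg.genotypes_path, cfg.genotypes_format, spec)
            pheno = io.read_phenotype_tsv(cfg.phenotype_path)
            phenotype = pheno.reindex(G.subject_ids).to_numpy(dtype=int)
            covariates = (
                io.read_covariates_tsv(cfg.covariates_path)
                if cfg.covariates_path
                else None
            )
        counts["n_subjects"] = G.n_subjects
        counts["n_variants"] = G.n_variants

        # ---- impute ------------------------------------------------------
        stage = "impute"
        if G.has_missing():
            G = impute_missing(G, method=cfg.imputation, seed=cfg.seed)

        # ---- covariates --------------------------------------------------
        stage = "substructure"
        if covariates is None or covariates.shape[1] < cfg.n_covariates:
            covariates = compute_substructure(G, k=max(cfg.n_mds, cfg.n_covariates))
        io.write_covariates_tsv(G.subject_ids, covariates, emit("covariates.tsv"))

        # ---- encode ------------------------------------------------------
        stage = "encode"
        I = encode_incidence(G, phenotype, phenotype_item=cfg.phenotype_item)
        io.write_incidence_tsv(I, emit("incidence.tsv"))

        # ---- mine --------------------------------------------------------
        stage = "mine"
        mcfg = cfg.mining_config()
        rules = mine_rules(I, mcfg)
        rules_to_frame(rules).to_csv(emit("rules.tsv"), sep="\t", index=False)
        io.write_json(
            {
                "thresholds": dataclasses.asdict(mcfg),
                "n_subjects": I.n_subjects,
                "n_items": I.n_items,
                "seed": cfg.seed,
                "n_rules": len(rules),
            },
            emit("rules_meta.json"),
        )
        counts["n_rules"] = len(rules)

        # ---- associate ---------------------------------------------------
        stage = "associate"
        to_test = (
            rank_rules(rules, key="confidence", top_k=cfg.assoc_top_k)
            if cfg.assoc_top_k
            else rules
        )
        assocs = associate_rules(
            I,
            to_test,
            covariates=covariates,
            n_boot=cfg.n_boot,
            seed=cfg.seed,
            n_covariates=cfg.n_covariates,
            alpha=cfg.alpha,
        )
        associations_to_frame(assocs).to_csv(
            emit("associations.tsv"), sep="\t", index=False
        )
        counts["n_significant_bonferroni"] = sum(
            bool(a.significant_bonferroni) for a in assocs
        )

        # ---- interactions ------------------------------------------------
        stage = "interact"
        triads = [r for r in rank_rules(rules, key="confidence") if len(r.lhs) == 3]
        reports = []
        for i, rule in enumerate(triads[: cfg.interact_top_k]):
            dec = interaction_decomposition(
                I,
                rule.lhs,
                covariates=covariates,
                n_boot=cfg.interaction_n_boot,
                seed=cfg.seed + i,
            )
            reports.append(
                {
                    "items": list(dec.items),
                    "stratified_ors": {
                        "".join(map(str, k)): v.odds_ratio
                        for k, v in dec.stratified.odds_ratios.items()
                    },
                    "stratified_counts": {
                        "".join(map(str, k)): list(v)
                        for k, v in dec.stratified.counts.items()
                    },
                    "reri3": dec.reri3,
                    "ap3": dec.ap3,
                    "ap_p": dec.ap_p,
                    "mult_or3": dec.mult_or3,
                    "mult_p": dec.mult_p,
                    "mult_separated": dec.mult_separated,
                    "mult_firth": dec.mult_firth,
                }
            )
        io.write_json(reports, emit("interactions.json"))

        # ---- summarize ---------------------------------------------------
        stage = "summarize"
        freq = item_frequency(rules, top_k=cfg.top_k, specs=G.variant_specs)
        item_frequency_frame(freq).to_csv(
            emit("item_frequency.tsv"), sep="\t", index=False
        )
        net = rules_network(rules, top_k=cfg.top_k)
        import networkx as nx

        nx.write_graphml(net, emit("rules_network.graphml"))
        pd.DataFrame(net.edges, columns=["item", "rule"]).to_csv(
            emit("rules_network_edges.tsv"), sep="\t", index=False
        )
        top_pairs = []
        if len(freq) >= 2:
            top_pairs.append(cooccurrence(rules, freq[0].item_id, freq[1].item_id))
        io.write_json(
            {"item_frequency_top": [dataclasses.asdict(r) for r in freq[:10]],
             "top_dyad_cooccurrence": top_pairs},
            emit("summary.json"),
        )

        # ---- report ------------------------------------------------------
        stage = "report"
        report = {
            "status": "complete",
            "seed": cfg.seed,
            "config": dataclasses.asdict(cfg),
            "counts": counts,
            "wall_time_s": round(time.time() - t0, 3),
            "versions": {
                "python": platform.python_version(),
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
        }
        io.write_json(report, emit("run_report.json"))
        io.write_json({"status": "complete", "outputs": manifest}, out / "MANIFEST.json")
        return report
    except Exception as e:  # noqa: BLE001 - annotate the failing stage
        io.write_json(
            {"status": "incomplete", "failed_stage": stage, "error": str(e),
             "outputs": manifest},
            out / "MANIFEST.json",
        )
        raise StageError(stage, e) from e
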