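"""Association statistics for mined rules.

Crude and covariate-adjusted odds ratios, bias-corrected bootstrap inference,
Bonferroni family-wise control, and the additive/multiplicative interaction
decomposition of a three-variant rule.

The logistic fitter is iteratively reweighted least squares (IRLS) with a
1e-8 log-likelihood tolerance, a 100-iteration cap, an explicit full-rank
check (collinear columns are named) and separation detection via diverging
coefficient magnitude.  The bootstrap resamples subjects with replacement,
reports the full-data point estimate (never a replicate mean), the replicate
standard deviation as SE, a bias-corrected (BC) percentile interval, and a
two-sided normal-based p-value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as sla
from scipy.special import expit
from scipy.stats import norm

from .containers import IncidenceMatrix
from .mining import Rule

_SEPARATION_COEF = 15.0


class SeparationError(RuntimeError):
    pass


class RankDeficiencyError(ValueError):
    pass


# ---------------------------------------------------------------------------
# contingency tables and crude odds ratios


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 carrier-by-phenotype table: a/b carriers, c/d non-carriers."""

    a: int  # carriers, cases
    b: int  # carriers, controls
    c: int  # non-carriers, cases
    d: int  # non-carriers, controls

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")

    @property
    def n_cases(self) -> int:
        return self.a + self.c

    @property
    def n_controls(self) -> int:
        return self.b + self.d

    @property
    def case_carrier_frequency(self) -> float:
        return self.a / self.n_cases if self.n_cases else float("nan")

    @property
    def control_carrier_frequency(self) -> float:
        return self.b / self.n_controls if self.n_controls else float("nan")


@dataclass(frozen=True)
class OddsRatioResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    log_or: float
    se: float
    corrected: bool = False  # Haldane +0.5 applied
    degenerate: bool = False  # infinite/zero OR returned uncorrected


def rule_contingency(I: IncidenceMatrix, rule: Rule) -> ContingencyTable:
    """Exact carrier-by-phenotype counts for a rule's LHS."""
    carrier = I.columns(rule.lhs).all(axis=1)
    case = I.phenotype == 1
    return ContingencyTable(
        a=int((carrier & case).sum()),
        b=int((carrier & ~case).sum()),
        c=int((~carrier & case).sum()),
        d=int((~carrier & ~case).sum()),
    )


def crude_odds_ratio(
    t: ContingencyTable, zero_cell: str = "haldane", ci_level: float = 0.95
) -> OddsRatioResult:
    """OR = ad/bc with a Woolf log-scale confidence interval.

    A zero cell is handled by adding 0.5 to all four cells when
    ``zero_cell="haldane"`` (flagged ``corrected``); with ``zero_cell="none"``
    the infinite/zero OR is returned with the ``degenerate`` flag set and no
    silent correction.
    """
    a, b, c, d = float(t.a), float(t.b), float(t.c), float(t.d)
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        raise ValueError("degenerate margin: an entire row or column is empty")
    z = norm.ppf(0.5 + ci_level / 2)
    has_zero = min(a, b, c, d) == 0
    if has_zero and zero_cell == "none":
        orr = math.inf if (b == 0 or c == 0) else 0.0
        return OddsRatioResult(
            odds_ratio=orr,
            ci_low=float("nan"),
            ci_high=float("nan"),
            log_or=math.inf if orr == math.inf else -math.inf,
            se=float("nan"),
            degenerate=True,
        )
    if has_zero:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    log_or = math.log(a * d / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return OddsRatioResult(
        odds_ratio=math.exp(log_or),
        ci_low=math.exp(log_or - z * se),
        ci_high=math.exp(log_or + z * se),
        log_or=log_or,
        se=se,
        corrected=has_zero,
    )


# ---------------------------------------------------------------------------
# logistic regression (IRLS)


@dataclass
class LogisticFit:
    coef: np.ndarray
    cov: np.ndarray
    converged: bool
    separated: bool
    n_iter: int
    loglik: float

    def wald_p(self, j: int) -> float:
        se = math.sqrt(self.cov[j, j])
        if se == 0 or not math.isfinite(se):
            return float("nan")
        return 2 * float(norm.sf(abs(self.coef[j]) / se))


def _check_rank(X: np.ndarray) -> None:
    n, p = X.shape
    if p > n:
        raise RankDeficiencyError("more columns than rows in design matrix")
    _, r, piv = sla.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    if rank < p:
        bad = sorted(int(j) for j in piv[rank:])
        raise RankDeficiencyError(f"design matrix is rank deficient; collinear columns: {bad}")


def fit_logistic(
    y: np.ndarray,
    X: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 100,
    check_rank: bool = True,
) -> LogisticFit:
    """Maximum-likelihood logistic fit by IRLS.

    Converges on log-likelihood change < ``tol``; complete or quasi-complete
    separation is flagged when coefficients diverge.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if check_rank:
        _check_rank(X)
    p = X.shape[1]
    beta = np.zeros(p)
    ll_old = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = expit(eta)
        mu = np.clip(mu, 1e-12, 1 - 1e-12)
        w = mu * (1 - mu)
        z = eta + (y - mu) / w
        Xw = X * w[:, None]
        try:
            beta = np.linalg.solve(X.T @ Xw, Xw.T @ z)
        except np.linalg.LinAlgError:
            break
        ll = float(y @ np.log(mu) + (1 - y) @ np.log1p(-mu))
        if abs(ll - ll_old) < tol:
            ll_old = ll
            converged = True
            break
        ll_old = ll
    separated = bool(np.max(np.abs(beta)) > _SEPARATION_COEF)
    mu = np.clip(expit(X @ beta), 1e-12, 1 - 1e-12)
    w = mu * (1 - mu)
    info = X.T @ (X * w[:, None])
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
    return LogisticFit(
        coef=beta,
        cov=cov,
        converged=converged and not separated,
        separated=separated,
        n_iter=it,
        loglik=ll_old,
    )


def fit_logistic_firth(
    y: np.ndarray, X: np.ndarray, tol: float = 1e-8, max_iter: int = 100
) -> LogisticFit:
    """Firth-penalized logistic fit (Jeffreys prior); finite under separation."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    _check_rank(X)
    p = X.shape[1]
    beta = np.zeros(p)
    ll_old = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        mu = np.clip(expit(X @ beta), 1e-10, 1 - 1e-10)
        w = mu * (1 - mu)
        Xw = X * w[:, None]
        info = X.T @ Xw
        info_inv = np.linalg.inv(info)
        h = np.einsum("ij,jk,ik->i", X * w[:, None], info_inv, X)
        score = X.T @ (y - mu + h * (0.5 - mu))
        step = info_inv @ score
        beta = beta + step
        mu2 = np.clip(expit(X @ beta), 1e-10, 1 - 1e-10)
        ll = float(
            y @ np.log(mu2)
            + (1 - y) @ np.log1p(-mu2)
            + 0.5 * np.linalg.slogdet(X.T @ (X * (mu2 * (1 - mu2))[:, None]))[1]
        )
        if abs(ll - ll_old) < tol:
            converged = True
            ll_old = ll
            break
        ll_old = ll
    mu = np.clip(expit(X @ beta), 1e-10, 1 - 1e-10)
    info = X.T @ (X * (mu * (1 - mu))[:, None])
    cov = np.linalg.inv(info)
    return LogisticFit(
        coef=beta, cov=cov, converged=converged, separated=False, n_iter=it,
        loglik=ll_old,
    )


# ---------------------------------------------------------------------------
# bootstrap association


@dataclass
class RuleAssociation:
    rule: Rule
    or_crude: float
    or_adjusted: float
    ci_low: float
    ci_high: float
    se_log_or: float
    p_value: float
    n_boot: int
    n_dropped: int = 0
    unstable: bool = False
    separated: bool = False
    significant_bonferroni: bool | None = None


def _bc_interval(boot: np.ndarray, point: float, level: float = 0.95) -> tuple[float, float]:
    """Bias-corrected (BC) percentile interval on the bootstrap distribution."""
    frac = np.mean(boot < point)
    frac = min(max(frac, 1.0 / (len(boot) + 1)), 1 - 1.0 / (len(boot) + 1))
    z0 = norm.ppf(frac)
    z = norm.ppf(0.5 + level / 2)
    lo_q = norm.cdf(2 * z0 - z)
    hi_q = norm.cdf(2 * z0 + z)
    return (
        float(np.quantile(boot, lo_q)),
        float(np.quantile(boot, hi_q)),
    )


def _design(I: IncidenceMatrix, rule: Rule, covariates, n_covariates: int):
    carrier = I.columns(rule.lhs).all(axis=1).astype(float)
    y = I.phenotype.astype(float)
    cols = [np.ones(I.n_subjects), carrier]
    if covariates is not None and n_covariates > 0:
        C = np.asarray(covariates, dtype=float)[:, :n_covariates]
        cols.extend(C.T)
    return y, np.column_stack(cols)


def bootstrap_association(
    I: IncidenceMatrix,
    rule: Rule,
    covariates: np.ndarray | None = None,
    n_boot: int = 5000,
    seed: int = 0,
    n_covariates: int = 3,
    stratified: bool = False,
    on_separation: str = "error",
) -> RuleAssociation:
    """Covariate-adjusted rule-vs-disease association with bootstrap inference.

    Subjects are resampled with replacement (unstratified by default;
    ``stratified=True`` resamples within cases and controls).  Replicates
    whose fit does not converge are dropped and counted; >10% drops flags the
    result unstable.  The point estimate is always the full-data fit.
    """
    y, X = _design(I, rule, covariates, n_covariates)
    t = rule_contingency(I, rule)
    crude = crude_odds_ratio(t)

    fit = fit_logistic(y, X)
    if fit.separated or not fit.converged:
        if on_separation == "error":
            raise SeparationError(
                "full-data logistic fit separated or non-convergent; "
                "pass on_separation='haldane_crude' to fall back to the "
                "Haldane-corrected crude log-OR"
            )
        point = crude.log_or
        use_crude = True
    else:
        point = float(fit.coef[1])
        use_crude = False

    rng = np.random.default_rng(seed)
    n = I.n_subjects
    case_idx = np.flatnonzero(y == 1)
    ctrl_idx = np.flatnonzero(y == 0)
    boot = []
    dropped = 0
    for _ in range(n_boot):
        if stratified:
            idx = np.concatenate(
                [
                    rng.choice(case_idx, size=len(case_idx), replace=True),
                    rng.choice(ctrl_idx, size=len(ctrl_idx), replace=True),
                ]
            )
        else:
            idx = rng.integers(0, n, size=n)
        if use_crude:
            yb, xb = y[idx], X[idx, 1]
            tb_a = int(((xb == 1) & (yb == 1)).sum())
            tb_b = int(((xb == 1) & (yb == 0)).sum())
            tb_c = int(((xb == 0) & (yb == 1)).sum())
            tb_d = int(((xb == 0) & (yb == 0)).sum())
            try:
                boot.append(
                    crude_odds_ratio(ContingencyTable(tb_a, tb_b, tb_c, tb_d)).log_or
                )
            except ValueError:
                dropped += 1
            continue
        f = fit_logistic(y[idx], X[idx], check_rank=False)
        if f.converged:
            boot.append(float(f.coef[1]))
        else:
            dropped += 1

    if not boot:
        raise RuntimeError("all bootstrap replicates failed to converge")
    boot_arr = np.array(boot)
    se = float(boot_arr.std(ddof=1)) if len(boot_arr) > 1 else float("nan")
    lo, hi = _bc_interval(boot_arr, point)
    if se and math.isfinite(se) and se > 0:
        p = 2 * float(norm.sf(abs(point) / se))
        p = max(p, np.finfo(float).tiny)
    else:
        p = float("nan")
    return RuleAssociation(
        rule=rule,
        or_crude=crude.odds_ratio,
        or_adjusted=math.exp(point),
        ci_low=math.exp(lo),
        ci_high=math.exp(hi),
        se_log_or=se,
        p_value=min(p, 1.0),
        n_boot=n_boot,
        n_dropped=dropped,
        unstable=dropped > 0.1 * n_boot,
        separated=use_crude,
    )


def bonferroni(p_values, alpha: float = 0.05) -> tuple[float, list[bool]]:
    """Family-wise threshold alpha/m and per-test flags p <= threshold."""
    m = len(p_values)
    if m < 1:
        raise ValueError("need at least one p-value")
    threshold = alpha / m
    return threshold, [bool(p <= threshold) for p in p_values]


def associate_rules(
    I: IncidenceMatrix,
    rules: list[Rule],
    covariates: np.ndarray | None = None,
    n_boot: int = 5000,
    seed: int = 0,
    n_covariates: int = 3,
    alpha: float = 0.05,
    on_separation: str = "haldane_crude",
) -> list[RuleAssociation]:
    """Bootstrap every rule and apply Bonferroni across the family."""
    rng = np.random.default_rng(seed)
    out = []
    for rule in rules:
        out.append(
            bootstrap_association(
                I,
                rule,
                covariates=covariates,
                n_boot=n_boot,
                seed=int(rng.integers(2**31 - 1)),
                n_covariates=n_covariates,
                on_separation=on_separation,
            )
        )
    if out:
        _, flags = bonferroni([a.p_value for a in out], alpha=alpha)
        for a, f in zip(out, flags):
            a.significant_bonferroni = f
    return out


# ---------------------------------------------------------------------------
# interaction decomposition


@dataclass
class StratifiedORs:
    """OR of each carrier profile (g1,g2,g3 in {0,1}) vs the (0,0,0) stratum."""

    items: tuple[str, str, str]
    odds_ratios: dict[tuple[int, int, int], OddsRatioResult]
    counts: dict[tuple[int, int, int], tuple[int, int]]  # (cases, controls)


@dataclass
class InteractionDecomposition:
    items: tuple[str, str, str]
    stratified: StratifiedORs
    reri3: float
    ap3: float
    ap_p: float
    mult_or3: float
    mult_p: float
    mult_separated: bool = False
    mult_firth: bool = False


def _profiles(I: IncidenceMatrix, variants) -> np.ndarray:
    variants = tuple(variants)
    if len(variants) != 3:
        raise ValueError("exactly three items required")
    return I.columns(variants).astype(int)


def stratified_ors(
    I: IncidenceMatrix,
    variants,
    phenotype: np.ndarray | None = None,
) -> StratifiedORs:
    """Profile-vs-reference ORs over the 8 carrier profiles of three items.

    Reference is (0,0,0); OR(0,0,0) = 1 by definition.  Zero cells in a
    profile's 2x2 sub-table get the Haldane correction, flagged.
    """
    G = _profiles(I, variants)
    y = I.phenotype if phenotype is None else np.asarray(phenotype).astype(int)
    counts: dict[tuple[int, int, int], tuple[int, int]] = {}
    for g1 in (0, 1):
        for g2 in (0, 1):
            for g3 in (0, 1):
                mask = (G[:, 0] == g1) & (G[:, 1] == g2) & (G[:, 2] == g3)
                counts[(g1, g2, g3)] = (
                    int((mask & (y == 1)).sum()),
                    int((mask & (y == 0)).sum()),
                )
    ref_cases, ref_controls = counts[(0, 0, 0)]
    if ref_cases == 0 or ref_controls == 0:
        raise ValueError(
            "reference stratum (0,0,0) has an empty phenotype cell "
            f"(cases={ref_cases}, controls={ref_controls}); "
            "choose a different reference"
        )
    ors: dict[tuple[int, int, int], OddsRatioResult] = {}
    for profile, (ca, co) in counts.items():
        if profile == (0, 0, 0):
            ors[profile] = OddsRatioResult(1.0, 1.0, 1.0, 0.0, 0.0)
            continue
        if ca + co == 0:
            # empty stratum: OR undefined, never silently corrected
            ors[profile] = OddsRatioResult(
                float("nan"), float("nan"), float("nan"),
                float("nan"), float("nan"), degenerate=True,
            )
            continue
        t = ContingencyTable(a=ca, b=co, c=ref_cases, d=ref_controls)
        ors[profile] = crude_odds_ratio(t, zero_cell="haldane")
    return StratifiedORs(items=tuple(variants), odds_ratios=ors, counts=counts)


def reri_ap(ors: dict[tuple[int, int, int], float]) -> tuple[float, float]:
    """Three-way relative excess odds due to interaction and its attributable
    proportion: RERI3 = OR111 - OR110 - OR101 - OR011 + OR100 + OR010 + OR001 - 1,
    AP3 = RERI3 / OR111."""
    o = ors
    reri = (
        o[(1, 1, 1)]
        - o[(1, 1, 0)]
        - o[(1, 0, 1)]
        - o[(0, 1, 1)]
        + o[(1, 0, 0)]
        + o[(0, 1, 0)]
        + o[(0, 0, 1)]
        - 1.0
    )
    if o[(1, 1, 1)] <= 0:
        raise ValueError("OR(1,1,1) must be positive for the attributable proportion")
    return reri, reri / o[(1, 1, 1)]


def additive_interaction(
    I: IncidenceMatrix,
    variants,
    n_boot: int = 2000,
    seed: int = 0,
) -> tuple[float, float, float, np.ndarray]:
    """Point RERI3/AP3 from the stratified ORs plus a bootstrap percentile p.

    p is the two-sided probability, over subject-resampled replicates, of the
    AP distribution crossing zero (add-one smoothed).  Returns
    (reri3, ap3, ap_p, bootstrap AP draws).
    """
    strat = stratified_ors(I, variants)
    empty = [p for p, (ca, co) in strat.counts.items() if ca + co == 0]
    if empty:
        raise ValueError(f"undefined strata (no subjects): {sorted(empty)}")
    point_or = {k: v.odds_ratio for k, v in strat.odds_ratios.items()}
    reri, ap = reri_ap(point_or)

    rng = np.random.default_rng(seed)
    n = I.n_subjects
    aps = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        Ib = IncidenceMatrix(
            subject_ids=[I.subject_ids[i] for i in idx],
            item_ids=list(I.item_ids),
            cells=I.cells[idx],
            phenotype_item=I.phenotype_item,
        )
        try:
            sb = stratified_ors(Ib, variants)
            _, apb = reri_ap({k: v.odds_ratio for k, v in sb.odds_ratios.items()})
        except ValueError:
            continue
        if math.isfinite(apb):
            aps.append(apb)
    aps_arr = np.array(aps)
    if len(aps_arr) == 0:
        raise RuntimeError("no valid bootstrap replicates for the AP")
    b = len(aps_arr)
    p_low = (np.sum(aps_arr <= 0) + 1) / (b + 1)
    p_high = (np.sum(aps_arr >= 0) + 1) / (b + 1)
    ap_p = min(1.0, 2 * min(p_low, p_high))
    return reri, ap, ap_p, aps_arr


def multiplicative_interaction(
    y: np.ndarray,
    items: np.ndarray,
    covariates: np.ndarray | None = None,
    n_covariates: int = 3,
    firth_on_separation: bool = False,
) -> tuple[float, float, LogisticFit, bool]:
    """Three-way interaction on the multiplicative (log-odds) scale.

    Fits the fully parameterized model — all main effects, all two-way
    products, the three-way product, plus covariates — and returns the
    exponentiated three-way coefficient, its Wald p, the fit, and whether the
    Firth-penalized fallback was used.  A constant item produces a
    rank-deficiency error; separation is flagged (with an optional labeled
    Firth fallback).
    """
    y = np.asarray(y, dtype=float)
    G = np.asarray(items, dtype=float)
    if G.shape[1] != 3:
        raise ValueError("items must be a subjects x 3 binary matrix")
    g1, g2, g3 = G[:, 0], G[:, 1], G[:, 2]
    cols = [
        np.ones_like(y), g1, g2, g3,
        g1 * g2, g1 * g3, g2 * g3, g1 * g2 * g3,
    ]
    if covariates is not None and n_covariates > 0:
        C = np.asarray(covariates, dtype=float)[:, :n_covariates]
        cols.extend(C.T)
    X = np.column_stack(cols)
    fit = fit_logistic(y, X)
    used_firth = False
    if (fit.separated or not fit.converged) and firth_on_separation:
        fit = fit_logistic_firth(y, X)
        used_firth = True
    j = 7  # three-way product column
    return math.exp(float(fit.coef[j])), fit.wald_p(j), fit, used_firth


def interaction_decomposition(
    I: IncidenceMatrix,
    variants,
    covariates: np.ndarray | None = None,
    n_boot: int = 2000,
    seed: int = 0,
) -> InteractionDecomposition:
    """Full additive + multiplicative decomposition of a three-variant rule."""
    strat = stratified_ors(I, variants)
    reri, ap, ap_p, _ = additive_interaction(I, variants, n_boot=n_boot, seed=seed)
    mult_or, mult_p, fit, used_firth = multiplicative_interaction(
        I.phenotype, _profiles(I, variants), covariates,
        firth_on_separation=True,
    )
    return InteractionDecomposition(
        items=tuple(variants),
        stratified=strat,
        reri3=reri,
        ap3=ap,
        ap_p=ap_p,
        mult_or3=mult_or,
        mult_p=mult_p,
        mult_separated=fit.separated,
        mult_firth=used_firth,
    )
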