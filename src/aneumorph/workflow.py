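"""Staged statistical workflow for rupture-risk assessment.

Given a cohort table (one row per aneurysm, three groups: ruptured,
unruptured, stable) the workflow runs six stages:

1. **Comparative analysis** — group means and Mann-Whitney U-tests for
   every parameter and every group pairing; parameters not significant for
   the ruptured-vs-stable comparison are dropped.
2. **Collinearity analysis** — Pearson correlations on the
   ruptured + stable subset; of every highly correlated pair (|rho| above
   the cutoff) only the member with the stronger univariate separation
   (smaller U-test p) is kept.
3. **Predictive modeling** — univariate and multivariate logistic
   regressions (ruptured = 1, stable = 0) reporting odds ratios with Wald
   95% confidence intervals.
4. **Composite parameters** — fixed products of the strongest predictors:
   WG = WSS_rel_max * GLN, GD = GLN * D_rel_max,
   WGD = WSS_rel_max * GLN * D_rel_max.
5. **Performance evaluation** — ROC curves, AUC, and a threshold chosen to
   maximise specificity subject to a sensitivity target.
6. **Threshold validation** — frozen thresholds applied to an independent
   ruptured-only validation set; sensitivity reported as k/n and percent.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

__all__ = [
    "PARAMETERS",
    "GROUPS",
    "COMPOSITES",
    "WorkflowConfig",
    "WorkflowReport",
    "mann_whitney",
    "screen_parameters",
    "prune_collinear",
    "logistic_fit",
    "composite_scores",
    "roc_curve_points",
    "roc_and_threshold",
    "validate_threshold",
    "run_workflow",
]

#: canonical parameter columns of a cohort table, in reporting order
PARAMETERS = [
    "WSS_rel_max", "WSS_max", "WSS_av",
    "OSI_max", "OSI_av", "OSI_min",
    "P_max", "P_av", "P_min",
    "D_rel_max", "MISES_max", "MISES_av",
    "S", "AR", "SR", "VOR", "V", "GLN",
]

GROUPS = ["ruptured", "unruptured", "stable"]

#: composite scores: name -> factor columns (product)
COMPOSITES = {
    "WG": ("WSS_rel_max", "GLN"),
    "GD": ("GLN", "D_rel_max"),
    "WGD": ("WSS_rel_max", "GLN", "D_rel_max"),
}

_Z975 = float(stats.norm.ppf(0.975))


@dataclass
class WorkflowConfig:
    """Tunable knobs of the staged analysis."""

    alpha: float = 0.05
    collinearity_cutoff: float = 0.75
    sensitivity_target: float = 0.8
    pair: tuple[str, str] = ("ruptured", "stable")
    standardize: bool = False          # z-standardize predictors before logistic fits
    multiple_testing: str | None = None  # None or "bh" (Benjamini-Hochberg) at screening
    #: which predictors are co-entered in the multivariate model:
    #: "univariate_significant" (staged model building; predictors whose
    #: univariate fit is estimable and significant) or "pruned" (all
    #: survivors of the collinearity stage)
    multivariate_entry: str = "univariate_significant"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.collinearity_cutoff <= 1:
            raise ValueError("collinearity cutoff must be in (0, 1]")
        if not 0 < self.sensitivity_target < 1:
            raise ValueError("sensitivity target must be in (0, 1)")
        if self.multivariate_entry not in ("univariate_significant", "pruned"):
            raise ValueError("multivariate_entry must be 'univariate_significant' or 'pruned'")
        self.pair = tuple(self.pair)  # type: ignore[assignment]

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def mann_whitney(group_a: np.ndarray, group_b: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney U-test; returns ``(U, p)``.

    U is the statistic of ``group_a``.  The exact null distribution is
    used when ``min(n_a, n_b) <= 8`` and there are no ties; otherwise the
    normal approximation with tie and continuity corrections.
    """
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        warnings.warn("all values identical in both groups; p = 1")
        return len(a) * len(b) / 2.0, 1.0
    ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (min(len(a), len(b)) <= 8 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def _split(cohort: pd.DataFrame, pair: tuple[str, str]) -> tuple[pd.DataFrame, pd.DataFrame]:
    g0 = cohort[cohort["group"] == pair[0]]
    g1 = cohort[cohort["group"] == pair[1]]
    if len(g0) == 0 or len(g1) == 0:
        raise ValueError(f"cohort lacks records for pair {pair}")
    return g0, g1


def screen_parameters(
    cohort: pd.DataFrame,
    pair: tuple[str, str] = ("ruptured", "stable"),
    alpha: float = 0.05,
    parameters: list[str] | None = None,
    multiple_testing: str | None = None,
) -> tuple[list[str], pd.DataFrame, pd.DataFrame]:
    """Stage 1: group means, U-test p-value grid, and the retained list.

    Returns ``(retained, means, pvalues)``.  ``means`` has one row per
    parameter and one column per group; ``pvalues`` one column per group
    pairing.  Retained are parameters with ``p < alpha`` for the primary
    pairing; zero-variance parameters are excluded with a warning.
    """
    params = parameters or [p for p in PARAMETERS if p in cohort.columns]
    pairs = [(a, b) for i, a in enumerate(GROUPS) for b in GROUPS[i + 1:]
             if (cohort["group"] == a).any() and (cohort["group"] == b).any()]
    means = pd.DataFrame(index=params, dtype=float)
    for g in GROUPS:
        sub = cohort[cohort["group"] == g]
        if len(sub):
            means[g] = sub[params].mean()
    pvals = pd.DataFrame(index=params, dtype=float)
    for a, b in pairs:
        col = f"{a}_vs_{b}"
        ga, gb = cohort[cohort["group"] == a], cohort[cohort["group"] == b]
        pvals[col] = [
            mann_whitney(ga[p].to_numpy(), gb[p].to_numpy())[1] for p in params
        ]
    key = f"{pair[0]}_vs_{pair[1]}"
    if key not in pvals.columns:
        key = f"{pair[1]}_vs_{pair[0]}"
    screen_p = pvals[key].copy()
    if multiple_testing == "bh":
        screen_p = pd.Series(
            sm.stats.multipletests(screen_p.to_numpy(), method="fdr_bh")[1],
            index=screen_p.index,
        )
    retained = []
    for p in params:
        if cohort[p].nunique() <= 1:
            warnings.warn(f"parameter {p} has zero variance; excluded from screening")
            continue
        if screen_p[p] < alpha:
            retained.append(p)
    return retained, means, pvals


def prune_collinear(
    cohort: pd.DataFrame,
    params: list[str],
    cutoff: float = 0.75,
    pair: tuple[str, str] = ("ruptured", "stable"),
) -> tuple[list[str], pd.DataFrame]:
    """Stage 2: drop one member of every highly correlated parameter pair.

    The |Pearson rho| matrix is computed on the primary-pair subset.
    Pairs with |rho| > cutoff are resolved highest-|rho| first, keeping the
    member with the smaller ruptured-vs-stable U-test p (ties broken
    lexicographically), so the result is independent of column order.
    Constant columns are dropped with a warning.
    """
    g0, g1 = _split(cohort, pair)
    sub = pd.concat([g0, g1])
    params = list(params)
    for p in list(params):
        if sub[p].nunique() <= 1:
            warnings.warn(f"parameter {p} is constant; dropped from collinearity analysis")
            params.remove(p)
    corr = sub[params].corr(method="pearson")
    upv = {p: mann_whitney(g0[p].to_numpy(), g1[p].to_numpy())[1] for p in params}
    retained = set(params)
    while True:
        worst, worst_rho = None, cutoff
        for i, a in enumerate(params):
            if a not in retained:
                continue
            for b in params[i + 1:]:
                if b not in retained:
                    continue
                r = abs(corr.loc[a, b])
                if r > worst_rho:
                    worst, worst_rho = (a, b), r
        if worst is None:
            break
        a, b = worst
        # drop the member with the weaker separation
        if (upv[a], a) <= (upv[b], b):
            retained.discard(b)
        else:
            retained.discard(a)
    return [p for p in params if p in retained], corr


def logistic_fit(
    cohort: pd.DataFrame,
    params: list[str],
    mode: str = "univariate",
    pair: tuple[str, str] = ("ruptured", "stable"),
    standardize: bool = False,
) -> pd.DataFrame:
    """Stage 3: logistic regression odds ratios (pair[0] = 1, pair[1] = 0).

    Maximum-likelihood fit by Newton iteration (tolerance 1e-8, at most
    100 iterations) with Wald 95% confidence intervals on the log-odds
    scale, exponentiated to ORs.  ORs are per raw unit unless
    ``standardize`` z-scales the predictors (per-SD ORs).  Perfectly
    separated fits are flagged ``estimable = False`` with NaN OR rather
    than reporting a divergent number.
    """
    if mode not in ("univariate", "multivariate"):
        raise ValueError(f"unknown mode {mode!r}")
    g0, g1 = _split(cohort, pair)
    sub = pd.concat([g0, g1])
    y = (sub["group"] == pair[0]).to_numpy(dtype=float)
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    blocks = [[p] for p in params] if mode == "univariate" else [list(params)]
    rows = {}
    for block in blocks:
        X = sub[block].to_numpy(dtype=np.float64)
        sd = X.std(axis=0)
        if (sd == 0).any():
            raise ValueError("constant predictor in logistic fit")
        # fit on z-scaled predictors for conditioning; the MLE is affine-
        # equivariant, so per-unit coefficients are recovered exactly
        Xs = (X - X.mean(axis=0)) / sd
        Xc = sm.add_constant(Xs, has_constant="add")
        beta = se = pv = None
        ok = True
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("error", PerfectSeparationWarning)
                warnings.filterwarnings("ignore", message="overflow")
                with np.errstate(over="ignore"):
                    fit = sm.Logit(y, Xc).fit(
                        method="newton", maxiter=100, tol=1e-8, disp=0
                    )
            beta, se, pv = fit.params[1:], fit.bse[1:], fit.pvalues[1:]
            ok = bool(fit.mle_retvals.get("converged", True))
        except (PerfectSeparationError, PerfectSeparationWarning, np.linalg.LinAlgError):
            ok = False
        for j, p in enumerate(block):
            # |z-scale beta| beyond ~50 or exploding SE means (near-)separation
            if (not ok or beta is None or not np.isfinite(se[j])
                    or se[j] > 50 or abs(beta[j]) > 50):
                rows[p] = dict(OR=np.nan, CI_low=np.nan, CI_high=np.nan,
                               p=np.nan, estimable=False)
            else:
                b, s = (beta[j], se[j]) if standardize else (beta[j] / sd[j], se[j] / sd[j])
                rows[p] = dict(
                    OR=float(np.exp(b)),
                    CI_low=float(np.exp(b - _Z975 * s)),
                    CI_high=float(np.exp(b + _Z975 * s)),
                    p=float(pv[j]),
                    estimable=True,
                )
    return pd.DataFrame.from_dict(rows, orient="index").loc[params]


def composite_scores(records: pd.DataFrame) -> pd.DataFrame:
    """Stage 4: composite products WG, GD, WGD per record.

    Records missing any factor are skipped with a warning (NaN row).
    """
    needed = sorted({c for cols in COMPOSITES.values() for c in cols})
    missing_cols = [c for c in needed if c not in records.columns]
    if missing_cols:
        raise ValueError(f"missing columns for composite scores: {missing_cols}")
    out = pd.DataFrame(index=records.index)
    bad = records[needed].isna().any(axis=1) | ~np.isfinite(records[needed]).all(axis=1)
    if bad.any():
        warnings.warn(f"{int(bad.sum())} record(s) with missing composite inputs skipped")
    for name, cols in COMPOSITES.items():
        out[name] = records[list(cols)].prod(axis=1)
        out.loc[bad, name] = np.nan
    return out


def roc_curve_points(
    scores: np.ndarray, labels: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """ROC sweep over all observed score values (classification: score > t).

    Returns ``(thresholds, tpr, fpr)`` sorted by descending threshold,
    with sentinel endpoints (+inf -> (0,0) and -inf -> (1,1)).
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(bool)
    if labels.all() or not labels.any():
        raise ValueError("ROC needs both classes")
    thr = np.concatenate([[np.inf], np.unique(scores)[::-1], [-np.inf]])
    pos, neg = scores[labels], scores[~labels]
    tpr = np.array([(pos > t).mean() for t in thr])
    fpr = np.array([(neg > t).mean() for t in thr])
    return thr, tpr, fpr


def roc_and_threshold(
    scores: np.ndarray,
    labels: np.ndarray,
    sensitivity_target: float = 0.8,
) -> dict:
    """Stage 5: AUC and the operating threshold.

    AUC by trapezoid over the swept curve.  Among observed-score
    thresholds with sensitivity >= target, the one with maximal
    specificity is chosen (ties: maximal Youden J, then smallest
    threshold).  If no threshold reaches the target, the maximal-Youden
    point is used and a warning issued.
    """
    thr, tpr, fpr = roc_curve_points(scores, labels)
    auc = float(np.trapezoid(tpr, fpr))
    finite = np.isfinite(thr)
    cand = finite & (tpr >= sensitivity_target)
    met_target = bool(cand.any())
    if not met_target:
        warnings.warn(
            f"no threshold reaches sensitivity target {sensitivity_target}; "
            "falling back to maximal Youden J"
        )
        cand = finite
    spec = 1.0 - fpr
    youden = tpr + spec - 1.0
    order = sorted(
        np.flatnonzero(cand),
        key=lambda i: (-spec[i], -youden[i], thr[i]),
    )
    i = order[0]
    return {
        "AUC": auc,
        "threshold": float(thr[i]),
        "sensitivity": float(tpr[i]),
        "specificity": float(spec[i]),
        "target_met": met_target,
    }


def validate_threshold(
    validation_scores: np.ndarray, threshold: float
) -> tuple[int, int, float]:
    """Stage 6: sensitivity of a frozen threshold on ruptured-only scores.

    Returns ``(k, n, percent)`` with k the count of scores strictly above
    the threshold.
    """
    s = np.asarray(validation_scores, dtype=np.float64)
    if len(s) == 0:
        raise ValueError("empty validation set")
    k = int((s > threshold).sum())
    return k, len(s), 100.0 * k / len(s)


@dataclass
class WorkflowReport:
    """All stage outputs of one workflow run."""

    group_sizes: dict
    group_means: pd.DataFrame
    pvalues: pd.DataFrame
    retained_after_screen: list[str]
    pearson: pd.DataFrame
    retained_after_prune: list[str]
    univariate: pd.DataFrame
    multivariate: pd.DataFrame
    multivariate_significant: list[str]
    composite_means: pd.DataFrame
    composite_pvalues: pd.DataFrame
    roc: pd.DataFrame
    validation: pd.DataFrame
    config: WorkflowConfig
    config_hash: str
    or_scale: str
    warnings: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        def df(d: pd.DataFrame) -> dict:
            return json.loads(d.to_json(orient="index"))

        payload = {
            "config": asdict(self.config),
            "config_hash": self.config_hash,
            "or_scale": self.or_scale,
            "group_sizes": self.group_sizes,
            "group_means": df(self.group_means),
            "pvalues": df(self.pvalues),
            "retained_after_screen": self.retained_after_screen,
            "pearson": df(self.pearson),
            "retained_after_prune": self.retained_after_prune,
            "univariate": df(self.univariate),
            "multivariate": df(self.multivariate),
            "multivariate_significant": self.multivariate_significant,
            "composite_means": df(self.composite_means),
            "composite_pvalues": df(self.composite_pvalues),
            "roc": df(self.roc),
            "validation": df(self.validation),
            "warnings": self.warnings,
        }
        return json.dumps(payload, indent=2, default=str)

    def to_markdown(self) -> str:
        lines = [
            "# Rupture-risk workflow report",
            "",
            f"Config hash: `{self.config_hash}`; odds ratios are {self.or_scale}.",
            f"Group sizes: {self.group_sizes}",
            "",
            "## Stage 1 — group means and U-test p-values",
            self.group_means.round(4).to_markdown(),
            "",
            self.pvalues.round(4).to_markdown(),
            "",
            f"Retained after screening: {', '.join(self.retained_after_screen) or '(none)'}",
            "",
            "## Stage 2 — collinearity (Pearson rho)",
            self.pearson.round(3).to_markdown(),
            "",
            f"Retained after pruning: {', '.join(self.retained_after_prune) or '(none)'}",
            "",
            "## Stage 3 — logistic regression",
            "### Univariate",
            self.univariate.round(4).to_markdown(),
            "### Multivariate",
            self.multivariate.round(4).to_markdown(),
            "",
            f"Multivariate-significant: {', '.join(self.multivariate_significant) or '(none)'}",
            "",
            "## Stage 4 — composite parameters",
            self.composite_means.round(4).to_markdown(),
            "",
            self.composite_pvalues.round(4).to_markdown(),
            "",
            "## Stage 5 — ROC / thresholds",
            self.roc.round(4).to_markdown(),
            "",
            "## Stage 6 — internal threshold validation",
            self.validation.to_markdown(),
        ]
        if self.warnings:
            lines += ["", "## Warnings"] + [f"- {w}" for w in self.warnings]
        return "\n".join(lines) + "\n"


def run_workflow(
    cohort: pd.DataFrame,
    validation: pd.DataFrame | None = None,
    config: WorkflowConfig | None = None,
) -> WorkflowReport:
    """Run stages 1-6 and assemble a :class:`WorkflowReport`.

    ``cohort`` needs columns ``id``, ``group`` and the parameter columns;
    ``validation`` (optional) is a ruptured-only table with the same
    parameter columns.  Stages 2-5 are restricted to the configured group
    pair (default ruptured vs stable).  Deterministic: identical inputs
    and config reproduce the report bit-for-bit.
    """
    cfg = config or WorkflowConfig()
    if "group" not in cohort.columns:
        raise ValueError("cohort table needs a 'group' column")
    bad_groups = set(cohort["group"]) - set(GROUPS)
    if bad_groups:
        raise ValueError(f"unknown group labels: {sorted(bad_groups)}")
    if "id" in cohort.columns and cohort["id"].duplicated().any():
        raise ValueError("duplicated ids in cohort")
    params = [p for p in PARAMETERS if p in cohort.columns]
    if not params:
        raise ValueError("cohort table has no recognised parameter columns")

    caught: list[str] = []

    def staged(stage, fn, *a, **k):
        try:
            with warnings.catch_warnings(record=True) as wlist:
                warnings.simplefilter("always")
                out = fn(*a, **k)
            caught.extend(f"{stage}: {w.message}" for w in wlist)
            return out
        except Exception as e:
            raise RuntimeError(f"workflow stage '{stage}' failed: {e}") from e

    group_sizes = cohort["group"].value_counts().to_dict()

    # stage 1 — comparative analysis
    retained, means, pvals = staged(
        "screening", screen_parameters, cohort, cfg.pair, cfg.alpha, params,
        cfg.multiple_testing,
    )

    # stage 2 — collinearity
    if len(retained) >= 2:
        pruned, corr = staged(
            "collinearity", prune_collinear, cohort, retained,
            cfg.collinearity_cutoff, cfg.pair,
        )
    else:
        pruned, corr = list(retained), pd.DataFrame()

    # stage 3 — predictive modeling
    if pruned:
        uni = staged("univariate regression", logistic_fit, cohort, pruned,
                     "univariate", cfg.pair, cfg.standardize)
        if cfg.multivariate_entry == "univariate_significant":
            entered = [
                p for p in pruned
                if bool(uni.loc[p, "estimable"]) and uni.loc[p, "p"] < cfg.alpha
            ]
        else:
            entered = list(pruned)
        if entered:
            multi = staged("multivariate regression", logistic_fit, cohort, entered,
                           "multivariate", cfg.pair, cfg.standardize)
        else:
            multi = pd.DataFrame(columns=["OR", "CI_low", "CI_high", "p", "estimable"])
        mv_sig = [
            p for p in entered
            if bool(multi.loc[p, "estimable"]) and multi.loc[p, "p"] < cfg.alpha
        ]
    else:
        uni = multi = pd.DataFrame(columns=["OR", "CI_low", "CI_high", "p", "estimable"])
        mv_sig = []

    # stage 4 — composite parameters
    comp = staged("composites", composite_scores, cohort[params])
    comp_means = pd.DataFrame(
        {g: comp[cohort["group"] == g].mean() for g in GROUPS if (cohort["group"] == g).any()}
    )
    comp_pvals = pd.DataFrame(index=list(COMPOSITES), dtype=float)
    for i, a in enumerate(GROUPS):
        for b in GROUPS[i + 1:]:
            if (cohort["group"] == a).any() and (cohort["group"] == b).any():
                comp_pvals[f"{a}_vs_{b}"] = [
                    mann_whitney(
                        comp.loc[cohort["group"] == a, c].dropna().to_numpy(),
                        comp.loc[cohort["group"] == b, c].dropna().to_numpy(),
                    )[1]
                    for c in COMPOSITES
                ]

    # stage 5 — ROC / thresholds on multivariate-significant singles + composites
    g0, g1 = _split(cohort, cfg.pair)
    pair_mask = cohort["group"].isin(cfg.pair)
    y = (cohort.loc[pair_mask, "group"] == cfg.pair[0]).to_numpy()
    score_cols: dict[str, np.ndarray] = {}
    for p in mv_sig:
        score_cols[p] = cohort.loc[pair_mask, p].to_numpy(dtype=float)
    for c in COMPOSITES:
        score_cols[c] = comp.loc[pair_mask, c].to_numpy(dtype=float)
    roc_rows = {}
    for name, s in score_cols.items():
        keep = np.isfinite(s)
        oriented, direction = s, 1
        res = staged(f"ROC ({name})", roc_and_threshold, s[keep], y[keep],
                     cfg.sensitivity_target)
        if res["AUC"] < 0.5:
            direction = -1
            res = staged(f"ROC ({name}, flipped)", roc_and_threshold,
                         -s[keep], y[keep], cfg.sensitivity_target)
            res["threshold"] = -res["threshold"]
        roc_rows[name] = {**res, "direction": direction}
    roc_df = pd.DataFrame.from_dict(roc_rows, orient="index")

    # stage 6 — internal threshold validation
    val_rows = {}
    if validation is not None and len(validation):
        vcomp = staged("composites (validation)", composite_scores, validation)
        for name, row in roc_rows.items():
            vs = (validation[name] if name in validation.columns else vcomp[name]).to_numpy(dtype=float)
            vs = vs[np.isfinite(vs)] * row["direction"]
            thr = row["threshold"] * row["direction"]
            k, n, pct = staged(f"validation ({name})", validate_threshold, vs, thr)
            val_rows[name] = {"correct": k, "n": n, "sensitivity_pct": pct}
    val_df = pd.DataFrame.from_dict(val_rows, orient="index") if val_rows else pd.DataFrame()

    return WorkflowReport(
        group_sizes=group_sizes,
        group_means=means,
        pvalues=pvals,
        retained_after_screen=retained,
        pearson=corr,
        retained_after_prune=pruned,
        univariate=uni,
        multivariate=multi,
        multivariate_significant=mv_sig,
        composite_means=comp_means,
        composite_pvalues=comp_pvals,
        roc=roc_df,
        validation=val_df,
        config=cfg,
        config_hash=cfg.hash(),
        or_scale="per standard deviation" if cfg.standardize else "per raw unit",
        warnings=caught,
    )
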