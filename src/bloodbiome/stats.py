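"""Hypothesis tests and effect sizes for microbiome diversity.

Covers the full inferential layer: covariate-adjusted group contrasts of
(normalised) alpha diversity, logistic-regression effect sizes via the
reduction in Nagelkerke's R², pairwise beta-diversity group comparison,
distance-based PERMANOVA, exact 2xK presence/absence tests, ordination-
axis association with case status, and partial correlation of cell-type
proportions with alpha diversity.

Covariate convention: every adjusted model includes sex and age plus the
technical covariates RIN, batch, flow-cell lane and RNA concentration;
batch and lane enter as categorical factors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import gammaln
from scipy.stats import norm, pearsonr, rankdata

COVARIATES = ("age", "sex", "rin", "batch", "lane", "rna_concentration")
CATEGORICAL = ("sex", "batch", "lane")


@dataclass
class ModelResult:
    estimates: dict = field(default_factory=dict)
    pvalues: dict = field(default_factory=dict)
    adjusted_pvalues: dict = field(default_factory=dict)
    loglik: dict = field(default_factory=dict)
    r2: dict = field(default_factory=dict)
    pseudo_f: float | None = None
    permutation_p: float | None = None
    n_permutations: int | None = None
    seed: int | None = None
    flags: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "estimates": self.estimates, "pvalues": self.pvalues,
            "adjusted_pvalues": self.adjusted_pvalues, "loglik": self.loglik,
            "r2": self.r2, "pseudo_f": self.pseudo_f,
            "permutation_p": self.permutation_p,
            "n_permutations": self.n_permutations, "seed": self.seed,
            "flags": self.flags,
        }


@dataclass
class PresenceTable:
    taxon: str
    present: np.ndarray  # per group
    totals: np.ndarray

    def __post_init__(self):
        self.present = np.asarray(self.present, dtype=int)
        self.totals = np.asarray(self.totals, dtype=int)
        if (self.present < 0).any() or (self.present > self.totals).any():
            raise ValueError("present counts must lie in [0, total] per group")


# --------------------------------------------------------------------------
# normalisation and design matrices
# --------------------------------------------------------------------------

def normalize_alpha(alpha, method: str = "inverse_normal") -> np.ndarray:
    """Rank-based inverse-normal transform (default) or plain z-score.

    The inverse-normal transform maps average ranks through
    Phi^-1((rank - 0.5) / n); it is invariant to monotone transforms of
    the input and robust to the right skew of the inverse Simpson index.
    """
    x = np.asarray(alpha, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("alpha values must be finite")
    if len(x) < 3:
        raise ValueError("need at least 3 values to normalise")
    if method == "inverse_normal":
        return norm.ppf((rankdata(x) - 0.5) / len(x))
    if method == "zscore":
        return (x - x.mean()) / x.std(ddof=1)
    raise ValueError(f"unknown method {method!r}")


def covariate_matrix(design: pd.DataFrame,
                     covariates=COVARIATES) -> pd.DataFrame:
    """Dummy-coded covariate matrix (no intercept column)."""
    cols = []
    for c in covariates:
        if c not in design.columns:
            raise ValueError(f"design table lacks covariate {c!r}")
        if c in CATEGORICAL:
            dummies = pd.get_dummies(design[c].astype(str), prefix=c,
                                     drop_first=True, dtype=float)
            cols.append(dummies)
        else:
            cols.append(design[[c]].astype(float))
    return pd.concat(cols, axis=1)


def _find_aliased(X: pd.DataFrame) -> list[str]:
    """Columns made redundant by earlier ones (greedy elimination)."""
    if np.linalg.matrix_rank(X.values.astype(float)) == X.shape[1]:
        return []
    keep: list[str] = []
    aliased: list[str] = []
    for c in X.columns:
        if np.linalg.matrix_rank(X[keep + [c]].values.astype(float)) == len(keep) + 1:
            keep.append(c)
        else:
            aliased.append(c)
    return aliased


def _check_full_rank(X: pd.DataFrame) -> None:
    aliased = _find_aliased(X)
    if aliased:
        raise ValueError(f"rank-deficient design; aliased columns: {aliased}")


def _drop_aliased(X: pd.DataFrame, protect: tuple[str, ...] = ()) -> tuple[pd.DataFrame, list[str]]:
    """Drop aliased columns, never dropping the protected ones."""
    cols = [c for c in protect if c in X.columns] + [c for c in X.columns if c not in protect]
    aliased = _find_aliased(X[cols])
    return X.drop(columns=aliased), aliased


# --------------------------------------------------------------------------
# alpha contrasts (ANCOVA-style linear model)
# --------------------------------------------------------------------------

def alpha_group_contrasts(alpha: pd.Series, design: pd.DataFrame,
                          reference_group: str,
                          normalization: str = "inverse_normal",
                          drop_aliased: bool = False) -> ModelResult:
    """Linear model of normalised alpha on group + covariates.

    The reference group is the contrast target: each reported contrast is
    (other group - reference), with Bonferroni adjustment over the number
    of contrasts. A rank-deficient design is an error naming the aliased
    columns unless ``drop_aliased`` is set, in which case redundant
    covariate columns are removed and flagged.
    """
    design = design.loc[alpha.index]
    y = normalize_alpha(alpha.values, normalization)
    groups = design["group"].astype(str)
    if reference_group not in set(groups):
        raise ValueError(f"reference group {reference_group!r} not in design")
    gd = pd.get_dummies(groups, prefix="group", dtype=float)
    gd = gd.drop(columns=f"group_{reference_group}")
    X = pd.concat([gd, covariate_matrix(design)], axis=1)
    X.insert(0, "const", 1.0)
    res = ModelResult()
    if drop_aliased:
        X, dropped = _drop_aliased(X, protect=("const", *gd.columns))
        if dropped:
            res.flags.append(f"dropped aliased covariates: {dropped}")
    else:
        _check_full_rank(X)
    fit = sm.OLS(y, X.astype(float)).fit()
    contrasts = [c for c in gd.columns]
    m = len(contrasts)
    for c in contrasts:
        name = c.removeprefix("group_")
        res.estimates[name] = float(fit.params[c])
        p = float(fit.pvalues[c])
        res.pvalues[name] = p
        res.adjusted_pvalues[name] = bonferroni(p, m) if np.isfinite(p) else p
    for c in X.columns:
        if c not in gd.columns:
            res.estimates.setdefault(c, float(fit.params[c]))
    res.loglik["model"] = float(fit.llf)
    res.r2["linear"] = float(fit.rsquared)
    return res


# --------------------------------------------------------------------------
# logistic models and Nagelkerke R^2
# --------------------------------------------------------------------------

def nagelkerke_r2(ll_model: float, ll_null: float, n: int) -> float:
    cox_snell = 1.0 - np.exp(2.0 * (ll_null - ll_model) / n)
    max_r2 = 1.0 - np.exp(2.0 * ll_null / n)
    return float(cox_snell / max_r2)


def _fit_logit(y: np.ndarray, X: pd.DataFrame):
    """Logit fit with a penalised fallback under (quasi-)separation."""
    import warnings

    model = sm.Logit(y, X.astype(float))
    flag = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            with np.errstate(all="ignore"):
                fit = model.fit(disp=0, method="newton", maxiter=100)
            if not fit.mle_retvals.get("converged", True):
                raise RuntimeError("no convergence")
        except Exception:
            try:
                with np.errstate(all="ignore"):
                    fit = model.fit(disp=0, method="bfgs", maxiter=500)
                flag = "bfgs_fallback"
            except Exception:
                fit = model.fit_regularized(alpha=1e-4, disp=0, maxiter=500)
                flag = "penalized_fit_separation"
    return fit, flag


def logistic_delta_r2(case_labels: pd.Series, alpha: pd.Series,
                      design: pd.DataFrame,
                      normalization: str = "inverse_normal") -> ModelResult:
    """Nagelkerke R² reduction when alpha is dropped from the case model."""
    idx = alpha.index
    y = np.asarray(case_labels.loc[idx], dtype=float)
    if set(np.unique(y)) != {0.0, 1.0}:
        raise ValueError("case labels must contain both classes")
    design = design.loc[idx]
    n = len(y)
    Xcov = covariate_matrix(design)
    Xcov.insert(0, "const", 1.0)
    Xfull = Xcov.copy()
    Xfull["alpha"] = normalize_alpha(alpha.values, normalization)
    Xfull, dropped = _drop_aliased(Xfull, protect=("const", "alpha"))
    Xcov = Xcov.drop(columns=[c for c in dropped if c in Xcov.columns])

    null_fit, _ = _fit_logit(y, Xcov[["const"]])
    full_fit, f1 = _fit_logit(y, Xfull)
    red_fit, f2 = _fit_logit(y, Xcov)
    ll0 = float(null_fit.llf)
    r2_full = nagelkerke_r2(float(full_fit.llf), ll0, n)
    r2_red = nagelkerke_r2(float(red_fit.llf), ll0, n)
    res = ModelResult()
    res.loglik = {"null": ll0, "full": float(full_fit.llf), "reduced": float(red_fit.llf)}
    res.r2 = {"nagelkerke_full": r2_full, "nagelkerke_reduced": r2_red,
              "delta": r2_full - r2_red}
    res.estimates["alpha"] = float(full_fit.params["alpha"])
    try:
        res.pvalues["alpha"] = float(full_fit.pvalues["alpha"])
    except Exception:  # penalised fits carry no Wald p
        res.pvalues["alpha"] = float("nan")
    res.flags = [f for f in (f1, f2) if f]
    if dropped:
        res.flags.append(f"dropped aliased covariates: {dropped}")
    return res


# --------------------------------------------------------------------------
# beta diversity comparisons
# --------------------------------------------------------------------------

def _pair_category_means(d: np.ndarray, lab: np.ndarray):
    """(within_A, within_B, between) means of off-diagonal entries."""
    iu = np.triu_indices(len(lab), k=1)
    li, lj = lab[iu[0]], lab[iu[1]]
    vals = d[iu]
    wa = vals[(li == 0) & (lj == 0)]
    wb = vals[(li == 1) & (lj == 1)]
    bt = vals[li != lj]
    return (wa.mean() if len(wa) else np.nan,
            wb.mean() if len(wb) else np.nan,
            bt.mean() if len(bt) else np.nan)


def beta_pair_groups(d, labels: pd.Series, n_perm: int = 999,
                     seed: int = 0) -> dict:
    """Compare within-A / within-B / between pair-category means.

    Significance comes from label permutation (pairs recomputed per
    permutation) which respects the dependence between pairs sharing a
    sample. The permutation p for each category difference is one-sided
    in the direction of the observed difference, doubled (capped at 1).
    """
    values = d.values if hasattr(d, "values") else np.asarray(d)
    ids = list(d.ids) if hasattr(d, "ids") else list(range(len(values)))
    lab_raw = np.asarray(labels.loc[ids] if hasattr(labels, "loc") else labels)
    uniq = sorted(set(lab_raw))
    if len(uniq) != 2:
        raise ValueError("beta_pair_groups needs exactly two groups")
    lab = (lab_raw == uniq[1]).astype(int)
    flags = [f"group {u} has < 2 samples; its within mean is undefined"
             for u, c in zip(uniq, np.bincount(lab, minlength=2)) if c < 2]
    obs = _pair_category_means(values, lab)
    names = (f"within_{uniq[0]}", f"within_{uniq[1]}", "between")
    rng = np.random.default_rng(seed)
    diffs = {(i, j): obs[i] - obs[j] for i in range(3) for j in range(i + 1, 3)}
    exceed = dict.fromkeys(diffs, 0)
    for _ in range(n_perm):
        perm = rng.permutation(lab)
        pm = _pair_category_means(values, perm)
        for (i, j), dobs in diffs.items():
            if np.isnan(dobs):
                continue
            if abs(pm[i] - pm[j]) >= abs(dobs) - 1e-15:
                exceed[i, j] += 1
    pvals = {f"{names[i]}_vs_{names[j]}": (1 + exceed[i, j]) / (1 + n_perm)
             for (i, j) in diffs}
    return {"means": dict(zip(names, obs)), "pvalues": pvals,
            "n_permutations": n_perm, "seed": seed, "flags": flags}


def permanova(d, labels: pd.Series, n_perm: int = 1000,
              seed: int = 0) -> ModelResult:
    """Distance-based multivariate ANOVA with a permutation p-value.

    pseudo-F = (SS_between / (a-1)) / (SS_within / (N-a)) where
    SS_total = sum_{i<j} d_ij^2 / N and SS_within sums within-group
    squared distances divided by group size. The p-value uses the
    add-one estimator (1 + #{F_perm >= F_obs}) / (1 + n_perm).
    """
    values = d.values if hasattr(d, "values") else np.asarray(d)
    ids = list(d.ids) if hasattr(d, "ids") else list(range(len(values)))
    lab = np.asarray(labels.loc[ids] if hasattr(labels, "loc") else labels)
    uniq, lab_int = np.unique(lab, return_inverse=True)
    a = len(uniq)
    n = len(lab_int)
    if a < 2 or np.bincount(lab_int).min() < 2:
        raise ValueError("need >= 2 groups with >= 2 samples each")
    D2 = values**2
    ss_total = D2[np.triu_indices(n, k=1)].sum() / n

    sizes = np.bincount(lab_int)

    def pseudo_f(assign: np.ndarray) -> float:
        ss_within = 0.0
        for g in range(a):
            mask = assign == g
            sub = D2[np.ix_(mask, mask)]
            ss_within += sub[np.triu_indices(sizes[g], k=1)].sum() / sizes[g]
        ss_between = ss_total - ss_within
        return (ss_between / (a - 1)) / (ss_within / (n - a))

    f_obs = pseudo_f(lab_int)
    rng = np.random.default_rng(seed)
    count = sum(pseudo_f(rng.permutation(lab_int)) >= f_obs - 1e-12
                for _ in range(n_perm))
    res = ModelResult()
    res.pseudo_f = float(f_obs)
    res.permutation_p = (1 + count) / (1 + n_perm)
    res.n_permutations = n_perm
    res.seed = seed
    return res


# --------------------------------------------------------------------------
# exact presence/absence tests
# --------------------------------------------------------------------------

def _log_comb(n, x):
    return gammaln(n + 1) - gammaln(x + 1) - gammaln(n - x + 1)


def fisher_exact_2xk(table: PresenceTable | tuple) -> float:
    """Two-sided exact test on a 2xK presence table.

    Conditional on all margins, the cell counts follow a multivariate
    hypergeometric law; the two-sided p is the total probability of the
    tables whose probability does not exceed the observed one (the
    probability-ordering convention of the classical exact test),
    enumerated over the K-1 free cells.
    """
    if isinstance(table, PresenceTable):
        present, totals = table.present, table.totals
    else:
        present, totals = (np.asarray(v, dtype=int) for v in table)
    if len(present) < 2:
        raise ValueError("need at least two groups")
    if (totals <= 0).any():
        raise ValueError("group totals must be positive")
    if (present < 0).any() or (present > totals).any():
        raise ValueError("present counts must lie in [0, total]")
    K = len(totals)
    m = int(present.sum())
    N = int(totals.sum())
    denom = _log_comb(N, m)
    lc = [
        {x: _log_comb(totals[g], x) for x in range(totals[g] + 1)} for g in range(K)
    ]
    logp_obs = sum(lc[g][int(present[g])] for g in range(K)) - denom
    suffix = np.concatenate([np.cumsum(totals[::-1])[::-1][1:], [0]])
    total = 0.0

    def rec(g: int, rem: int, acc: float) -> None:
        nonlocal total
        if g == K - 1:
            if 0 <= rem <= totals[g]:
                lp = acc + lc[g][rem] - denom
                if lp <= logp_obs + 1e-7:
                    total += np.exp(lp)
            return
        lo = max(0, rem - int(suffix[g]))
        hi = min(int(totals[g]), rem)
        for x in range(lo, hi + 1):
            rec(g + 1, rem - x, acc + lc[g][x])

    rec(0, m, 0.0)
    return float(min(total, 1.0))


def bonferroni(p: float, m: int) -> float:
    if not 0 <= p <= 1 or m < 1:
        raise ValueError("require p in [0,1] and m >= 1")
    return float(min(1.0, p * m))


def presence_tests(table, groups: pd.Series) -> pd.DataFrame:
    """Per-taxon 2xK presence tests with Bonferroni over observed taxa.

    Presence is abundance > 0 at the table's rank; the Bonferroni
    multiplier is the number of taxa observed in at least one sample.
    """
    rel = table.relative
    groups = groups.loc[rel.index].astype(str)
    glabels = sorted(groups.unique())
    present_mask = rel > 0
    observed = [t for t in rel.columns if present_mask[t].any()]
    m = len(observed)
    rows = []
    for t in observed:
        pres = np.array([int(present_mask.loc[groups == g, t].sum()) for g in glabels])
        tot = np.array([int((groups == g).sum()) for g in glabels])
        p = fisher_exact_2xk((pres, tot))
        rows.append({"taxon": t, **{f"present_{g}": pres[i] for i, g in enumerate(glabels)},
                     "p": p, "p_bonferroni": bonferroni(p, m)})
    return pd.DataFrame(rows).set_index("taxon")


# --------------------------------------------------------------------------
# ordination-axis and cell-proportion associations
# --------------------------------------------------------------------------

def ordination_association(coords: pd.DataFrame, case_labels: pd.Series,
                           design: pd.DataFrame, n_axes: int = 3) -> ModelResult:
    """Logistic model of case status on the leading ordination axes plus
    covariates; per-axis Wald p and joint Nagelkerke ΔR² for the block."""
    idx = coords.index
    y = np.asarray(case_labels.loc[idx], dtype=float)
    design = design.loc[idx]
    axes = list(coords.columns[:n_axes])
    Xcov = covariate_matrix(design)
    Xcov.insert(0, "const", 1.0)
    Xfull = pd.concat([Xcov, coords[axes]], axis=1)
    Xfull, dropped = _drop_aliased(Xfull, protect=("const", *axes))
    Xcov = Xcov.drop(columns=[c for c in dropped if c in Xcov.columns])
    n = len(y)
    null_fit, _ = _fit_logit(y, Xcov[["const"]])
    full_fit, f1 = _fit_logit(y, Xfull)
    red_fit, f2 = _fit_logit(y, Xcov)
    ll0 = float(null_fit.llf)
    res = ModelResult()
    for ax in axes:
        res.estimates[ax] = float(full_fit.params[ax])
        try:
            res.pvalues[ax] = float(full_fit.pvalues[ax])
        except Exception:
            res.pvalues[ax] = float("nan")
    res.r2 = {
        "nagelkerke_full": nagelkerke_r2(float(full_fit.llf), ll0, n),
        "nagelkerke_reduced": nagelkerke_r2(float(red_fit.llf), ll0, n),
    }
    res.r2["delta"] = res.r2["nagelkerke_full"] - res.r2["nagelkerke_reduced"]
    res.flags = [f for f in (f1, f2) if f]
    if dropped:
        res.flags.append(f"dropped aliased covariates: {dropped}")
    return res


def _residualize(y: np.ndarray, X: pd.DataFrame) -> np.ndarray:
    Xv = np.column_stack([np.ones(len(y)), X.values.astype(float)]) if X.shape[1] else np.ones((len(y), 1))
    beta, *_ = np.linalg.lstsq(Xv, y, rcond=None)
    return y - Xv @ beta


def cell_proportion_association(alpha: pd.Series, cell_table: pd.DataFrame,
                                design: pd.DataFrame | None = None,
                                covariates=COVARIATES) -> pd.DataFrame:
    """Partial correlation of each cell type's proportion with alpha.

    For each cell type, alpha and the proportion are residualised on the
    covariates plus all *other* cell types; because proportions sum to
    one, the last other cell type is dropped from the adjustment set.
    Reports the Pearson correlation of residuals, its p, and Bonferroni
    over cell types.
    """
    idx = alpha.index
    cell_table = cell_table.loc[idx]
    if cell_table.shape[1] < 2:
        raise ValueError("need at least two cell types")
    if design is not None:
        Xcov = covariate_matrix(design.loc[idx], covariates)
    else:
        Xcov = pd.DataFrame(index=idx)
    rows = []
    m = cell_table.shape[1]
    for ct in cell_table.columns:
        others = [c for c in cell_table.columns if c != ct][:-1]  # drop one: sum-to-1
        X = pd.concat([Xcov, cell_table[others]], axis=1)
        ra = _residualize(np.asarray(alpha, dtype=float), X)
        rc = _residualize(cell_table[ct].values.astype(float), X)
        r, p = pearsonr(ra, rc)
        rows.append({"cell_type": ct, "partial_r": float(r), "p": float(p),
                     "p_bonferroni": bonferroni(p, m)})
    return pd.DataFrame(rows).set_index("cell_type")
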