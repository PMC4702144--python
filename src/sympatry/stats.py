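"""Statistical battery: two-sample tests, ICC gating, mixed models,
information-theoretic model sets and repeated cross-validation.

Model formulas use a small lme4-style grammar::

    response ~ term1 + term2 + (1|group)

Gaussian responses are fitted as linear mixed models (ML, random intercept);
binomial responses as maximum-likelihood random-intercept logistic models.
Convention throughout: p < 0.05 is significant, 0.05 <= p < 0.10 marginal.
"""
from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from statsmodels.stats.outliers_influence import variance_inflation_factor

from .exceptions import InputError, PipelineError, UndefinedResultError
from .glmm import BinomialRandomInterceptGLMM

log = logging.getLogger(__name__)

ICC_CUTOFF = 0.30          # below this, clustering is ignored and K-S used
DELTA_AIC_SUPPORT = 2.0    # strictly less than: substantial support


# ---------------------------------------------------------------------------
# two-sample tests

@dataclass
class TestResult:
    test: str
    statistic: float
    p_value: float
    alternative: str
    n_x: int
    n_y: int
    extra: dict = field(default_factory=dict)


def ks_two_sample(x, y, alternative: str = "two_sided") -> TestResult:
    """Two-sample Kolmogorov-Smirnov test.

    ``alternative='greater'`` tests whether the distribution of ``x`` is
    stochastically greater than that of ``y`` (its ECDF lies below).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or y.size < 3:
        raise InputError("K-S test needs at least 3 values per sample")
    alt = {"two_sided": "two-sided", "greater": "less",
           "less": "greater"}.get(alternative)
    if alt is None:
        raise InputError(f"unknown alternative {alternative!r}")
    res = sps.ks_2samp(x, y, alternative=alt, method="auto")
    return TestResult("ks", float(res.statistic), float(res.pvalue),
                      alternative, x.size, y.size)


def mann_whitney(x, y) -> TestResult:
    """Mann-Whitney U test with a tie-corrected normal-approximation Z.

    For small samples (n + m <= 18) the p-value is exact: the full
    permutation distribution of U is enumerated (midranks, so ties are
    handled) and the two-sided p is ``min(1, 2 * min(lower tail, upper
    tail))``, both tails including the observed value.  Larger samples use
    the tie-corrected normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = x.size, y.size
    if n < 3 or m < 3:
        raise InputError("Mann-Whitney test needs at least 3 values")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    u_x = ranks[:n].sum() - n * (n + 1) / 2.0
    mu = n * m / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts ** 3 - tie_counts).sum()
    var = n * m / 12.0 * ((n + m + 1) - tie_term /
                          ((n + m) * (n + m - 1.0)))
    z = 0.0 if var <= 0 else (u_x - mu) / np.sqrt(var)
    if var <= 0:
        p = 1.0
    elif n + m <= 18:
        import itertools
        combos = np.array(list(itertools.combinations(range(n + m), n)))
        u_all = ranks[combos].sum(axis=1) - n * (n + 1) / 2.0
        lo = (u_all <= u_x + 1e-9).mean()
        hi = (u_all >= u_x - 1e-9).mean()
        p = float(min(1.0, 2.0 * min(lo, hi)))
    else:
        p = float(2 * sps.norm.sf(abs(z)))
    return TestResult("mann_whitney", float(u_x), p, "two_sided", n, m,
                      extra={"z": float(z)})


def icc(values, clusters) -> float:
    """One-way random-effects intraclass correlation via ANOVA variance
    components; negative between-cluster estimates truncate to 0."""
    values = np.asarray(values, dtype=float)
    codes, _ = pd.factorize(np.asarray(clusters))
    k = codes.max() + 1
    if k < 2:
        raise UndefinedResultError("ICC needs at least 2 clusters")
    n_i = np.bincount(codes)
    if n_i.max() < 2:
        raise UndefinedResultError("ICC needs repeated values in a cluster")
    n = values.size
    grand = values.mean()
    means = np.bincount(codes, weights=values) / n_i
    ss_between = (n_i * (means - grand) ** 2).sum()
    ss_within = ((values - means[codes]) ** 2).sum()
    ms_between = ss_between / (k - 1)
    ms_within = ss_within / (n - k) if n > k else 0.0
    n0 = (n - (n_i ** 2).sum() / n) / (k - 1)
    sigma_b = max((ms_between - ms_within) / n0, 0.0)
    denom = sigma_b + ms_within
    return float(sigma_b / denom) if denom > 0 else 0.0


# ---------------------------------------------------------------------------
# design helpers

def standardize(data: pd.DataFrame, columns) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Z-standardize predictor columns; zero-SD columns are dropped with a
    warning.  Returns the transformed frame and the stored means/SDs."""
    out = data.copy()
    rows = []
    for c in columns:
        mu = float(out[c].mean())
        sd = float(out[c].std(ddof=0))   # population SD: {0,1} maps to +-1
        if not np.isfinite(sd) or sd == 0:
            warnings.warn(f"column {c!r} has zero variance; dropped",
                          stacklevel=2)
            out = out.drop(columns=[c])
            continue
        out[c] = (out[c] - mu) / sd
        rows.append({"column": c, "mean": mu, "sd": sd})
    return out, pd.DataFrame(rows)


def vif(design: pd.DataFrame) -> pd.Series:
    """Variance inflation factor per predictor (intercept added
    internally); infinite values flag perfect collinearity."""
    if design.shape[1] < 2:
        raise InputError("VIF needs at least 2 predictors")
    if design.shape[0] <= design.shape[1]:
        raise InputError("VIF needs more rows than predictors")
    X = sm.add_constant(design.to_numpy(float), has_constant="add")
    vals = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for j, c in enumerate(design.columns, start=1):
            v = variance_inflation_factor(X, j)
            vals[c] = float(v) if np.isfinite(v) else np.inf
    return pd.Series(vals, name="vif")


# ---------------------------------------------------------------------------
# mixed models

_FORMULA_RE = re.compile(
    r"^\s*(?P<resp>[\w.]+)\s*~\s*(?P<rhs>.*?)\s*$")
_RANDOM_RE = re.compile(r"\(\s*1\s*\|\s*(?P<group>[\w.]+)\s*\)")


def parse_formula(formula: str) -> tuple[str, list[str], str | None]:
    """Split ``y ~ a + b + (1|g)`` into (response, fixed terms, group)."""
    m = _FORMULA_RE.match(formula)
    if not m:
        raise InputError(f"cannot parse formula {formula!r}")
    resp, rhs = m.group("resp"), m.group("rhs")
    rm = _RANDOM_RE.search(rhs)
    group = rm.group("group") if rm else None
    rhs = _RANDOM_RE.sub("", rhs)
    fixed = [t.strip() for t in rhs.split("+")
             if t.strip() and t.strip() != "1"]
    return resp, fixed, group


_TRANSFORMS = {
    None: lambda v: v,
    "log10": np.log10,
    "sqrt": np.sqrt,
}


@dataclass
class ModelFit:
    """One fitted (mixed) model: coefficient table, AIC, convergence."""

    formula: str
    family: str
    params: pd.DataFrame       # term / estimate / se / stat / p
    aic: float
    re_var: float              # random-intercept variance (0 if no group)
    converged: bool
    nobs: int
    group: str | None
    result: object = field(repr=False, default=None)

    def coef(self, term: str) -> pd.Series:
        sub = self.params[self.params["term"] == term]
        if sub.empty:
            raise KeyError(term)
        return sub.iloc[0]


def _design(data: pd.DataFrame, fixed: list[str]) -> tuple[np.ndarray, list]:
    cols = [np.ones(len(data))]
    names = ["(Intercept)"]
    for term in fixed:
        if term not in data.columns:
            raise InputError(f"term {term!r} not in data")
        v = data[term]
        if v.dtype == object or isinstance(v.dtype, pd.CategoricalDtype) \
                or v.dtype == bool:
            codes, levels = pd.factorize(v, sort=True)
            for lev in range(1, len(levels)):
                cols.append((codes == lev).astype(float))
                names.append(f"{term}[{levels[lev]}]")
        else:
            cols.append(v.to_numpy(float))
            names.append(term)
    return np.column_stack(cols), names


def fit_mixed(formula: str, data: pd.DataFrame, family: str = "gaussian",
              transform: str | None = None,
              min_groups_warn: int = 5) -> ModelFit:
    """Fit a random-intercept mixed model by maximum likelihood.

    Gaussian responses use a linear mixed model; binomial responses a
    Gauss-Hermite ML logistic mixed model.  Without a ``(1|group)`` term the
    corresponding ordinary model is fitted.
    """
    resp, fixed, group = parse_formula(formula)
    if resp not in data.columns:
        raise InputError(f"response {resp!r} not in data")
    rows = data.dropna(subset=[resp] + fixed +
                       ([group] if group else [])).copy()
    y = _TRANSFORMS[transform](rows[resp].to_numpy(float))
    X, names = _design(rows, fixed)
    if group is not None:
        n_groups = rows[group].nunique()
        if n_groups < min_groups_warn:
            warnings.warn(f"only {n_groups} groups for random intercept",
                          stacklevel=2)

    if family == "gaussian":
        if group is None:
            res = sm.OLS(y, X).fit()
            table = pd.DataFrame({
                "term": names, "estimate": res.params, "se": res.bse,
                "stat": res.tvalues, "p": res.pvalues})
            return ModelFit(formula, family, table, float(res.aic), 0.0,
                            True, int(res.nobs), None, res)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM(y, X, groups=rows[group].to_numpy())
            res = model.fit(reml=False)
        k = X.shape[1] + 2          # fixed effects + 2 variances
        aic = 2 * k - 2 * res.llf
        table = pd.DataFrame({
            "term": names, "estimate": res.fe_params,
            "se": res.bse_fe, "stat": res.tvalues[:len(names)],
            "p": res.pvalues[:len(names)]})
        re_var = float(np.asarray(res.cov_re).ravel()[0])
        return ModelFit(formula, family, table, float(aic), re_var,
                        bool(res.converged), int(res.nobs), group, res)

    if family == "binomial":
        uniq = set(np.unique(y))
        if not uniq <= {0.0, 1.0}:
            raise InputError("binomial response must be coded 0/1")
        if group is None:
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
            table = pd.DataFrame({
                "term": names, "estimate": res.params, "se": res.bse,
                "stat": res.tvalues, "p": res.pvalues})
            return ModelFit(formula, family, table, float(res.aic), 0.0,
                            True, int(res.nobs), None, res)
        model = BinomialRandomInterceptGLMM(
            y, X, rows[group].to_numpy(), exog_names=names)
        res = model.fit()
        table = res.summary_frame()
        return ModelFit(formula, family, table, float(res.aic),
                        float(res.sigma_u ** 2), res.converged,
                        res.nobs, group, res)

    raise InputError(f"unknown family {family!r}")


@dataclass
class ModelSet:
    """AIC-ranked candidate models (information-theoretic comparison)."""

    table: pd.DataFrame        # formula / aic / delta_aic / supported
    fits: list

    @property
    def best(self) -> ModelFit:
        return self.fits[int(self.table["aic"].idxmin())]


def support_flag(delta_aic) -> np.ndarray:
    """Substantial support: strictly dAIC < 2 (a model at exactly 2.0 is
    not supported)."""
    return np.asarray(delta_aic) < DELTA_AIC_SUPPORT


def model_set(formulas, data: pd.DataFrame, family: str = "gaussian",
              transform: str | None = None) -> ModelSet:
    """Fit every candidate, rank by AIC; strict dAIC < 2 marks support.
    Non-converged fits are excluded with a log entry."""
    fits, rows = [], []
    for f in formulas:
        fit = fit_mixed(f, data, family=family, transform=transform)
        if not fit.converged or not np.isfinite(fit.aic):
            log.warning("model %r did not converge; excluded", f)
            continue
        fits.append(fit)
        rows.append({"formula": f, "aic": fit.aic})
    if not fits:
        raise PipelineError("all candidate models failed to converge")
    table = pd.DataFrame(rows)
    table["delta_aic"] = table["aic"] - table["aic"].min()
    table["supported"] = support_flag(table["delta_aic"])
    return ModelSet(table=table, fits=fits)


# ---------------------------------------------------------------------------
# cross-validation

def confusion_metrics(tp: int, fp: int, fn: int, tn: int) -> dict:
    """Sensitivity, specificity, percent-correctly-classified and Cohen's
    kappa from a 2x2 confusion matrix."""
    n = tp + fp + fn + tn
    po = (tp + tn) / n
    pe = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / n ** 2
    return {
        "sensitivity": tp / (tp + fn) if tp + fn else np.nan,
        "specificity": tn / (tn + fp) if tn + fp else np.nan,
        "pcc": 100.0 * po,
        "kappa": (po - pe) / (1 - pe) if pe < 1 else 1.0,
    }


@dataclass
class CVReport:
    """Repeated k-fold cross-validation metrics (pooled out-of-fold)."""

    per_repeat: pd.DataFrame
    threshold: float

    def summary(self) -> pd.DataFrame:
        s = self.per_repeat.agg(["mean", "std"]).T
        s.columns = ["mean", "sd"]
        return s


def cross_validate(formula: str, data: pd.DataFrame,
                   family: str = "binomial", folds: int = 10,
                   repeats: int = 10, threshold: float = 0.5,
                   seed: int = 0) -> CVReport:
    """Stratified repeated k-fold CV of a presence/absence model.

    Out-of-fold population-level probabilities are pooled within each
    repeat, then kappa / PCC / sensitivity / specificity at the given
    threshold and the rank-based AUC are computed.
    """
    resp, fixed, group = parse_formula(formula)
    rows = data.dropna(subset=[resp] + fixed +
                       ([group] if group else [])).reset_index(drop=True)
    y = rows[resp].to_numpy(float)
    n_pos, n_neg = int((y == 1).sum()), int((y == 0).sum())
    if min(n_pos, n_neg) < folds:
        raise InputError(
            f"need at least {folds} cases of each class for {folds}-fold CV")
    X, _ = _design(rows, fixed)
    out = []
    for rep in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True,
                              random_state=(seed + rep) % (2 ** 31))
        proba = np.empty_like(y)
        for train, test in skf.split(X, y):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                fit = fit_mixed(formula, rows.iloc[train], family=family)
            proba[test] = fit.result.predict(X[test])
        pred = (proba >= threshold).astype(int)
        tp = int(((pred == 1) & (y == 1)).sum())
        fp = int(((pred == 1) & (y == 0)).sum())
        fn = int(((pred == 0) & (y == 1)).sum())
        tn = int(((pred == 0) & (y == 0)).sum())
        m = confusion_metrics(tp, fp, fn, tn)
        m["auc"] = float(roc_auc_score(y, proba))
        out.append(m)
    return CVReport(per_repeat=pd.DataFrame(out), threshold=threshold)


# ---------------------------------------------------------------------------
# the ICC gate

def gated_comparison(x, y, clusters_x=None, clusters_y=None,
                     icc_cutoff: float = ICC_CUTOFF,
                     alternative: str = "two_sided") -> dict:
    """Compare two depth distributions, using the simpler K-S test when the
    intraclass correlation within either sample is low (< cutoff) and a
    random-intercept LMM otherwise."""
    iccs = []
    for v, c in ((x, clusters_x), (y, clusters_y)):
        if c is not None and pd.Series(c).nunique() > 1:
            try:
                iccs.append(icc(v, c))
            except UndefinedResultError:
                pass
    use_ks = (not iccs) or max(iccs) < icc_cutoff
    if use_ks:
        res = ks_two_sample(x, y, alternative=alternative)
        return {"method": "ks", "icc": max(iccs) if iccs else np.nan,
                "statistic": res.statistic, "p": res.p_value,
                "n_x": res.n_x, "n_y": res.n_y}
    df = pd.DataFrame({
        "value": np.concatenate([np.asarray(x, float),
                                 np.asarray(y, float)]),
        "grp": ["x"] * len(x) + ["y"] * len(y),
        "cluster": np.concatenate([np.asarray(clusters_x),
                                   np.asarray(clusters_y)]),
    })
    fit = fit_mixed("value ~ grp + (1|cluster)", df, family="gaussian",
                    transform="sqrt")
    row = fit.coef("grp[y]")
    return {"method": "lmm", "icc": max(iccs), "statistic": row["stat"],
            "p": row["p"], "n_x": len(x), "n_y": len(y)}
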