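"""Baseline predictors of cluster membership.

Workflow: screen candidate covariates by one-way ANOVA (continuous) or
Pearson chi-square (categorical) at uncorrected p < 0.05; multiply impute
missing covariates by chained equations with the cluster label included in
every conditional model; fit a baseline-category multinomial logistic
regression of cluster membership per completed dataset; pool estimates by
Rubin's rules; and report odds ratios with Wald confidence intervals,
Nagelkerke R-squared, and variance inflation factors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LinearRegression, LogisticRegression
from sklearn.exceptions import ConvergenceWarning
import statsmodels.api as sm

from ._util import spawn_seed


# ---------------------------------------------------------------------------
# typing and screening
# ---------------------------------------------------------------------------


def infer_types(table: pd.DataFrame) -> dict[str, str]:
    """Guess each covariate's type: binary, categorical or continuous."""
    types = {}
    for col in table.columns:
        if col == "participant":
            continue
        v = table[col].dropna()
        if v.dtype == object or isinstance(v.dtype, pd.CategoricalDtype):
            types[col] = "categorical"
        elif set(np.unique(v)) <= {0, 1}:
            types[col] = "binary"
        else:
            types[col] = "continuous"
    return types


def screen_predictors(covariate_table: pd.DataFrame, labels: pd.Series,
                      types: dict[str, str] | None = None,
                      alpha: float = 0.05) -> pd.DataFrame:
    """Per-variable between-cluster tests on available cases, no correction.

    Continuous variables get a one-way ANOVA F across clusters; binary and
    categorical variables a Pearson chi-square on the contingency table.
    A variable is selected iff p < ``alpha``; variables with a single
    observed level are excluded with a reason.
    """
    labels = labels.reindex(covariate_table.index)
    if labels.nunique() < 2:
        raise ValueError("need at least 2 clusters to screen predictors")
    types = types or infer_types(covariate_table)
    rows = []
    for var, kind in types.items():
        x = covariate_table[var]
        obs = x.notna() & labels.notna()
        xv, lv = x[obs], labels[obs]
        if xv.nunique() < 2:
            rows.append({"variable": var, "test": "excluded", "statistic": np.nan,
                         "df": np.nan, "p": np.nan, "selected": False,
                         "reason": "single observed level"})
            continue
        if kind == "continuous":
            groups = [g.to_numpy(float) for _, g in xv.groupby(lv, observed=True)]
            stat, p = stats.f_oneway(*groups)
            df = f"({len(groups) - 1}, {len(xv) - len(groups)})"
            test = "anova_f"
        else:
            table = pd.crosstab(xv, lv)
            stat, p, dof, _ = stats.chi2_contingency(table, correction=False)
            df, test = str(dof), "chi_square"
        rows.append({"variable": var, "test": test, "statistic": float(stat),
                     "df": df, "p": float(p), "selected": bool(p < alpha),
                     "reason": ""})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# multiple imputation by chained equations
# ---------------------------------------------------------------------------


@dataclass
class ImputedStack:
    tables: list[pd.DataFrame]
    metadata: dict = field(default_factory=dict)

    @property
    def m(self) -> int:
        return len(self.tables)


def _predictor_matrix(table: pd.DataFrame, labels: pd.Series, exclude: str,
                      types: dict[str, str]) -> np.ndarray:
    parts = []
    for col, kind in types.items():
        if col == exclude:
            continue
        if kind == "categorical":
            parts.append(pd.get_dummies(table[col], prefix=col, drop_first=True)
                         .to_numpy(float))
        else:
            parts.append(table[[col]].to_numpy(float))
    parts.append(pd.get_dummies(labels, drop_first=True).to_numpy(float))
    return np.column_stack(parts)


def mice_impute(covariate_table: pd.DataFrame, labels: pd.Series, m: int = 100,
                iterations: int = 10, seed: int = 0,
                types: dict[str, str] | None = None) -> ImputedStack:
    """Chained-equation multiple imputation of the covariate table.

    Conditional models per type: linear regression with predictive mean
    matching (5 donors) for continuous variables, logistic for binary,
    multinomial for nominal.  The cluster label enters every conditional
    model as a predictor; variables are visited in order of increasing
    missingness.  Between-imputation variability comes from a row bootstrap
    of each conditional model's fitting sample and from the stochastic
    draws, stream-seeded so the ``m`` chains are independent.  Observed
    cells are identical across all returned tables.
    """
    table = covariate_table.drop(columns=["participant"], errors="ignore")
    types = types or infer_types(table)
    labels = labels.reindex(table.index)
    missing = {v: table[v].isna() for v in types}
    for v in types:
        if missing[v].all():
            raise ValueError(f"{v}: no observed values to impute from")
    incomplete = sorted((v for v in types if missing[v].any()),
                        key=lambda v: (missing[v].mean(), v))
    if not incomplete:
        stack = [table.copy() for _ in range(m)]
        return ImputedStack(stack, {"iterations": 0, "seed": seed,
                                    "methods": {}})

    methods = {v: {"continuous": "pmm", "binary": "logistic",
                   "categorical": "multinomial"}[types[v]] for v in incomplete}
    tables = []
    for chain in range(m):
        rng = np.random.default_rng(spawn_seed(seed, 31, chain))
        cur = table.copy()
        for v in incomplete:  # initialize from the observed marginal
            obs_vals = table.loc[~missing[v], v].to_numpy()
            cur.loc[missing[v], v] = rng.choice(obs_vals, size=int(missing[v].sum()))
        for _ in range(iterations):
            for v in incomplete:
                X = _predictor_matrix(cur, labels, v, types)
                obs_idx = np.where(~missing[v].to_numpy())[0]
                mis_idx = np.where(missing[v].to_numpy())[0]
                boot = rng.choice(obs_idx, size=len(obs_idx), replace=True)
                y_obs = cur[v].to_numpy()[boot]
                try:
                    if methods[v] == "pmm":
                        lm = LinearRegression().fit(X[boot], y_obs.astype(float))
                        yhat_obs = lm.predict(X[obs_idx])
                        yhat_mis = lm.predict(X[mis_idx])
                        donors = np.argsort(
                            np.abs(yhat_obs[None, :] - yhat_mis[:, None]), axis=1)[:, :5]
                        pick = donors[np.arange(len(mis_idx)),
                                      rng.integers(0, donors.shape[1], len(mis_idx))]
                        cur.iloc[mis_idx, cur.columns.get_loc(v)] = (
                            cur[v].to_numpy()[obs_idx[pick]])
                    else:
                        if len(np.unique(y_obs)) < 2:
                            continue  # bootstrap collapsed to one class
                        with warnings.catch_warnings():
                            warnings.simplefilter("error", ConvergenceWarning)
                            clf = LogisticRegression(max_iter=200, C=1e6).fit(X[boot], y_obs)
                        proba = clf.predict_proba(X[mis_idx])
                        cum = proba.cumsum(axis=1)
                        u = rng.random((len(mis_idx), 1))
                        draw = (u > cum).sum(axis=1)
                        cur.iloc[mis_idx, cur.columns.get_loc(v)] = clf.classes_[draw]
                except ConvergenceWarning:
                    warnings.warn(f"conditional model for {v} did not converge; "
                                  "variable skipped this iteration", stacklevel=2)
        tables.append(cur)
    return ImputedStack(tables, {"iterations": iterations, "seed": seed,
                                 "methods": methods})


# ---------------------------------------------------------------------------
# multinomial logistic regression
# ---------------------------------------------------------------------------


@dataclass
class MultinomialFit:
    params: pd.DataFrame  # MultiIndex (cluster, predictor) -> estimate
    bse: pd.DataFrame
    llf: float
    llnull: float
    n: int
    design: pd.DataFrame
    clusters: list[str]


def build_design(covariate_table: pd.DataFrame, types: dict[str, str] | None = None,
                 standardize: bool = True) -> pd.DataFrame:
    """Numeric design matrix: standardized continuous, 0/1 binary, dummies."""
    table = covariate_table.drop(columns=["participant"], errors="ignore")
    types = types or infer_types(table)
    parts = []
    for col, kind in types.items():
        if kind == "categorical":
            parts.append(pd.get_dummies(table[col], prefix=col, drop_first=True)
                         .astype(float))
        elif kind == "continuous" and standardize:
            v = table[col].astype(float)
            parts.append(((v - v.mean()) / v.std(ddof=1)).to_frame(col))
        else:
            parts.append(table[col].astype(float).to_frame(col))
    return pd.concat(parts, axis=1)


def fit_multinomial(covariate_table: pd.DataFrame, labels: pd.Series,
                    reference_cluster, types: dict[str, str] | None = None,
                    standardize: bool = True) -> MultinomialFit:
    """Baseline-category multinomial logit by maximum likelihood.

    Continuous predictors are standardized before fitting; the cluster
    named ``reference_cluster`` is the baseline category.  Wald standard
    errors come from the observed information.  Possible separation
    (|coefficient| > 15) raises a warning, rank deficiency an error naming
    the collinear columns.
    """
    labels = labels.reindex(covariate_table.index)
    cats = list(pd.unique(labels.dropna()))
    if reference_cluster not in cats:
        raise ValueError(f"reference cluster {reference_cluster!r} not present")
    order = [reference_cluster] + sorted(c for c in cats if c != reference_cluster)
    y = pd.Categorical(labels, categories=order).codes
    X = build_design(covariate_table, types, standardize)
    Xc = sm.add_constant(X, prepend=True)
    rank = np.linalg.matrix_rank(Xc.to_numpy(float))
    if rank < Xc.shape[1]:
        bad = _collinear_columns(Xc)
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")
    model = sm.MNLogit(y, Xc.to_numpy(float))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(method="newton", maxiter=200, disp=0, tol=1e-10)
    names = list(Xc.columns)
    non_ref = order[1:]
    params = pd.DataFrame(res.params, index=names, columns=non_ref)
    bse = pd.DataFrame(res.bse, index=names, columns=non_ref)
    if (params.abs() > 15).any().any():
        warnings.warn("possible separation: a |coefficient| exceeds 15", stacklevel=2)
    return MultinomialFit(params=params, bse=bse, llf=float(res.llf),
                          llnull=float(res.llnull), n=int(len(y)),
                          design=X, clusters=order)


def _collinear_columns(X: pd.DataFrame) -> list[str]:
    arr = X.to_numpy(float)
    bad = []
    for j, name in enumerate(X.columns):
        others = np.delete(arr, j, axis=1)
        resid = arr[:, j] - others @ np.linalg.lstsq(others, arr[:, j], rcond=None)[0]
        if np.abs(resid).max() < 1e-8:
            bad.append(name)
    return bad


# ---------------------------------------------------------------------------
# Rubin pooling and model-fit measures
# ---------------------------------------------------------------------------


def coefficient_frame(fit: MultinomialFit) -> pd.DataFrame:
    """Flatten a fit into (cluster, predictor) -> estimate, se rows."""
    rows = []
    for cluster in fit.params.columns:
        for pred in fit.params.index:
            rows.append({"cluster": cluster, "predictor": pred,
                         "estimate": fit.params.loc[pred, cluster],
                         "se": fit.bse.loc[pred, cluster]})
    return pd.DataFrame(rows).set_index(["cluster", "predictor"])


def pool_rubin(coefficient_sets: list[pd.DataFrame], alpha: float = 0.05) -> pd.DataFrame:
    """Rubin's rules over m per-imputation coefficient tables.

    Q̄ = mean estimate, W = mean squared SE, B = between-imputation
    variance, T = W + (1 + 1/m) B, Barnard–Rubin-style df
    (m − 1)[1 + W/((1 + 1/m)B)]² (infinite when B = 0), t-based CI and
    two-sided p.  Odds ratios are the exponentiated pooled log-odds.
    """
    m = len(coefficient_sets)
    if m == 0:
        raise ValueError("no coefficient sets to pool")
    index = coefficient_sets[0].index
    for cs in coefficient_sets[1:]:
        if not cs.index.equals(index):
            raise ValueError("coefficient names differ across imputations")
    if m == 1:
        warnings.warn("pooling a single imputation: between-variance is zero",
                      stacklevel=2)
    est = np.column_stack([cs["estimate"].to_numpy(float) for cs in coefficient_sets])
    ses = np.column_stack([cs["se"].to_numpy(float) for cs in coefficient_sets])
    qbar = est.mean(axis=1)
    w = (ses**2).mean(axis=1)
    b = est.var(axis=1, ddof=1) if m > 1 else np.zeros_like(qbar)
    t_var = w + (1 + 1 / m) * b
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(b > 0, w / ((1 + 1 / m) * np.where(b > 0, b, 1.0)), 0.0)
        df = np.where(b > 0, max(m - 1, 1) * (1 + ratio) ** 2, np.inf)
    se_t = np.sqrt(t_var)
    tcrit = stats.t.ppf(1 - alpha / 2, df)
    stat = np.divide(qbar, se_t, out=np.zeros_like(qbar), where=se_t > 0)
    p = 2 * stats.t.sf(np.abs(stat), df)
    out = pd.DataFrame({
        "Qbar": qbar, "W": w, "B": b, "T": t_var, "df": df,
        "OR": np.exp(qbar),
        "ci_low": np.exp(qbar - tcrit * se_t),
        "ci_high": np.exp(qbar + tcrit * se_t),
        "p": np.clip(p, np.finfo(float).tiny, 1.0),
    }, index=index)
    return out


def nagelkerke_r2(ll_model: float, ll_null: float, n: int) -> float:
    """Rescaled Cox–Snell R² for likelihood-based categorical models."""
    if n <= 0:
        raise ValueError("n must be positive")
    if ll_model < ll_null - 1e-8:
        raise ValueError("model log-likelihood below the null's")
    r2_cs = 1.0 - np.exp(2.0 * (ll_null - ll_model) / n)
    denom = 1.0 - np.exp(2.0 * ll_null / n)
    return float(r2_cs / denom) if denom > 0 else 0.0


def compute_vif(design: pd.DataFrame,
                groups: dict[str, list[str]] | None = None) -> pd.Series:
    """Variance inflation per predictor (generalized for dummy groups).

    Single-column predictors get the classical 1/(1 − R²); a multi-column
    group (the dummies of one categorical variable) gets the generalized
    VIF normalized by its degrees of freedom, GVIF^(1/df), which reduces to
    the classical value for df = 1.  Perfect collinearity reports inf.
    """
    if design.shape[1] < 2:
        raise ValueError("need at least 2 predictors")
    X = design.to_numpy(float)
    if (X.std(axis=0) == 0).any():
        raise ValueError("constant column in the design matrix")
    corr = np.corrcoef(X, rowvar=False)
    groups = groups or {c: [c] for c in design.columns}
    cols = {c: i for i, c in enumerate(design.columns)}
    out = {}
    det_all = np.linalg.det(corr)
    for name, members in groups.items():
        idx = [cols[c] for c in members]
        rest = [i for i in range(len(cols)) if i not in idx]
        det1 = np.linalg.det(corr[np.ix_(idx, idx)])
        det2 = np.linalg.det(corr[np.ix_(rest, rest)])
        if det_all <= 1e-12:
            out[name] = np.inf
            continue
        gvif = det1 * det2 / det_all
        out[name] = float(gvif ** (1.0 / len(idx)))
    return pd.Series(out, name="vif")


# ---------------------------------------------------------------------------
# end-to-end convenience
# ---------------------------------------------------------------------------


@dataclass
class PredictorAnalysis:
    screening: pd.DataFrame
    pooled: pd.DataFrame
    nagelkerke: float
    vif: pd.Series
    m: int


def run_predictor_analysis(covariate_table: pd.DataFrame, labels: pd.Series,
                           reference_cluster, m: int = 100, iterations: int = 5,
                           seed: int = 0, types: dict[str, str] | None = None
                           ) -> PredictorAnalysis:
    """Screen, multiply impute, fit, and pool — the full regression stage.

    Nagelkerke R² is computed per imputation and averaged; VIF is computed
    on the first imputed dataset.
    """
    table = covariate_table.drop(columns=["participant"], errors="ignore")
    types = types or infer_types(table)
    screening = screen_predictors(table, labels, types)
    keep = screening.loc[screening["selected"], "variable"].tolist()
    if not keep:
        raise ValueError("no covariate passed screening")
    sub_types = {v: types[v] for v in keep}
    stack = mice_impute(table[keep], labels, m=m, iterations=iterations,
                        seed=seed, types=sub_types)
    fits = [fit_multinomial(tbl, labels, reference_cluster, types=sub_types)
            for tbl in stack.tables]
    pooled = pool_rubin([coefficient_frame(f) for f in fits])
    r2 = float(np.mean([nagelkerke_r2(f.llf, f.llnull, f.n) for f in fits]))
    if fits[0].design.shape[1] >= 2:
        vif = compute_vif(fits[0].design)
    else:  # a lone predictor cannot be collinear with anything
        vif = pd.Series(1.0, index=fits[0].design.columns, name="vif")
    return PredictorAnalysis(screening, pooled, r2, vif, m=stack.m)
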