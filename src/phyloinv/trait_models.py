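"""Trait contrasts and invasiveness models.

Four pieces of machinery:

* :func:`trait_contrasts` builds the per-alien design matrix: treewide
  PNND, alien group, absolute trait values (Ellenberg L/F/N/R/S, log
  height, clonality, life-form), and *differences* to the nearest native
  relative (native minus alien for continuous traits; 0/1 mismatch for
  categorical ones).
* :func:`fit_binomial_glm`, :func:`enumerate_candidates` and
  :func:`model_average` implement all-subsets (up to five variables)
  binomial GLMs of invasiveness with AICc multimodel averaging:
  Akaike weights from AICc differences, full (zero-substituted) averaged
  coefficients, unconditional standard errors per Burnham & Anderson,
  and relative variable importance (the sum of Akaike weights over
  models containing the variable).
* :func:`country_group_lm` and :func:`fit_nested_lmm` compare PNND/MPD
  between invasive and non-invasive aliens: a pooled two-group linear
  model at the country scale, and at the plot scale a REML linear mixed
  model with a random intercept per species and per square nested within
  species (``value ~ invasiveness + (1 | species/square)``).
* :func:`wilcoxon_rank_sum` checks that invasive aliens increased more
  in range (change index) than non-invasive aliens.

The GLM fits themselves use statsmodels (IRLS); this module owns the
candidate enumeration, averaging and bookkeeping around them.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

__all__ = [
    "trait_contrasts",
    "fit_binomial_glm",
    "enumerate_candidates",
    "model_average",
    "country_group_lm",
    "fit_nested_lmm",
    "wilcoxon_rank_sum",
    "GLMFit",
    "LMMResult",
    "ChangeIndexTest",
    "DESIGN_VARIABLES",
]

CONTINUOUS_TRAITS = [
    "ellenberg_L",
    "ellenberg_F",
    "ellenberg_N",
    "ellenberg_R",
    "ellenberg_S",
    "log_height",
]
CATEGORICAL_TRAITS = ["life_form", "clonal"]

#: candidate variables for the invasiveness model, in reporting order.
#: ``life_form`` is a factor block (reference-coded dummies) that enters
#: and leaves candidate models as a unit and counts as one variable.
DESIGN_VARIABLES = (
    ["pnnd", "alien_group"]
    + CONTINUOUS_TRAITS
    + ["clonal", "life_form"]
    + [f"d_{t}" for t in CONTINUOUS_TRAITS]
    + ["d_clonal", "d_life_form"]
)


def trait_contrasts(
    species: pd.DataFrame, country_records: pd.DataFrame
) -> pd.DataFrame:
    """Design matrix of absolute traits and nearest-native contrasts.

    Continuous differences are native minus alien (height on the log
    scale); categorical differences are 1 if the alien and its nearest
    native differ in class, else 0.  Aliens whose nearest native lacks
    trait data are excluded and counted in ``df.attrs['n_excluded']``.
    The sign convention is stamped into ``df.attrs['difference']``.
    """
    traits = species.set_index("species")
    rows = []
    n_excluded = 0
    for _, rec in country_records.iterrows():
        alien, native = rec["species"], rec["nearest_native"]
        if alien not in traits.index or native not in traits.index:
            n_excluded += 1
            continue
        a, nat = traits.loc[alien], traits.loc[native]
        cols = CONTINUOUS_TRAITS + CATEGORICAL_TRAITS
        if a[cols].isna().any() or nat[cols].isna().any():
            n_excluded += 1
            continue
        row = {
            "species": alien,
            "invasive": int(rec["invasive"]),
            "pnnd": float(rec["pnnd"]),
            "alien_group": a["alien_group"],
        }
        for t in CONTINUOUS_TRAITS:
            row[t] = float(a[t])
            row[f"d_{t}"] = float(nat[t]) - float(a[t])
        row["clonal"] = int(a["clonal"])
        row["d_clonal"] = int(a["clonal"] != nat["clonal"])
        row["life_form"] = str(a["life_form"])
        row["d_life_form"] = int(str(a["life_form"]) != str(nat["life_form"]))
        rows.append(row)
    out = pd.DataFrame(rows)
    out.attrs["difference"] = "native minus alien"
    out.attrs["n_excluded"] = n_excluded
    return out


def _expand_columns(design: pd.DataFrame, variables) -> tuple[np.ndarray, list[str]]:
    """Numeric design columns for a variable subset (intercept excluded).

    Categorical variables expand to reference-coded dummies; the most
    frequent class is the reference.
    """
    cols: list[np.ndarray] = []
    names: list[str] = []
    for v in variables:
        s = design[v]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            counts = s.value_counts()
            ref = counts.index[0]
            for lev in [l for l in counts.index if l != ref]:
                cols.append((s == lev).to_numpy(dtype=float))
                names.append(f"{v}[{lev}]")
        else:
            cols.append(s.to_numpy(dtype=float))
            names.append(v)
    X = (
        np.column_stack(cols)
        if cols
        else np.empty((len(design), 0))
    )
    return X, names


@dataclass
class GLMFit:
    variables: tuple
    names: list[str]  # expanded column names, intercept first
    coef: np.ndarray
    cov: np.ndarray
    llf: float
    aicc: float
    n: int
    k: int
    converged: bool
    separation: bool


def fit_binomial_glm(
    design: pd.DataFrame,
    variables,
    response: str = "invasive",
) -> GLMFit:
    """Maximum-likelihood logistic fit (IRLS) of invasiveness on a subset.

    ``AICc = -2 llf + 2k + 2k(k+1)/(n-k-1)``.  Diverging coefficients or
    a non-converged fit mark the model as separation-affected; such fits
    are excluded from model averaging by the caller.
    """
    y = design[response].to_numpy(dtype=float)
    if y.min() == y.max():
        raise ValueError("response must contain both classes")
    X, names = _expand_columns(design, variables)
    X = np.column_stack([np.ones(len(design)), X])
    names = ["intercept"] + names
    n, k = X.shape
    if np.linalg.matrix_rank(X) < k:
        raise ValueError("design is rank-deficient for this variable subset")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(y, X, family=sm.families.Binomial())
        res = model.fit(maxiter=100)
    coef = np.asarray(res.params)
    cov = np.asarray(res.cov_params())
    converged = bool(res.converged)
    separation = (not converged) or bool(np.any(np.abs(coef) > 20)) or bool(
        np.any(np.sqrt(np.diag(cov)) > 100)
    )
    llf = float(res.llf)
    aicc = -2 * llf + 2 * k + 2 * k * (k + 1) / (n - k - 1)
    return GLMFit(
        variables=tuple(variables),
        names=names,
        coef=coef,
        cov=cov,
        llf=llf,
        aicc=aicc,
        n=n,
        k=k,
        converged=converged,
        separation=separation,
    )


def enumerate_candidates(variables, max_size: int = 5) -> list[tuple]:
    """All variable subsets of size 0..max_size, in deterministic order.

    The intercept-only model is the empty tuple.  A categorical factor
    is a single variable here: its dummy block enters and leaves models
    as a unit.
    """
    if max_size < 1:
        raise ValueError("max_size must be >= 1")
    variables = list(variables)
    out: list[tuple] = []
    for size in range(0, min(max_size, len(variables)) + 1):
        out.extend(itertools.combinations(variables, size))
    return out


def model_average(
    fits: list[GLMFit],
    variables=None,
    ic: str = "aicc",
    mode: str = "full",
    z: float = 1.96,
) -> pd.DataFrame:
    """AICc model averaging over a candidate set (Burnham & Anderson).

    Akaike weights ``w_i = exp(-delta_i / 2) / sum`` from AICc
    differences.  With ``mode='full'`` a model that omits a variable
    contributes a zero coefficient with zero variance (Table-style full
    averaging); ``mode='conditional'`` averages only over models that
    contain the variable.  The unconditional SE is
    ``sqrt(sum_i w_i [var_i + (b_i - b_bar)^2])``; the 95% CI is
    ``b_bar +/- z * SE``; relative importance is the summed weight of
    models containing the variable.  Separation-affected fits are
    excluded with a warning.
    """
    ok = [f for f in fits if not f.separation]
    n_dropped = len(fits) - len(ok)
    if n_dropped:
        warnings.warn(
            f"{n_dropped} candidate fits excluded (separation or "
            "non-convergence)"
        )
    if not ok:
        raise ValueError("no successful fits to average")
    if mode not in ("full", "conditional"):
        raise ValueError("mode must be 'full' or 'conditional'")
    crit = np.array(
        [f.aicc if ic == "aicc" else -2 * f.llf + 2 * f.k for f in ok]
    )
    delta = crit - crit.min()
    w = np.exp(-delta / 2)
    w /= w.sum()

    if variables is None:
        seen: dict = {}
        for f in ok:
            for v in f.variables:
                seen.setdefault(v, None)
        variables = list(seen)
    # expanded coefficient names per variable
    name_map: dict[str, list[str]] = {}
    for f in ok:
        for nm in f.names[1:]:
            var = nm.split("[")[0]
            name_map.setdefault(var, [])
            if nm not in name_map[var]:
                name_map[var].append(nm)

    rows = []
    for var in variables:
        for nm in name_map.get(var, [var]):
            betas = np.zeros(len(ok))
            vars_ = np.zeros(len(ok))
            contains = np.zeros(len(ok), dtype=bool)
            for i, f in enumerate(ok):
                if var in f.variables and nm in f.names:
                    j = f.names.index(nm)
                    betas[i] = f.coef[j]
                    vars_[i] = f.cov[j, j]
                    contains[i] = True
            importance = float(w[contains].sum())
            if mode == "full":
                ww, bb, vv = w, betas, vars_
            else:
                if not contains.any():
                    continue
                ww = w[contains] / w[contains].sum()
                bb, vv = betas[contains], vars_[contains]
            b_bar = float(ww @ bb)
            se = float(np.sqrt(ww @ (vv + (bb - b_bar) ** 2)))
            rows.append(
                {
                    "variable": nm,
                    "coefficient": b_bar,
                    "adjusted_se": se,
                    "ci_lower": b_bar - z * se,
                    "ci_upper": b_bar + z * se,
                    "importance": importance,
                    "significant": bool(
                        (b_bar - z * se) * (b_bar + z * se) > 0
                    ),
                }
            )
    out = pd.DataFrame(rows)
    out.attrs["n_candidates"] = len(fits)
    out.attrs["n_averaged"] = len(ok)
    out.attrs["weights"] = w
    return out


def country_group_lm(country_records: pd.DataFrame) -> pd.DataFrame:
    """Two-group linear model of PNND and MPD at the country scale.

    Equivalent to a pooled-variance two-sample t-test of invasive vs
    non-invasive aliens; df = n1 + n2 - 2, two-sided p.
    """
    rows = []
    for response in ("pnnd", "mpd"):
        g1 = country_records.loc[
            country_records["invasive"] == 1, response
        ].to_numpy(dtype=float)
        g0 = country_records.loc[
            country_records["invasive"] == 0, response
        ].to_numpy(dtype=float)
        if g1.size < 2 or g0.size < 2:
            raise ValueError("each invasiveness group needs >= 2 species")
        t, p = stats.ttest_ind(g1, g0, equal_var=True)
        rows.append(
            {
                "response": response,
                "mean_invasive": float(g1.mean()),
                "mean_noninvasive": float(g0.mean()),
                "t": float(t),
                "df": int(g1.size + g0.size - 2),
                "p": float(p),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class LMMResult:
    """REML fit of ``value ~ invasiveness + (1 | species/square)``."""

    response: str
    mean_invasive: float
    se_invasive: float
    mean_noninvasive: float
    se_noninvasive: float
    var_species: float
    var_square_in_species: float
    var_residual: float
    loglike: float
    converged: bool
    n: int


def fit_nested_lmm(
    plot_records: pd.DataFrame, response: str = "pnnd"
) -> LMMResult:
    """Mixed model of plot-scale PNND or MPD with nested random effects.

    Fixed effect: invasiveness (cell-means coding, so the estimated
    per-group means and SEs are read off directly).  Random effects: a
    random intercept per species and a variance component for square
    nested within species.  Fit by REML (statsmodels MixedLM, lbfgs with
    default convergence tolerance); non-convergence is reported on the
    result, never silently replaced.
    """
    df = plot_records[["species", "square", "invasive", response]].copy()
    df = df.rename(columns={response: "value"})
    df["grp"] = df["invasive"].map({1: "invasive", 0: "noninvasive"})
    if df["grp"].nunique() < 2:
        raise ValueError("both invasiveness groups required")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM.from_formula(
            "value ~ 0 + C(grp)",
            groups="species",
            re_formula="1",
            vc_formula={"square": "0 + C(square)"},
            data=df,
        )
        res = model.fit(reml=True, method="lbfgs", maxiter=200)
    fe = res.fe_params
    se = res.bse_fe
    name_inv = [n for n in fe.index if "invasive]" in n and "noninvasive" not in n][0]
    name_non = [n for n in fe.index if "noninvasive]" in n][0]
    return LMMResult(
        response=response,
        mean_invasive=float(fe[name_inv]),
        se_invasive=float(se[name_inv]),
        mean_noninvasive=float(fe[name_non]),
        se_noninvasive=float(se[name_non]),
        var_species=float(res.cov_re.iloc[0, 0]),
        var_square_in_species=float(res.vcomp[0]),
        var_residual=float(res.scale),
        loglike=float(res.llf),
        converged=bool(res.converged),
        n=len(df),
    )


@dataclass
class ChangeIndexTest:
    W: float
    p: float
    n_invasive: int
    n_noninvasive: int
    method: str


def wilcoxon_rank_sum(
    x, y, alternative: str = "two-sided"
) -> ChangeIndexTest:
    """Wilcoxon rank-sum (Mann-Whitney) test with mid-rank ties.

    ``W`` is the Mann-Whitney U statistic of ``x``.  Exact enumeration
    when both samples are small (min n <= 8) and tie-free; otherwise the
    normal approximation with tie correction.
    """
    x = np.asarray(x, dtype=float)
    x = x[~np.isnan(x)]
    y = np.asarray(y, dtype=float)
    y = y[~np.isnan(y)]
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = (
        "exact" if (min(x.size, y.size) <= 8 and not ties) else "asymptotic"
    )
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method)
    return ChangeIndexTest(
        W=float(res.statistic),
        p=float(res.pvalue),
        n_invasive=int(x.size),
        n_noninvasive=int(y.size),
        method=method,
    )
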