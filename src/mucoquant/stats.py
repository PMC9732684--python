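"""Mixed-model inference on log-scale cell counts.

Cell counts per biopsy are right-skewed and come in dependent pairs
(two biopsy locations per subject), so group comparisons use a
random-intercept linear mixed model on natural-log measures:

    log(y_ij) = x_ij' beta + b_i + e_ij,
    b_i ~ N(0, sigma_b^2),  e_ij ~ N(0, sigma_e^2),

with diagnosis/activity group and colon location as fixed factors and the
subject as the random factor.  Estimation is REML via the profiled
likelihood over the single variance ratio lambda = sigma_b^2 / sigma_e^2
(one random intercept makes this a bounded 1-D optimisation).  Group
differences are reported back-transformed: fold change FC = exp(delta) with
a t-based 95% CI, where delta is the difference of estimated marginal means
on the log scale and the t degrees of freedom come from a
Satterthwaite-style approximation (normal quantile as fallback).  Pairwise
post hoc comparisons are least-significant-difference (LSD): unadjusted,
deliberately without multiplicity correction.

Supporting pieces: the Nancy activity dichotomy (grades 0-1 inactive, 2-4
active), the intraclass correlation sigma_b^2 / (sigma_b^2 + sigma_e^2),
Spearman rank correlation (blood vs mucosa ratios) and the tie-corrected
Kruskal-Wallis test (proximal vs distal counts).  Zero counts are handled
by a +0.5 offset before the log (configurable; +1 is the sensitivity
setting).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

__all__ = [
    "ModelSpec",
    "MixedModelResult",
    "SingularDesignError",
    "SchemaError",
    "dichotomize_nancy",
    "fit_lmm",
    "pairwise_contrasts",
    "icc",
    "spearman_corr",
    "kruskal_wallis",
    "run_study_analysis",
    "StudyResults",
    "validate_cohort",
]

_MEASURE_OF_COMPARTMENT = {
    "epithelium": "per_100_epithelial_cells",
    "subepithelial_band": "per_100_epithelial_cells",
    "lamina_propria": "per_mm2",
}


class SingularDesignError(ValueError):
    """The fixed-effect design matrix is rank deficient."""


class SchemaError(ValueError):
    """Cohort table violates the expected schema."""


class ConvergenceWarningFlag:
    pass


def dichotomize_nancy(grade: int) -> str:
    """Nancy histological grade -> activity class.

    Grades 0-1 (no neutrophils) are ``inactive``; grades 2-4 (neutrophils
    present) are ``active``.
    """
    g = int(grade)
    if g not in (0, 1, 2, 3, 4):
        raise ValueError(f"Nancy grade must be 0-4, got {grade}")
    return "inactive" if g <= 1 else "active"


# ---------------------------------------------------------------------------
# Design matrix
# ---------------------------------------------------------------------------

@dataclass
class ModelSpec:
    """What to fit: response column, fixed factors, covariates, grouping.

    ``response`` must be strictly positive after the offset when
    ``log_transform`` is on.  ``offset`` is added to the response before the
    natural log (zero-count handling; set to 0 when the response is already
    a log).
    """

    response: str
    fixed_factors: tuple[str, ...] = ()
    covariates: tuple[str, ...] = ()
    group_col: str = "subject_id"
    log_transform: bool = True
    offset: float = 0.5
    ci_level: float = 0.95

    def __post_init__(self) -> None:
        if not 0 < self.ci_level < 1:
            raise ValueError("CI level must be in (0, 1)")


def _encode_design(frame: pd.DataFrame, factor_levels: dict,
                   covariates: tuple[str, ...]) -> tuple[np.ndarray, list[str]]:
    """Treatment-coded design matrix with intercept; stable column order."""
    n = len(frame)
    cols = [np.ones(n)]
    names = ["Intercept"]
    for f, levels in factor_levels.items():
        vals = frame[f].to_numpy()
        for lev in levels[1:]:
            cols.append((vals == lev).astype(float))
            names.append(f"{f}[{lev}]")
    for c in covariates:
        cols.append(frame[c].to_numpy(dtype=float))
        names.append(c)
    return np.column_stack(cols), names


def _check_full_rank(x: np.ndarray, names: list[str]) -> None:
    rank = 0
    for j in range(x.shape[1]):
        new_rank = np.linalg.matrix_rank(x[:, : j + 1])
        if new_rank == rank:
            raise SingularDesignError(f"design column {names[j]!r} is aliased")
        rank = new_rank


# ---------------------------------------------------------------------------
# Profiled REML for the random-intercept model
# ---------------------------------------------------------------------------

def _group_sums(x: np.ndarray, y: np.ndarray, groups: np.ndarray):
    """Per-group row sums of X and y plus global cross-products."""
    uniq, idx = np.unique(groups, return_inverse=True)
    g = uniq.size
    p = x.shape[1]
    sx = np.zeros((g, p))
    sy = np.zeros(g)
    np.add.at(sx, idx, x)
    np.add.at(sy, idx, y)
    ni = np.bincount(idx, minlength=g).astype(float)
    return sx, sy, ni, x.T @ x, x.T @ y, float(y @ y)


def _gls_pieces(lam: float, sx, sy, ni, xtx, xty, yty):
    """A = X'V0^-1 X, b = X'V0^-1 y, q = y'V0^-1 y for V0 = I + lam*ZZ'."""
    w = lam / (1.0 + lam * ni)
    a = xtx - np.einsum("g,gj,gk->jk", w, sx, sx)
    b = xty - (w * sy) @ sx
    q = yty - float(w @ (sy * sy))
    return a, b, q


def _neg2_reml_profiled(lam: float, sx, sy, ni, xtx, xty, yty, n: int, p: int):
    a, b, q = _gls_pieces(lam, sx, sy, ni, xtx, xty, yty)
    sign, logdet_a = np.linalg.slogdet(a)
    if sign <= 0:
        return np.inf, None, None
    beta = np.linalg.solve(a, b)
    rss = max(q - 2 * b @ beta + beta @ a @ beta, 1e-300)
    sigma2 = rss / (n - p)
    val = ((n - p) * np.log(sigma2) + np.sum(np.log1p(lam * ni))
           + logdet_a + (n - p))
    return val, beta, sigma2


def _neg2_reml_full(theta: np.ndarray, sx, sy, ni, xtx, xty, yty, n: int):
    """Unprofiled -2 REML log-likelihood at (sigma_b^2, sigma_e^2)."""
    s2b, s2e = float(theta[0]), float(theta[1])
    if s2e <= 0 or s2b < 0:
        return np.inf
    lam = s2b / s2e
    a0, b0, q0 = _gls_pieces(lam, sx, sy, ni, xtx, xty, yty)
    sign, logdet_a0 = np.linalg.slogdet(a0)
    if sign <= 0:
        return np.inf
    p = a0.shape[0]
    beta = np.linalg.solve(a0, b0)
    rss = q0 - 2 * b0 @ beta + beta @ a0 @ beta
    # log|V| = (n - G) log s2e + sum log(s2e + ni s2b); here expressed via V0
    logdet_v = n * np.log(s2e) + np.sum(np.log1p(lam * ni))
    logdet_xvx = logdet_a0 - p * np.log(s2e)
    return logdet_v + logdet_xvx + rss / s2e


@dataclass
class MixedModelResult:
    """Fitted random-intercept model on the (log) scale.

    ``params``/``cov_params`` are the fixed effects; variance components are
    on the response (log) scale.  ``converged`` is False when the profiled
    REML optimiser did not bracket a finite optimum.
    """

    params: pd.Series
    cov_params: pd.DataFrame
    sigma2_subject: float
    sigma2_resid: float
    n_obs: int
    n_groups: int
    neg2_loglik_reml: float
    converged: bool
    resid_skewness: float
    ci_level: float
    factor_levels: dict
    covariates: tuple[str, ...]
    frame: pd.DataFrame = field(repr=False)
    _sums: tuple = field(repr=False, default=None)

    @property
    def icc(self) -> float:
        tot = self.sigma2_subject + self.sigma2_resid
        return 0.0 if tot <= 0 else self.sigma2_subject / tot

    def design_for(self, frame: pd.DataFrame) -> np.ndarray:
        x, _ = _encode_design(frame, self.factor_levels, self.covariates)
        return x


def fit_lmm(data: pd.DataFrame, spec: ModelSpec) -> MixedModelResult:
    """Fit the random-intercept model by profiled REML.

    Deterministic: the single variance ratio is found by bounded scalar
    minimisation (tolerance 1e-10) of the profiled -2 REML criterion, with
    the boundary lambda = 0 (no subject variance) checked explicitly.
    """
    needed = ([spec.response] + list(spec.fixed_factors)
              + list(spec.covariates) + [spec.group_col])
    missing = [c for c in needed if c not in data.columns]
    if missing:
        raise SchemaError(f"missing columns: {missing}")
    frame = data[needed].dropna().reset_index(drop=True)
    y = frame[spec.response].to_numpy(dtype=float)
    if spec.log_transform:
        shifted = y + spec.offset
        if np.any(shifted <= 0):
            raise ValueError("response must be strictly positive after offset")
        y = np.log(shifted)
    groups = frame[spec.group_col].to_numpy()
    if np.unique(groups).size < 2:
        raise ValueError("need at least two subjects")
    factor_levels = {f: sorted(pd.unique(frame[f]).tolist())
                     for f in spec.fixed_factors}
    x, names = _encode_design(frame, factor_levels, spec.covariates)
    _check_full_rank(x, names)
    n, p = x.shape
    sums = _group_sums(x, y, groups)
    sx, sy, ni, xtx, xty, yty = sums

    def objective(t: float) -> float:
        return _neg2_reml_profiled(np.exp(t), *sums, n, p)[0]

    val0, beta0, sig0 = _neg2_reml_profiled(0.0, *sums, n, p)
    res = optimize.minimize_scalar(objective, bounds=(np.log(1e-8), np.log(1e4)),
                                   method="bounded",
                                   options={"xatol": 1e-10})
    converged = bool(np.isfinite(val0))
    lam = 0.0
    best_val = val0
    if res.success and np.isfinite(res.fun) and res.fun < val0 - 1e-12:
        lam = float(np.exp(res.x))
        best_val = float(res.fun)
    val, beta, sigma2 = _neg2_reml_profiled(lam, *sums, n, p)
    if beta is None:
        raise SingularDesignError("GLS normal equations are singular")
    a, _, _ = _gls_pieces(lam, sx, sy, ni, xtx, xty, yty)
    cov_beta = sigma2 * np.linalg.inv(a)
    sigma2_subject = lam * sigma2

    # marginal residual skewness as a normality diagnostic
    resid = y - x @ beta
    skew = float(sps.skew(resid)) if n > 2 else 0.0

    return MixedModelResult(
        params=pd.Series(beta, index=names),
        cov_params=pd.DataFrame(cov_beta, index=names, columns=names),
        sigma2_subject=float(sigma2_subject),
        sigma2_resid=float(sigma2),
        n_obs=n,
        n_groups=int(np.unique(groups).size),
        neg2_loglik_reml=float(best_val),
        converged=converged,
        resid_skewness=skew,
        ci_level=spec.ci_level,
        factor_levels=factor_levels,
        covariates=tuple(spec.covariates),
        frame=frame,
        _sums=sums,
    )


# ---------------------------------------------------------------------------
# Contrasts on estimated marginal means
# ---------------------------------------------------------------------------

def _contrast_variance_at(theta: np.ndarray, c: np.ndarray, result: MixedModelResult
                          ) -> float:
    sx, sy, ni, xtx, xty, yty = result._sums
    s2b, s2e = float(theta[0]), float(theta[1])
    lam = 0.0 if s2e <= 0 else max(s2b, 0.0) / s2e
    a, _, _ = _gls_pieces(lam, sx, sy, ni, xtx, xty, yty)
    return float(s2e * c @ np.linalg.solve(a, c))


def _satterthwaite_df(result: MixedModelResult, c: np.ndarray) -> float:
    """Satterthwaite-style df for a contrast: 2*Vc^2 / Var(Vc), with the
    variance of the variance-component estimates from the numeric REML
    information matrix.  Falls back to the residual df n - p."""
    n = result.n_obs
    p = len(result.params)
    fallback = max(n - p, 1)
    theta = np.array([result.sigma2_subject, result.sigma2_resid])
    if theta[0] < 1e-12 * max(theta[1], 1e-300):
        return float(fallback)  # boundary: no subject variance -> OLS df
    sx, sy, ni, xtx, xty, yty = result._sums
    try:
        h = np.zeros((2, 2))
        step = np.maximum(1e-4 * theta, 1e-10)

        def f(t):
            return _neg2_reml_full(t, sx, sy, ni, xtx, xty, yty, n)

        f0 = f(theta)
        if not np.isfinite(f0):
            return float(fallback)
        for i in range(2):
            for j in range(i, 2):
                ei = np.eye(2)[i] * step[i]
                ej = np.eye(2)[j] * step[j]
                h[i, j] = h[j, i] = (
                    f(theta + ei + ej) - f(theta + ei - ej)
                    - f(theta - ei + ej) + f(theta - ei - ej)
                ) / (4 * step[i] * step[j])
        var_theta = 2.0 * np.linalg.inv(h)
        g = np.zeros(2)
        for i in range(2):
            ei = np.eye(2)[i] * step[i]
            g[i] = (_contrast_variance_at(theta + ei, c, result)
                    - _contrast_variance_at(theta - ei, c, result)) / (2 * step[i])
        vc = _contrast_variance_at(theta, c, result)
        denom = float(g @ var_theta @ g)
        if denom <= 0 or vc <= 0:
            return float(fallback)
        df = 2.0 * vc**2 / denom
        if not np.isfinite(df) or df < 1:
            return float(fallback)
        return float(min(df, 1e7))
    except np.linalg.LinAlgError:
        return float(fallback)


def _emm_vector(result: MixedModelResult, factor: str, level) -> np.ndarray:
    """L-vector of the estimated marginal mean: average design row over the
    observed covariate/factor distribution with ``factor`` forced to
    ``level`` (proportional weighting)."""
    if factor not in result.factor_levels:
        raise ValueError(f"{factor!r} is not a fitted factor")
    if level not in result.factor_levels[factor]:
        raise ValueError(f"unknown level {level!r} of factor {factor!r}")
    frame = result.frame.copy()
    frame[factor] = level
    return result.design_for(frame).mean(axis=0)


def pairwise_contrasts(result: MixedModelResult, factor: str,
                       pairs: list[tuple] | None = None) -> pd.DataFrame:
    """LSD pairwise comparisons of estimated marginal means on the log scale.

    Unadjusted p-values (least significant difference); fold change and CI
    are back-transformed: FC = exp(delta), CI = exp(delta +/- t_q * SE).
    """
    levels = result.factor_levels.get(factor)
    if levels is None:
        raise ValueError(f"{factor!r} is not a fitted factor")
    if pairs is None:
        pairs = list(itertools.combinations(levels, 2))
    beta = result.params.to_numpy()
    cov = result.cov_params.to_numpy()
    rows = []
    alpha = 1 - result.ci_level
    for a, b in pairs:
        c = _emm_vector(result, factor, a) - _emm_vector(result, factor, b)
        delta = float(c @ beta)
        se = float(np.sqrt(max(c @ cov @ c, 0.0)))
        df = _satterthwaite_df(result, c)
        if se == 0:
            tstat, pval, q = 0.0, 1.0, sps.norm.ppf(1 - alpha / 2)
        else:
            tstat = delta / se
            try:
                pval = float(2 * sps.t.sf(abs(tstat), df))
                q = float(sps.t.ppf(1 - alpha / 2, df))
            except Exception:
                pval = float(2 * sps.norm.sf(abs(tstat)))
                q = float(sps.norm.ppf(1 - alpha / 2))
        rows.append({
            "contrast": f"{a} vs {b}",
            "level_a": a, "level_b": b,
            "log_fc": delta, "se": se, "df": df, "t": tstat,
            "fc": float(np.exp(delta)),
            "ci_low": float(np.exp(delta - q * se)),
            "ci_high": float(np.exp(delta + q * se)),
            "p": pval,
        })
    return pd.DataFrame(rows)


def icc(result: MixedModelResult) -> float:
    """Intraclass correlation sigma_b^2 / (sigma_b^2 + sigma_e^2)."""
    return result.icc


def interaction_pvalue(data: pd.DataFrame, spec: ModelSpec,
                       factor_a: str, factor_b: str) -> float:
    """Wald chi-squared p-value for the a x b interaction block, from a fit
    with explicit product columns added as covariates."""
    frame = data.copy()
    la = sorted(pd.unique(frame[factor_a].dropna()))
    lb = sorted(pd.unique(frame[factor_b].dropna()))
    inter_cols = []
    for a in la[1:]:
        for b in lb[1:]:
            col = f"_ix_{a}_{b}"
            frame[col] = ((frame[factor_a] == a) & (frame[factor_b] == b)).astype(float)
            inter_cols.append(col)
    if not inter_cols:
        return float("nan")
    spec2 = ModelSpec(response=spec.response,
                      fixed_factors=spec.fixed_factors,
                      covariates=tuple(spec.covariates) + tuple(inter_cols),
                      group_col=spec.group_col,
                      log_transform=spec.log_transform, offset=spec.offset,
                      ci_level=spec.ci_level)
    try:
        res = fit_lmm(frame, spec2)
    except SingularDesignError:
        return float("nan")
    idx = [res.params.index.get_loc(c) for c in inter_cols]
    b = res.params.to_numpy()[idx]
    v = res.cov_params.to_numpy()[np.ix_(idx, idx)]
    try:
        w = float(b @ np.linalg.solve(v, b))
    except np.linalg.LinAlgError:
        return float("nan")
    return float(sps.chi2.sf(w, len(idx)))


# ---------------------------------------------------------------------------
# Rank statistics
# ---------------------------------------------------------------------------

def spearman_corr(x, y) -> tuple[float, float]:
    """Spearman rank correlation with mid-ranks for ties; two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired values")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def kruskal_wallis(groups: list) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-squared p (k-1 df)."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("groups must be non-empty")
    if all(np.all(a == arrays[0][0]) for a in arrays):
        return 0.0, 1.0  # all values identical: H = 0 by definition
    h, p = sps.kruskal(*arrays)
    return float(h), float(p)


# ---------------------------------------------------------------------------
# Whole-study analysis
# ---------------------------------------------------------------------------

_REQUIRED_COLUMNS = (
    "subject_id", "group", "diagnosis", "nancy_grade", "location",
    "stain", "compartment", "count", "epithelial_cells", "area_mm2",
)


def validate_cohort(df: pd.DataFrame) -> None:
    """Raise :class:`SchemaError` listing offending row numbers."""
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing columns: {missing}")
    problems = []
    bad = df.index[~df["nancy_grade"].isin([0, 1, 2, 3, 4])].tolist()
    if bad:
        problems.append(f"nancy_grade outside 0-4 at rows {bad[:10]}")
    bad = df.index[df["count"] < 0].tolist()
    if bad:
        problems.append(f"negative count at rows {bad[:10]}")
    bad = df.index[~df["stain"].isin(["CD3", "TCRdelta"])].tolist()
    if bad:
        problems.append(f"unknown stain at rows {bad[:10]}")
    known = set(_MEASURE_OF_COMPARTMENT)
    bad = df.index[~df["compartment"].isin(known)].tolist()
    if bad:
        problems.append(f"unknown compartment at rows {bad[:10]}")
    bad = df.index[(df["epithelial_cells"] <= 0) | (df["area_mm2"] <= 0)].tolist()
    if bad:
        problems.append(f"non-positive denominator at rows {bad[:10]}")
    if problems:
        raise SchemaError("; ".join(problems))


def _measure_column(df: pd.DataFrame, offset: float) -> pd.Series:
    """Normalised measure with the zero-count offset applied to the count."""
    shifted = df["count"].astype(float) + offset
    per100 = 100.0 * shifted / df["epithelial_cells"].astype(float)
    permm2 = shifted / df["area_mm2"].astype(float)
    return per100.where(df["compartment"] != "lamina_propria", permm2)


@dataclass
class StudyResults:
    """Bundle of every table the study analysis emits."""

    contrasts: pd.DataFrame
    variance_components: pd.DataFrame
    group_summaries: pd.DataFrame
    covariate_effects: pd.DataFrame
    adjusted_contrasts: pd.DataFrame
    interactions: pd.DataFrame
    spearman: pd.DataFrame
    kruskal: pd.DataFrame
    offset: float

    def report(self) -> str:
        lines = ["Compartmental T-cell study analysis",
                 "=" * 40,
                 f"log offset for zero counts: +{self.offset}",
                 "",
                 "Pairwise group fold changes (LSD, back-transformed):"]
        for _, r in self.contrasts.iterrows():
            star = " *" if r["p"] < 0.05 else ""
            lines.append(
                f"  {r['stain']:9s} {r['compartment']:18s} {r['contrast']:28s}"
                f" FC {r['fc']:.2f} (95% CI {r['ci_low']:.2f}-{r['ci_high']:.2f})"
                f" p={r['p']:.4f}{star}")
        lines.append("")
        lines.append("Variance components / ICC:")
        for _, r in self.variance_components.iterrows():
            lines.append(
                f"  {r['stain']:9s} {r['compartment']:18s}"
                f" sigma2_subject={r['sigma2_subject']:.4f}"
                f" sigma2_resid={r['sigma2_resid']:.4f} ICC={r['icc']:.3f}")
        if len(self.spearman):
            lines.append("")
            lines.append("Blood vs mucosa gamma-delta/CD3 ratio (Spearman):")
            for _, r in self.spearman.iterrows():
                lines.append(f"  {r['subset']:12s} {r['compartment']:18s}"
                             f" rho={r['rho']:.3f} p={r['p']:.3f} n={int(r['n'])}")
        if len(self.kruskal):
            lines.append("")
            lines.append("Proximal vs distal (Kruskal-Wallis, HC + inactive IBD):")
            for _, r in self.kruskal.iterrows():
                lines.append(f"  {r['stain']:9s} {r['compartment']:18s}"
                             f" H={r['H']:.3f} p={r['p']:.4f}")
        return "\n".join(lines)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.contrasts.to_csv(outdir / "contrasts.csv", index=False)
        self.variance_components.to_csv(outdir / "variance_components.csv", index=False)
        self.group_summaries.to_csv(outdir / "group_summaries.csv", index=False)
        self.covariate_effects.to_csv(outdir / "covariate_effects.csv", index=False)
        self.adjusted_contrasts.to_csv(outdir / "adjusted_contrasts.csv", index=False)
        self.interactions.to_csv(outdir / "interactions.csv", index=False)
        self.spearman.to_csv(outdir / "spearman_blood_mucosa.csv", index=False)
        self.kruskal.to_csv(outdir / "kruskal_location.csv", index=False)
        (outdir / "report.txt").write_text(self.report() + "\n")


def _fit_measure(sub: pd.DataFrame, covariates: tuple[str, ...] = ()
                 ) -> MixedModelResult:
    factors = ["group"]
    if sub["location"].nunique() > 1:
        factors.append("location")
    cat_covs = [c for c in covariates if c in ("gender",)]
    num_covs = [c for c in covariates if c not in cat_covs]
    spec = ModelSpec(response="log_measure", fixed_factors=tuple(factors + cat_covs),
                     covariates=tuple(num_covs), group_col="subject_id",
                     log_transform=False, offset=0.0)
    return fit_lmm(sub, spec)


def run_study_analysis(cohort: pd.DataFrame, offset: float = 0.5,
                       contrast_pairs: list[tuple] | None = None,
                       covariate_analyses: bool = True,
                       interaction_checks: bool = True) -> StudyResults:
    """Run the complete inference over a cohort count table.

    For every stain x compartment (plus the per-biopsy gamma-delta/CD3 ratio
    as a third 'stain') the random-intercept model is fitted on the log
    measure with group and location fixed and subject random; all pairwise
    group contrasts are emitted LSD-style with back-transformed FC and 95%
    CI.  Separate covariate-adjusted refits (oral steroids, age, gender,
    disease duration), group x location interaction checks, Spearman
    blood-mucosa correlations and proximal-vs-distal Kruskal-Wallis tests
    complete the bundle.
    """
    validate_cohort(cohort)
    df = cohort.copy()
    df["activity"] = [dichotomize_nancy(g) for g in df["nancy_grade"]]
    df["measure"] = _measure_column(df, offset)
    df["log_measure"] = np.log(df["measure"])

    # per-biopsy gamma-delta / CD3 ratio on matching normalised measures
    key = ["subject_id", "group", "location", "compartment"]
    piv = df.pivot_table(index=key, columns="stain", values="measure",
                         aggfunc="first").reset_index()
    extra = df.drop_duplicates(subset=["subject_id"])[
        ["subject_id", "age", "gender", "duration_months", "oral_steroids",
         "blood_gd_cd3_ratio"]] if "blood_gd_cd3_ratio" in df.columns else None
    ratio = None
    if {"CD3", "TCRdelta"}.issubset(piv.columns):
        piv = piv.dropna(subset=["CD3", "TCRdelta"])
        piv = piv[piv["CD3"] > 0]
        ratio = piv[key].copy()
        ratio["measure"] = 100.0 * piv["TCRdelta"] / piv["CD3"]
        ratio["log_measure"] = np.log(ratio["measure"])
        ratio["stain"] = "gd_cd3_ratio"
        if extra is not None:
            ratio = ratio.merge(extra, on="subject_id", how="left")

    units = []
    for (stain, comp), sub in df.groupby(["stain", "compartment"], sort=True):
        units.append((stain, comp, _MEASURE_OF_COMPARTMENT[comp], sub))
    if ratio is not None:
        for comp, sub in ratio.groupby("compartment", sort=True):
            units.append(("gd_cd3_ratio", comp, "percent", sub))

    contrasts_rows, vc_rows, summary_rows = [], [], []
    adj_rows, cov_rows, inter_rows = [], [], []
    covariate_sets = {"oral_steroids": ("oral_steroids",), "age": ("age",),
                      "gender": ("gender",), "duration_months": ("duration_months",)}
    for stain, comp, measure_name, sub in units:
        sub = sub.copy()
        if "oral_steroids" in sub.columns:
            sub["oral_steroids"] = sub["oral_steroids"].astype(float)
        res = _fit_measure(sub)
        table = pairwise_contrasts(res, "group", pairs=contrast_pairs)
        table.insert(0, "measure", measure_name)
        table.insert(0, "compartment", comp)
        table.insert(0, "stain", stain)
        contrasts_rows.append(table)
        vc_rows.append({
            "stain": stain, "compartment": comp,
            "sigma2_subject": res.sigma2_subject, "sigma2_resid": res.sigma2_resid,
            "icc": res.icc, "converged": res.converged,
            "resid_skewness": res.resid_skewness,
            "n_obs": res.n_obs, "n_subjects": res.n_groups})
        for level in res.factor_levels["group"]:
            l_vec = _emm_vector(res, "group", level)
            emm = float(l_vec @ res.params.to_numpy())
            grp = sub[sub["group"] == level]["measure"]
            summary_rows.append({
                "stain": stain, "compartment": comp, "group": level,
                "model_geometric_mean": float(np.exp(emm)),
                "sample_median": float(grp.median()), "n": int(len(grp))})
        if not interaction_checks:
            inter_p = float("nan")
        else:
            inter_p = (interaction_pvalue(
                sub, ModelSpec(response="log_measure",
                               fixed_factors=("group", "location"),
                               group_col="subject_id", log_transform=False,
                               offset=0.0),
                "group", "location")
                if sub["location"].nunique() > 1 else float("nan"))
        inter_rows.append({"stain": stain, "compartment": comp,
                           "interaction": "group x location", "p": inter_p})
        for cov_name, cols in (covariate_sets.items() if covariate_analyses else ()):
            if any(c not in sub.columns for c in cols):
                continue
            if sub[list(cols)].nunique().min() < 2:
                continue
            try:
                res_adj = _fit_measure(sub, covariates=cols)
            except (SingularDesignError, ValueError):
                continue
            adj = pairwise_contrasts(res_adj, "group", pairs=contrast_pairs)
            adj.insert(0, "covariate", cov_name)
            adj.insert(0, "compartment", comp)
            adj.insert(0, "stain", stain)
            adj_rows.append(adj)
            for pname in res_adj.params.index:
                base = pname.split("[")[0]
                if base in cols:
                    est = float(res_adj.params[pname])
                    se = float(np.sqrt(res_adj.cov_params.loc[pname, pname]))
                    dfree = max(res_adj.n_obs - len(res_adj.params), 1)
                    pv = (2 * sps.t.sf(abs(est / se), dfree)) if se > 0 else 1.0
                    cov_rows.append({
                        "stain": stain, "compartment": comp, "covariate": cov_name,
                        "term": pname, "log_effect": est, "fc_per_unit": float(np.exp(est)),
                        "se": se, "p": float(pv)})

    contrasts = pd.concat(contrasts_rows, ignore_index=True)
    adjusted = (pd.concat(adj_rows, ignore_index=True)
                if adj_rows else pd.DataFrame())

    # Spearman: blood vs mucosal gamma-delta/CD3 ratio, per compartment,
    # within healthy controls and the active-disease groups.
    spearman_rows = []
    if ratio is not None and "blood_gd_cd3_ratio" in ratio.columns:
        for subset in sorted(ratio["group"].unique()):
            part = ratio[ratio["group"] == subset]
            for comp, g in part.groupby("compartment"):
                per_subj = g.groupby("subject_id").agg(
                    mucosa=("measure", "mean"),
                    blood=("blood_gd_cd3_ratio", "first")).dropna()
                if len(per_subj) >= 3:
                    rho, p = spearman_corr(per_subj["blood"], per_subj["mucosa"])
                    spearman_rows.append({"subset": subset, "compartment": comp,
                                          "rho": rho, "p": p, "n": len(per_subj)})

    # Kruskal-Wallis proximal vs distal in HC + histologically inactive IBD
    kruskal_rows = []
    inactive = df[df["activity"] == "inactive"]
    for (stain, comp), sub in inactive.groupby(["stain", "compartment"]):
        grps = [g["measure"].to_numpy() for _, g in sub.groupby("location")]
        if len(grps) >= 2 and all(len(g) for g in grps):
            h, p = kruskal_wallis(grps)
            kruskal_rows.append({"stain": stain, "compartment": comp,
                                 "H": h, "p": p})

    return StudyResults(
        contrasts=contrasts,
        variance_components=pd.DataFrame(vc_rows),
        group_summaries=pd.DataFrame(summary_rows),
        covariate_effects=pd.DataFrame(cov_rows),
        adjusted_contrasts=adjusted,
        interactions=pd.DataFrame(inter_rows),
        spearman=pd.DataFrame(spearman_rows),
        kruskal=pd.DataFrame(kruskal_rows),
        offset=offset,
    )
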