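"""Mixed-model inference for the 2x2 within-subject design.

The central object is :class:`PupilLMM`, a linear mixed model with a random
participant intercept,

    y_ij = x_ij' beta + b_i + eps_ij,   b_i ~ N(0, tau^2),  eps_ij ~ N(0, sigma^2),

built from a long DataFrame with :meth:`PupilLMM.from_dataframe` under
treatment (0/1) coding — reference levels are single-sentence load, distractor
copresence and no previous-trial feedback, so each coefficient is the change
from its reference. :meth:`PupilLMM.fit` returns a :class:`PupilLMMResults`
carrying, per fixed-effect term, the estimate, Wald 95% CI, and an F-test on
Satterthwaite denominator degrees of freedom.

REML/ML estimation is delegated to :mod:`statsmodels` ``MixedLM``; the
Satterthwaite layer is computed here from the closed-form random-intercept
REML profile (Woodbury identities per participant) with finite-difference
derivatives, and reproduces lmerTest to ~1e-5 in the denominator df.

Also here: paired t-tests, Pearson correlations with their t-statistics, and
log-likelihood-ratio tests for adding a participant-level covariate (main
effect plus all interactions with the 2x2 factors, 4 df).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .datatypes import CorrelationResult, EffectEstimate, LRTResult

__all__ = [
    "PupilLMM",
    "PupilLMMResults",
    "fit_lmm_2x2",
    "fit_feedback_lmm",
    "paired_t",
    "pearson_corr",
    "lrt_add_covariate",
]

log = logging.getLogger("pupilvr")

FACTOR_CODES = {
    "load": {"single": 0.0, "dual": 1.0},
    "copresence": {"distractors": 0.0, "agents": 1.0},
    "prev_feedback": {"none": 0.0, "positive": 1.0},
}
# display names for terms built from factor columns
_TERM_NAMES = {"prev_feedback": "feedback"}


def _code(df: pd.DataFrame, col: str) -> np.ndarray:
    codes = FACTOR_CODES[col]
    vals = df[col]
    bad = set(vals.unique()) - set(codes)
    if bad:
        raise ValueError(f"unknown level(s) {sorted(bad)} in factor {col!r}")
    return vals.map(codes).to_numpy(dtype=float)


class _RandomInterceptProfile:
    """Closed-form REML/ML machinery for the single-random-intercept LMM.

    With V_i = sigma^2 I + tau^2 11', Woodbury gives per-group inverses from
    scalar weights, so X'V^-1X, X'V^-1y, y'V^-1y and log|V| cost O(G p^2) per
    evaluation regardless of sample size.
    """

    def __init__(self, X: np.ndarray, y: np.ndarray, group_idx: np.ndarray):
        self.n, self.p = X.shape
        G = int(group_idx.max()) + 1
        self.ng = np.bincount(group_idx, minlength=G).astype(float)
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)
        self.s1x = np.zeros((G, self.p))
        np.add.at(self.s1x, group_idx, X)
        self.s1y = np.bincount(group_idx, weights=y, minlength=G)

    def _blocks(self, theta):
        tau2, sig2 = theta
        w = tau2 / (sig2 + self.ng * tau2)
        XtVX = (self.XtX - (self.s1x * w[:, None]).T @ self.s1x) / sig2
        XtVy = (self.Xty - self.s1x.T @ (w * self.s1y)) / sig2
        ytVy = (self.yty - float(w @ self.s1y ** 2)) / sig2
        logdet = self.n * np.log(sig2) + float(np.sum(np.log1p(self.ng * tau2 / sig2)))
        return XtVX, XtVy, ytVy, logdet

    def beta_cov(self, theta):
        XtVX, XtVy, _, _ = self._blocks(theta)
        C = np.linalg.inv(XtVX)
        return C @ XtVy, C

    def reml_loglik(self, theta) -> float:
        XtVX, XtVy, ytVy, logdet = self._blocks(theta)
        beta = np.linalg.solve(XtVX, XtVy)
        quad = ytVy - float(beta @ XtVy)
        _, ld2 = np.linalg.slogdet(XtVX)
        return float(-0.5 * (logdet + ld2 + quad)
                     - 0.5 * (self.n - self.p) * np.log(2 * np.pi))

    def ml_loglik(self, theta) -> float:
        XtVX, XtVy, ytVy, logdet = self._blocks(theta)
        beta = np.linalg.solve(XtVX, XtVy)
        quad = ytVy - float(beta @ XtVy)
        return float(-0.5 * (logdet + quad) - 0.5 * self.n * np.log(2 * np.pi))

    def maximize(self, reml: bool, start: np.ndarray | None = None):
        """Own optimizer over log-variances; used when statsmodels falls over."""
        f = self.reml_loglik if reml else self.ml_loglik

        def objective(z):
            try:
                v = -f(np.exp(z))
            except np.linalg.LinAlgError:
                return 1e300
            return v if np.isfinite(v) else 1e300

        vy = max(self.yty / self.n, 1e-12)
        x0 = np.log(start if start is not None else np.array([vy / 2, vy / 2]))
        res = optimize.minimize(objective, x0, method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12,
                                         "maxiter": 2000})
        return np.exp(res.x)

    def reml_info_inv(self, theta) -> np.ndarray | None:
        """Asymptotic covariance of (tau^2, sigma^2): inverse of the observed
        REML information, by central-difference Hessian."""
        theta = np.asarray(theta, dtype=float)
        h = 1e-4 * theta + 1e-10
        H = np.zeros((2, 2))
        for k in range(2):
            for m in range(k, 2):
                ek = np.zeros(2); ek[k] = h[k]
                em = np.zeros(2); em[m] = h[m]
                H[k, m] = H[m, k] = (
                    self.reml_loglik(theta + ek + em)
                    - self.reml_loglik(theta + ek - em)
                    - self.reml_loglik(theta - ek + em)
                    + self.reml_loglik(theta - ek - em)) / (4 * h[k] * h[m])
        try:
            A = np.linalg.inv(-H)
        except np.linalg.LinAlgError:
            return None
        return A if np.all(np.isfinite(A)) else None

    def satterthwaite_df(self, theta, j: int, A: np.ndarray | None = None) -> float:
        """Denominator df for coefficient ``j``: 2 v^2 / (g' A g) with
        v = Var(beta_j), g its gradient in (tau^2, sigma^2), and A the inverse
        observed REML information of the variance components."""
        theta = np.asarray(theta, dtype=float)
        if A is None:
            A = self.reml_info_inv(theta)
        h = 1e-4 * theta + 1e-10

        def vfun(t):
            return self.beta_cov(t)[1][j, j]

        g = np.zeros(2)
        for k in range(2):
            e = np.zeros(2)
            e[k] = h[k]
            g[k] = (vfun(theta + e) - vfun(theta - e)) / (2 * h[k])
        denom = float(g @ A @ g) if A is not None else -1.0
        v = vfun(theta)
        if denom <= 0 or not np.isfinite(denom):
            return float(self.n - self.p)  # residual-df fallback
        return float(np.clip(2 * v ** 2 / denom, 1.0, 10 * self.n))


@dataclass
class PupilLMMResults:
    """Fitted-model results: per-term estimates, CIs and Satterthwaite F-tests."""

    term_names: list
    params: np.ndarray
    cov_params: np.ndarray
    tau2: float
    sigma2: float
    llf: float
    reml: bool
    n_obs: int
    n_groups: int
    df_method: str
    singular: bool = False
    estimates: list = field(default_factory=list)

    def __getitem__(self, term: str) -> EffectEstimate:
        for e in self.estimates:
            if e.term == term:
                return e
        raise KeyError(term)

    @property
    def estimates_frame(self) -> pd.DataFrame:
        rows = [(e.term, e.estimate, e.ci_low, e.ci_high, e.se,
                 e.F, e.df_num, e.df_den, e.p) for e in self.estimates]
        return pd.DataFrame(rows, columns=["term", "estimate", "ci_low", "ci_high",
                                           "se", "F", "df_num", "df_den", "p"])

    def summary(self) -> str:
        head = (f"Random-intercept LMM ({'REML' if self.reml else 'ML'}), "
                f"{self.n_obs} obs / {self.n_groups} participants\n"
                f"participant var {self.tau2:.4g}, residual var {self.sigma2:.4g}, "
                f"loglik {self.llf:.3f}"
                + ("  [singular: pooled OLS fallback]" if self.singular else "")
                + "\n")
        tbl = self.estimates_frame.to_string(
            index=False, float_format=lambda v: f"{v: .4f}")
        return head + tbl


class PupilLMM:
    """Linear mixed model with random participant intercepts, treatment coding.

    Parameters
    ----------
    endog : outcome vector.
    exog : design matrix including intercept column.
    groups : participant labels, one per row.
    term_names : one name per design column.
    """

    def __init__(self, endog, exog, groups, term_names):
        self.y = np.asarray(endog, dtype=float)
        self.X = np.asarray(exog, dtype=float)
        self.term_names = list(term_names)
        labels, self.group_idx = np.unique(np.asarray(groups), return_inverse=True)
        self.n_groups = labels.size
        if self.n_groups < 2:
            raise ValueError("need >= 2 participants")
        if self.X.shape[0] != self.y.size:
            raise ValueError("endog/exog length mismatch")
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("design matrix is rank deficient "
                             "(a term has no variation in these data)")
        self._profile = _RandomInterceptProfile(self.X, self.y, self.group_idx)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, outcome: str,
                       factors: tuple = ("load", "copresence"),
                       group: str = "participant_id",
                       covariate: str | None = None) -> "PupilLMM":
        """Build the 2x2 (+ optional covariate) design from long-format rows.

        The design is intercept, the two 0/1-coded factors and their product;
        with ``covariate`` the covariate main effect and its interactions with
        factor 1, factor 2 and their product are appended (4 extra columns).
        """
        f1, f2 = factors
        a = _code(df, f1)
        b = _code(df, f2)
        n1 = _TERM_NAMES.get(f1, f1)
        n2 = _TERM_NAMES.get(f2, f2)
        cols = [np.ones(len(df)), a, b, a * b]
        names = ["intercept", n1, n2, f"{n1}:{n2}"]
        if covariate is not None:
            z = df[covariate].to_numpy(dtype=float)
            per_group = df.groupby(group)[covariate].nunique()
            if (per_group > 1).any():
                raise ValueError(f"covariate {covariate!r} varies within participant")
            cols += [z, z * a, z * b, z * a * b]
            names += [covariate, f"{covariate}:{n1}", f"{covariate}:{n2}",
                      f"{covariate}:{n1}:{n2}"]
        return cls(df[outcome], np.column_stack(cols), df[group], names)

    # -- fitting -----------------------------------------------------------

    def fit(self, reml: bool = True,
            df_method: str = "satterthwaite") -> PupilLMMResults:
        """Fit by REML (reported estimates/CIs) or full ML (for LRTs).

        ``df_method``: "satterthwaite" (default) or "residual" (n - p; cheap,
        used inside large simulation loops where only estimates matter).
        A singular fit (participant variance estimated at zero) falls back to
        pooled ordinary least squares with a logged warning.
        """
        var_y = float(np.var(self.y))
        beta_ols, _, _, _ = np.linalg.lstsq(self.X, self.y, rcond=None)
        resid_var = float(np.var(self.y - self.X @ beta_ols))
        if var_y < 1e-14 or resid_var < 1e-12 * max(var_y, 1.0):
            return self._fit_degenerate()
        theta = self._estimate_theta(reml)
        if theta is None or theta[0] <= 1e-8 * var_y:
            return self._fit_pooled_ols(reml)
        beta, C = self._profile.beta_cov(theta)
        llf = (self._profile.reml_loglik(theta) if reml
               else self._profile.ml_loglik(theta))
        res = PupilLMMResults(
            term_names=self.term_names, params=beta, cov_params=C,
            tau2=float(theta[0]), sigma2=float(theta[1]), llf=llf, reml=reml,
            n_obs=self._profile.n, n_groups=self.n_groups, df_method=df_method)
        A = (self._profile.reml_info_inv(theta)
             if df_method == "satterthwaite" else None)
        for j, name in enumerate(self.term_names):
            se = float(np.sqrt(C[j, j]))
            if df_method == "satterthwaite":
                ddf = self._profile.satterthwaite_df(theta, j, A)
            else:
                ddf = float(self._profile.n - self._profile.p)
            F = float(beta[j] ** 2 / C[j, j])
            res.estimates.append(EffectEstimate(
                term=name, estimate=float(beta[j]),
                ci_low=float(beta[j] - 1.96 * se),
                ci_high=float(beta[j] + 1.96 * se), se=se,
                F=F, df_num=1, df_den=ddf, p=float(stats.f.sf(F, 1, ddf))))
        return res

    def _estimate_theta(self, reml: bool):
        import statsmodels.api as sm
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m = sm.MixedLM(self.y, self.X, groups=self.group_idx)
                r = m.fit(reml=reml, method="lbfgs")
            theta = np.array([float(np.asarray(r.cov_re)[0, 0]), float(r.scale)])
            if np.all(np.isfinite(theta)) and theta[1] > 0:
                if not getattr(r, "converged", True) and theta[0] > 1e-10:
                    # polish rare near-boundary non-convergence with the
                    # closed-form profile
                    theta = self._profile.maximize(reml, start=theta)
                return theta
        except Exception:  # pragma: no cover - statsmodels failure path
            pass
        return self._profile.maximize(reml)

    def _fit_pooled_ols(self, reml: bool) -> PupilLMMResults:
        log.warning("singular fit (zero participant variance); "
                    "falling back to pooled OLS")
        n, p = self.X.shape
        beta, _, _, _ = np.linalg.lstsq(self.X, self.y, rcond=None)
        resid = self.y - self.X @ beta
        dfres = n - p
        s2 = float(resid @ resid / dfres)
        C = s2 * np.linalg.inv(self.X.T @ self.X)
        llf = float(-0.5 * n * (np.log(2 * np.pi * max(s2, 1e-300)) + 1))
        res = PupilLMMResults(
            term_names=self.term_names, params=beta, cov_params=C,
            tau2=0.0, sigma2=s2, llf=llf, reml=reml, n_obs=n,
            n_groups=self.n_groups, df_method="residual", singular=True)
        for j, name in enumerate(self.term_names):
            se = float(np.sqrt(C[j, j]))
            F = float(beta[j] ** 2 / C[j, j]) if se > 0 else np.inf
            res.estimates.append(EffectEstimate(
                term=name, estimate=float(beta[j]),
                ci_low=float(beta[j] - 1.96 * se),
                ci_high=float(beta[j] + 1.96 * se), se=se, F=F, df_num=1,
                df_den=float(dfres), p=float(stats.f.sf(F, 1, dfres))))
        return res

    def _fit_degenerate(self) -> PupilLMMResults:
        # zero-variance outcome: estimates are exact, tests are vacuous
        beta, _, _, _ = np.linalg.lstsq(self.X, self.y, rcond=None)
        res = PupilLMMResults(
            term_names=self.term_names, params=beta,
            cov_params=np.zeros((len(beta), len(beta))), tau2=0.0, sigma2=0.0,
            llf=np.inf, reml=True, n_obs=self._profile.n,
            n_groups=self.n_groups, df_method="degenerate", singular=True)
        for j, name in enumerate(self.term_names):
            est = float(beta[j])
            nonzero = abs(est) > 1e-10
            res.estimates.append(EffectEstimate(
                term=name, estimate=est, ci_low=est, ci_high=est, se=0.0,
                F=np.inf if nonzero else 0.0, df_num=1,
                df_den=float(self._profile.n - self._profile.p),
                p=0.0 if nonzero else 1.0))
        return res


# -- convenience wrappers ----------------------------------------------------

def fit_lmm_2x2(df: pd.DataFrame, outcome: str = "value",
                df_method: str = "satterthwaite") -> PupilLMMResults:
    """Fit the 2x2 task-load x copresence model with random participant
    intercepts to long rows (participant_id, load, copresence, outcome)."""
    return PupilLMM.from_dataframe(df, outcome).fit(df_method=df_method)


def fit_feedback_lmm(df: pd.DataFrame, outcome: str = "value",
                     df_method: str = "satterthwaite") -> PupilLMMResults:
    """Fit the task-load x previous-trial-feedback model (levels: none,
    positive) to the re-binned outcome rows."""
    for level in ("none", "positive"):
        n_with = df.loc[df["prev_feedback"] == level, "participant_id"].nunique()
        if n_with < 2:
            raise ValueError(
                f"feedback level {level!r} present for {n_with} participants; "
                "need >= 2 for estimability")
    return PupilLMM.from_dataframe(
        df, outcome, factors=("load", "prev_feedback")).fit(df_method=df_method)


def paired_t(x, y) -> tuple[float, int, float]:
    """Classic paired-samples t-test; incomplete pairs are dropped.

    Returns (t, df, p); a zero-variance difference with nonzero mean reports
    an infinite t with p = 0."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired_t requires equal-length inputs")
    ok = np.isfinite(x) & np.isfinite(y)
    d = x[ok] - y[ok]
    n = d.size
    if n < 2:
        raise ValueError("need >= 2 complete pairs")
    df = n - 1
    sd = float(d.std(ddof=1))
    mean = float(d.mean())
    if sd == 0.0:
        if mean == 0.0:
            return 0.0, df, 1.0
        return float(np.sign(mean) * np.inf), df, 0.0
    t = mean / (sd / np.sqrt(n))
    return float(t), df, float(2 * stats.t.sf(abs(t), df))


def pearson_corr(x, y) -> CorrelationResult:
    """Pearson correlation with t = r sqrt(df / (1 - r^2)), df = n - 2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need >= 3 complete pairs")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined for zero-variance input")
    r, _ = stats.pearsonr(x, y)
    df = x.size - 2
    if abs(r) >= 1.0:
        return CorrelationResult(r=float(np.sign(r)), t=float(np.sign(r) * np.inf),
                                 df=df, p=0.0)
    t = r * np.sqrt(df / (1 - r * r))
    return CorrelationResult(r=float(r), t=float(t), df=df,
                             p=float(2 * stats.t.sf(abs(t), df)))


def lrt_add_covariate(df: pd.DataFrame, outcome: str, covariate: str,
                      factors: tuple = ("load", "copresence")) -> LRTResult:
    """Log-likelihood-ratio test for adding a participant-level covariate.

    Both models are refitted by full (not restricted) maximum likelihood on
    identical rows; the covariate enters as a main effect plus interactions
    with both factors and their product, so the test has 4 df.
    """
    rows = df.dropna(subset=[outcome, covariate])
    base = PupilLMM.from_dataframe(rows, outcome, factors=factors).fit(reml=False)
    full = PupilLMM.from_dataframe(rows, outcome, factors=factors,
                                   covariate=covariate).fit(reml=False)
    k = len(full.term_names) - len(base.term_names)
    if k <= 0 or not set(base.term_names) <= set(full.term_names):
        raise ValueError("models are not nested")
    chi2 = max(0.0, 2.0 * (full.llf - base.llf))
    return LRTResult(chi_square=chi2, df=k, p=float(stats.chi2.sf(chi2, k)))
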