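"""Beta-response mixed-effects modelling of epoch-level coherence.

Epoch-level wavelet-coherence values lie in (0, 1), so they are modelled
with a logit-link beta regression

    y_ij ~ Beta(mu_ij * phi, (1 - mu_ij) * phi),
    logit(mu_ij) = x_ij' beta + z_ij' b_i,      b_i ~ N(0, diag(sigma^2)),

with a random intercept per dyad and *uncorrelated* random slopes for each
fixed effect added along the model ladder (the "||" convention).  The
marginal likelihood integrates the dyad-level effects out by a Laplace
approximation (adaptive Gauss-Hermite quadrature for intercept-only random
structures); models are estimated by maximum likelihood and compared with
likelihood-ratio tests, mirroring the Models 1-7 ladder: turn-taking, time,
their interaction, then turn duration, relevance, intrusiveness and
contingency each added to the interaction model.

Interaction effects are followed up with marginal link-scale trends of the
focal predictor at early (epochs 1-4) vs late (epochs 5-8) time, or at
median-split groups of the moderator, with delta-method standard errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, gammaln, digamma, polygamma
from scipy.stats import chi2 as chi2_dist

from dyadsync.behavior import DyadScores
from dyadsync.coherence import CoherenceTable
from dyadsync.montage_io import ValidationError
from dyadsync.surrogates import SurrogateSet

PREDICTORS = ("turn_taking", "relevance", "contingency", "intrusiveness",
              "turn_duration")

_ETA_CLIP = 30.0
_MU_EPS = 1e-9


# ---------------------------------------------------------------------------
# Model frame
# ---------------------------------------------------------------------------

def compress_boundary(y: np.ndarray, n: int | None = None) -> np.ndarray:
    """Pull exact 0/1 responses inside (0,1): y <- (y*(n-1) + 0.5) / n.

    Applied only to boundary values; interior values are untouched.
    """
    y = np.asarray(y, dtype=float)
    n = len(y) if n is None else n
    squeezed = (y * (n - 1) + 0.5) / n
    return np.where((y <= 0.0) | (y >= 1.0), squeezed, y)


def zscore(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=0)
    if sd == 0:
        raise ValidationError("cannot z-standardize a constant predictor")
    return (x - x.mean()) / sd


def build_model_frame(coherence_tables: list[CoherenceTable],
                      scores: list[DyadScores],
                      roi: str | None = None) -> pd.DataFrame:
    """Join epoch-level coherence to dyad-level conversation scores.

    Returns one row per (dyad, channel, epoch) with the response ``wtc``
    (boundary-compressed into the open interval) and z-standardized
    predictors ``turn_taking_z``, ``relevance_z``, ``contingency_z``,
    ``intrusiveness_z``, ``turn_duration_z`` and ``time_z`` (epoch index).
    Missing coherence cells are dropped (count reported via attrs).
    """
    score_map = {s.dyad_id: s for s in scores}
    parts = []
    for tab in coherence_tables:
        if tab.dyad_id not in score_map:
            continue
        df = tab.to_frame()
        s = score_map[tab.dyad_id]
        df["turn_taking"] = s.turn_taking
        df["relevance"] = s.relevance
        df["contingency"] = s.contingency
        df["intrusiveness"] = s.intrusiveness
        df["turn_duration"] = s.mean_turn_duration_ms
        parts.append(df)
    if not parts:
        raise ValidationError("no coherence table matches any dyad score")
    frame = pd.concat(parts, ignore_index=True)
    if roi is not None:
        frame = frame[frame["roi"] == roi].reset_index(drop=True)
    n_total = len(frame)
    frame = frame.dropna(subset=["wtc"]).reset_index(drop=True)
    if frame.empty:
        raise ValidationError("all coherence values missing after join")
    frame["wtc"] = compress_boundary(frame["wtc"].to_numpy())
    frame["time_z"] = zscore(frame["epoch"].to_numpy())
    for col in PREDICTORS:
        frame[f"{col}_z"] = zscore(frame[col].to_numpy())
    frame.attrs["n_dropped_missing"] = n_total - len(frame)
    return frame


# ---------------------------------------------------------------------------
# Beta mixed model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FormulaSpec:
    """Fixed and (uncorrelated, dyad-level) random-slope terms.

    Terms are frame column names; ``a:b`` denotes a product interaction.
    The fixed intercept and the random intercept are always included.
    """

    fixed: tuple[str, ...] = ()
    random: tuple[str, ...] = ()
    group: str = "dyad_id"

    def with_term(self, term: str, slope: bool = True) -> "FormulaSpec":
        return FormulaSpec(fixed=self.fixed + (term,),
                           random=self.random + ((term,) if slope else ()),
                           group=self.group)

    @property
    def n_params(self) -> int:
        # intercept + fixed + phi + random intercept var + slope vars
        return 1 + len(self.fixed) + 1 + 1 + len(self.random)


def _term_column(frame: pd.DataFrame, term: str) -> np.ndarray:
    cols = term.split(":")
    missing = [c for c in cols if c not in frame.columns]
    if missing:
        raise KeyError(f"model frame lacks column(s) {missing} for term {term!r}")
    out = np.ones(len(frame))
    for c in cols:
        out = out * frame[c].to_numpy(dtype=float)
    return out


def _design(frame: pd.DataFrame, formula: FormulaSpec):
    x_cols = [np.ones(len(frame))] + [_term_column(frame, t)
                                      for t in formula.fixed]
    x = np.column_stack(x_cols)
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        raise ValidationError(
            f"design matrix rank-deficient: terms {('intercept',) + formula.fixed}")
    z = np.column_stack([np.ones(len(frame))]
                        + [_term_column(frame, t) for t in formula.random])
    codes, groups = pd.factorize(frame[formula.group].to_numpy())
    return (x, ("intercept",) + formula.fixed, z,
            ("intercept",) + formula.random, codes, list(groups))


@dataclass
class BetaMixedFit:
    """Maximum-likelihood fit of the beta mixed model."""

    formula: FormulaSpec
    fixed_names: tuple[str, ...]
    beta: np.ndarray
    se: np.ndarray | None
    vcov: np.ndarray | None
    phi: float
    sigma: dict[str, float]
    loglik: float
    n_obs: int
    n_groups: int
    n_params: int
    converged: bool
    method: str
    frame: pd.DataFrame | None = field(default=None, repr=False)

    def coef(self, name: str) -> float:
        return float(self.beta[self.fixed_names.index(name)])

    def coef_se(self, name: str) -> float:
        if self.se is None:
            raise ValidationError("fit was computed without standard errors")
        return float(self.se[self.fixed_names.index(name)])

    def coef_table(self) -> pd.DataFrame:
        se = self.se if self.se is not None else np.full_like(self.beta, np.nan)
        return pd.DataFrame({
            "term": self.fixed_names, "estimate": self.beta, "se": se,
            "ci_low": self.beta - 1.959964 * se,
            "ci_high": self.beta + 1.959964 * se})


class _BetaMixedProblem:
    """Batched Laplace/AGQ marginal likelihood for diagonal random effects."""

    def __init__(self, y, x, z, codes):
        self.y = np.asarray(y, float)
        if np.any(self.y <= 0) or np.any(self.y >= 1):
            raise ValidationError("response must lie strictly inside (0, 1)")
        self.x = x
        self.z = z
        self.codes = codes
        self.G = codes.max() + 1
        self.p = x.shape[1]
        self.q = z.shape[1]
        self.ystar = np.log(self.y) - np.log1p(-self.y)
        self.logy = np.log(self.y)
        self.log1my = np.log1p(-self.y)
        self._warm = np.zeros((self.G, self.q))

    # -- per-row beta log-density pieces ------------------------------------
    def _row_terms(self, eta, phi):
        mu = expit(np.clip(eta, -_ETA_CLIP, _ETA_CLIP))
        mu = np.clip(mu, _MU_EPS, 1 - _MU_EPS)
        a = mu * phi
        b = (1 - mu) * phi
        ll = (gammaln(phi) - gammaln(a) - gammaln(b)
              + (a - 1) * self.logy + (b - 1) * self.log1my)
        mustar = digamma(a) - digamma(b)
        dmu = mu * (1 - mu)
        g = phi * (self.ystar - mustar) * dmu
        w_fisher = phi * phi * (polygamma(1, a) + polygamma(1, b)) * dmu * dmu
        w_obs = w_fisher - phi * (self.ystar - mustar) * dmu * (1 - 2 * mu)
        w = np.where(w_obs > 1e-12, w_obs, w_fisher)
        return ll, g, w

    def _group_sum(self, v):
        return np.bincount(self.codes, weights=v, minlength=self.G)

    def _joint_parts(self, b, eta0, phi, sigma2):
        eta = eta0 + np.einsum("nq,nq->n", self.z, b[self.codes])
        ll, g, w = self._row_terms(eta, phi)
        ll_g = self._group_sum(ll)
        prior = -0.5 * (b * b / sigma2).sum(axis=1)
        return ll_g + prior, g, w

    def _grad_hess(self, b, g, w, sigma2):
        q = self.q
        grad = np.empty((self.G, q))
        hess = np.empty((self.G, q, q))
        for k in range(q):
            grad[:, k] = self._group_sum(g * self.z[:, k]) - b[:, k] / sigma2[k]
            for l in range(k, q):
                hkl = self._group_sum(w * self.z[:, k] * self.z[:, l])
                hess[:, k, l] = hkl
                hess[:, l, k] = hkl
        hess[:, np.arange(q), np.arange(q)] += 1.0 / sigma2
        return grad, hess

    def _inner_newton(self, eta0, phi, sigma2, max_iter=60, tol=1e-9):
        b = self._warm.copy()
        obj, g, w = self._joint_parts(b, eta0, phi, sigma2)
        for _ in range(max_iter):
            grad, hess = self._grad_hess(b, g, w, sigma2)
            if np.abs(grad).max() < tol:
                break
            try:
                delta = np.linalg.solve(hess, grad[..., None])[..., 0]
            except np.linalg.LinAlgError:
                delta = grad / hess[:, np.arange(self.q), np.arange(self.q)]
            step = np.ones(self.G)
            for _half in range(20):
                b_try = b + step[:, None] * delta
                obj_try, g_try, w_try = self._joint_parts(b_try, eta0, phi,
                                                          sigma2)
                worse = obj_try < obj - 1e-10
                if not worse.any():
                    break
                step[worse] *= 0.5
            improved = obj_try >= obj - 1e-10
            if not improved.any():
                break
            if improved.all():
                b, obj, g, w = b_try, obj_try, g_try, w_try
            else:
                b = np.where(improved[:, None], b_try, b)
                obj, g, w = self._joint_parts(b, eta0, phi, sigma2)
        _, hess = self._grad_hess(b, g, w, sigma2)
        self._warm = b
        return b, hess

    def nll(self, theta, method="laplace", agq_points=15):
        beta = theta[:self.p]
        phi = np.exp(theta[self.p])
        sigma = np.exp(theta[self.p + 1:])
        sigma2 = sigma ** 2
        eta0 = self.x @ beta
        b_hat, hess = self._inner_newton(eta0, phi, sigma2)
        obj, _, _ = self._joint_parts(b_hat, eta0, phi, sigma2)
        # joint density includes the normal prior normalisation
        obj = obj - np.log(sigma).sum() - 0.5 * self.q * np.log(2 * np.pi)
        sign, logdet = np.linalg.slogdet(hess)
        if np.any(sign <= 0):
            return 1e10
        if method == "laplace" or self.q != 1:
            ll = obj + 0.5 * self.q * np.log(2 * np.pi) - 0.5 * logdet
            return -ll.sum()
        # adaptive Gauss-Hermite, q == 1
        nodes, weights = np.polynomial.hermite.hermgauss(agq_points)
        sig_star = 1.0 / np.sqrt(hess[:, 0, 0])
        terms = np.empty((self.G, agq_points))
        for j, (xj, wj) in enumerate(zip(nodes, weights)):
            bj = b_hat + (np.sqrt(2.0) * sig_star * xj)[:, None]
            obj_j, _, _ = self._joint_parts(bj, eta0, phi, sigma2)
            obj_j = obj_j - np.log(sigma).sum() - 0.5 * np.log(2 * np.pi)
            terms[:, j] = np.log(wj) + xj * xj + obj_j
        m = terms.max(axis=1)
        ll = m + np.log(np.exp(terms - m[:, None]).sum(axis=1)) \
            + np.log(np.sqrt(2.0) * sig_star)
        return -ll.sum()


def _start_values(y, x, q):
    ystar = np.log(y) - np.log1p(-y)
    beta0, *_ = np.linalg.lstsq(x, ystar, rcond=None)
    mu = expit(np.clip(x @ beta0, -_ETA_CLIP, _ETA_CLIP))
    resid_var = np.var(y - mu)
    phi0 = np.clip(np.mean(mu * (1 - mu)) / max(resid_var, 1e-6) - 1, 2.0, 300.0)
    return beta0, np.log(phi0)


def fit_beta_mixed(frame: pd.DataFrame, formula: FormulaSpec,
                   method: str = "auto", compute_se: bool = True,
                   response: str = "wtc", starts: int = 2) -> BetaMixedFit:
    """Fit the logit-link beta mixed model by maximum likelihood.

    ``method``: "laplace", "agq" (adaptive Gauss-Hermite; random intercept
    only) or "auto" (AGQ when the only random effect is the intercept,
    Laplace otherwise).  Standard errors come from the numerically
    differentiated observed information of the marginal likelihood.
    """
    x, fixed_names, z, random_names, codes, _ = _design(frame, formula)
    y = frame[response].to_numpy(dtype=float)
    prob = _BetaMixedProblem(y, x, z, codes)
    if method == "auto":
        method = "agq" if prob.q == 1 else "laplace"
    if method == "agq" and prob.q != 1:
        raise ValidationError("adaptive quadrature supports intercept-only "
                              "random structures")
    p, q = prob.p, prob.q
    beta0, logphi0 = _start_values(y, x, q)
    bounds = ([(None, None)] * p + [(-2.0, 8.0)] + [(-7.0, 2.5)] * q)
    best = None
    for logsig0 in (-1.5, -3.0)[:max(starts, 1)]:
        theta0 = np.concatenate([beta0, [logphi0], np.full(q, logsig0)])
        prob._warm = np.zeros((prob.G, q))
        res = optimize.minimize(
            prob.nll, theta0, args=(method,), method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 500, "ftol": 1e-11, "gtol": 1e-6, "eps": 1e-6})
        if best is None or res.fun < best.fun:
            best = res
    theta = best.x
    loglik = -best.fun
    se = vcov = None
    if compute_se:
        vcov_full = _numeric_vcov(lambda th: prob.nll(th, method), theta)
        vcov = vcov_full[:p, :p]
        se = np.sqrt(np.maximum(np.diag(vcov), 0.0))
    sigma = {name: float(np.exp(theta[p + 1 + i]))
             for i, name in enumerate(random_names)}
    return BetaMixedFit(formula=formula, fixed_names=fixed_names,
                        beta=theta[:p], se=se, vcov=vcov,
                        phi=float(np.exp(theta[p])), sigma=sigma,
                        loglik=float(loglik), n_obs=len(y),
                        n_groups=prob.G, n_params=p + 1 + q,
                        converged=bool(best.success
                                       or best.status == 1), method=method,
                        frame=frame)


def _numeric_vcov(fun, theta, step=1e-4):
    """Inverse of a central-difference Hessian (observed information)."""
    k = len(theta)
    h = np.empty((k, k))
    f0 = fun(theta)
    steps = np.maximum(np.abs(theta) * step, step)

    def f(dx):
        return fun(theta + dx)

    for i in range(k):
        ei = np.zeros(k)
        ei[i] = steps[i]
        h[i, i] = (f(ei) - 2 * f0 + f(-ei)) / steps[i] ** 2
        for j in range(i + 1, k):
            ej = np.zeros(k)
            ej[j] = steps[j]
            hij = (f(ei + ej) - f(ei - ej) - f(-ei + ej) + f(-ei - ej)) \
                / (4 * steps[i] * steps[j])
            h[i, j] = h[j, i] = hij
    try:
        return np.linalg.inv(h)
    except np.linalg.LinAlgError:
        return np.linalg.pinv(h)


# ---------------------------------------------------------------------------
# Model comparison
# ---------------------------------------------------------------------------

def lrt(fit_null: BetaMixedFit, fit_full: BetaMixedFit) -> tuple[float, int, float]:
    """Likelihood-ratio test of nested ML fits on identical rows."""
    if fit_null.n_obs != fit_full.n_obs:
        raise ValidationError("models were fit on different data")
    df = fit_full.n_params - fit_null.n_params
    if df <= 0:
        raise ValidationError("models are not nested (no added parameters)")
    missing = set(fit_null.fixed_names) - set(fit_full.fixed_names)
    if missing:
        raise ValidationError(f"models not nested: {missing} absent from full")
    chi2 = max(2.0 * (fit_full.loglik - fit_null.loglik), 0.0)
    return chi2, df, float(chi2_dist.sf(chi2, df))


@dataclass
class LadderResult:
    fits: dict[str, BetaMixedFit]
    comparisons: pd.DataFrame

    def fit(self, name: str) -> BetaMixedFit:
        return self.fits[name]


LADDER_STEPS = (
    ("M1", "turn_taking_z", "M0"),
    ("M2", "time_z", "M1"),
    ("M3", "turn_taking_z:time_z", "M2"),
    ("M4", "turn_duration_z", "M3"),
    ("M5", "relevance_z", "M3"),
    ("M6", "intrusiveness_z", "M3"),
    ("M7", "contingency_z", "M3"),
)


def model_ladder(frame: pd.DataFrame, upto: str = "M7",
                 method: str = "laplace", compute_se: bool = True,
                 ) -> LadderResult:
    """Fit the Models 0-7 ladder and its likelihood-ratio comparisons.

    M0: intercept + dyad random intercept; M1 adds turn-taking (fixed +
    uncorrelated random slope); M2 adds time; M3 adds turn-taking x time;
    M4-M7 each add turn duration / relevance / intrusiveness / contingency
    to M3 and are compared against M3.
    """
    order = [s[0] for s in LADDER_STEPS]
    if upto not in ("M0",) + tuple(order):
        raise ValueError(f"unknown ladder stop {upto!r}")
    needed = {"M1": ["turn_taking_z"], "M2": ["time_z"], "M3": [],
              "M4": ["turn_duration_z"], "M5": ["relevance_z"],
              "M6": ["intrusiveness_z"], "M7": ["contingency_z"]}
    stop_idx = -1 if upto == "M0" else order.index(upto)
    for name in order[:stop_idx + 1]:
        for col in needed[name]:
            if col not in frame.columns:
                raise KeyError(f"model frame lacks column {col!r} "
                               f"required by {name}")
    fits = {"M0": fit_beta_mixed(frame, FormulaSpec(), method="auto",
                                 compute_se=compute_se)}
    rows = []
    spec_by_name = {"M0": FormulaSpec()}
    for name, term, base in LADDER_STEPS[:stop_idx + 1]:
        spec = spec_by_name[base].with_term(term)
        spec_by_name[name] = spec
        fits[name] = fit_beta_mixed(frame, spec, method=method,
                                    compute_se=compute_se)
        chi2, df, p = lrt(fits[base], fits[name])
        rows.append((f"{name} vs {base}", chi2, df, p))
    comparisons = pd.DataFrame(rows, columns=["comparison", "chi2", "df", "p"])
    return LadderResult(fits=fits, comparisons=comparisons)


# ---------------------------------------------------------------------------
# Marginal trends
# ---------------------------------------------------------------------------

def trend_contrast(fit: BetaMixedFit, focal: str = "turn_taking_z",
                   moderator: str = "time_z",
                   split_spec: str = "early_late") -> pd.DataFrame:
    """Link-scale marginal slope of ``focal`` at two moderator levels.

    ``split_spec``: "early_late" evaluates the moderator at the mean
    z-time of epochs 1-4 and 5-8; "median" uses the means of the two
    median-split halves of the moderator.  The slope at level m is
    ``beta_focal + beta_interaction * m`` with delta-method SE; the last row
    is the (late - early) difference contrast.
    """
    inter = f"{focal}:{moderator}"
    if inter not in fit.fixed_names and f"{moderator}:{focal}" in fit.fixed_names:
        inter = f"{moderator}:{focal}"
    if inter not in fit.fixed_names:
        raise ValidationError(f"fit lacks interaction term {inter!r}")
    if fit.frame is None or fit.vcov is None:
        raise ValidationError("fit must carry its frame and vcov for trends")
    frame = fit.frame
    if split_spec == "early_late":
        half = (frame["epoch"].max() + frame["epoch"].min()) / 2.0
        lo = frame.loc[frame["epoch"] <= half, moderator].mean()
        hi = frame.loc[frame["epoch"] > half, moderator].mean()
        labels = ("early", "late")
    elif split_spec == "median":
        med = frame[moderator].median()
        lo = frame.loc[frame[moderator] <= med, moderator].mean()
        hi = frame.loc[frame[moderator] > med, moderator].mean()
        labels = ("low", "high")
    else:
        raise ValueError(f"unknown split_spec {split_spec!r}")
    i_f = fit.fixed_names.index(focal)
    i_i = fit.fixed_names.index(inter)
    bf, bi = fit.beta[i_f], fit.beta[i_i]
    v = fit.vcov
    rows = []
    for label, m in zip(labels, (lo, hi)):
        trend = bf + bi * m
        se = np.sqrt(max(v[i_f, i_f] + m * m * v[i_i, i_i]
                         + 2 * m * v[i_f, i_i], 0.0))
        rows.append((label, float(m), float(trend), float(se),
                     float(trend - 1.959964 * se), float(trend + 1.959964 * se)))
    dm = hi - lo
    diff = bi * dm
    se_d = np.sqrt(max(v[i_i, i_i], 0.0)) * abs(dm)
    rows.append((f"{labels[1]}-{labels[0]}", float(dm), float(diff),
                 float(se_d), float(diff - 1.959964 * se_d),
                 float(diff + 1.959964 * se_d)))
    return pd.DataFrame(rows, columns=["level", "moderator_value", "trend",
                                       "se", "ci_low", "ci_high"])


# ---------------------------------------------------------------------------
# Original vs surrogate pairing comparison
# ---------------------------------------------------------------------------

def pairing_frame(originals: list[CoherenceTable],
                  surrogate: SurrogateSet) -> pd.DataFrame:
    """Stack original values against per-child surrogate means.

    ``pairing`` is 0 for original rows and 1 for random-pair rows (the
    per-cell mean over surrogate draws, the chance-synchrony reference);
    ``time_z`` is the standardized epoch index, the grouping unit is the
    child/dyad.
    """
    if surrogate.n_draws == 0:
        raise ValidationError("surrogate set has zero draws")
    surr_mean = surrogate.per_child_mean()
    child_idx = {cid: i for i, cid in enumerate(surrogate.child_ids)}
    rows = []
    for tab in originals:
        ci = child_idx[tab.dyad_id]
        for c in range(tab.values.shape[0]):
            for e in range(tab.n_epochs):
                yo = tab.values[c, e]
                ys = surr_mean[ci, c, e]
                if np.isfinite(yo):
                    rows.append((tab.dyad_id, c + 1, e + 1, yo, 0))
                if np.isfinite(ys):
                    rows.append((tab.dyad_id, c + 1, e + 1, ys, 1))
    frame = pd.DataFrame(rows, columns=["dyad_id", "channel_id", "epoch",
                                        "wtc", "pairing"])
    if frame.empty:
        raise ValidationError("no finite coherence rows to compare")
    frame["wtc"] = compress_boundary(frame["wtc"].to_numpy())
    frame["time_z"] = zscore(frame["epoch"].to_numpy())
    frame["pairing_random"] = frame["pairing"].astype(float)
    return frame


def pairing_comparison(originals: list[CoherenceTable],
                       surrogate: SurrogateSet,
                       method: str = "laplace",
                       compute_se: bool = True) -> LadderResult:
    """Test pairing (original vs random), time, and pairing x time.

    Successive LRTs on a child-level random-intercept beta model:
    P0 (intercept) -> P1 (+pairing) -> P2 (+time) -> P3 (+pairing x time),
    each non-intercept effect entering with an uncorrelated random slope.
    """
    frame = pairing_frame(originals, surrogate)
    specs = {"P0": FormulaSpec()}
    specs["P1"] = specs["P0"].with_term("pairing_random")
    specs["P2"] = specs["P1"].with_term("time_z")
    specs["P3"] = specs["P2"].with_term("pairing_random:time_z")
    fits = {}
    rows = []
    prev = None
    for name in ("P0", "P1", "P2", "P3"):
        fits[name] = fit_beta_mixed(frame, specs[name],
                                    method="auto" if name == "P0" else method,
                                    compute_se=compute_se)
        if prev is not None:
            chi2, df, p = lrt(fits[prev], fits[name])
            rows.append((f"{name} vs {prev}", chi2, df, p))
        prev = name
    comparisons = pd.DataFrame(rows, columns=["comparison", "chi2", "df", "p"])
    return LadderResult(fits=fits, comparisons=comparisons)


def pairing_time_trends(result: LadderResult) -> pd.DataFrame:
    """Link-scale slope of time for original (0) vs random (1) pairing."""
    fit = result.fits["P3"]
    i_t = fit.fixed_names.index("time_z")
    i_i = fit.fixed_names.index("pairing_random:time_z")
    v = fit.vcov
    rows = []
    for label, pval in (("original", 0.0), ("random", 1.0)):
        trend = fit.beta[i_t] + fit.beta[i_i] * pval
        se = np.sqrt(max(v[i_t, i_t] + pval * pval * v[i_i, i_i]
                         + 2 * pval * v[i_t, i_i], 0.0))
        rows.append((label, float(trend), float(se),
                     float(trend - 1.959964 * se), float(trend + 1.959964 * se)))
    return pd.DataFrame(rows, columns=["pairing", "trend", "se", "ci_low",
                                       "ci_high"])


# ---------------------------------------------------------------------------
# Direct simulation from the model (parameter-recovery / power studies)
# ---------------------------------------------------------------------------

def simulate_beta_mixed(n_groups: int = 40, n_per_group: int = 128,
                        beta: dict[str, float] | None = None,
                        sigma: dict[str, float] | None = None,
                        phi: float = 30.0, seed: int = 0,
                        n_epochs: int = 8) -> pd.DataFrame:
    """Simulate a model frame directly from the beta mixed model.

    ``beta``/``sigma`` map term names to true values; the intercept is
    ``"intercept"``.  Covariates: ``time_z`` cycles over z-standardized epoch
    indices; any other named predictor is drawn once per group from N(0,1)
    (dyad-constant, like the conversation composites).  Returns a frame
    compatible with :func:`fit_beta_mixed`.
    """
    beta = dict(beta or {"intercept": 0.5})
    sigma = dict(sigma or {"intercept": 0.3})
    rng = np.random.default_rng(seed)
    epochs = np.tile(np.arange(1, n_epochs + 1),
                     int(np.ceil(n_per_group / n_epochs)))[:n_per_group]
    time_z_all = (epochs - epochs.mean()) / epochs.std()
    rows = []
    terms = [t for t in beta if t != "intercept"]
    base_terms = sorted({c for t in terms for c in t.split(":")
                         if c != "time_z"})
    for g in range(n_groups):
        covs = {c: rng.standard_normal() for c in base_terms}
        b = {t: rng.standard_normal() * s for t, s in sigma.items()}
        for j in range(n_per_group):
            covs_row = dict(covs)
            covs_row["time_z"] = time_z_all[j]
            eta = beta["intercept"] + b.get("intercept", 0.0)
            for t in terms:
                val = np.prod([covs_row[c] for c in t.split(":")])
                eta += (beta[t] + b.get(t, 0.0)) * val
            mu = expit(eta)
            y = rng.beta(mu * phi, (1 - mu) * phi)
            rows.append({"dyad_id": f"g{g:03d}", "epoch": int(epochs[j]),
                         "wtc": y, **{c: covs_row[c] for c in base_terms},
                         "time_z": covs_row["time_z"]})
    frame = pd.DataFrame(rows)
    frame["wtc"] = compress_boundary(frame["wtc"].to_numpy())
    return frame
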