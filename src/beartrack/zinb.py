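"""Zero-inflated negative-binomial mixed models for site-month counts.

The observation model for monthly detection counts y_ij at site i in month j
is a two-part mixture: with probability pi the count is a structural zero,
otherwise it is negative binomial with conditional mean

    log mu_ij = x_ij' beta + u_i + log(effort_ij),   u_i ~ Normal(0, sigma^2)

The site random intercept u_i absorbs repeat-visit correlation; the
log-effort offset accounts for unequal active camera days.  Two negative
binomial variance structures are supported: "nb1" with Var = mu(1 + alpha)
(linear) and "nb2" with Var = mu(1 + mu/theta) (quadratic).

The marginal likelihood integrates the random intercept out per site with
adaptive Gauss-Hermite quadrature (Laplace-centred, 15 nodes by default),
and is maximized by quasi-Newton iteration from several documented starting
points.  Model comparison uses AICc and Akaike weights.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

__all__ = [
    "ModelSpec",
    "Design",
    "FitResult",
    "build_design",
    "zinb_nll",
    "fit",
    "aicc",
    "akaike_weights",
    "compare_sets",
    "table1_model_sets",
    "table2_model_set",
]

SEASON_LEVELS = ("spring", "summer", "autumn", "winter")
STRATUM_LEVELS = ("urban", "rural", "wild")


# ---------------------------------------------------------------------------
# model specification and design matrices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """A candidate model: fixed-effect terms plus family.

    Terms may be continuous covariate names (``"HD"``), squares
    (``"HD^2"``), products of two continuous covariates (``"TD*HD"``),
    the factors ``"season"`` (spring reference) and ``"stratum"``
    (configurable reference, wild by default), and continuous-by-factor
    interactions (``"conflict_prob*season"``), which expand to the
    interaction columns only — main effects are listed explicitly.
    Zero inflation is an intercept-only logit; all models carry a site
    random intercept and a log-effort offset.
    """

    name: str
    terms: tuple[str, ...] = ()
    family: str = "nb2"
    set_name: str = ""
    stratum_ref: str = "wild"

    def __post_init__(self):
        if self.family not in ("nb1", "nb2"):
            raise ValueError(f"unknown family {self.family!r}")
        object.__setattr__(self, "terms", tuple(self.terms))

    def n_fixed(self) -> int:
        """Number of fixed-effect columns including the intercept."""
        n = 1
        for t in self.terms:
            n += len(_term_columns_names(t, self.stratum_ref))
        return n

    @property
    def k(self) -> int:
        """Parameter count: fixed effects + random-intercept sd
        + dispersion + zero-inflation intercept."""
        return self.n_fixed() + 3

    def with_family(self, family: str) -> "ModelSpec":
        return ModelSpec(self.name, self.terms, family, self.set_name, self.stratum_ref)


def _factor_levels(factor: str, stratum_ref: str) -> tuple[str, tuple[str, ...]]:
    if factor == "season":
        return "spring", tuple(l for l in SEASON_LEVELS if l != "spring")
    if factor == "stratum":
        return stratum_ref, tuple(l for l in STRATUM_LEVELS if l != stratum_ref)
    raise ValueError(f"unknown factor {factor!r}")


def _term_columns_names(term: str, stratum_ref: str) -> list[str]:
    term = term.replace(":", "*")
    if term in ("season", "stratum"):
        _, levels = _factor_levels(term, stratum_ref)
        return [f"{term}[{l}]" for l in levels]
    if "*" in term:
        a, b = term.split("*")
        if b in ("season", "stratum"):
            _, levels = _factor_levels(b, stratum_ref)
            return [f"{a}:{b}[{l}]" for l in levels]
        if a in ("season", "stratum"):
            _, levels = _factor_levels(a, stratum_ref)
            return [f"{b}:{a}[{l}]" for l in levels]
        return [f"{a}:{b}"]
    return [term]


def _term_columns(term: str, data: pd.DataFrame, stratum_ref: str) -> tuple[list[str], list[np.ndarray]]:
    term = term.replace(":", "*")
    names = _term_columns_names(term, stratum_ref)

    def cont(name: str) -> np.ndarray:
        if name.endswith("^2"):
            return cont(name[:-2]) ** 2
        if name not in data.columns:
            raise ValueError(f"covariate {name!r} missing from data")
        return data[name].to_numpy(dtype=float)

    if term in ("season", "stratum"):
        _, levels = _factor_levels(term, stratum_ref)
        fac = data[term].astype(str).to_numpy()
        return names, [(fac == l).astype(float) for l in levels]
    if "*" in term:
        a, b = term.split("*")
        if b in ("season", "stratum") or a in ("season", "stratum"):
            fac_name = b if b in ("season", "stratum") else a
            cov_name = a if fac_name == b else b
        else:
            return names, [cont(a) * cont(b)]
        _, levels = _factor_levels(fac_name, stratum_ref)
        fac = data[fac_name].astype(str).to_numpy()
        x = cont(cov_name)
        return names, [x * (fac == l) for l in levels]
    return names, [cont(term)]


@dataclass
class Design:
    """Built design: response, fixed-effect matrix, offset, site grouping."""

    y: np.ndarray
    X: np.ndarray
    colnames: list[str]
    offset: np.ndarray
    site_idx: np.ndarray
    site_ids: list
    n_dropped: int
    index: pd.Index

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)


def build_design(spec: ModelSpec, data: pd.DataFrame) -> Design:
    """Assemble design matrices for a spec from the site-month table.

    ``data`` needs ``site_id``, ``count``, ``effort`` and every covariate
    the spec references (continuous covariates already standardized).
    Rows with zero effort are dropped (log-offset undefined); the count of
    dropped rows is recorded on the design.
    """
    keep = data["effort"].to_numpy(dtype=float) > 0
    n_dropped = int((~keep).sum())
    d = data.loc[keep].reset_index(drop=False)

    names: list[str] = ["(Intercept)"]
    cols: list[np.ndarray] = [np.ones(len(d))]
    for term in spec.terms:
        t_names, t_cols = _term_columns(term, d, spec.stratum_ref)
        names.extend(t_names)
        cols.extend(t_cols)
    X = np.column_stack(cols)

    sites = pd.Categorical(d["site_id"])
    return Design(
        y=d["count"].to_numpy(dtype=float),
        X=X,
        colnames=names,
        offset=np.log(d["effort"].to_numpy(dtype=float)),
        site_idx=np.asarray(sites.codes, dtype=np.intp),
        site_ids=list(sites.categories),
        n_dropped=n_dropped,
        index=pd.Index(d["index"]),
    )


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

class _LikContext:
    """Per-parameter-value evaluation context for the marginal likelihood.

    Precomputes everything that does not depend on the random-effect value
    (gamma-function constants, zero-inflation logs), so mode-finding and
    quadrature only pay for the mu-dependent terms.
    """

    def __init__(self, beta_eta, y, site_idx, n_sites, sigma, disp, pi_logit,
                 family):
        self.beta_eta = beta_eta
        self.y = y
        self.site_idx = site_idx
        self.n_sites = n_sites
        self.sigma = sigma
        self.family = family
        self.disp = disp
        self.is0 = y == 0
        self.l1mpi = -np.logaddexp(0.0, pi_logit)   # log(1 - pi)
        self.lpi = pi_logit + self.l1mpi            # log(pi)
        if family == "nb2":
            theta = disp
            self.const = (special.gammaln(y + theta) - special.gammaln(theta)
                          - special.gammaln(y + 1.0) + theta * math.log(theta))
        else:
            alpha = disp
            self.log1pa = math.log1p(alpha)
            self.const = (-special.gammaln(y + 1.0)
                          + y * (math.log(alpha) - self.log1pa))

    def _nb_parts(self, lmu, derivs):
        """(logf, g1, g2) of the NB part; g = d/d log mu."""
        y = self.y
        if self.family == "nb2":
            theta = self.disp
            mu = np.exp(lmu)
            logf = self.const + y * lmu - (y + theta) * np.log(theta + mu)
            if not derivs:
                return logf, None, None
            g1 = y - mu * (y + theta) / (theta + mu)
            g2 = -mu * theta * (y + theta) / (theta + mu) ** 2
            return logf, g1, g2
        alpha = self.disp
        r = np.exp(lmu) / alpha
        logf = (self.const + special.gammaln(y + r) - special.gammaln(r)
                - r * self.log1pa)
        if not derivs:
            return logf, None, None
        A = special.digamma(y + r) - special.digamma(r) - self.log1pa
        g1 = r * A
        g2 = r * A + r * r * (special.polygamma(1, y + r) - special.polygamma(1, r))
        return logf, g1, g2

    def obs_loglik(self, u_obs, derivs=False):
        """Zero-inflated per-observation log density at random effect u."""
        logf, g1, g2 = self._nb_parts(self.beta_eta + u_obs, derivs)
        lm = self.l1mpi + logf
        lm0 = np.logaddexp(self.lpi, lm)
        out = np.where(self.is0, lm0, lm)
        if not derivs:
            return out, None, None
        # weight of the NB branch at observed zeros
        w = np.where(self.is0, np.exp(np.minimum(lm - lm0, 0.0)), 1.0)
        d1 = w * g1
        d2 = w * g2 + w * (1.0 - w) * g1 * g1
        return out, d1, d2

    def site_h(self, z, derivs=False):
        """h_i(z) = log phi(z) + sum_j log p(y_ij | u = sigma z_i)."""
        lm, d1, d2 = self.obs_loglik(self.sigma * z[self.site_idx], derivs)
        h = np.bincount(self.site_idx, weights=lm, minlength=self.n_sites)
        h += -0.5 * z * z - 0.5 * math.log(2.0 * math.pi)
        if not derivs:
            return h, None, None
        h1 = self.sigma * np.bincount(self.site_idx, weights=d1, minlength=self.n_sites) - z
        h2 = (self.sigma ** 2) * np.bincount(self.site_idx, weights=d2, minlength=self.n_sites) - 1.0
        return h, h1, h2

    def laplace_mode(self, tol=1e-9, max_iter=40):
        """Per-site mode and curvature of h_i by safeguarded Newton."""
        z = np.zeros(self.n_sites)
        h2 = None
        for _ in range(max_iter):
            _, h1, h2 = self.site_h(z, derivs=True)
            denom = np.where(h2 < -1e-8, -h2, 1.0)
            step = np.clip(h1 / denom, -2.0, 2.0)
            z = z + step
            if np.max(np.abs(h1)) < tol:
                break
        _, _, h2 = self.site_h(z, derivs=True)
        curv = np.where(h2 < -1e-8, -h2, 1e-8)
        return z, curv


def zinb_nll(params: np.ndarray, design: Design, family: str,
             n_quad: int = 15) -> float:
    """Negative marginal log-likelihood of a zero-inflated NB mixed model.

    ``params`` is [beta..., logit(pi), log(dispersion), log(sigma_site)].
    The per-site 1-D random-effect integral is evaluated by Gauss-Hermite
    quadrature adapted to the Laplace mode and curvature of each site's
    joint density.  ``n_quad=1`` reduces to the Laplace approximation.
    """
    p = design.X.shape[1]
    beta = params[:p]
    pi_logit = float(np.clip(params[p], -35.0, 35.0))
    # clamp the log-scale parameters so optimizer excursions cannot
    # underflow the dispersion or overflow the random-effect scale
    disp = math.exp(float(np.clip(params[p + 1], -20.0, 25.0)))
    sigma = math.exp(float(np.clip(params[p + 2], -25.0, 5.0)))
    beta_eta = design.X @ beta + design.offset
    S = design.n_sites
    ctx = _LikContext(beta_eta, design.y, design.site_idx, S, sigma, disp,
                      pi_logit, family)

    if sigma < 1e-8:
        lm, _, _ = ctx.obs_loglik(np.zeros(design.n))
        return float(-np.sum(lm))

    z_hat, curv = ctx.laplace_mode()
    tau = 1.0 / np.sqrt(curv)
    nodes, weights = special.roots_hermite(n_quad)
    # integral ~ sqrt(2) tau sum_k w_k exp(t_k^2) exp(h(z_hat + sqrt(2) tau t_k))
    logterms = np.empty((n_quad, S))
    for k in range(n_quad):
        zk = z_hat + math.sqrt(2.0) * tau * nodes[k]
        h, _, _ = ctx.site_h(zk)
        logterms[k] = math.log(weights[k]) + nodes[k] ** 2 + h
    site_loglik = special.logsumexp(logterms, axis=0) + 0.5 * math.log(2.0) + np.log(tau)
    total = float(np.sum(site_loglik))
    if not np.isfinite(total):
        bad = [design.site_ids[i] for i in np.where(~np.isfinite(site_loglik))[0][:5]]
        raise FloatingPointError(f"non-finite marginal likelihood at sites {bad}")
    return -total


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """A fitted candidate model."""

    spec: ModelSpec
    params: np.ndarray
    coef: pd.DataFrame            # estimate, se, z, p per fixed effect
    pi: float                     # zero-inflation probability
    dispersion: float             # theta (nb2) or alpha (nb1)
    sigma_site: float             # random-intercept sd
    loglik: float
    k: int
    n: int
    aicc: float
    converged: bool
    n_dropped: int
    colnames: list[str] = field(default_factory=list)

    @property
    def name(self) -> str:
        return self.spec.name

    @property
    def family(self) -> str:
        return self.spec.family

    def summary(self) -> pd.DataFrame:
        return self.coef


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample corrected AIC: -2 logLik + 2k + 2k(k+1)/(n-k-1)."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} <= k+1={k + 1}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1.0) / (n - k - 1.0)


def _start_points(design: Design, seed: int | None) -> list[np.ndarray]:
    """Five documented starting points for the optimizer.

    Start 1 is moment-based: intercept at log(mean count per active day),
    slopes zero, pi 0.25, unit dispersion, sigma 0.5.  Starts 2-5 vary the
    zero-inflation and random-effect scale and jitter slopes slightly
    (seeded, hence reproducible).
    """
    p = design.X.shape[1]
    rate = max(design.y.sum() / np.exp(design.offset).sum(), 1e-6)
    base = np.zeros(p + 3)
    base[0] = math.log(rate)
    base[p] = math.log(0.25 / 0.75)
    base[p + 1] = 0.0
    base[p + 2] = math.log(0.5)
    starts = [base]
    rng = np.random.default_rng(0 if seed is None else seed)
    for logit_pi, log_sig in ((-2.0, math.log(0.2)), (0.0, math.log(1.0)),
                              (-1.0, math.log(0.5)), (-2.0, math.log(1.0))):
        s = base.copy()
        s[1:p] = 0.05 * rng.standard_normal(p - 1)
        s[p] = logit_pi
        s[p + 2] = log_sig
        starts.append(s)
    return starts


def _numeric_hessian(f, x, h_rel=1e-4):
    p = len(x)
    h = h_rel * np.maximum(1.0, np.abs(x))
    H = np.empty((p, p))
    for i in range(p):
        for j in range(i, p):
            ei = np.zeros(p); ei[i] = h[i]
            ej = np.zeros(p); ej[j] = h[j]
            v = (f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej))
            H[i, j] = H[j, i] = v / (4.0 * h[i] * h[j])
    return H


def fit(spec: ModelSpec, data: pd.DataFrame, seed: int | None = 0,
        n_quad: int = 15, n_starts: int = 5, compute_se: bool = True) -> FitResult:
    """Fit a spec to the site-month table by marginal maximum likelihood.

    Runs L-BFGS-B from up to ``n_starts`` documented starting points and
    keeps the best optimum; standard errors come from the numeric Hessian
    at the optimum.  Refitting with the same seed is deterministic.
    """
    design = build_design(spec, data)
    p = design.X.shape[1]

    def obj(x):
        try:
            return zinb_nll(x, design, spec.family, n_quad)
        except FloatingPointError:
            return 1e12

    best = None
    for x0 in _start_points(design, seed)[:n_starts]:
        res = optimize.minimize(obj, x0, method="L-BFGS-B",
                                options={"maxiter": 400, "maxfun": 4000})
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun - 1e-9):
            best = res
    converged = best is not None and bool(best.success) and best.fun < 1e11
    if best is None:
        raise RuntimeError(f"all starts failed for model {spec.name!r}")

    x = best.x
    loglik = -best.fun
    k = p + 3
    se = np.full(p, np.nan)
    if compute_se:
        try:
            H = _numeric_hessian(obj, x)
            cov = np.linalg.inv(H)
            dse = np.sqrt(np.diag(cov))
            if np.all(np.isfinite(dse[:p])):
                se = dse[:p]
            else:
                converged = False
        except np.linalg.LinAlgError:
            converged = False

    beta = x[:p]
    zval = beta / se
    pval = 2.0 * stats.norm.sf(np.abs(zval))
    coef = pd.DataFrame({"estimate": beta, "se": se, "z": zval, "p": pval},
                        index=design.colnames)
    return FitResult(
        spec=spec,
        params=x,
        coef=coef,
        pi=float(special.expit(x[p])),
        dispersion=float(math.exp(x[p + 1])),
        sigma_site=float(math.exp(x[p + 2])),
        loglik=float(loglik),
        k=k,
        n=design.n,
        aicc=aicc(loglik, k, design.n),
        converged=converged,
        n_dropped=design.n_dropped,
        colnames=design.colnames,
    )


# ---------------------------------------------------------------------------
# model comparison
# ---------------------------------------------------------------------------

def akaike_weights(aicc_values) -> np.ndarray:
    """Akaike weights: exp(-delta/2) normalized over the compared set."""
    a = np.asarray(aicc_values, dtype=float)
    if a.size == 0 or not np.all(np.isfinite(a)):
        raise ValueError("need at least one finite AICc value")
    delta = a - a.min()
    w = np.exp(-delta / 2.0)
    return w / w.sum()


def compare_sets(fits_by_set: dict[str, list[FitResult]],
                 presentation_delta: float = 2.0) -> pd.DataFrame:
    """Within-set and between-set AICc comparison of candidate models.

    Within-set delta is relative to the best model of the same hypothesis
    set; between-set delta compares set leaders.  Akaike weights are
    normalized across all compared models.  ``retained`` marks models
    within ``presentation_delta`` of their set's best.  Non-converged fits
    are excluded with a warning column.
    """
    rows = []
    for set_name, fits in fits_by_set.items():
        if not fits:
            raise ValueError(f"empty model set {set_name!r}")
        for f in fits:
            rows.append({"set": set_name, "model": f.name, "family": f.family,
                         "k": f.k, "n": f.n, "loglik": f.loglik,
                         "aicc": f.aicc, "converged": f.converged})
    df = pd.DataFrame(rows)
    dropped = df[~df["converged"]]
    if len(dropped):
        import warnings
        warnings.warn(f"excluding non-converged fits: {list(dropped['model'])}")
        df = df[df["converged"]].reset_index(drop=True)
    df["delta_within"] = df["aicc"] - df.groupby("set")["aicc"].transform("min")
    leaders = df.groupby("set")["aicc"].min()
    df["delta_between"] = df["set"].map(leaders - leaders.min())
    df["weight"] = akaike_weights(df["aicc"])
    df["retained"] = df["delta_within"] <= presentation_delta
    return df.sort_values(["delta_between", "set", "delta_within"]).reset_index(drop=True)


# candidate-set factories -----------------------------------------------------

_T1_CORE = ("HD", "HD^2", "RD", "EVI", "DUrb", "DAg", "Ele", "TD")


def table1_model_sets(family: str = "nb2") -> dict[str, list[ModelSpec]]:
    """The habitat-use candidate sets: conflict, full, anthropogenic,
    environmental and null hypotheses, each anthropogenic set with and
    without the trail-by-human-density interaction."""
    def spec(name, terms, set_name):
        return ModelSpec(name, terms, family, set_name)

    return {
        "conflict": [
            spec("conflict+TDxHD", _T1_CORE + ("TD*HD",), "conflict"),
            spec("conflict", _T1_CORE, "conflict"),
        ],
        "full": [
            spec("full+TDxHD", _T1_CORE + ("Con", "DW", "Sal", "TD*HD"), "full"),
            spec("full", _T1_CORE + ("Con", "DW", "Sal"), "full"),
        ],
        "anthropogenic": [
            spec("anthro+TDxHD", ("HD", "HD^2", "RD", "DUrb", "DAg", "Con", "TD", "TD*HD"), "anthropogenic"),
            spec("anthro", ("HD", "HD^2", "RD", "DUrb", "DAg", "Con", "TD"), "anthropogenic"),
        ],
        "environmental": [spec("environmental", ("EVI", "DW", "Sal", "Ele"), "environmental")],
        "null": [spec("null", (), "null")],
    }


def table2_model_set() -> list[ModelSpec]:
    """The seasonal conflict-probability hypotheses (8 specs).

    Each is meant to be fitted under both nb1 and nb2 with the
    lower-AICc family retained (see ``fit_best_family``).
    """
    hyp = [
        ("conflict_x_season", ("conflict_prob", "season", "conflict_prob*season")),
        ("conflict_plus_season", ("conflict_prob", "season")),
        ("season", ("season",)),
        ("conflict_plus_strata", ("conflict_prob", "stratum")),
        ("conflict_x_strata", ("conflict_prob", "stratum", "conflict_prob*stratum")),
        ("conflict", ("conflict_prob",)),
        ("strata", ("stratum",)),
        ("null", ()),
    ]
    return [ModelSpec(name, terms, "nb1", "seasonal_conflict") for name, terms in hyp]


def fit_best_family(spec: ModelSpec, data: pd.DataFrame, seed: int | None = 0,
                    **kw) -> FitResult:
    """Fit a spec under nb1 and nb2 and return the lower-AICc variant."""
    fits = [fit(spec.with_family(fam), data, seed=seed, **kw) for fam in ("nb1", "nb2")]
    fits = [f for f in fits if f.converged] or fits
    return min(fits, key=lambda f: f.aicc)


def specs_from_yaml(path) -> list[ModelSpec]:
    """Load a declarative candidate-model list.

    The file holds a ``models:`` list; each entry has ``name``, ``terms``
    (list of term strings), and optional ``family`` (nb1/nb2, default nb2),
    ``set`` and ``stratum_ref``.  Expressive enough for every published
    candidate model.
    """
    import yaml

    doc = yaml.safe_load(Path(path).read_text())
    specs = []
    for m in doc["models"]:
        specs.append(ModelSpec(
            name=m["name"],
            terms=tuple(m.get("terms", ())),
            family=m.get("family", "nb2"),
            set_name=m.get("set", ""),
            stratum_ref=m.get("stratum_ref", "wild"),
        ))
    return specs
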