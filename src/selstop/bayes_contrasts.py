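"""Bayesian mixed models, posterior contrasts, and the HDI+ROPE decision rule.

Four model families cover the analyses: shifted-lognormal (RTs), Gaussian
(averaged SSRTs), Gamma with a log link (MEP amplitudes), and Bernoulli with
a logit link (stopping success).  Fixed effects use cell-means coding (one
coefficient per factor-level combination), so contrasts are simple averages
of named cells; by-participant random intercepts (plus, for the marginalised
families, by-participant cell deviations) absorb between-subject variation.

For every contrast the posterior is summarised by the median, the 89%
highest-density interval (shortest interval containing 89% of the draws), the
probability of direction (pd: share of draws on the median's side of the null
point, 50-100%), the percentage of HDI draws inside a region of practical
equivalence (ROPE), and the three-way HDI+ROPE decision: the null is accepted
when the HDI lies completely inside the ROPE, rejected when HDI and ROPE are
disjoint, and no decision is reached otherwise.  Log-link contrasts are
back-transformed to conditioned/unconditioned-style ratios or percent changes
before summarising.
"""

from __future__ import annotations

import math
import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from ._mcmc import sample_posterior

FAMILIES = ("shifted_lognormal_identity", "gaussian_identity", "gamma_log",
            "bernoulli_logit")
SCALES = ("ms", "response", "ratio", "percent_change", "log_odds")
RHAT_LIMIT = 1.1


# ---------------------------------------------------------------------------
# posterior indices (implemented from scratch; the core decision machinery)

def probability_of_direction(draws: np.ndarray, null: float = 0.0) -> float:
    """pd: percentage of draws on the median's side of the null point (50-100)."""
    d = np.asarray(draws, dtype=float) - null
    if d.size == 0:
        raise ValueError("pd requires at least one draw")
    n_pos = int(np.sum(d > 0))
    n_neg = int(np.sum(d < 0))
    return 100.0 * max(n_pos, n_neg, d.size / 2) / d.size


def hdi(draws: np.ndarray, prob: float = 0.89) -> tuple[float, float]:
    """Shortest interval containing ``prob`` of the draws.

    Computed by scanning every window of ceil(prob * n) consecutive sorted
    draws; ties broken by the first (lowest) window.
    """
    d = np.sort(np.asarray(draws, dtype=float))
    n = d.size
    if n < 100:
        raise ValueError(
            "HDI on fewer than 100 draws is unstable; collect more draws "
            "(increase chains or post-warmup samples)")
    m = int(math.ceil(prob * n))
    widths = d[m - 1:] - d[: n - m + 1]
    i = int(np.argmin(widths))
    return float(d[i]), float(d[i + m - 1])


def rope_percentage(draws: np.ndarray, rope: tuple[float, float],
                    hdi_bounds: tuple[float, float] | None = None,
                    prob: float = 0.89) -> float:
    """% of HDI-defining draws that fall inside the ROPE."""
    d = np.asarray(draws, dtype=float)
    lo, hi = hdi_bounds if hdi_bounds is not None else hdi(d, prob)
    inside_hdi = (d >= lo) & (d <= hi)
    n_hdi = int(inside_hdi.sum())
    if n_hdi == 0:
        return float("nan")
    in_rope = inside_hdi & (d >= rope[0]) & (d <= rope[1])
    return 100.0 * int(in_rope.sum()) / n_hdi


def hdi_rope_decision(hdi_bounds: tuple[float, float],
                      rope: tuple[float, float]) -> str:
    lo, hi = hdi_bounds
    if lo >= rope[0] and hi <= rope[1]:
        return "accept_null"
    if hi < rope[0] or lo > rope[1]:
        return "reject_null"
    return "undecided"


def default_rope(scale_tag: str, reference: float | None = None) -> tuple[float, float]:
    """ROPE conventions: +/-5% (ratio [0.95, 1.05]) for all models, except
    +/-0.05 on the log-odds scale for the logistic model; identity-link scales
    use +/-5% of a stated reference response."""
    if scale_tag == "percent_change":
        return (-5.0, 5.0)
    if scale_tag == "ratio":
        return (0.95, 1.05)
    if scale_tag == "log_odds":
        return (-0.05, 0.05)
    if scale_tag in ("ms", "response"):
        if reference is None:
            raise ValueError("identity-link ROPE needs a reference response value")
        half = 0.05 * abs(reference)
        return (-half, half)
    raise ValueError(f"unknown scale_tag {scale_tag!r}")


def null_value(scale_tag: str) -> float:
    return 1.0 if scale_tag == "ratio" else 0.0


@dataclass
class PosteriorDraws:
    """Posterior draws of one contrast on a stated reporting scale."""

    draws: np.ndarray
    scale_tag: str
    name: str = ""

    def __post_init__(self):
        self.draws = np.asarray(self.draws, dtype=float)
        if self.draws.size < 1:
            raise ValueError("PosteriorDraws requires at least one draw")
        if self.scale_tag not in SCALES:
            raise ValueError(f"unknown scale_tag {self.scale_tag!r}")

    @property
    def n_draws(self) -> int:
        return int(self.draws.size)


@dataclass
class ContrastSummary:
    name: str
    scale_tag: str
    median: float
    hdi89_low: float
    hdi89_high: float
    pd: float
    pct_hdi_in_rope: float
    decision: str
    rope_low: float
    rope_high: float

    def report_line(self) -> str:
        return (f"{self.name}: {self.median:.3g} "
                f"[{self.hdi89_low:.3g} - {self.hdi89_high:.3g}], "
                f"pd = {self.pd:.1f}%, {self.pct_hdi_in_rope:.1f}% in ROPE, "
                f"{self.decision}")


def summarize_contrast(pdraws: PosteriorDraws,
                       rope: tuple[float, float] | None = None,
                       rope_reference: float | None = None) -> ContrastSummary:
    d = pdraws.draws
    if rope is None:
        rope = default_rope(pdraws.scale_tag, rope_reference)
    bounds = hdi(d)
    med = float(np.median(d))
    return ContrastSummary(
        name=pdraws.name, scale_tag=pdraws.scale_tag, median=med,
        hdi89_low=bounds[0], hdi89_high=bounds[1],
        pd=probability_of_direction(d, null_value(pdraws.scale_tag)),
        pct_hdi_in_rope=rope_percentage(d, rope, bounds),
        decision=hdi_rope_decision(bounds, rope),
        rope_low=rope[0], rope_high=rope[1])


# ---------------------------------------------------------------------------
# model specification and design construction

@dataclass
class ModelSpec:
    """One mixed-model fit.

    Fixed factors are combined into cells (cell-means coding); numeric
    covariates get population-level slopes.  Random structure: by-participant
    intercepts, plus by-participant cell deviations (shared SD) for the
    marginalised Gaussian-core families when ``random_cell_effects`` is on.
    Defaults give 8 chains x 1,500 post-warmup draws = 12,000 draws.
    """

    family: str
    response: str
    fixed_factors: list[str] = field(default_factory=list)
    covariates: list[str] = field(default_factory=list)
    subject_col: str = "subject_id"
    shift: float = 0.0          # shifted-lognormal location (ms)
    random_cell_effects: bool = True
    chains: int = 8
    warmup_draws: int = 1500
    post_warmup_draws_per_chain: int = 1500

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")

    @property
    def total_post_draws(self) -> int:
        return self.chains * self.post_warmup_draws_per_chain


def cell_label(values: tuple) -> str:
    return "|".join(str(v) for v in values)


def build_design(data: pd.DataFrame, spec: ModelSpec):
    """(X, coef_names, subject_codes, n_cells) with cell-means coding."""
    n = len(data)
    if spec.fixed_factors:
        cells = data[spec.fixed_factors].astype(str).agg("|".join, axis=1)
        levels = sorted(cells.unique())
        X = np.zeros((n, len(levels)))
        for j, lev in enumerate(levels):
            X[:, j] = (cells == lev).to_numpy(dtype=float)
        names = list(levels)
    else:
        X = np.ones((n, 1))
        names = ["intercept"]
    n_cells = len(names)
    for cov in spec.covariates:
        X = np.column_stack([X, data[cov].to_numpy(dtype=float)])
        names.append(cov)
    subj = pd.Categorical(data[spec.subject_col])
    return X, names, np.asarray(subj.codes), n_cells


# ---------------------------------------------------------------------------
# log posteriors

class _MarginalGaussian:
    """Gaussian mixed model with random effects integrated out analytically.

    Per subject, y_i ~ N(X_i beta, sigma^2 I + Z_i D Z_i') with
    Z_i = [1 | cell indicators] and D = diag(tau0^2, tau1^2, ..., tau1^2).
    The likelihood is evaluated from per-subject sufficient statistics via
    the Woodbury identity, so cost is independent of trial counts.
    Parameters: beta (p), sigma, tau0[, tau1], all scale parameters sampled
    directly on the positive scale (positivity enforced through the prior).
    """

    def __init__(self, y, X, subj, n_cells, random_cells: bool, prior_scale: float):
        self.p = X.shape[1]
        self.random_cells = random_cells
        self.k = 1 + (n_cells if random_cells else 0)
        self.prior_scale = prior_scale
        self.stats = []
        for s in np.unique(subj):
            m = subj == s
            Xi, yi = X[m], y[m]
            Zi = np.column_stack([np.ones(m.sum())] +
                                 ([Xi[:, j] for j in range(n_cells)]
                                  if random_cells else []))
            self.stats.append(dict(
                n=int(m.sum()), yty=float(yi @ yi), Xty=Xi.T @ yi,
                XtX=Xi.T @ Xi, ZtZ=Zi.T @ Zi, Zty=Zi.T @ yi, XtZ=Xi.T @ Zi))
        self.ndim = self.p + 2 + (1 if random_cells else 0)

    def unpack(self, theta):
        beta = theta[:, : self.p]
        sigma = theta[:, self.p]
        tau0 = theta[:, self.p + 1]
        tau1 = theta[:, self.p + 2] if self.random_cells else None
        return beta, sigma, tau0, tau1

    def __call__(self, theta):
        theta = np.asarray(theta, dtype=float)
        was_1d = theta.ndim == 1
        theta = np.atleast_2d(theta)
        W = theta.shape[0]
        beta, sigma, tau0, tau1 = self.unpack(theta)
        out = np.full(W, -np.inf)
        eps = 1e-8
        ok = (sigma > eps) & (tau0 > eps)
        if tau1 is not None:
            ok &= tau1 > eps
        if not ok.any():
            return out[0] if was_1d else out
        sigma = np.where(ok, sigma, 1.0)
        tau0 = np.where(ok, tau0, 1.0)
        if tau1 is not None:
            tau1 = np.where(ok, tau1, 1.0)
        sigma2 = sigma ** 2
        d = np.empty((W, self.k))
        d[:, 0] = tau0 ** 2
        if self.random_cells:
            d[:, 1:] = (tau1 ** 2)[:, None]
        ll = np.zeros(W)
        k = self.k
        for st in self.stats:
            rr = (st["yty"] - 2 * beta @ st["Xty"]
                  + np.einsum("wi,ij,wj->w", beta, st["XtX"], beta))
            u = st["Zty"][None, :] - beta @ st["XtZ"]          # (W, k)
            A = np.broadcast_to(st["ZtZ"], (W, k, k)).copy()
            A[:, np.arange(k), np.arange(k)] += sigma2[:, None] / d
            sign, logdetA = np.linalg.slogdet(A)
            x = np.linalg.solve(A, u[:, :, None])[:, :, 0]
            quad = (rr - np.einsum("wk,wk->w", u, x)) / sigma2
            logdet = ((st["n"] - k) * 2 * np.log(sigma) + np.log(d).sum(axis=1)
                      + logdetA)
            ll += -0.5 * (st["n"] * math.log(2 * math.pi) + logdet + quad)
        # priors: flat beta; flat (positive) sigma; tau ~ HalfNormal
        lp = ll - 0.5 * (tau0 / self.prior_scale) ** 2
        if self.random_cells:
            lp += -0.5 * (tau1 / self.prior_scale) ** 2
        out = np.where(ok & np.isfinite(lp), lp, -np.inf)
        return out[0] if was_1d else out

    def start(self, y, X, subj):
        beta0, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta0
        s = max(float(np.std(resid)), 1e-3)
        x0 = np.concatenate([beta0, [s, s / 2] +
                             ([s / 2] if self.random_cells else [])])
        return x0


class _ExplicitGlmm:
    """Gamma (log link) or Bernoulli (logit link) mixed model with explicit
    by-subject random intercepts.

    Parameters: beta (p), [shape], tau, u (n_subjects); shape and tau are
    sampled directly on the positive scale.
    """

    def __init__(self, family, y, X, subj, tau_prior_scale: float = 1.0):
        self.family = family
        self.y = np.asarray(y, dtype=float)
        self.X = np.asarray(X, dtype=float)
        self.subj = np.asarray(subj)
        self.S = int(self.subj.max()) + 1
        self.p = X.shape[1]
        self.has_shape = family == "gamma_log"
        self.tau_prior_scale = tau_prior_scale
        self.ndim = self.p + (1 if self.has_shape else 0) + 1 + self.S
        if self.has_shape:
            self.logy = np.log(self.y)

    def unpack(self, theta):
        i = self.p
        beta = theta[:, :i]
        shape = None
        if self.has_shape:
            shape = theta[:, i]
            i += 1
        tau = theta[:, i]
        u = theta[:, i + 1:]
        return beta, shape, tau, u

    def __call__(self, theta):
        theta = np.asarray(theta, dtype=float)
        was_1d = theta.ndim == 1
        theta = np.atleast_2d(theta)
        beta, shape, tau, u = self.unpack(theta)
        W = theta.shape[0]
        eps = 1e-8
        ok = tau > eps
        if shape is not None:
            ok &= shape > eps
        tau = np.where(ok, tau, 1.0)
        if shape is not None:
            shape = np.where(ok, shape, 1.0)
        eta = self.X @ beta.T + u[:, self.subj].T        # (n, W)
        if self.family == "gamma_log":
            a = shape[None, :]
            ll = (a * np.log(shape)[None, :] - gammaln(a) - a * eta
                  + (a - 1) * self.logy[:, None]
                  - a * self.y[:, None] * np.exp(-np.clip(eta, -30, 30))).sum(axis=0)
        else:  # bernoulli_logit
            yv = self.y[:, None]
            ll = (yv * eta - np.logaddexp(0.0, eta)).sum(axis=0)
        lp = ll
        lp += (-0.5 * (u ** 2).sum(axis=1) / tau ** 2
               - self.S * np.log(tau))                    # u | tau
        lp += -0.5 * (tau / self.tau_prior_scale) ** 2    # HalfNormal(tau)
        if shape is not None:
            lp += -np.log(shape)                          # flat in log shape
        out = np.where(ok & np.isfinite(lp), lp, -np.inf)
        return out[0] if was_1d else out

    def start(self):
        if self.family == "gamma_log":
            # cell-wise log means via least squares on log y
            beta0, *_ = np.linalg.lstsq(self.X, self.logy, rcond=None)
            x0 = np.concatenate([beta0, [2.0, 0.3], np.zeros(self.S)])
        else:
            pbar = float(np.clip(self.y.mean(), 0.05, 0.95))
            b0 = np.zeros(self.p)
            b0[0] = math.log(pbar / (1 - pbar))
            x0 = np.concatenate([b0, [0.5], np.zeros(self.S)])
        return x0


# ---------------------------------------------------------------------------
# fitting

@dataclass
class FitResult:
    spec: ModelSpec
    coef_names: list[str]
    draws: dict[str, np.ndarray]
    rhat: dict[str, float]
    n_draws: int
    warnings: list[str]

    @property
    def converged(self) -> bool:
        return all(r < RHAT_LIMIT for r in self.rhat.values() if np.isfinite(r))


def _sampler_plan(spec: ModelSpec, ndim: int):
    nw = max(2 * ndim + 2, 2 * spec.chains, 32)
    if nw % 2:
        nw += 1
    post = max(800, math.ceil(spec.total_post_draws / nw))
    warm = max(1200, math.ceil(spec.chains * spec.warmup_draws / nw))
    return nw, warm, post


def fit_model(spec: ModelSpec, data: pd.DataFrame, rng_seed: int = 0) -> FitResult:
    """Fit one mixed model; returns named posterior draws plus a convergence
    report (split-chain Rhat, flagged at >= 1.1)."""
    y = data[spec.response].to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ValueError("response contains missing values")
    X, names, subj, n_cells = build_design(data, spec)

    if spec.family == "gamma_log":
        if (y <= 0).any():
            raise ValueError("gamma_log requires strictly positive responses")
        model = _ExplicitGlmm("gamma_log", y, X, subj)
        x0 = model.start()
        scalar_names = ["shape", "tau"]
    elif spec.family == "bernoulli_logit":
        if not np.isin(y, (0.0, 1.0)).all():
            raise ValueError("bernoulli_logit requires a 0/1 response")
        if y.min() == y.max():
            _warnings.warn("all outcomes identical: complete separation; "
                           "slope posterior will be prior-dominated")
        model = _ExplicitGlmm("bernoulli_logit", y, X, subj)
        x0 = model.start()
        scalar_names = ["tau"]
    else:
        if spec.family == "shifted_lognormal_identity":
            if (y <= spec.shift).any():
                raise ValueError("responses must exceed the lognormal shift")
            yt = np.log(y - spec.shift)
        else:
            yt = y
        prior_scale = max(2.5 * float(np.std(yt)), 1e-3)
        model = _MarginalGaussian(yt, X, subj, n_cells,
                                  spec.random_cell_effects, prior_scale)
        x0 = model.start(yt, X, subj)
        scalar_names = ["sigma", "tau0"] + (["tau1"] if spec.random_cell_effects else [])

    nw, warm, post = _sampler_plan(spec, model.ndim)
    chain, rhat, n_draws = sample_posterior(model, x0, seed=rng_seed,
                                            n_walkers=nw, warmup_steps=warm,
                                            post_steps=post)
    flat = chain.reshape(-1, model.ndim)
    p = len(names)
    draws = {name: flat[:, j] for j, name in enumerate(names)}
    for j, nm in enumerate(scalar_names):
        draws[nm] = flat[:, p + j]
    rhat_map = {name: float(rhat[j]) for j, name in enumerate(names)}
    for j, nm in enumerate(scalar_names):
        rhat_map[nm] = float(rhat[p + j])
    warns = [f"Rhat {v:.3f} >= {RHAT_LIMIT} for {k}"
             for k, v in rhat_map.items() if np.isfinite(v) and v >= RHAT_LIMIT]
    for w in warns:
        _warnings.warn(w)
    return FitResult(spec, names, draws, rhat_map, n_draws, warns)


# ---------------------------------------------------------------------------
# contrasts

@dataclass
class ContrastDef:
    """Linear combination of coefficient cells on the model's link scale.

    With ``plus``/``minus``, the contrast is mean(plus) - mean(minus) (a
    marginal-mean comparison, emmeans-style).  ``weights`` overrides this with
    an explicit cell -> coefficient map, e.g. a {+1, +1, -1, -1} double
    difference for interaction (ratio-of-ratios) contrasts.
    """

    name: str
    plus: list[str] = field(default_factory=list)
    minus: list[str] = field(default_factory=list)
    weights: dict[str, float] | None = None
    scale: str = "response"   # response | ms | ratio | percent_change | log_odds


def contrast(fit: FitResult, cdef: ContrastDef) -> PosteriorDraws:
    """Per-draw linear combination of cell coefficients, back-transformed to
    the requested reporting scale."""
    cells = (list(cdef.weights) if cdef.weights is not None
             else cdef.plus + cdef.minus)
    if not cells:
        raise ValueError("contrast definition names no coefficients")
    for cell in cells:
        if cell not in fit.draws:
            raise ValueError(f"unknown coefficient {cell!r}; "
                             f"available: {fit.coef_names}")
    if cdef.weights is not None:
        link_draws = sum(w * fit.draws[c] for c, w in cdef.weights.items())
    else:
        plus = np.mean([fit.draws[c] for c in cdef.plus], axis=0)
        minus = (np.mean([fit.draws[c] for c in cdef.minus], axis=0)
                 if cdef.minus else 0.0)
        link_draws = plus - minus
    log_scale_families = ("gamma_log", "shifted_lognormal_identity")
    if cdef.scale == "ratio":
        if fit.spec.family not in log_scale_families:
            raise ValueError("ratio contrasts require a log-scale family")
        d = np.exp(link_draws)
    elif cdef.scale == "percent_change":
        if fit.spec.family not in log_scale_families:
            raise ValueError("percent-change contrasts require a log-scale family")
        d = 100.0 * (np.exp(link_draws) - 1.0)
    else:
        d = link_draws
    return PosteriorDraws(d, cdef.scale, cdef.name)


# ---------------------------------------------------------------------------
# stopping-success logistic model

def stopping_success_model(meps: pd.DataFrame, spec: ModelSpec | None = None,
                           rng_seed: int = 0) -> dict[str, ContrastSummary]:
    """Regress stopping success on CSE amplitude, per stimulation timepoint.

    ``meps`` must carry ``amplitude``, ``success`` (0/1), ``subject_id`` and
    ``tms_timepoint`` restricted to the maybe-stopping hand's CSE records on
    proactive stop trials at IS and IS150.  Returns a slope ContrastSummary
    (log-odds scale, ROPE +/-0.05) per timepoint.
    """
    out: dict[str, ContrastSummary] = {}
    for tp, sub in meps.groupby("tms_timepoint"):
        y = sub["success"].to_numpy(dtype=float)
        if y.min() == y.max():
            _warnings.warn(f"timepoint {tp}: all outcomes identical "
                           "(separation); skipping")
            continue
        mspec = spec or ModelSpec(family="bernoulli_logit", response="success",
                                  covariates=["amplitude"])
        mspec = ModelSpec(family="bernoulli_logit", response="success",
                          covariates=["amplitude"], chains=mspec.chains,
                          warmup_draws=mspec.warmup_draws,
                          post_warmup_draws_per_chain=mspec.post_warmup_draws_per_chain)
        fit = fit_model(mspec, sub, rng_seed=rng_seed)
        pdraws = PosteriorDraws(fit.draws["amplitude"], "log_odds",
                                f"success~CSE@{tp}")
        out[str(tp)] = summarize_contrast(pdraws, rope=(-0.05, 0.05))
    return out
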