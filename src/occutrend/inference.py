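"""Posterior inference for the dynamic occupancy model.

The sampler operates on the z-marginalized likelihood: for each site the
latent occupancy sequence is summed out by a two-state forward recursion, so
the posterior over the (typically ~11) regression-scale parameters is
sampled directly with a componentwise stepping-out slice sampler (Neal 2003,
Ann. Statist. 31:705-767).  Slice sampling needs no tuning beyond an
initial bracket width (adapted during burn-in) and is rejection-free, which
keeps autocorrelation low for these well-identified logistic posteriors.

Latent states are recovered per retained draw by forward-filtering
backward-sampling from their exact full conditional given the parameters,
giving joint posterior draws of (parameters, z) equivalent to a
Gibbs scheme that includes z.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .model import COVARIATES, ParamSet
from .priors import PriorSpec
from .survey import SurveyDataset

__all__ = [
    "McmcConfig",
    "PosteriorDraws",
    "param_names",
    "fit_model",
    "gelman_rubin",
    "flag_nonconverged",
    "summarize_posterior",
    "predict_psi_frame",
]


def param_names(
    n_transitions: int,
    share_transitions: bool = False,
    interaction: bool = False,
) -> list[str]:
    """Canonical parameter ordering used throughout fitting and summaries."""
    names = ["beta0"] + [f"beta_{c}" for c in COVARIATES]
    if n_transitions > 0:
        if share_transitions:
            names += ["a", "b"]
        else:
            names += [f"a[{t}]" for t in range(2, n_transitions + 2)]
            names += [f"b[{t}]" for t in range(2, n_transitions + 2)]
    if interaction:
        names += ["beta_interaction"]
    names += ["alpha0", "alpha1"]
    return names


@dataclass
class McmcConfig:
    """MCMC settings.

    ``n_retained`` is the total post-burn-in, post-thinning draw count pooled
    across chains (the per-chain count is ``ceil(n_retained / n_chains)``).
    Defaults mirror a standard three-chain budget: 5,000 burn-in, 10,000
    retained thinned by 3.  ``seed`` must be set explicitly.
    """

    seed: int
    n_chains: int = 3
    n_burnin: int = 5000
    n_retained: int = 10000
    thin: int = 3
    init_jitter: float = 0.1

    def __post_init__(self):
        for name in ("n_chains", "n_burnin", "n_retained", "thin"):
            if getattr(self, name) < (0 if name == "n_burnin" else 1):
                raise ValueError(f"{name} must be positive")
        if self.seed is None:
            raise ValueError("seed must be set explicitly")

    @property
    def n_keep_per_chain(self) -> int:
        return math.ceil(self.n_retained / self.n_chains)

    def to_dict(self) -> dict:
        return {
            "seed": int(self.seed),
            "n_chains": self.n_chains,
            "n_burnin": self.n_burnin,
            "n_retained": self.n_retained,
            "thin": self.thin,
            "init_jitter": self.init_jitter,
        }


@dataclass
class PosteriorDraws:
    """MCMC output: (chain, iteration, parameter) draws plus optional z draws."""

    names: list
    values: np.ndarray
    z_draws: np.ndarray | None = None
    config_echo: dict = field(default_factory=dict)
    n_transitions: int = 0
    share_transitions: bool = False
    interaction: bool = False
    years: tuple = ()

    def __post_init__(self):
        if self.values.ndim != 3 or self.values.shape[2] != len(self.names):
            raise ValueError("values must be (chains, iterations, parameters)")
        if not np.isfinite(self.values).all():
            raise ValueError("non-finite values in posterior draws")

    @property
    def chains(self) -> int:
        return self.values.shape[0]

    @property
    def iterations(self) -> int:
        return self.values.shape[1]

    def to_matrix(self) -> np.ndarray:
        """(chains * iterations, parameters), chains stacked."""
        return self.values.reshape(-1, len(self.names))

    def index(self, name: str) -> int:
        return self.names.index(name)

    def get(self, name: str) -> np.ndarray:
        """All draws of one parameter, pooled across chains."""
        return self.to_matrix()[:, self.index(name)]

    def paramset(self, vector: np.ndarray) -> ParamSet:
        """Unpack one draw vector into a :class:`ParamSet`."""
        return _unpack(vector, self.names, self.n_transitions,
                       self.share_transitions, self.interaction)

    def to_frame(self) -> pd.DataFrame:
        """Long-format (chain, iteration, parameter, value) table."""
        ch, it, k = self.values.shape
        rows = {
            "chain": np.repeat(np.arange(1, ch + 1), it * k),
            "iteration": np.tile(np.repeat(np.arange(1, it + 1), k), ch),
            "parameter": np.tile(self.names, ch * it),
            "value": self.values.reshape(-1),
        }
        return pd.DataFrame(rows)


def _unpack(vec, names, n_transitions, share_transitions, interaction) -> ParamSet:
    vec = np.asarray(vec, dtype=float)
    d = dict(zip(names, vec))
    k = len(COVARIATES)
    beta = np.array([d[f"beta_{c}"] for c in COVARIATES])
    if n_transitions == 0:
        a = np.zeros(0)
        b = np.zeros(0)
    elif share_transitions:
        a = np.full(n_transitions, d["a"])
        b = np.full(n_transitions, d["b"])
    else:
        a = np.array([d[f"a[{t}]"] for t in range(2, n_transitions + 2)])
        b = np.array([d[f"b[{t}]"] for t in range(2, n_transitions + 2)])
    return ParamSet(
        beta0=d["beta0"], beta=beta, a=a, b=b,
        alpha0=d["alpha0"], alpha1=d["alpha1"],
        beta_interaction=d.get("beta_interaction"),
    )


# ---------------------------------------------------------------------------
# fast marginal posterior
# ---------------------------------------------------------------------------

def _softplus(x):
    return np.logaddexp(0.0, x)


class _MarginalPosterior:
    """Precomputed z-marginalized log-posterior over the packed vector.

    Detection contributions under z = 0 do not depend on the parameters
    (they are 0 or -inf), so they are precomputed once; per evaluation only
    the z = 1 detection sums and the two-state forward recursion are redone.
    """

    def __init__(self, data: SurveyDataset, priors: PriorSpec,
                 share_transitions=False, interaction=False):
        self.data = data
        n, T, J = data.y.shape
        self.n, self.T = n, T
        self.share = share_transitions
        self.interaction = interaction
        self.names = param_names(T - 1, share_transitions, interaction)
        self.K = len(self.names)

        self.X = np.ascontiguousarray(np.asarray(data.covariates, dtype=float))
        self.precip = self.X[:, COVARIATES.index("precipitation")]

        obs = ~np.isnan(data.y)
        self.cell = np.flatnonzero(obs.reshape(n * T, J).any(axis=1))  # unused fast path aid
        flat_obs = obs.reshape(-1)
        self.obs_cell_index = (np.arange(n * T * J) // J)[flat_obs]
        self.y_obs = data.y.reshape(-1)[flat_obs]
        self.date_obs = data.date.reshape(-1)[flat_obs]
        self.y_is_one = self.y_obs == 1.0

        any_det = np.nan_to_num(data.y, nan=0.0).max(axis=2) > 0
        self.ld0 = np.where(any_det, -np.inf, 0.0)  # log P(y_t | z_t = 0)

        self.prior_mean, self.prior_sd = priors.arrays(self.names)
        # last-value caches; componentwise samplers leave the detection
        # sums (alphas fixed) or the covariate projection (betas fixed)
        # unchanged for most evaluations
        self._ld1_key = None
        self._ld1 = None
        self._xb_key = None
        self._xb = None
        # slices into the packed vector
        kcov = len(COVARIATES)
        self.s_beta0 = 0
        self.s_beta = slice(1, 1 + kcov)
        na = 1 if share_transitions else (T - 1)
        self.na = na if T > 1 else 0
        off = 1 + kcov
        self.s_a = slice(off, off + self.na)
        self.s_b = slice(off + self.na, off + 2 * self.na)
        off += 2 * self.na
        self.s_int = off if interaction else None
        if interaction:
            off += 1
        self.s_alpha0 = off
        self.s_alpha1 = off + 1

    # -- pieces ---------------------------------------------------------
    def _detection_ld1(self, alpha0, alpha1):
        """log P(y_t | z_t = 1) per (site, season); cached on (alpha0, alpha1)."""
        key = (alpha0, alpha1)
        if key == self._ld1_key:
            return self._ld1
        eta = alpha0 + alpha1 * self.date_obs
        contrib = np.where(self.y_is_one, -_softplus(-eta), -_softplus(eta))
        self._ld1 = np.bincount(
            self.obs_cell_index, weights=contrib, minlength=self.n * self.T
        ).reshape(self.n, self.T)
        self._ld1_key = key
        return self._ld1

    def _covariate_projection(self, beta):
        key = tuple(beta)
        if key == self._xb_key:
            return self._xb
        self._xb = self.X @ beta
        self._xb_key = key
        return self._xb

    def _transition_etas(self, vec, Xb, t):
        """(eta | z_prev = 0, eta | z_prev = 1) linear predictors, season t+2."""
        a = vec[self.s_a]
        b = vec[self.s_b]
        k = 0 if self.share else t
        eta0 = a[k] + Xb
        eta1 = eta0 + b[k]
        if self.s_int is not None:
            eta1 = eta1 + vec[self.s_int] * self.precip
        return eta0, eta1

    def loglik(self, vec) -> float:
        l0, l1 = self._forward(vec)[-1]
        return float(np.logaddexp(l0, l1).sum())

    def _forward(self, vec):
        """Forward log-filter; returns list of (l0, l1) per season where
        l_z = log P(z_t = z, y_{1..t}) per site."""
        Xb = self._covariate_projection(vec[self.s_beta])
        ld1 = self._detection_ld1(vec[self.s_alpha0], vec[self.s_alpha1])
        eta_psi = vec[self.s_beta0] + Xb
        states = []
        l1 = -_softplus(-eta_psi) + ld1[:, 0]
        l0 = -_softplus(eta_psi) + self.ld0[:, 0]
        states.append((l0, l1))
        for t in range(self.T - 1):
            eta0, eta1 = self._transition_etas(vec, Xb, t)
            new_l1 = np.logaddexp(l0 - _softplus(-eta0), l1 - _softplus(-eta1)) + ld1[:, t + 1]
            new_l0 = np.logaddexp(l0 - _softplus(eta0), l1 - _softplus(eta1)) + self.ld0[:, t + 1]
            l0, l1 = new_l0, new_l1
            states.append((l0, l1))
        return states

    def logpost(self, vec) -> float:
        lp = -0.5 * float(
            (((vec - self.prior_mean) / self.prior_sd) ** 2).sum()
        )
        return lp + self.loglik(vec)

    __call__ = logpost

    # -- latent states ---------------------------------------------------
    def sample_z(self, vec, rng) -> np.ndarray:
        """Backward-sample z ~ P(z | y, theta) for all sites; (n, T) int8."""
        states = self._forward(vec)
        n, T = self.n, self.T
        z = np.empty((n, T), dtype=np.int8)
        l0, l1 = states[-1]
        z[:, T - 1] = rng.random(n) < expit(l1 - l0)
        if T > 1:
            Xb = self._covariate_projection(vec[self.s_beta])
        for t in range(T - 2, -1, -1):
            eta0, eta1 = self._transition_etas(vec, Xb, t)
            znext = z[:, t + 1]
            # log P(z_{t+1} | z_t = 0 / 1)
            lt0 = np.where(znext == 1, -_softplus(-eta0), -_softplus(eta0))
            lt1 = np.where(znext == 1, -_softplus(-eta1), -_softplus(eta1))
            l0, l1 = states[t]
            z[:, t] = rng.random(n) < expit((l1 + lt1) - (l0 + lt0))
        return z


# ---------------------------------------------------------------------------
# slice sampler
# ---------------------------------------------------------------------------

_MAX_STEPOUT = 50


def _slice_update(logpost, x, lp, k, w, rng):
    """One stepping-out slice update of component k; mutates x in place."""
    logy = lp + np.log(rng.random())
    xk = x[k]
    L = xk - w * rng.random()
    R = L + w

    x[k] = L
    fL = logpost(x)
    steps = _MAX_STEPOUT
    while fL > logy and steps > 0:
        L -= w
        x[k] = L
        fL = logpost(x)
        steps -= 1
    x[k] = R
    fR = logpost(x)
    steps = _MAX_STEPOUT
    while fR > logy and steps > 0:
        R += w
        x[k] = R
        fR = logpost(x)
        steps -= 1

    while True:
        v = L + (R - L) * rng.random()
        x[k] = v
        fv = logpost(x)
        if fv >= logy:
            return fv
        if v < xk:
            L = v
        else:
            R = v


def _run_chain(logpost, x0, widths, n_burn, n_keep, thin, rng):
    x = np.array(x0, dtype=float)
    K = x.size
    widths = np.array(widths, dtype=float)
    lp = logpost(x)
    if not np.isfinite(lp):
        raise RuntimeError("initial state has non-finite log posterior")
    keep = np.empty((n_keep, K))
    recent = np.empty((200, K))
    ri = 0
    total = n_burn + n_keep * thin
    kept = 0
    for it in range(total):
        for k in range(K):
            lp = _slice_update(logpost, x, lp, k, widths[k], rng)
        if it < n_burn:
            recent[ri % 200] = x
            ri += 1
            if ri % 200 == 0:
                sd = recent.std(axis=0)
                widths = np.where(sd > 1e-3, 2.5 * sd, widths)
        else:
            if (it - n_burn) % thin == thin - 1:
                keep[kept] = x
                kept += 1
    return keep[:kept]


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def fit_model(
    data: SurveyDataset,
    priors: PriorSpec,
    config: McmcConfig,
    share_transitions: bool = False,
    interaction: bool = False,
    store_z: bool = True,
) -> PosteriorDraws:
    """Sample the posterior over all model parameters (and latent states).

    Runs ``config.n_chains`` independent slice-sampling chains on the
    z-marginalized posterior, each with a distinct sub-seed derived from
    ``config.seed``; identical configs reproduce identical draws.  When
    ``store_z`` is set, a latent-state draw is generated for every retained
    parameter draw by forward-filtering backward-sampling.
    """
    data.validate()
    post = _MarginalPosterior(data, priors, share_transitions, interaction)
    names = post.names
    prior_mean, prior_sd = post.prior_mean, post.prior_sd

    seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    n_keep = config.n_keep_per_chain
    chains_out = []
    z_out = [] if store_z else None
    for c in range(config.n_chains):
        rng = np.random.default_rng(seeds[c])
        x0 = prior_mean + config.init_jitter * rng.standard_normal(post.K)
        widths = np.clip(prior_sd, 0.25, 3.0)
        keep = _run_chain(
            post, x0, widths, config.n_burnin, n_keep, config.thin, rng
        )
        chains_out.append(keep)
        if store_z:
            zc = np.empty((keep.shape[0], post.n, post.T), dtype=np.int8)
            for m in range(keep.shape[0]):
                zc[m] = post.sample_z(keep[m], rng)
            z_out.append(zc)

    values = np.stack(chains_out)
    return PosteriorDraws(
        names=names,
        values=values,
        z_draws=np.stack(z_out) if store_z else None,
        config_echo=config.to_dict(),
        n_transitions=data.n_seasons - 1,
        share_transitions=share_transitions,
        interaction=interaction,
        years=data.years,
    )


def attach_z(draws: PosteriorDraws, data: SurveyDataset, seed: int = 0) -> PosteriorDraws:
    """Regenerate latent-state draws for an existing parameter posterior.

    z | y, theta does not depend on the priors, so any fit loaded from disk
    (which stores only parameter draws) can have its z draws re-sampled by
    forward-filtering backward-sampling, seed-controlled.
    """
    from .priors import vague_priors

    post = _MarginalPosterior(
        data, vague_priors(draws.names),
        draws.share_transitions, draws.interaction,
    )
    rng = np.random.default_rng(seed)
    z = np.empty(
        (draws.chains, draws.iterations, data.n_sites, data.n_seasons),
        dtype=np.int8,
    )
    for c in range(draws.chains):
        for m in range(draws.iterations):
            z[c, m] = post.sample_z(draws.values[c, m], rng)
    draws.z_draws = z
    return draws


# ---------------------------------------------------------------------------
# diagnostics and summaries
# ---------------------------------------------------------------------------

def gelman_rubin(draws: PosteriorDraws) -> pd.Series:
    """Split-chain potential scale reduction factor R-hat per parameter.

    Each chain is split in half, giving 2 x chains sequences; R-hat is
    sqrt(((n-1)/n W + B/n) / W) over those sequences.  Raises for a single
    chain or too-short chains; returns NaN for a degenerate (constant)
    parameter.
    """
    if draws.chains < 2:
        raise ValueError("R-hat needs >= 2 chains")
    n = draws.iterations
    if n < 10:
        raise ValueError("R-hat needs >= 10 iterations per chain")
    half = n // 2
    segs = []
    for c in range(draws.chains):
        segs.append(draws.values[c, :half])
        segs.append(draws.values[c, half:2 * half])
    seq = np.stack(segs)          # (m, half, K)
    m = seq.shape[0]
    means = seq.mean(axis=1)      # (m, K)
    W = seq.var(axis=1, ddof=1).mean(axis=0)
    B_over_n = means.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        var_plus = (half - 1) / half * W + B_over_n
        rhat = np.sqrt(var_plus / W)
    return pd.Series(rhat, index=draws.names, name="rhat")


def flag_nonconverged(rhat: pd.Series, tol: float = 0.1) -> list:
    """Parameters failing the |R-hat - 1| < tol criterion (NaN counts as failing)."""
    bad = ~(np.abs(rhat - 1.0) < tol)
    return list(rhat.index[bad])


def _derived_per_draw(draws: PosteriorDraws) -> dict:
    """Per-draw derived dynamic quantities at the average covariate profile."""
    mat = draws.to_matrix()
    names = draws.names
    Tm1 = draws.n_transitions
    beta0 = mat[:, names.index("beta0")]
    psi = [expit(beta0)]
    out = {}
    for t in range(2, Tm1 + 2):
        a = mat[:, names.index("a" if draws.share_transitions else f"a[{t}]")]
        b = mat[:, names.index("b" if draws.share_transitions else f"b[{t}]")]
        phi = expit(a + b)
        gamma = expit(a)
        out[f"phi[{t}]"] = phi
        out[f"gamma[{t}]"] = gamma
        psi.append(psi[-1] * phi + (1 - psi[-1]) * gamma)
    for t, p in enumerate(psi, start=1):
        out[f"psi[{t}]"] = p
    if Tm1 >= 1:
        lam = psi[-1] / psi[0]
        out["lambda_total"] = lam
        out["lambda_annual"] = lam ** (1.0 / Tm1)
    return out


def summarize_posterior(draws: PosteriorDraws, derived: bool = True) -> pd.DataFrame:
    """Posterior mean, SD and equal-tailed 95% interval per parameter.

    With ``derived=True``, also summarizes phi_t, gamma_t, the psi trajectory
    at average covariates, and the growth rates lambda — each computed per
    draw and then summarized, never from summarized parameters.
    """
    cols = {name: draws.get(name) for name in draws.names}
    if derived:
        cols.update(_derived_per_draw(draws))
    rows = []
    for name, v in cols.items():
        q = np.quantile(v, [0.025, 0.975])
        rows.append((name, v.mean(), v.std(ddof=1), q[0], q[1]))
    return pd.DataFrame(
        rows, columns=["parameter", "mean", "sd", "q2.5", "q97.5"]
    ).set_index("parameter")


def psi_draws_for_sites(draws: PosteriorDraws, covariates, year_index: int,
                        chunk: int = 1000) -> np.ndarray:
    """Per-draw occupancy probability psi[draw, site] for one season.

    ``covariates`` is an (n, 4) standardized array/DataFrame;
    ``year_index`` is 0-based.  The site-level recursion
    psi_{t+1,i} = psi_{t,i} phi_{t,i} + (1 - psi_{t,i}) gamma_{t,i} is run
    with each draw's parameters.
    """
    X = np.asarray(covariates, dtype=float)
    mat = draws.to_matrix()
    names = draws.names
    M = mat.shape[0]
    beta_cols = [names.index(f"beta_{c}") for c in COVARIATES]
    out = np.empty((M, X.shape[0]))
    for lo in range(0, M, chunk):
        sub = mat[lo:lo + chunk]
        Xb = sub[:, beta_cols] @ X.T                      # (m, n)
        psi = expit(sub[:, [names.index("beta0")]] + Xb)
        for t in range(2, year_index + 2):
            a = sub[:, [names.index("a" if draws.share_transitions else f"a[{t}]")]]
            b = sub[:, [names.index("b" if draws.share_transitions else f"b[{t}]")]]
            gamma = expit(a + Xb)
            phi = expit(a + b + Xb)
            psi = psi * phi + (1 - psi) * gamma
        out[lo:lo + sub.shape[0]] = psi
    return out


def _resolve_year_index(draws: PosteriorDraws, year) -> int:
    T = draws.n_transitions + 1
    if year is None:
        return T - 1
    if draws.years and year in draws.years:
        return draws.years.index(year)
    if 1 <= year <= T:
        return int(year) - 1
    raise ValueError(f"year {year} not in {draws.years} nor in 1..{T}")


def predict_psi_frame(
    draws: PosteriorDraws,
    frame_covariates: pd.DataFrame,
    year=None,
    scaler=None,
    cell_id=None,
) -> pd.DataFrame:
    """Posterior mean and SD of psi for every frame cell in a given season.

    Frame covariates must be on the same standardized scale as the fitted
    data: pass raw-named columns (forest_pct, ...) together with the fit's
    stored ``scaler`` to transform here, or already-standardized canonical
    columns.  Raw columns without a scaler raise.
    """
    from .survey import RAW_COVARIATE_COLUMNS

    cov = frame_covariates
    if any(c in cov.columns for c in RAW_COVARIATE_COLUMNS):
        if scaler is None:
            raise ValueError(
                "frame covariates look unstandardized (raw column names); "
                "pass the scaler stored with the fitted dataset"
            )
        cov = scaler.transform(cov.rename(columns=RAW_COVARIATE_COLUMNS))
    cov = cov[list(COVARIATES)]
    yi = _resolve_year_index(draws, year)
    psi = psi_draws_for_sites(draws, cov, yi)
    if cell_id is None:
        cell_id = (
            frame_covariates["cell_id"].to_numpy()
            if "cell_id" in frame_covariates.columns
            else np.arange(1, len(cov) + 1)
        )
    return pd.DataFrame(
        {"cell_id": cell_id, "psi_mean": psi.mean(axis=0), "psi_sd": psi.std(axis=0)}
    )
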