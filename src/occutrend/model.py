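"""Core equations of the autoregressive multi-season (dynamic) occupancy model.

The model describes detection/nondetection data ``y[i, t, j]`` for sites
``i = 1..n``, seasons ``t = 1..T`` and within-season visits ``j = 1..J``:

* initial occupancy      ``z[i,1] ~ Bernoulli(psi1_i)`` with
  ``logit(psi1_i) = beta0 + x_i' beta``;
* transitions            ``z[i,t] | z[i,t-1] ~ Bernoulli(pi_ti)`` with
  ``logit(pi_ti) = a_t + b_t z[i,t-1] + x_i' beta`` (autologistic form);
* detection              ``y[i,t,j] | z[i,t] ~ Bernoulli(p_itj * z[i,t])``
  with ``logit(p_itj) = alpha0 + alpha1 * date_itj``.

The autologistic parameterization yields the derived dynamic rates
``phi_t = expit(a_t + b_t)`` (persistence) and ``gamma_t = expit(a_t)``
(colonization), the recursive occupancy trajectory
``psi_t = psi_{t-1} phi_t + (1 - psi_{t-1}) gamma_t`` and the occurrence
growth rate ``lambda = psi_T / psi_1`` used as the regional trend metric.

Detection is false-negative only: an observed detection at an unoccupied
site has probability zero, so such configurations have log-likelihood -inf.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logit  # noqa: F401  (logit re-exported for callers)

#: canonical order of the site-level occupancy covariates
COVARIATES = ("forest", "elevation", "precipitation", "roughness")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ParamSet:
    """All free parameters of the dynamic occupancy model.

    ``beta`` follows the order of :data:`COVARIATES`.  ``a`` and ``b`` hold one
    entry per season transition (t = 2..T); with ``share_transitions`` fits
    they still carry T-1 (identical) entries here for uniformity.
    ``beta_interaction`` is the optional precipitation x z(t-1) transition
    term; ``None`` means the interaction is disabled.
    """

    beta0: float
    beta: np.ndarray
    a: np.ndarray
    b: np.ndarray
    alpha0: float
    alpha1: float
    beta_interaction: float | None = None

    def __post_init__(self) -> None:
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        self.a = np.atleast_1d(np.asarray(self.a, dtype=float))
        self.b = np.atleast_1d(np.asarray(self.b, dtype=float))
        if self.a.shape != self.b.shape:
            raise ValueError(
                f"a and b must have equal length, got {self.a.size} and {self.b.size}"
            )
        vals = np.concatenate(
            [self.beta, self.a, self.b,
             [self.beta0, self.alpha0, self.alpha1],
             [] if self.beta_interaction is None else [self.beta_interaction]]
        )
        if not np.all(np.isfinite(vals)):
            raise ValueError("all parameters must be finite")

    @property
    def n_transitions(self) -> int:
        return self.a.size


@dataclass
class LatentStates:
    """Latent occupancy states z[i, t] in {0, 1}."""

    z: np.ndarray

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z)
        if not np.isin(self.z, (0, 1)).all():
            raise ValueError("z entries must be 0 or 1")


@dataclass
class DerivedDynamics:
    """Derived dynamic parameters at a reference covariate profile (usually 0)."""

    phi: np.ndarray
    gamma: np.ndarray
    psi: np.ndarray
    lambda_total: float
    lambda_annual: float

    def __post_init__(self) -> None:
        for name in ("phi", "gamma", "psi"):
            v = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, v)
            if ((v < 0) | (v > 1)).any():
                raise ValueError(f"{name} must lie in [0, 1]")


# ---------------------------------------------------------------------------
# covariate standardization
# ---------------------------------------------------------------------------

@dataclass
class Scaler:
    """Per-column (mean, sd) pairs; population-SD convention.

    Serialized alongside fits so that frame-wide prediction can apply the
    identical transform used at fitting time.
    """

    means: dict = field(default_factory=dict)
    sds: dict = field(default_factory=dict)

    def transform(self, table):
        out = table.copy()
        for col in self.means:
            out[col] = (table[col] - self.means[col]) / self.sds[col]
        return out

    def inverse_transform(self, table):
        out = table.copy()
        for col in self.means:
            out[col] = table[col] * self.sds[col] + self.means[col]
        return out

    def to_dict(self) -> dict:
        return {"means": dict(self.means), "sds": dict(self.sds)}

    @classmethod
    def from_dict(cls, d: dict) -> "Scaler":
        return cls(means=dict(d["means"]), sds=dict(d["sds"]))


def standardize_covariates(raw_table):
    """Mean-center and scale each column to unit (population) SD.

    Returns ``(standardized_table, scaler)``.  Raises ``ValueError`` naming
    the offending column when a covariate has zero variance.
    """
    scaler = Scaler()
    out = raw_table.copy()
    for col in raw_table.columns:
        x = np.asarray(raw_table[col], dtype=float)
        m = float(np.mean(x))
        s = float(np.std(x))  # population convention (ddof=0)
        if s == 0.0:
            raise ValueError(f"zero variance in covariate column '{col}'")
        scaler.means[col] = m
        scaler.sds[col] = s
        out[col] = (x - m) / s
    return out, scaler


# ---------------------------------------------------------------------------
# model equations
# ---------------------------------------------------------------------------

def initial_occupancy_prob(params: ParamSet, site_covs) -> np.ndarray:
    """First-season occupancy probability psi1 per site.

    ``site_covs`` is an (n, k) array (or DataFrame) of standardized
    covariates matching ``params.beta``.
    """
    x = np.asarray(site_covs, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    if x.shape[1] != params.beta.size:
        raise ValueError(
            f"covariate/coefficient mismatch: {x.shape[1]} columns "
            f"vs {params.beta.size} slopes"
        )
    return expit(params.beta0 + x @ params.beta)


def transition_prob(params: ParamSet, site_covs, z_prev, t: int) -> np.ndarray:
    """Occupancy transition probability pi_ti for season t (2 <= t <= T).

    ``z_prev`` is the previous-season occupancy state (0/1, scalar or per
    site).  With the optional interaction enabled the linear predictor gains
    ``beta_interaction * precipitation_i * z_prev``.
    """
    T = params.n_transitions + 1
    if not (2 <= t <= T):
        raise ValueError(f"t must be in [2, {T}], got {t}")
    x = np.asarray(site_covs, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    if x.shape[1] != params.beta.size:
        raise ValueError("covariate/coefficient mismatch")
    z_prev = np.asarray(z_prev, dtype=float)
    k = t - 2
    eta = params.a[k] + params.b[k] * z_prev + x @ params.beta
    if params.beta_interaction is not None:
        precip = x[:, COVARIATES.index("precipitation")]
        eta = eta + params.beta_interaction * precip * z_prev
    return expit(eta)


def derived_dynamics(a_t: float, b_t: float) -> tuple[float, float]:
    """Persistence and colonization implied by one transition's (a_t, b_t).

    phi = expit(a + b), gamma = expit(a).  Accepts arrays elementwise.
    """
    a_t = np.asarray(a_t, dtype=float)
    b_t = np.asarray(b_t, dtype=float)
    phi = expit(a_t + b_t)
    gamma = expit(a_t)
    if phi.ndim == 0:
        return float(phi), float(gamma)
    return phi, gamma


def occupancy_recursion(psi_prev, phi_t, gamma_t):
    """One step of psi_t = psi_{t-1} phi_t + (1 - psi_{t-1}) gamma_t."""
    for name, v in (("psi_prev", psi_prev), ("phi_t", phi_t), ("gamma_t", gamma_t)):
        v = np.asarray(v, dtype=float)
        if ((v < 0) | (v > 1)).any():
            raise ValueError(f"{name} must lie in [0, 1]")
    return np.asarray(psi_prev) * np.asarray(phi_t) + (
        1.0 - np.asarray(psi_prev)
    ) * np.asarray(gamma_t)


def psi_trajectory(params: ParamSet, psi1=None) -> np.ndarray:
    """Full occupancy trajectory at the average covariate profile (covs = 0).

    Starting from ``psi1`` (default ``expit(beta0)``), applies the recursion
    through every transition.  Returns an array of length T.
    """
    if psi1 is None:
        psi1 = expit(params.beta0)
    out = [np.asarray(psi1, dtype=float)]
    for k in range(params.n_transitions):
        phi, gamma = derived_dynamics(params.a[k], params.b[k])
        out.append(occupancy_recursion(out[-1], phi, gamma))
    return np.stack(out, axis=-1)


def occurrence_growth_rate(psi_trajectory) -> tuple[float, float]:
    """Trend metric lambda from an occupancy trajectory.

    Returns ``(lambda_total, lambda_annual)`` where
    ``lambda_total = psi_T / psi_1`` and ``lambda_annual`` is its
    per-transition geometric mean ``lambda_total ** (1 / (T - 1))``.
    """
    psi = np.asarray(psi_trajectory, dtype=float)
    T = psi.shape[-1]
    if T < 2:
        raise ValueError("trajectory must span at least 2 seasons")
    psi1 = psi[..., 0]
    if np.any(psi1 == 0):
        raise ValueError("psi in the first season is 0; growth rate undefined")
    lam_total = psi[..., -1] / psi1
    lam_annual = lam_total ** (1.0 / (T - 1))
    if lam_total.ndim == 0:
        return float(lam_total), float(lam_annual)
    return lam_total, lam_annual


def detection_prob(alpha0: float, alpha1: float, date) -> np.ndarray:
    """Per-visit detection probability expit(alpha0 + alpha1 * date)."""
    return expit(alpha0 + alpha1 * np.asarray(date, dtype=float))


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def _log_bernoulli(y, p):
    with np.errstate(divide="ignore"):
        return np.where(y == 1, np.log(p), np.log1p(-p))


def complete_data_loglik(params: ParamSet, z: LatentStates, data) -> float:
    """Joint log-likelihood of latent states and observations.

    Sums ``log P(z_i1) + sum_t log P(z_it | z_i,t-1) + sum_tj log
    P(y_itj | z_it)`` over sites, skipping missing visits.  A detection at an
    unoccupied site-year contributes ``log 0 = -inf`` (no false positives);
    -inf propagates rather than raising.
    """
    zz = np.asarray(z.z if isinstance(z, LatentStates) else z, dtype=float)
    y = data.y
    n, T = zz.shape
    x = np.asarray(data.covariates, dtype=float)

    psi1 = initial_occupancy_prob(params, x)
    total = _log_bernoulli(zz[:, 0], psi1).sum()
    for t in range(2, T + 1):
        pi = transition_prob(params, x, zz[:, t - 2], t)
        total += _log_bernoulli(zz[:, t - 1], pi).sum()

    p = detection_prob(params.alpha0, params.alpha1, data.date)
    obs = ~np.isnan(y)
    with np.errstate(divide="ignore"):
        occ = np.where(y == 1, np.log(p), np.log1p(-p))   # z = 1
    emp = np.where(y == 1, -np.inf, 0.0)                  # z = 0: y must be 0
    det = np.where(zz[:, :, None] == 1, occ, emp)
    total += det[obs].sum()
    return float(total)


def site_marginal_loglik(params: ParamSet, data, site: int) -> float:
    """Marginal log-likelihood of one site's detection history.

    Sums the complete-data likelihood over all 2^T latent sequences by a
    forward recursion over seasons (two-state HMM filter), never by
    enumeration.
    """
    y = data.y[site]
    date = data.date[site]
    x = np.asarray(data.covariates, dtype=float)[site]
    T = y.shape[0]

    p = detection_prob(params.alpha0, params.alpha1, date)
    obs = ~np.isnan(y)

    def emit(t: int) -> tuple[float, float]:
        """(log P(y_t | z=0), log P(y_t | z=1)) for season t."""
        yt, pt, ot = y[t], p[t], obs[t]
        if not ot.any():
            return 0.0, 0.0
        l1 = float(_log_bernoulli(yt[ot], pt[ot]).sum())
        l0 = -np.inf if (yt[ot] == 1).any() else 0.0
        return l0, l1

    psi1 = float(initial_occupancy_prob(params, x[None, :])[0])
    e0, e1 = emit(0)
    with np.errstate(divide="ignore"):
        l0 = np.log1p(-psi1) + e0
        l1 = np.log(psi1) + e1
    for t in range(1, T):
        g = float(transition_prob(params, x[None, :], 0, t + 1)[0])
        f = float(transition_prob(params, x[None, :], 1, t + 1)[0])
        e0, e1 = emit(t)
        with np.errstate(divide="ignore"):
            new_l1 = np.logaddexp(l0 + np.log(g), l1 + np.log(f)) + e1
            new_l0 = np.logaddexp(l0 + np.log1p(-g), l1 + np.log1p(-f)) + e0
        l0, l1 = new_l0, new_l1
    return float(np.logaddexp(l0, l1))


def marginal_loglik(params: ParamSet, data) -> float:
    """Dataset marginal log-likelihood (z summed out), all sites."""
    return float(
        sum(site_marginal_loglik(params, data, i) for i in range(data.n_sites))
    )
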