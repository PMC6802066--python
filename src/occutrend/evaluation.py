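"""Model evaluation: posterior AUC, residual spatial autocorrelation,
and vague-vs-informative prior-sensitivity comparison.

AUC follows the internal-validation convention for occupancy models: for
each retained draw, the model's occupancy probabilities psi_i score that
same draw's latent states z_i, and the resulting AUC distribution is
summarized.  Spatial structure left in the model is probed with Moran's I
on the per-draw occupancy residuals z_i - psi_i at a ladder of distance
thresholds, with a permutation-null p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import gaussian_kde, rankdata

from .inference import PosteriorDraws, _resolve_year_index, psi_draws_for_sites

DEFAULT_THRESHOLDS_KM = (10.0, 20.0, 30.0, 40.0, 50.0)


# ---------------------------------------------------------------------------
# AUC
# ---------------------------------------------------------------------------

def auc_rank(scores, labels) -> float:
    """Rank (Mann-Whitney) AUC: P(random positive outscores random negative),
    ties counted one half.  Requires both classes present."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("labels must contain at least one positive and one negative")
    r = rankdata(scores)
    u = r[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


@dataclass
class AucSummary:
    """Posterior summary of the per-draw AUC for one season."""

    mean: float
    sd: float
    q2_5: float
    q97_5: float
    year: object
    n_draws: int
    n_skipped: int

    def to_dict(self) -> dict:
        return {
            "mean": self.mean, "sd": self.sd,
            "q2.5": self.q2_5, "q97.5": self.q97_5,
            "year": self.year, "n_draws": self.n_draws,
            "n_skipped": self.n_skipped,
        }


def posterior_auc(
    draws: PosteriorDraws,
    data,
    year=None,
    use_z_labels: bool = True,
) -> AucSummary:
    """AUC of psi_i against latent z_i, per retained draw, summarized.

    With ``use_z_labels=False`` the raw ever-detected indicator for the
    season is used as the label instead (conflates detection with
    occupancy; provided for comparison only).  Draws whose labels are
    single-class are skipped and counted.
    """
    yi = _resolve_year_index(draws, year)
    psi = psi_draws_for_sites(draws, data.covariates, yi)
    if use_z_labels:
        if draws.z_draws is None:
            raise ValueError("posterior AUC with z labels requires z_draws")
        labels = draws.z_draws.reshape(-1, data.n_sites, data.n_seasons)[:, :, yi]
    else:
        labels = np.broadcast_to(
            data.ever_detected[:, yi], (psi.shape[0], data.n_sites)
        )
    aucs = []
    skipped = 0
    for m in range(psi.shape[0]):
        lab = labels[m]
        if lab.min() == lab.max():
            skipped += 1
            continue
        aucs.append(auc_rank(psi[m], lab))
    if not aucs:
        raise ValueError("no draws with both occupied and unoccupied sites")
    aucs = np.asarray(aucs)
    q = np.quantile(aucs, [0.025, 0.975])
    yr = draws.years[yi] if draws.years else yi + 1
    return AucSummary(
        mean=float(aucs.mean()), sd=float(aucs.std(ddof=1)) if aucs.size > 1 else 0.0,
        q2_5=float(q[0]), q97_5=float(q[1]),
        year=yr, n_draws=int(aucs.size), n_skipped=skipped,
    )


# ---------------------------------------------------------------------------
# Moran's I
# ---------------------------------------------------------------------------

def _weights(coords, threshold_km: float) -> np.ndarray:
    d = squareform(pdist(np.asarray(coords, dtype=float)))
    w = (d > 0) & (d <= threshold_km)  # closed interval at the threshold
    return w.astype(float)


def morans_i(x, coords, threshold_km: float) -> float:
    """Moran's I with binary distance-threshold weights.

    I = (n / S0) * sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2
    with w_ij = 1 iff 0 < d(i, j) <= threshold (Euclidean km), w_ii = 0.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    w = _weights(coords, threshold_km)
    s0 = w.sum()
    if s0 == 0:
        raise ValueError(f"no neighbor pairs at threshold {threshold_km} km")
    xc = x - x.mean()
    den = float(xc @ xc)
    if den == 0:
        raise ValueError("zero variance in x; Moran's I undefined")
    return float(n / s0 * (xc @ w @ xc) / den)


def moran_permutation_p(x, coords, threshold_km: float, n_perm: int = 999,
                        rng=None) -> tuple[float, float]:
    """One-sided (positive-autocorrelation) permutation p for Moran's I.

    Returns ``(I_observed, p)`` with p = (1 + #{I_perm >= I_obs}) / (n_perm + 1).
    """
    rng = np.random.default_rng(rng)
    x = np.asarray(x, dtype=float)
    n = x.size
    w = _weights(coords, threshold_km)
    s0 = w.sum()
    if s0 == 0:
        raise ValueError(f"no neighbor pairs at threshold {threshold_km} km")
    xc = x - x.mean()
    den = float(xc @ xc)
    if den == 0:
        raise ValueError("zero variance in x; Moran's I undefined")
    i_obs = float(n / s0 * (xc @ w @ xc) / den)
    perms = np.stack([rng.permutation(xc) for _ in range(n_perm)])
    i_perm = n / s0 * np.einsum("pi,ij,pj->p", perms, w, perms) / den
    p = (1.0 + float((i_perm >= i_obs).sum())) / (n_perm + 1.0)
    return i_obs, p


@dataclass
class MoranProfile:
    """Posterior-mean Moran's I of occupancy residuals per distance threshold."""

    thresholds_km: tuple
    I: np.ndarray
    null_mean: float
    p: np.ndarray
    year: object = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"threshold_km": self.thresholds_km, "I": self.I, "p": self.p,
             "null_mean": self.null_mean}
        )


def moran_profile(
    draws: PosteriorDraws,
    data,
    thresholds=DEFAULT_THRESHOLDS_KM,
    n_perm: int = 999,
    seed: int = 0,
    year=None,
) -> MoranProfile:
    """Spatial autocorrelation profile of final-season occupancy residuals.

    Residuals per draw are r_i = z_i - psi_i for the chosen season (default
    the last).  Per threshold, Moran's I is averaged over draws; the
    permutation p-value is computed on the posterior-mean residual vector
    with seed-controlled site-label permutations.
    """
    if draws.z_draws is None:
        raise ValueError("moran_profile requires z_draws")
    yi = _resolve_year_index(draws, year)
    psi = psi_draws_for_sites(draws, data.covariates, yi)
    z = draws.z_draws.reshape(-1, data.n_sites, data.n_seasons)[:, :, yi]
    resid = z - psi                                   # (draws, n)
    rc = resid - resid.mean(axis=1, keepdims=True)
    den = (rc * rc).sum(axis=1)
    n = data.n_sites
    rng = np.random.default_rng(seed)
    i_means, ps = [], []
    rbar = resid.mean(axis=0)
    for thr in thresholds:
        w = _weights(data.coords, thr)
        s0 = w.sum()
        if s0 == 0:
            raise ValueError(f"no neighbor pairs at threshold {thr} km")
        i_draws = n / s0 * ((rc @ w) * rc).sum(axis=1) / den
        i_means.append(float(i_draws.mean()))
        _, p = moran_permutation_p(rbar, data.coords, thr, n_perm=n_perm, rng=rng)
        ps.append(p)
    yr = draws.years[yi] if draws.years else yi + 1
    return MoranProfile(
        thresholds_km=tuple(thresholds),
        I=np.asarray(i_means),
        null_mean=-1.0 / (n - 1),
        p=np.asarray(ps),
        year=yr,
    )


# ---------------------------------------------------------------------------
# prior sensitivity
# ---------------------------------------------------------------------------

def prior_sensitivity(
    draws_vague: PosteriorDraws,
    draws_informative: PosteriorDraws,
    priors_vague=None,
    priors_informative=None,
    grid_points: int = 200,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Compare posteriors under the two prior regimes, parameter by parameter.

    Returns ``(table, densities)``: the table holds posterior mean and SD
    under each regime, the informative/vague SD ratio, and whether the two
    regimes agree on the 95% interval's position relative to zero; the
    densities frame is plotting-ready (parameter, regime, kind in
    {prior, posterior}, grid_value, density), with prior curves included
    when the corresponding :class:`~occutrend.priors.PriorSpec` is given.
    """
    if list(draws_vague.names) != list(draws_informative.names):
        raise ValueError("parameter sets differ between the two fits")
    rows = []
    dens_rows = []
    regimes = (
        ("vague", draws_vague, priors_vague),
        ("informative", draws_informative, priors_informative),
    )
    for name in draws_vague.names:
        stats = {}
        for regime, draws, priors in regimes:
            v = draws.get(name)
            lo, hi = np.quantile(v, [0.025, 0.975])
            stats[regime] = (v.mean(), v.std(ddof=1), lo, hi)
            grid = np.linspace(v.min() - 3 * v.std(), v.max() + 3 * v.std(),
                               grid_points)
            kde = gaussian_kde(v)
            dens_rows.append(pd.DataFrame({
                "parameter": name, "regime": regime, "kind": "posterior",
                "grid_value": grid, "density": kde(grid),
            }))
            if priors is not None and name in priors:
                pr = priors[name]
                pgrid = np.linspace(pr.mean - 4 * pr.sd, pr.mean + 4 * pr.sd,
                                    grid_points)
                dens_rows.append(pd.DataFrame({
                    "parameter": name, "regime": regime, "kind": "prior",
                    "grid_value": pgrid,
                    "density": np.exp(pr.logpdf(pgrid)),
                }))
        mv, sv, lov, hiv = stats["vague"]
        mi, si, loi, hii = stats["informative"]

        def _pos(lo, hi):
            return "above0" if lo > 0 else ("below0" if hi < 0 else "spans0")

        rows.append({
            "parameter": name,
            "mean_vague": mv, "sd_vague": sv,
            "mean_informative": mi, "sd_informative": si,
            "sd_ratio": si / sv,
            "ci_position_vague": _pos(lov, hiv),
            "ci_position_informative": _pos(loi, hii),
            "sign_agreement": _pos(lov, hiv) == _pos(loi, hii),
        })
    table = pd.DataFrame(rows).set_index("parameter")
    densities = pd.concat(dens_rows, ignore_index=True)
    return table, densities
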