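"""Survey dataset container: detection histories, visit dates, covariates.

A :class:`SurveyDataset` holds the binary-or-missing detection array
``y[i, t, j]`` together with standardized visit dates, standardized site
covariates and projected site coordinates (km).  Construction from the raw
CSV column conventions lives in :mod:`occutrend.io`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import COVARIATES, Scaler, standardize_covariates

#: raw sites.csv column -> canonical covariate name
RAW_COVARIATE_COLUMNS = {
    "forest_pct": "forest",
    "elev_m": "elevation",
    "precip_mm": "precipitation",
    "rough_sd_m": "roughness",
}


@dataclass
class SurveyDataset:
    """Detection/nondetection histories with covariates and coordinates.

    ``y`` uses NaN for missing visits; ``date`` is standardized day-of-year
    (NaN wherever ``y`` is missing).  ``covariates`` is an (n, 4) DataFrame
    in :data:`~occutrend.model.COVARIATES` order, already standardized; the
    scalers used are retained for frame-wide prediction and back-transforms.
    """

    site_id: np.ndarray
    y: np.ndarray
    date: np.ndarray
    covariates: pd.DataFrame
    coords: np.ndarray
    years: tuple
    cov_scaler: Scaler = field(default_factory=Scaler)
    date_scaler: tuple = (0.0, 1.0)

    def __post_init__(self) -> None:
        self.site_id = np.asarray(self.site_id)
        self.y = np.asarray(self.y, dtype=float)
        self.date = np.asarray(self.date, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        self.years = tuple(self.years)
        self.validate()

    # -- dimensions -----------------------------------------------------
    @property
    def n_sites(self) -> int:
        return self.y.shape[0]

    @property
    def n_seasons(self) -> int:
        return self.y.shape[1]

    @property
    def n_visits(self) -> int:
        return self.y.shape[2]

    @property
    def ever_detected(self) -> np.ndarray:
        """Per (site, season) indicator of >=1 detection (ignoring missing)."""
        return np.nan_to_num(self.y, nan=0.0).max(axis=2).astype(int)

    def validate(self) -> None:
        if self.y.ndim != 3:
            raise ValueError("y must be (sites, seasons, visits)")
        n, T, J = self.y.shape
        if n < 1 or T < 1 or J < 1:
            raise ValueError("need n >= 1, T >= 1, J >= 1")
        obs = ~np.isnan(self.y)
        vals = self.y[obs]
        if not np.isin(vals, (0.0, 1.0)).all():
            raise ValueError("y entries must be 0, 1 or missing (NaN)")
        if not obs.any(axis=(1, 2)).all():
            raise ValueError("every site needs >=1 non-missing visit")
        if np.isnan(self.date[obs]).any():
            raise ValueError("observed visits must carry a date")
        if self.date.shape != self.y.shape:
            raise ValueError("date must match y's shape")
        if len(self.years) != T:
            raise ValueError("years must have one entry per season")
        if list(self.covariates.columns) != list(COVARIATES):
            raise ValueError(f"covariate columns must be {COVARIATES}")
        if len(self.covariates) != n or self.coords.shape != (n, 2):
            raise ValueError("covariates/coords must have one row per site")
        if self.cov_scaler.means:
            cov = np.asarray(self.covariates, dtype=float)
            if (np.abs(cov.mean(axis=0)) > 1e-9).any() or (
                np.abs(cov.std(axis=0) - 1) > 1e-9
            ).any():
                raise ValueError("covariates are not standardized")

    # -- constructors ---------------------------------------------------
    @classmethod
    def from_arrays(
        cls,
        y: np.ndarray,
        date_raw: np.ndarray,
        raw_covariates: pd.DataFrame,
        coords: np.ndarray,
        years,
        site_id=None,
    ) -> "SurveyDataset":
        """Build from raw (unstandardized) dates and covariates.

        ``raw_covariates`` may use either the raw CSV column names or the
        canonical covariate names.  Dates are raw day-of-year values and are
        standardized here with the population-SD convention over observed
        visits.
        """
        y = np.asarray(y, dtype=float)
        if site_id is None:
            site_id = np.arange(1, y.shape[0] + 1)
        cov = raw_covariates.rename(columns=RAW_COVARIATE_COLUMNS)
        cov = cov[list(COVARIATES)]
        cov_std, scaler = standardize_covariates(cov)

        date_raw = np.asarray(date_raw, dtype=float)
        obs = ~np.isnan(y)
        dm = float(np.nanmean(np.where(obs, date_raw, np.nan)))
        ds = float(np.nanstd(np.where(obs, date_raw, np.nan)))
        if ds == 0.0:
            ds = 1.0
        date_std = np.where(obs, (date_raw - dm) / ds, np.nan)
        return cls(
            site_id=np.asarray(site_id),
            y=y,
            date=date_std,
            covariates=cov_std,
            coords=coords,
            years=years,
            cov_scaler=scaler,
            date_scaler=(dm, ds),
        )

    def check_single_visit(self) -> None:
        if self.n_visits == 1:
            warnings.warn(
                "single-visit design (J = 1): detection and occupancy are "
                "only weakly separable",
                UserWarning,
                stacklevel=2,
            )
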