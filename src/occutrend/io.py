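"""Plain-text file formats: survey CSVs, prior JSON, posterior tables.

Conventions:

* ``detections.csv`` — site_id, year, visit, detected (0/1/empty =
  missing), date (ISO yyyy-mm-dd).
* ``sites.csv`` — site_id, x_km, y_km, forest_pct, elev_m, precip_mm,
  rough_sd_m (raw units; standardization happens on load).
* ``priors.json`` — {"param": {"family": "normal", "mean": m, "sd": s},
  ..., "provenance": ...}.
* ``posterior.csv`` — long format chain, iteration, parameter, value.
"""

from __future__ import annotations

import datetime as _dt
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .inference import PosteriorDraws
from .model import Scaler
from .priors import PriorSpec
from .survey import RAW_COVARIATE_COLUMNS, SurveyDataset


def _doy_to_iso(year: int, doy: float) -> str:
    d = _dt.date(int(year), 1, 1) + _dt.timedelta(days=int(round(doy)) - 1)
    return d.isoformat()


def _iso_to_doy(iso: str) -> float:
    d = _dt.date.fromisoformat(iso)
    return float(d.timetuple().tm_yday)


# ---------------------------------------------------------------------------
# survey data
# ---------------------------------------------------------------------------

def write_survey(data: SurveyDataset, detections_path, sites_path) -> None:
    """Write a dataset to the detections.csv / sites.csv pair."""
    dm, ds = data.date_scaler
    rows = []
    for i in range(data.n_sites):
        for t, year in enumerate(data.years):
            for j in range(data.n_visits):
                yij = data.y[i, t, j]
                if np.isnan(yij):
                    rows.append((data.site_id[i], year, j + 1, "", ""))
                else:
                    doy = data.date[i, t, j] * ds + dm
                    rows.append(
                        (data.site_id[i], year, j + 1, int(yij),
                         _doy_to_iso(year, doy))
                    )
    det = pd.DataFrame(rows, columns=["site_id", "year", "visit", "detected", "date"])
    det.to_csv(detections_path, index=False)

    raw = data.cov_scaler.inverse_transform(data.covariates)
    inv = {v: k for k, v in RAW_COVARIATE_COLUMNS.items()}
    sites = pd.DataFrame({"site_id": data.site_id})
    sites["x_km"] = data.coords[:, 0]
    sites["y_km"] = data.coords[:, 1]
    for canon, rawname in inv.items():
        sites[rawname] = np.asarray(raw[canon])
    sites.to_csv(sites_path, index=False)


def read_survey(detections_path, sites_path) -> SurveyDataset:
    """Load a detections.csv / sites.csv pair into a :class:`SurveyDataset`."""
    det = pd.read_csv(detections_path, dtype={"detected": "Int64"})
    sites = pd.read_csv(sites_path)
    site_ids = sites["site_id"].to_numpy()
    order = {sid: k for k, sid in enumerate(site_ids)}
    years = tuple(sorted(det["year"].unique()))
    yidx = {yr: t for t, yr in enumerate(years)}
    J = int(det["visit"].max())
    n, T = len(site_ids), len(years)

    y = np.full((n, T, J), np.nan)
    date = np.full((n, T, J), np.nan)
    for row in det.itertuples(index=False):
        if pd.isna(row.detected):
            continue
        i = order[row.site_id]
        t = yidx[row.year]
        j = int(row.visit) - 1
        y[i, t, j] = float(row.detected)
        date[i, t, j] = _iso_to_doy(str(row.date))
    return SurveyDataset.from_arrays(
        y=y,
        date_raw=date,
        raw_covariates=sites,
        coords=sites[["x_km", "y_km"]].to_numpy(dtype=float),
        years=years,
        site_id=site_ids,
    )


# ---------------------------------------------------------------------------
# priors / truth / scalers
# ---------------------------------------------------------------------------

def write_priors(priors: PriorSpec, path) -> None:
    Path(path).write_text(json.dumps(priors.to_dict(), indent=1) + "\n")


def read_priors(path) -> PriorSpec:
    return PriorSpec.from_dict(json.loads(Path(path).read_text()))


def write_json(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, default=_jsonable) + "\n")


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")


def write_scaler(scaler: Scaler, path) -> None:
    write_json(scaler.to_dict(), path)


def read_scaler(path) -> Scaler:
    return Scaler.from_dict(read_json(path))


# ---------------------------------------------------------------------------
# posterior tables
# ---------------------------------------------------------------------------

def write_posterior(draws: PosteriorDraws, path, meta_path=None) -> None:
    """Long-format posterior.csv; sampler metadata to a JSON sidecar."""
    draws.to_frame().to_csv(path, index=False)
    if meta_path is not None:
        write_json(
            {
                "names": list(draws.names),
                "config": draws.config_echo,
                "n_transitions": draws.n_transitions,
                "share_transitions": draws.share_transitions,
                "interaction": draws.interaction,
                "years": list(draws.years),
            },
            meta_path,
        )


def read_posterior(path, meta_path=None) -> PosteriorDraws:
    df = pd.read_csv(path)
    names = list(df["parameter"].unique())
    chains = int(df["chain"].max())
    its = int(df["iteration"].max())
    values = np.empty((chains, its, len(names)))
    pidx = {p: k for k, p in enumerate(names)}
    values[
        df["chain"].to_numpy() - 1,
        df["iteration"].to_numpy() - 1,
        df["parameter"].map(pidx).to_numpy(),
    ] = df["value"].to_numpy()
    meta = read_json(meta_path) if meta_path else {}
    n_trans = meta.get("n_transitions")
    if n_trans is None:
        n_trans = sum(1 for p in names if p.startswith("a[") or p == "a")
    return PosteriorDraws(
        names=names,
        values=values,
        config_echo=meta.get("config", {}),
        n_transitions=n_trans,
        share_transitions=bool(meta.get("share_transitions", False)),
        interaction=bool(meta.get("interaction", False)),
        years=tuple(meta.get("years", ())),
    )
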