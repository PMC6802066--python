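"""Prior construction: vague priors and empirically informed prior updating.

The package's Bayesian scaffolding works by carrying a monitoring period's
posterior summaries (per-parameter mean and SD) forward as independent
Normal priors for the next period's model.  Detection-level parameters
(alpha0, alpha1) always receive vague priors, since survey methodology and
call-identification workflows typically change between periods.

"Normal(0, 10)" vague priors are interpreted as variance 10 by default
(sd = sqrt(10) ~ 3.16), the BUGS precision-0.1 idiom: an SD of 10 on the
logit scale would not be regularizing.  The convention is switchable via
``scale_convention`` in {"sd", "variance", "precision"}.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from math import sqrt

import numpy as np

#: bundled period-1 (2010) posterior summaries usable as informed priors
SPECIES_TABLES = ("hoary", "little_brown")

_DETECTION_PARAMS = ("alpha0", "alpha1")


@dataclass(frozen=True)
class NormalPrior:
    mean: float
    sd: float

    def __post_init__(self):
        if not self.sd > 0:
            raise ValueError(f"prior sd must be > 0, got {self.sd}")

    def logpdf(self, x):
        return -0.5 * ((x - self.mean) / self.sd) ** 2 - np.log(self.sd) - 0.5 * np.log(2 * np.pi)


@dataclass
class PriorSpec:
    """Named independent Normal priors, one per free model parameter."""

    entries: dict = field(default_factory=dict)
    provenance: str = "vague"

    def __getitem__(self, name: str) -> NormalPrior:
        return self.entries[name]

    def __contains__(self, name: str) -> bool:
        return name in self.entries

    def names(self):
        return list(self.entries)

    def require(self, param_names) -> None:
        missing = [p for p in param_names if p not in self.entries]
        if missing:
            raise ValueError(f"priors missing for parameters: {missing}")

    def arrays(self, param_names):
        """(means, sds) aligned with ``param_names``."""
        self.require(param_names)
        m = np.array([self.entries[p].mean for p in param_names])
        s = np.array([self.entries[p].sd for p in param_names])
        return m, s

    def to_dict(self) -> dict:
        d = {
            name: {"family": "normal", "mean": pr.mean, "sd": pr.sd}
            for name, pr in self.entries.items()
        }
        d["provenance"] = self.provenance
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PriorSpec":
        prov = d.get("provenance", "unknown")
        entries = {
            name: NormalPrior(spec["mean"], spec["sd"])
            for name, spec in d.items()
            if name != "provenance"
        }
        return cls(entries=entries, provenance=prov)


def _vague_sd(scale: float, convention: str) -> float:
    if convention == "sd":
        return scale
    if convention == "variance":
        return sqrt(scale)
    if convention == "precision":
        return sqrt(1.0 / scale)
    raise ValueError("scale_convention must be 'sd', 'variance' or 'precision'")


def vague_priors(
    param_names, scale: float = 10.0, scale_convention: str = "variance"
) -> PriorSpec:
    """Vague Normal(0, 10) priors for every named parameter.

    By default the 10 is a variance (sd ~ 3.16); pass
    ``scale_convention="sd"`` for Normal(0, sd=10).
    """
    param_names = list(param_names)
    if not param_names:
        raise ValueError("param_names is empty")
    sd = _vague_sd(scale, scale_convention)
    return PriorSpec(
        entries={p: NormalPrior(0.0, sd) for p in param_names},
        provenance="vague",
    )


def informative_priors(
    period1_summary: dict,
    param_names,
    vague_scale: float = 10.0,
    scale_convention: str = "variance",
    provenance: str = "period1-posterior",
) -> PriorSpec:
    """Empirically informed priors from a previous period's posterior summary.

    ``period1_summary`` maps occupancy-level parameter names to
    ``(mean, sd)``.  The transition entries ``"a"`` and ``"b"`` are applied
    identically to every transition of the new model (keys like ``a[2]``),
    since a single posterior pair summarizes the earlier period's dynamics.
    Detection-level parameters are never taken from the summary; they always
    get vague priors ("from scratch").
    """
    entries = {}
    missing = []
    for name in param_names:
        if name in _DETECTION_PARAMS:
            entries[name] = NormalPrior(0.0, _vague_sd(vague_scale, scale_convention))
            continue
        base = name.split("[")[0]  # a[2] -> a
        src = period1_summary.get(name, period1_summary.get(base))
        if src is None:
            missing.append(name)
            continue
        mean, sd = float(src[0]), float(src[1])
        if not sd > 0:
            raise ValueError(f"nonpositive prior sd for '{name}': {sd}")
        entries[name] = NormalPrior(mean, sd)
    if missing:
        raise ValueError(f"period-1 summary missing occupancy-level parameters: {missing}")
    return PriorSpec(entries=entries, provenance=provenance)


def posterior_to_prior(draws, params=None) -> dict:
    """Summarize posterior draws into a (mean, sd) map for prior scaffolding.

    ``draws`` is a :class:`~occutrend.inference.PosteriorDraws`.  The output
    plugs directly into :func:`informative_priors`.  Requires >= 100 retained
    draws for stable moments and rejects degenerate (constant) draws.
    """
    mat = draws.to_matrix()
    names = list(draws.names)
    if mat.shape[0] < 100:
        raise ValueError(
            f"need >= 100 retained draws for stable prior moments, got {mat.shape[0]}"
        )
    params = list(params) if params is not None else names
    out = {}
    for p in params:
        col = mat[:, names.index(p)]
        sd = float(col.std())
        if sd <= 1e-12 * max(1.0, abs(float(col.mean()))):
            raise ValueError(f"degenerate (constant) posterior draws for '{p}'")
        out[p] = (float(col.mean()), sd)
    return out


def expand_for_model(
    spec: PriorSpec,
    param_names,
    vague_scale: float = 10.0,
    scale_convention: str = "variance",
) -> PriorSpec:
    """Align a PriorSpec with a model's full parameter list.

    Entries may be keyed by exact parameter names or by base names
    (``a`` covering ``a[2]``, ``a[3]``...).  Detection parameters missing
    from the spec receive vague priors; a missing occupancy-level parameter
    raises.
    """
    entries = {}
    for name in param_names:
        src = spec.entries.get(name) or spec.entries.get(name.split("[")[0])
        if src is not None:
            entries[name] = src
        elif name in _DETECTION_PARAMS:
            entries[name] = NormalPrior(0.0, _vague_sd(vague_scale, scale_convention))
        else:
            raise ValueError(f"prior spec has no entry for parameter '{name}'")
    return PriorSpec(entries=entries, provenance=spec.provenance)


def load_species_table(species: str) -> dict:
    """Bundled 2010 posterior summaries (mean, sd) for a monitored species.

    Keys: beta0, a, b, beta_forest, beta_elevation, beta_precipitation,
    beta_roughness.  ``species`` is one of :data:`SPECIES_TABLES`.
    """
    if species not in SPECIES_TABLES:
        raise ValueError(f"unknown species table '{species}'; have {SPECIES_TABLES}")
    ref = resources.files("occutrend.data").joinpath(f"{species}.json")
    d = json.loads(ref.read_text())
    return {k: (v["mean"], v["sd"]) for k, v in d.items()}
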