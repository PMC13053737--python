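"""Functional Aging Index (FAI) construction.

The FAI is a T-scored composite of four functional components measured at each
visit:

* **grip strength** -- regression-adjusted for sex (residual from an
  intercept + sex fit on the baseline reference), then reverse scored;
* **peak expiratory flow (PEF)** -- adjusted for body volume by dividing by
  squared height in metres, then reverse scored;
* **gait** -- time-to-walk, higher already means poorer;
* **sensory** -- self-reported vision and hearing difficulty, each z-scored
  and averaged into a single component.

Each component is z-scored against baseline (first visit per person) means and
SDs frozen in a :class:`StandardizationSpec`; grip and PEF z-scores are sign
flipped so that higher always means poorer functioning.  The composite is the
mean of the available component z-scores (at least ``min_components``), then
re-standardized against the baseline composite distribution and mapped to the
T-score metric 50 + 10 z.  Higher FAI = poorer functioning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .data_model import CohortTable

__all__ = [
    "StandardizationSpec",
    "adjust_grip",
    "adjust_pef",
    "fit_standardization",
    "score_fai",
]

COMPONENTS = ["grip", "pef", "gait", "sensory"]

#: Components whose raw direction is "higher = better" and must be reversed.
DEFAULT_REVERSE = {"grip": True, "pef": True, "gait": False, "sensory": False}


class EstimationError(ValueError):
    """The reference subset cannot support the requested adjustment."""


@dataclass
class StandardizationSpec:
    """Frozen baseline standardization parameters for FAI scoring.

    Estimated once from a declared baseline reference subset and then applied
    unchanged to every wave, so follow-up scores stay on the baseline metric.
    """

    component_means: dict[str, float]
    component_sds: dict[str, float]
    reverse_flags: dict[str, bool] = field(default_factory=lambda: dict(DEFAULT_REVERSE))
    grip_sex_model: tuple[float, float] = (0.0, 0.0)  # (intercept, male coefficient)
    sensory_item_stats: dict[str, tuple[float, float]] = field(default_factory=dict)
    composite_mean: float = 0.0
    composite_sd: float = 1.0
    tscore_mean: float = 50.0
    tscore_sd: float = 10.0

    def __post_init__(self):
        for name, sd in self.component_sds.items():
            if not sd > 0:
                raise ValueError(f"component {name!r} has non-positive SD {sd}")

    def to_yaml(self, path) -> None:
        payload = {
            "component_means": {k: float(v) for k, v in self.component_means.items()},
            "component_sds": {k: float(v) for k, v in self.component_sds.items()},
            "reverse_flags": {k: bool(v) for k, v in self.reverse_flags.items()},
            "grip_sex_model": [float(x) for x in self.grip_sex_model],
            "sensory_item_stats": {k: [float(a), float(b)] for k, (a, b) in self.sensory_item_stats.items()},
            "composite_mean": float(self.composite_mean),
            "composite_sd": float(self.composite_sd),
            "tscore_mean": float(self.tscore_mean),
            "tscore_sd": float(self.tscore_sd),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh)

    @classmethod
    def from_yaml(cls, path) -> "StandardizationSpec":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["grip_sex_model"] = tuple(d["grip_sex_model"])
        d["sensory_item_stats"] = {k: tuple(v) for k, v in d["sensory_item_stats"].items()}
        return cls(**d)


def fit_grip_sex_model(grip: np.ndarray, sex_male: np.ndarray) -> tuple[float, float]:
    """OLS fit of grip on intercept + male indicator over the reference subset."""
    mask = np.isfinite(grip) & np.isfinite(sex_male)
    g, s = np.asarray(grip, float)[mask], np.asarray(sex_male, float)[mask]
    if len(np.unique(s)) < 2 or (s == 1).sum() < 2 or (s == 0).sum() < 2:
        raise EstimationError("grip sex-adjustment needs >=2 observations of each sex")
    X = np.column_stack([np.ones_like(s), s])
    beta, *_ = np.linalg.lstsq(X, g, rcond=None)
    return float(beta[0]), float(beta[1])


def adjust_grip(grip, sex_male, model: tuple[float, float]):
    """Residual of grip strength on the (frozen) intercept + sex fit."""
    grip = np.asarray(grip, float)
    sex_male = np.asarray(sex_male, float)
    return grip - (model[0] + model[1] * sex_male)


def adjust_pef(pef, height_m):
    """Body-volume-adjusted peak expiratory flow: pef / height_m**2."""
    pef = np.asarray(pef, float)
    height_m = np.asarray(height_m, float)
    if np.any(height_m[np.isfinite(height_m)] <= 0):
        raise ValueError("height_m must be positive")
    return pef / height_m**2


def _component_frame(frame: pd.DataFrame, spec_or_model) -> pd.DataFrame:
    """Raw -> adjusted component values (grip residual, PEF/h^2, gait, sensory)."""
    out = pd.DataFrame(index=frame.index)
    if isinstance(spec_or_model, StandardizationSpec):
        grip_model = spec_or_model.grip_sex_model
        item_stats = spec_or_model.sensory_item_stats
    else:
        grip_model, item_stats = spec_or_model
    out["grip"] = adjust_grip(frame["grip"], frame["sex_male"], grip_model)
    out["pef"] = adjust_pef(frame["pef"], frame["height_m"])
    out["gait"] = frame["gait"].astype(float)
    zs = []
    for item in ("vision_self", "hearing_self"):
        m, s = item_stats[item]
        zs.append((frame[item].astype(float) - m) / s)
    out["sensory"] = pd.concat(zs, axis=1).mean(axis=1, skipna=True)
    return out


def baseline_mask(frame: pd.DataFrame) -> pd.Series:
    """First (youngest-age) visit per person."""
    first_age = frame.groupby("person_id")["age_years"].transform("min")
    return frame["age_years"] == first_age


def fit_standardization(
    cohort: CohortTable,
    reverse_flags: dict[str, bool] | None = None,
    min_components: int = 3,
) -> StandardizationSpec:
    """Estimate and freeze the FAI standardization from the baseline subset.

    The baseline reference is each person's first visit.  Grip sex adjustment,
    sensory item z-scoring, per-component means/SDs and the baseline composite
    distribution are all estimated here and never updated afterwards.
    """
    frame = cohort.analysis_frame()
    base = frame[baseline_mask(frame)]
    reverse = dict(DEFAULT_REVERSE if reverse_flags is None else reverse_flags)

    grip_model = fit_grip_sex_model(base["grip"].to_numpy(float), base["sex_male"].to_numpy(float))
    item_stats = {}
    for item in ("vision_self", "hearing_self"):
        x = base[item].astype(float)
        sd = x.std(ddof=1)
        if not sd > 0:
            sd = 1.0
        item_stats[item] = (float(x.mean()), float(sd))

    comps = _component_frame(base, (grip_model, item_stats))
    means = {c: float(comps[c].mean()) for c in COMPONENTS}
    sds = {}
    for c in COMPONENTS:
        sd = float(comps[c].std(ddof=1))
        sds[c] = sd if sd > 0 else 1.0

    spec = StandardizationSpec(
        component_means=means,
        component_sds=sds,
        reverse_flags=reverse,
        grip_sex_model=grip_model,
        sensory_item_stats=item_stats,
    )
    composite = _composite(base, spec, min_components)
    mu, sd = float(np.nanmean(composite)), float(np.nanstd(composite, ddof=1))
    spec.composite_mean = mu
    spec.composite_sd = sd if sd > 0 else 1.0
    return spec


def _composite(frame: pd.DataFrame, spec: StandardizationSpec, min_components: int) -> np.ndarray:
    comps = _component_frame(frame, spec)
    z = pd.DataFrame(index=frame.index)
    for c in COMPONENTS:
        zc = (comps[c] - spec.component_means[c]) / spec.component_sds[c]
        z[c] = -zc if spec.reverse_flags.get(c, False) else zc
    n_used = z.notna().sum(axis=1)
    composite = z.mean(axis=1, skipna=True).to_numpy(float)
    composite[n_used.to_numpy() < min_components] = np.nan
    return composite


def score_fai(cohort: CohortTable, spec: StandardizationSpec, min_components: int = 3) -> pd.DataFrame:
    """Score every visit against a frozen standardization spec.

    Returns a frame with ``person_id``, ``age_years``, ``fai`` (T-score units,
    NaN when fewer than ``min_components`` components are available) and
    ``n_components_used``.
    """
    frame = cohort.analysis_frame()
    comps = _component_frame(frame, spec)
    n_used = comps.notna().sum(axis=1)
    composite = _composite(frame, spec, min_components)
    z = (composite - spec.composite_mean) / spec.composite_sd
    fai = spec.tscore_mean + spec.tscore_sd * z
    return pd.DataFrame(
        {
            "person_id": frame["person_id"].to_numpy(),
            "age_years": frame["age_years"].to_numpy(float),
            "fai": fai,
            "n_components_used": n_used.to_numpy(int),
        }
    )
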