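"""Synthetic longitudinal twin cohorts with ACE-structured SES.

The generator emulates the statistical structure the co-twin analysis
assumes.  Per pair it draws three unit-variance latent factors:

* **A** (additive genetic): correlated 1.0 within MZ pairs, 0.5 within DZ;
* **C** (shared environment): identical within pair;
* **E** (unique environment): independent across members.

Observed SES is ``mean + sd * (a A + c C + e E)`` with loadings the square
roots of the ACE variance shares.  Each person's growth trajectory is a
two-slope spline with intercept at age 75 and per-decade slopes; the SES
latent value and the A/C factors feed the trajectory through three
configurable cross-paths:

* ``delta`` -- the direct (causal) path from standardized SES;
* ``kappa_a`` -- a genetic confounding path (A influences both SES and the
  outcome);
* ``kappa_c`` -- a shared-environment confounding path.

Cross-paths act on the intercept by default and optionally on slope 1.
Closed-form expected between/within regression coefficients
(:func:`oracle_coefficients`) serve as the analytic oracle for the whole
design: the within-MZ coefficient equals ``delta`` whatever the confounding
paths, which is precisely the inferential claim of the co-twin design.

Ages at baseline are uniform on a configurable range inside 42-93 years,
waves are 2-4 years apart with monotone per-wave attrition, so follow-up
spans 0 to roughly 27 years, the shape of pooled longitudinal twin studies
of aging.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

from .data_model import CohortTable

__all__ = [
    "ACEComponents",
    "solve_ace",
    "SimConfig",
    "simulate_cohort",
    "OracleCoefficients",
    "oracle_coefficients",
    "scenario_config",
    "SCENARIOS",
]


@dataclass
class ACEComponents:
    """Standardized biometrical variance shares (a2 + c2 + e2 = 1)."""

    a2: float
    c2: float
    e2: float
    boundary: bool = False  # True when the raw Falconer solution was inadmissible

    def __post_init__(self):
        total = self.a2 + self.c2 + self.e2
        if not np.isclose(total, 1.0, atol=1e-8):
            raise ValueError(f"a2 + c2 + e2 must be 1, got {total}")
        if min(self.a2, self.c2, self.e2) < -1e-12:
            raise ValueError("variance shares must be nonnegative")

    @property
    def loadings(self) -> tuple[float, float, float]:
        return (float(np.sqrt(self.a2)), float(np.sqrt(self.c2)), float(np.sqrt(self.e2)))

    @property
    def r_mz(self) -> float:
        return self.a2 + self.c2

    @property
    def r_dz(self) -> float:
        return 0.5 * self.a2 + self.c2


def solve_ace(r_mz: float, r_dz: float) -> ACEComponents:
    """Falconer point decomposition from twin correlations.

    a2 = 2 (r_MZ - r_DZ), c2 = r_MZ - a2, e2 = 1 - r_MZ.  When the raw
    solution leaves [0, 1] (e.g. r_MZ > 2 r_DZ gives c2 < 0, or r_MZ < r_DZ
    gives a2 < 0) the offending components are truncated to the boundary and
    the remainder renormalized to sum to 1, with ``boundary=True``.
    """
    for r in (r_mz, r_dz):
        if not -1 <= r <= 1:
            raise ValueError("twin correlations must lie inside [-1, 1]")
    a2 = 2.0 * (r_mz - r_dz)
    c2 = r_mz - a2
    e2 = 1.0 - r_mz
    if a2 >= 0 and c2 >= 0 and e2 >= 0:
        return ACEComponents(a2, c2, e2)
    a2, c2, e2 = (max(x, 0.0) for x in (a2, c2, e2))
    total = a2 + c2 + e2
    if total <= 0:
        return ACEComponents(0.0, 0.0, 1.0, boundary=True)
    return ACEComponents(a2 / total, c2 / total, e2 / total, boundary=True)


@dataclass
class SimConfig:
    """Generating conditions for a synthetic twin cohort.

    Defaults reflect the pooled three-study conditions the analysis emulates:
    142 MZ and 371 DZ pairs (about half the DZ pairs opposite-sex), baseline
    ages uniform on 42-93, up to 8 waves 2-4 years apart with 30% per-wave
    attrition (mean about 3.3 waves, follow-up 0 to ~27 years), FAI-like
    outcome on the T metric with per-decade slopes, and ISEI-like SES
    (mean 36, SD 19) with ACE shares from published ISEI twin correlations.
    Cross-paths default to zero (no SES-outcome relation).
    """

    n_pairs_mz: int = 142
    n_pairs_dz: int = 371
    dz_opposite_sex_fraction: float = 0.5
    ses_ace: ACEComponents = field(default_factory=lambda: solve_ace(0.53, 0.29))
    ses_mean: float = 36.0
    ses_sd: float = 19.0
    ses_name: str = "ses"
    mu_intercept: float = 47.5
    mu_slope1: float = 4.4
    mu_slope2: float = 9.9
    beta_sex_male: float = -2.9
    pair_sd: tuple[float, float, float] = (3.5, 0.8, 1.2)  # intercept, slope1, slope2
    individual_sd: tuple[float, float, float] = (3.5, 0.8, 1.2)
    residual_sd: float = 4.0
    delta: float = 0.0  # direct SES->intercept path, T units per latent-SES SD
    delta_slope1: float = 0.0
    kappa_a: float = 0.0  # genetic confound path on the intercept
    kappa_c: float = 0.0  # shared-environment confound path on the intercept
    kappa_a_slope1: float = 0.0
    kappa_c_slope1: float = 0.0
    age_min: float = 42.0
    age_max: float = 93.0
    n_waves: int = 8
    wave_spacing: tuple[float, float] = (2.0, 4.0)
    dropout: float = 0.3
    baseline_year: int = 1990

    def __post_init__(self):
        if min(*self.pair_sd, *self.individual_sd, self.residual_sd) < 0:
            raise ValueError("SDs must be nonnegative")
        if not 0 <= self.dropout <= 1 or not 0 <= self.dz_opposite_sex_fraction <= 1:
            raise ValueError("probabilities must lie in [0, 1]")
        if self.n_waves > 1 and self.wave_spacing[0] <= 0:
            raise ValueError("wave spacing must be positive")

    def to_yaml_dict(self) -> dict:
        d = self.__dict__.copy()
        d["ses_ace"] = {"a2": self.ses_ace.a2, "c2": self.ses_ace.c2, "e2": self.ses_ace.e2}
        for k in ("pair_sd", "individual_sd", "wave_spacing"):
            d[k] = list(d[k])
        return d

    @classmethod
    def from_yaml_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if isinstance(d.get("ses_ace"), dict):
            d["ses_ace"] = ACEComponents(**{k: v for k, v in d["ses_ace"].items()})
        for k in ("pair_sd", "individual_sd", "wave_spacing"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


# ordinal cutpoints chosen so marginals resemble the pooled study descriptives
_ISCED_PROBS = np.array([0.18, 0.32, 0.20, 0.12, 0.08, 0.05, 0.03, 0.015, 0.005])
_SEI_PROBS = np.array([0.28, 0.40, 0.25, 0.07])
_ITEM_PROBS = np.array([0.25, 0.25, 0.25, 0.25])


def _discretize(latent: np.ndarray, probs: np.ndarray, lowest: int) -> np.ndarray:
    cuts = norm.ppf(np.cumsum(probs)[:-1])
    return lowest + np.searchsorted(cuts, latent)


def simulate_cohort(config: SimConfig, seed: int, include_biomarkers: bool = True) -> tuple[CohortTable, dict]:
    """Draw a full synthetic cohort; byte-reproducible from (config, seed).

    Returns ``(cohort, truth)``.  ``truth`` holds the latent side tables:
    ``truth["persons"]`` with the A/C/E draws, standardized SES and the true
    growth coefficients, and ``truth["visits"]`` with the noiseless mean and
    realized outcome per retained visit.  The cohort's visit table carries the
    realized outcome ``y`` and, when ``include_biomarkers``, grip/PEF/gait/
    sensory measurements derived from the latent trajectory so the FAI
    pipeline can be exercised end to end.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n_mz, n_dz = config.n_pairs_mz, config.n_pairs_dz
    n_pairs = n_mz + n_dz
    zyg = np.array(["MZ"] * n_mz + ["DZ"] * n_dz)

    a_corr = np.where(zyg == "MZ", 1.0, 0.5)
    A1 = rng.standard_normal(n_pairs)
    A2 = a_corr * A1 + np.sqrt(1.0 - a_corr**2) * rng.standard_normal(n_pairs)
    A = np.column_stack([A1, A2])
    C = np.repeat(rng.standard_normal(n_pairs)[:, None], 2, axis=1)
    E = rng.standard_normal((n_pairs, 2))

    a, c, e = config.ses_ace.loadings
    ses_latent = a * A + c * C + e * E
    ses_obs = config.ses_mean + config.ses_sd * ses_latent

    # sex composition: MZ same-sex; DZ opposite-sex with configured fraction
    sex = np.empty((n_pairs, 2), dtype=object)
    mz_female = rng.random(n_mz) < 0.5
    sex[:n_mz, 0] = sex[:n_mz, 1] = np.where(mz_female, "female", "male")
    opp = rng.random(n_dz) < config.dz_opposite_sex_fraction
    dz_first_female = rng.random(n_dz) < 0.5
    first = np.where(dz_first_female, "female", "male")
    sex[n_mz:, 0] = first
    sex[n_mz:, 1] = np.where(opp, np.where(dz_first_female, "male", "female"), first)
    sex_male = (sex == "male").astype(float)

    u_pair = rng.standard_normal((n_pairs, 3)) * np.asarray(config.pair_sd)
    u_ind = rng.standard_normal((n_pairs, 2, 3)) * np.asarray(config.individual_sd)

    intercept = (
        config.mu_intercept
        + config.beta_sex_male * sex_male
        + config.delta * ses_latent
        + config.kappa_a * A
        + config.kappa_c * C
        + u_pair[:, [0]]
        + u_ind[:, :, 0]
    )
    slope1 = (
        config.mu_slope1
        + config.delta_slope1 * ses_latent
        + config.kappa_a_slope1 * A
        + config.kappa_c_slope1 * C
        + u_pair[:, [1]]
        + u_ind[:, :, 1]
    )
    slope2 = config.mu_slope2 + u_pair[:, [2]] + u_ind[:, :, 2]

    base_age = rng.uniform(config.age_min, config.age_max, size=n_pairs)
    if config.n_waves > 1:
        spacings = rng.uniform(*config.wave_spacing, size=(n_pairs, config.n_waves - 1))
        offsets = np.concatenate([np.zeros((n_pairs, 1)), np.cumsum(spacings, axis=1)], axis=1)
    else:
        offsets = np.zeros((n_pairs, 1))
    wave_ages = np.round(base_age[:, None] + offsets, 2)  # shared visit schedule per pair
    # monotone attrition: a person who misses a wave is gone for good
    surv = rng.random((n_pairs, 2, config.n_waves)) >= config.dropout
    surv[:, :, 0] = True
    retained = np.cumprod(surv, axis=2).astype(bool)

    # person-level ordinal SES plumbing
    isced = _discretize(ses_latent, _ISCED_PROBS, 0)
    isei = np.clip(np.round(ses_obs), 15, 89).astype(int)
    parental_latent = 0.6 * C[:, [0]] + 0.8 * rng.standard_normal((n_pairs, 1))
    parental_sei = np.repeat(_discretize(parental_latent, _SEI_PROBS, 1), 2, axis=1)
    strain = -0.6 * ses_latent + 0.8 * rng.standard_normal((n_pairs, 2))
    fs = np.stack(
        [
            _discretize(0.7 * strain + 0.71 * rng.standard_normal((n_pairs, 2)), _ITEM_PROBS, 1)
            for _ in range(4)
        ],
        axis=2,
    )
    height = np.round(np.where(sex_male == 1.0, 1.77, 1.64) + 0.06 * rng.standard_normal((n_pairs, 2)), 3)

    pair_ids = np.array([f"P{b:05d}" for b in range(n_pairs)])
    person_ids = np.char.add(np.repeat(pair_ids, 2), np.tile(np.array(["_1", "_2"]), n_pairs))

    persons = pd.DataFrame(
        {
            "person_id": person_ids,
            "pair_id": np.repeat(pair_ids, 2),
            "zygosity": np.repeat(zyg, 2),
            "sex": sex.ravel(),
            "birth_year": np.repeat(np.round(config.baseline_year - base_age).astype(int), 2),
            "study_label": np.repeat(
                np.where(zyg == "MZ", "SIM-A", np.where(np.concatenate([np.zeros(n_mz, bool), opp]), "SIM-C", "SIM-B")),
                2,
            ),
            "isced": isced.ravel(),
            "isei": isei.ravel(),
            "parental_sei": parental_sei.ravel(),
            "fs1": fs[:, :, 0].ravel(),
            "fs2": fs[:, :, 1].ravel(),
            "fs3": fs[:, :, 2].ravel(),
            "fs4": fs[:, :, 3].ravel(),
        }
    )
    persons[config.ses_name] = ses_obs.ravel()

    # visits, fully vectorized over (pair, member, wave)
    t = (wave_ages[:, None, :] - 75.0) / 10.0  # (n_pairs, 1, n_waves)
    mean_y = intercept[:, :, None] + slope1[:, :, None] * np.minimum(t, 0.0) + slope2[:, :, None] * np.maximum(t, 0.0)
    y = mean_y + rng.standard_normal((n_pairs, 2, config.n_waves)) * config.residual_sd
    keep = retained.ravel()
    pid_v = np.repeat(person_ids, config.n_waves)[keep]
    age_v = np.broadcast_to(wave_ages[:, None, :], (n_pairs, 2, config.n_waves)).ravel()[keep]
    y_v = y.ravel()[keep]
    visits = pd.DataFrame({"person_id": pid_v, "age_years": age_v})
    extra_visit_cols = ["y"]
    if include_biomarkers:
        dev = y - 50.0
        noise = rng.standard_normal((n_pairs, 2, config.n_waves, 4))
        grip = 33.0 + 11.0 * sex_male[:, :, None] - 0.45 * dev + 2.0 * noise[..., 0]
        pef = (95.0 - 1.1 * dev + 6.0 * noise[..., 1]) * (height[:, :, None] ** 2)
        gait = 11.0 + 0.22 * dev + 1.2 * noise[..., 2]
        sens = 2.5 + 0.05 * dev + 0.6 * noise[..., 3]
        visits["grip"] = np.round(grip.ravel()[keep], 2)
        visits["pef"] = np.round(pef.ravel()[keep], 1)
        visits["height_m"] = np.repeat(height.ravel(), config.n_waves)[keep]
        visits["gait"] = np.round(gait.ravel()[keep], 2)
        visits["vision_self"] = np.clip(np.round(sens), 1, 4).astype(int).ravel()[keep]
        visits["hearing_self"] = np.clip(np.round(sens + 0.3 * noise[..., 3]), 1, 4).astype(int).ravel()[keep]
    visits["y"] = y_v

    truth_persons = pd.DataFrame(
        {
            "person_id": person_ids,
            "pair_id": np.repeat(pair_ids, 2),
            "zygosity": np.repeat(zyg, 2),
            "A": A.ravel(),
            "C": C.ravel(),
            "E": E.ravel(),
            "ses_latent": ses_latent.ravel(),
            "intercept": intercept.ravel(),
            "slope1": slope1.ravel(),
            "slope2": slope2.ravel(),
        }
    )
    truth_visits = pd.DataFrame(
        {
            "person_id": pid_v,
            "age_years": age_v,
            "mean_y": mean_y.ravel()[keep],
            "y": y_v,
        }
    )
    cohort = CohortTable(persons, visits, extra_person_cols=[config.ses_name], extra_visit_cols=extra_visit_cols)
    cohort.validate()
    truth = {"persons": truth_persons, "visits": truth_visits, "config": config, "seed": seed}
    return cohort, truth


@dataclass
class OracleCoefficients:
    """Expected between/within regression coefficients of the intercept on
    standardized SES, per zygosity (T units per latent-SES SD)."""

    within_mz: float
    within_dz: float
    between_mz: float
    between_dz: float


def oracle_coefficients(config: SimConfig) -> OracleCoefficients:
    """Closed-form projections of the generating model.

    With unit-variance A, C, E, SES loadings (a, c, e) and cross-paths
    (delta, kappa_a, kappa_c) on the intercept:

    * within_MZ  = delta                                  (always)
    * within_DZ  = delta + kappa_a a / (a^2 + 2 e^2)
    * between_MZ = delta + (kappa_a a + kappa_c c) / (a^2 + c^2 + e^2 / 2)
    * between_DZ = delta + (0.75 kappa_a a + kappa_c c) / (0.75 a^2 + c^2 + e^2 / 2)

    Within-pair projections regress member deviations (from the pair mean) of
    the intercept on the same deviations of SES; between-pair projections
    regress pair means on pair means.  The within-MZ identity with the direct
    path holds for any (kappa_a, kappa_c) because MZ deviations carry no A or
    C variance.
    """
    a, c, e = config.ses_ace.loadings
    if a == 0 and c == 0 and e == 0:
        raise ValueError("degenerate SES loadings")
    d, ka, kc = config.delta, config.kappa_a, config.kappa_c
    within_mz = d
    within_dz = d + ka * a / (a**2 + 2.0 * e**2)
    between_mz = d + (ka * a + kc * c) / (a**2 + c**2 + e**2 / 2.0)
    between_dz = d + (0.75 * ka * a + kc * c) / (0.75 * a**2 + c**2 + e**2 / 2.0)
    return OracleCoefficients(within_mz, within_dz, between_mz, between_dz)


# ---------------------------------------------------------------------------
# scenario presets

#: Generating scenarios for the three confounding mechanisms.  Effect sizes
#: are in T units per latent-SES SD, matched so the marginal SES-intercept
#: association is of comparable magnitude (about 2-3 T units per SD) across
#: scenarios.  The genetic scenario uses a high-heritability SES (a2 = 0.6)
#: and the shared-environment scenario a high-c2 SES (c2 = 0.4), the regimes
#: in which each mechanism operates.
SCENARIOS = {
    "causal": dict(delta=2.0, kappa_a=0.0, kappa_c=0.0, ses_ace=solve_ace(0.53, 0.29)),
    "genetic": dict(delta=0.0, kappa_a=2.0, kappa_c=0.0, ses_ace=ACEComponents(0.6, 0.2, 0.2)),
    "shared_env": dict(delta=0.0, kappa_a=0.0, kappa_c=4.0, ses_ace=ACEComponents(0.3, 0.4, 0.3)),
}


def scenario_config(name: str, **overrides) -> SimConfig:
    """A :class:`SimConfig` preset for one confounding scenario."""
    if name not in SCENARIOS:
        raise KeyError(f"unknown scenario {name!r}; choose from {sorted(SCENARIOS)}")
    cfg = SimConfig(**SCENARIOS[name])
    return replace(cfg, **overrides) if overrides else cfg
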