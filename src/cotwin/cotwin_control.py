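"""Co-twin control analysis: between/within decomposition and confounding logic.

The co-twin control design splits an SES exposure into a **between-pair** part
(the pair mean, carrying everything that makes twins alike: genes and rearing
environment) and a **within-pair** part (each member's deviation from the pair
mean, automatically adjusted for familial factors).  Both enter the growth
model as covariates of the intercept and/or slope 1.  Comparing how much the
within-pair effect is attenuated in MZ pairs (who share all their segregating
genes) versus DZ pairs (half, on average) separates three explanations:

* **consistent with causation** -- within-pair effects persist, unattenuated,
  in both zygosity groups;
* **genetic confounding** -- the within-pair effect vanishes (or shrinks
  sharply) in MZ pairs but much less in DZ pairs;
* **shared-environment confounding** -- the within-pair effect is attenuated
  equally in MZ and DZ pairs.

The module provides the decomposition, stratified model fits, the MZ-vs-DZ
within-effect comparison, a reproducible threshold-based classification of the
attenuation pattern, sex-interaction models, double-entry twin correlations
with Falconer ACE estimates, and Fisher z comparisons of correlations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import CohortTable, complete_pairs
from .growth import FitResult, ModelSpec, fit_model

__all__ = [
    "decompose_between_within",
    "CotwinResult",
    "fit_cotwin_models",
    "compare_within_mz_dz",
    "Thresholds",
    "ConfoundingVerdict",
    "classify_confounding",
    "fit_sex_interaction",
    "twin_correlations",
    "compare_correlations",
]

STRATA = ("full", "MZ", "DZ")


def decompose_between_within(persons: pd.DataFrame, ses: str) -> pd.DataFrame:
    """Pair-mean / deviation decomposition of an SES variable.

    between = pair mean of the SES value; within = member value minus the pair
    mean, so the two within values of a pair sum to zero and
    between + within reconstructs each member exactly.  Requires complete
    pairs with non-missing SES (run :func:`~cotwin.data_model.complete_pairs`
    first).
    """
    d = persons[["person_id", "pair_id", ses]].copy()
    sizes = d.groupby("pair_id")["person_id"].size()
    bad = sizes.index[sizes != 2].tolist()
    if bad:
        raise ValueError(f"incomplete pair(s) {bad[:5]}: run complete_pairs first")
    if d[ses].isna().any():
        bad = d.loc[d[ses].isna(), "pair_id"].tolist()
        raise ValueError(f"missing {ses!r} in pair(s) {bad[:5]}: run complete_pairs first")
    mean = d.groupby("pair_id")[ses].transform("mean")
    return pd.DataFrame(
        {
            "person_id": d["person_id"].to_numpy(),
            "pair_id": d["pair_id"].to_numpy(),
            "between": mean.to_numpy(float),
            "within": d[ses].to_numpy(float) - mean.to_numpy(float),
        }
    )


def _cotwin_spec(targets, parental_sei: bool, random) -> ModelSpec:
    fixed = ["1", "s1", "s2", "sex_male"]
    if parental_sei:
        fixed.append("parental_sei")
    for target in targets:
        suffix = "" if target == "intercept" else f":{target}"
        fixed.append("ses_b" + suffix)
        fixed.append("ses_w" + suffix)
    rp, ri, cov = random
    return ModelSpec(fixed=fixed, random_pair=rp, random_individual=ri, pair_cov=cov, individual_cov=cov)


@dataclass
class CotwinResult:
    """Stratified between/within estimates and the underlying fits."""

    table: pd.DataFrame  # stratum, target, component, estimate, se, z, p
    fits: dict[str, FitResult]
    ses: str
    targets: tuple[str, ...]
    n_pairs: dict[str, int]
    skipped: list[str] = field(default_factory=list)

    def estimate(self, stratum: str, target: str, component: str) -> tuple[float, float, float]:
        row = self.table[
            (self.table.stratum == stratum) & (self.table.target == target) & (self.table.component == component)
        ]
        if row.empty:
            raise KeyError((stratum, target, component))
        r = row.iloc[0]
        return float(r.estimate), float(r.se), float(r.p)


def fit_cotwin_models(
    cohort: CohortTable,
    ses: str,
    outcome_frame: pd.DataFrame,
    targets: tuple[str, ...] = ("intercept",),
    strata: tuple[str, ...] = STRATA,
    parental_sei: bool = False,
    min_pairs: int = 10,
    random=(("1",), ("1",), "diag"),
) -> CotwinResult:
    """Fit the between/within LGCM on complete pairs, per stratum.

    Parameters
    ----------
    cohort : CohortTable
    ses : str
        Person-level SES column to decompose.
    outcome_frame : DataFrame
        (person_id, age_years, <outcome>) scores, e.g. from
        :func:`cotwin.fai.score_fai`; the outcome column must be named ``fai``
        or be its only extra column.
    targets : which growth parameters the SES terms covary ("intercept",
        "slope1", "slope2"), chosen from a prior phenotypic fit.
    parental_sei : include parental SEI as an intercept covariate (used for
        the financial-strain model only in the reference analysis).
    random : (pair terms, individual terms, cov kind) random structure.

    Strata with fewer than ``min_pairs`` complete pairs are skipped with a
    warning and recorded in ``CotwinResult.skipped``.
    """
    cc = complete_pairs(cohort, require=ses)
    if parental_sei:
        cc = complete_pairs(cc, require="parental_sei")
    decomp = decompose_between_within(cc.persons, ses)
    persons = cc.persons.merge(decomp[["person_id", "between", "within"]], on="person_id")

    outcome_cols = [c for c in outcome_frame.columns if c not in ("person_id", "age_years", "n_components_used")]
    outcome = outcome_cols[0]

    term_map = {"intercept": "intercept", "slope1": "s1", "slope2": "s2"}
    spec_targets = [term_map.get(t, t) for t in targets]
    spec_targets = ["intercept" if t == "intercept" else t for t in spec_targets]

    rows, fits, n_pairs, skipped = [], {}, {}, []
    for stratum in strata:
        sub = persons if stratum == "full" else persons[persons["zygosity"] == stratum]
        npairs = sub["pair_id"].nunique()
        n_pairs[stratum] = int(npairs)
        if npairs < min_pairs:
            warnings.warn(f"stratum {stratum}: only {npairs} complete pairs, skipped", stacklevel=2)
            skipped.append(stratum)
            continue
        visits = cc.visits[cc.visits["person_id"].isin(sub["person_id"])]
        frame = visits.drop(columns=[outcome], errors="ignore").merge(sub, on="person_id")
        frame = frame.merge(outcome_frame[["person_id", "age_years", outcome]], on=["person_id", "age_years"], how="left")
        frame = frame.rename(columns={"between": "ses_b", "within": "ses_w"})
        frame["sex_male"] = (frame["sex"] == "male").astype(float)
        spec = _cotwin_spec(spec_targets, parental_sei, random)
        spec.outcome = outcome
        fit = fit_model(frame, spec)
        fits[stratum] = fit
        for target, sterm in zip(targets, spec_targets):
            suffix = "" if sterm == "intercept" else f":{sterm}"
            for comp, term in (("between", "ses_b" + suffix), ("within", "ses_w" + suffix)):
                rows.append(
                    {
                        "stratum": stratum,
                        "target": target,
                        "component": comp,
                        "estimate": fit.params[term],
                        "se": fit.se[term],
                        "z": fit.zvalues[term],
                        "p": fit.pvalues[term],
                        "n_pairs": int(npairs),
                    }
                )
    return CotwinResult(pd.DataFrame(rows), fits, ses, tuple(targets), n_pairs, skipped)


def compare_within_mz_dz(result: CotwinResult, target: str = "intercept", sign_align: bool = True):
    """MZ-vs-DZ comparison of the within-pair effect: z and two-sided p.

    z = (within_DZ - within_MZ) / sqrt(SE_MZ^2 + SE_DZ^2).  With
    ``sign_align`` both estimates are first multiplied by the sign of the
    full-sample between estimate, so "z > 0" always reads "the DZ within
    effect is larger in the direction of the association" regardless of the
    SES variable's orientation.
    """
    w_mz, se_mz, _ = result.estimate("MZ", target, "within")
    w_dz, se_dz, _ = result.estimate("DZ", target, "within")
    s = 1.0
    if sign_align:
        try:
            b_full, _, _ = result.estimate("full", target, "between")
        except KeyError:
            b_full = w_dz
        s = 1.0 if b_full >= 0 else -1.0
    z = (s * w_dz - s * w_mz) / np.hypot(se_mz, se_dz)
    return float(z), float(2.0 * stats.norm.sf(abs(z)))


@dataclass
class Thresholds:
    """Decision thresholds for the attenuation-pattern classification.

    The published logic is verbal; these numeric defaults make it
    reproducible: a within/between ratio >= ``ratio_keep`` counts as "not
    attenuated", <= ``ratio_drop`` as "absent", ratios within ``equal_band``
    of each other as "equally attenuated", ``alpha`` is the two-sided
    significance level, ``z_one_sided`` the one-sided MZ<DZ comparison cut.
    """

    ratio_keep: float = 0.7
    ratio_drop: float = 0.3
    equal_band: float = 0.2
    alpha: float = 0.05
    z_one_sided: float = 1.645


@dataclass
class ConfoundingVerdict:
    verdict: str  # consistent_causal | genetic_confounding | shared_env_confounding | indeterminate
    evidence: dict
    thresholds: Thresholds


def classify_confounding(
    result: CotwinResult, target: str = "intercept", thresholds: Thresholds | None = None
) -> ConfoundingVerdict:
    """Classify the attenuation pattern across the MZ/DZ strata.

    Rules (r_g = within_g / between_g, sign-invariant by construction):

    1. within significant in both MZ and DZ with r_MZ and r_DZ >=
       ``ratio_keep``  ->  ``consistent_causal``;
    2. within_MZ non-significant AND (the MZ-vs-DZ comparison favours DZ at
       the one-sided cut OR r_MZ < ``ratio_drop``) while r_DZ >=
       ``ratio_keep``  ->  ``genetic_confounding``;
    3. within non-significant in both strata with |r_MZ - r_DZ| <
       ``equal_band``  ->  ``shared_env_confounding``;
    4. otherwise ``indeterminate``.
    """
    th = thresholds or Thresholds()
    b_mz, _, _ = result.estimate("MZ", target, "between")
    b_dz, _, _ = result.estimate("DZ", target, "between")
    w_mz, se_mz, p_mz = result.estimate("MZ", target, "within")
    w_dz, se_dz, p_dz = result.estimate("DZ", target, "within")

    def ratio(w, b):
        return w / b if abs(b) > 1e-12 else np.inf * np.sign(w) if w else 0.0

    r_mz, r_dz = ratio(w_mz, b_mz), ratio(w_dz, b_dz)
    z_cmp, p_cmp = compare_within_mz_dz(result, target)
    sig_mz, sig_dz = p_mz < th.alpha, p_dz < th.alpha
    low_power = se_mz > abs(b_mz) or se_dz > abs(b_dz)

    if sig_mz and sig_dz and r_mz >= th.ratio_keep and r_dz >= th.ratio_keep:
        verdict = "consistent_causal"
    elif (not sig_mz) and (z_cmp > th.z_one_sided or r_mz < th.ratio_drop) and r_dz >= th.ratio_keep:
        verdict = "genetic_confounding"
    elif (not sig_mz) and (not sig_dz) and abs(r_mz - r_dz) < th.equal_band:
        verdict = "shared_env_confounding"
    else:
        verdict = "indeterminate"

    evidence = {
        "target": target,
        "within_MZ": w_mz,
        "within_DZ": w_dz,
        "between_MZ": b_mz,
        "between_DZ": b_dz,
        "ratio_MZ": float(r_mz),
        "ratio_DZ": float(r_dz),
        "within_MZ_significant": bool(sig_mz),
        "within_DZ_significant": bool(sig_dz),
        "mz_dz_z": z_cmp,
        "mz_dz_p": p_cmp,
        "low_power": bool(low_power),
    }
    return ConfoundingVerdict(verdict, evidence, th)


def fit_sex_interaction(
    cohort: CohortTable,
    ses: str,
    outcome_frame: pd.DataFrame,
    strata: tuple[str, ...] = STRATA,
    parental_sei: bool = False,
    min_pairs: int = 10,
    random=(("1",), ("1",), "diag"),
) -> pd.DataFrame:
    """Sex-interaction co-twin model: women as base level, male corrections.

    Adds male x between and male x within interaction terms on the intercept
    only.  Returns a long table (stratum, term, estimate, se, z, p) with the
    base rows being the women's estimates and the ":sex_male" rows the
    corrections for men.  Single-sex strata are flagged and skipped.
    """
    cc = complete_pairs(cohort, require=ses)
    if parental_sei:
        cc = complete_pairs(cc, require="parental_sei")
    decomp = decompose_between_within(cc.persons, ses)
    persons = cc.persons.merge(decomp[["person_id", "between", "within"]], on="person_id")

    outcome_cols = [c for c in outcome_frame.columns if c not in ("person_id", "age_years", "n_components_used")]
    outcome = outcome_cols[0]

    rows = []
    for stratum in strata:
        sub = persons if stratum == "full" else persons[persons["zygosity"] == stratum]
        if sub["pair_id"].nunique() < min_pairs:
            warnings.warn(f"stratum {stratum}: too few pairs, skipped", stacklevel=2)
            continue
        if sub["sex"].nunique() < 2:
            warnings.warn(f"stratum {stratum}: single sex, interaction inestimable", stacklevel=2)
            rows.append({"stratum": stratum, "term": "inestimable", "estimate": np.nan, "se": np.nan, "z": np.nan, "p": np.nan})
            continue
        visits = cc.visits[cc.visits["person_id"].isin(sub["person_id"])]
        frame = visits.drop(columns=[outcome], errors="ignore").merge(sub, on="person_id")
        frame = frame.merge(outcome_frame[["person_id", "age_years", outcome]], on=["person_id", "age_years"], how="left")
        frame = frame.rename(columns={"between": "ses_b", "within": "ses_w"})
        frame["sex_male"] = (frame["sex"] == "male").astype(float)
        fixed = ["1", "s1", "s2", "sex_male", "ses_b", "ses_w", "ses_b:sex_male", "ses_w:sex_male"]
        if parental_sei:
            fixed.insert(4, "parental_sei")
        rp, ri, cov = random
        spec = ModelSpec(outcome=outcome, fixed=fixed, random_pair=rp, random_individual=ri, pair_cov=cov, individual_cov=cov)
        fit = fit_model(frame, spec)
        for term in ("ses_b", "ses_w", "ses_b:sex_male", "ses_w:sex_male"):
            rows.append(
                {
                    "stratum": stratum,
                    "term": term,
                    "estimate": fit.params[term],
                    "se": fit.se[term],
                    "z": fit.zvalues[term],
                    "p": fit.pvalues[term],
                }
            )
    return pd.DataFrame(rows)


def twin_correlations(persons: pd.DataFrame, variable: str):
    """Double-entry (intraclass) twin correlations and Falconer ACE estimates.

    Each complete pair contributes both orderings to a Pearson correlation per
    zygosity.  Returns (r_mz, r_dz, ace) where ``ace`` is the Falconer point
    solution from :func:`cotwin.simulate.solve_ace` (truncated at the [0, 1]
    boundary with a flag when the raw solution is inadmissible).
    """
    from .simulate import solve_ace

    rs = {}
    for zyg in ("MZ", "DZ"):
        sub = persons[(persons["zygosity"] == zyg) & persons[variable].notna()]
        sizes = sub.groupby("pair_id")["person_id"].size()
        keep = sizes.index[sizes == 2]
        sub = sub[sub["pair_id"].isin(keep)].sort_values(["pair_id", "person_id"])
        if len(keep) < 3:
            raise ValueError(f"fewer than 3 complete {zyg} pairs with {variable!r}")
        x = sub[variable].to_numpy(float).reshape(-1, 2)
        a = np.concatenate([x[:, 0], x[:, 1]])
        b = np.concatenate([x[:, 1], x[:, 0]])
        rs[zyg] = float(np.corrcoef(a, b)[0, 1])
    return rs["MZ"], rs["DZ"], solve_ace(rs["MZ"], rs["DZ"])


def compare_correlations(r1: float, n1: int, r2: float, n2: int):
    """Fisher z test for two independent correlations.

    z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3)), two-sided p.
    """
    for r, n in ((r1, n1), (r2, n2)):
        if not abs(r) < 1:
            raise ValueError("correlations must lie strictly inside (-1, 1)")
        if n <= 3:
            raise ValueError("need n > 3 per group")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    return float(z), float(2.0 * stats.norm.sf(abs(z)))
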