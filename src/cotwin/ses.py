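"""Financial-strain scoring: a single-factor model over four ordinal items.

Four subjective economy items (money covers needs, difficulty with monthly
expenses, economic situation relative to peers, money for extras), oriented so
higher = more strain, are summarized by one maximum-likelihood factor.  Factor
scores use the regression (Thomson) method restricted to each respondent's
observed items, so partially answered batteries still score, and are then
translated to the T-score metric (mean 50, SD 10) within each declared sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from sklearn.decomposition import FactorAnalysis

__all__ = ["FactorModel", "fit_single_factor", "score_fs", "FS_ITEMS"]

FS_ITEMS = ["fs1", "fs2", "fs3", "fs4"]

UNIQUENESS_FLOOR = 0.005


@dataclass
class FactorModel:
    """One-factor measurement model on standardized items.

    ``loadings`` and ``uniquenesses`` are on the standardized-item scale;
    ``item_means``/``item_sds`` standardize raw responses before scoring.
    """

    loadings: np.ndarray
    uniquenesses: np.ndarray
    item_means: np.ndarray
    item_sds: np.ndarray
    items: list[str] = field(default_factory=lambda: list(FS_ITEMS))
    heywood: bool = False

    def __post_init__(self):
        self.loadings = np.asarray(self.loadings, float)
        self.uniquenesses = np.asarray(self.uniquenesses, float)
        self.item_means = np.asarray(self.item_means, float)
        self.item_sds = np.asarray(self.item_sds, float)
        if np.any(self.uniquenesses <= 0):
            raise ValueError("uniquenesses must be positive")

    def to_yaml(self, path) -> None:
        payload = {
            "loadings": self.loadings.tolist(),
            "uniquenesses": self.uniquenesses.tolist(),
            "item_means": self.item_means.tolist(),
            "item_sds": self.item_sds.tolist(),
            "items": list(self.items),
            "heywood": bool(self.heywood),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh)

    @classmethod
    def from_yaml(cls, path) -> "FactorModel":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def fit_single_factor(items: pd.DataFrame, item_names: list[str] | None = None) -> FactorModel:
    """ML one-factor fit on standardized items (complete rows).

    Loadings are sign-fixed so their sum is positive.  A Heywood case
    (uniqueness collapsing toward zero, e.g. duplicated item columns) is
    flagged and the uniqueness floored at 0.005.  Items with almost no shared
    variance (no common factor) raise a warning but still return a model.
    """
    item_names = item_names or [c for c in FS_ITEMS if c in items.columns] or list(items.columns)
    X = items[item_names].astype(float)
    complete = X.dropna()
    if len(complete) < 20:
        raise ValueError(f"need >=20 complete rows to fit the factor model, got {len(complete)}")
    means = complete.mean().to_numpy()
    sds = complete.std(ddof=1).to_numpy()
    if np.any(sds <= 0):
        raise ValueError("constant item column; cannot standardize")
    Z = (complete.to_numpy() - means) / sds

    fa = FactorAnalysis(n_components=1, svd_method="lapack")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fa.fit(Z)
    lam = fa.components_[0].copy()
    psi = fa.noise_variance_.copy()
    if lam.sum() < 0:
        lam = -lam
    heywood = bool(np.any(psi < UNIQUENESS_FLOOR) or np.any(lam**2 > 1.0))
    psi = np.maximum(psi, UNIQUENESS_FLOOR)
    corr = np.corrcoef(Z, rowvar=False)
    mean_abs_r = np.abs(corr[np.triu_indices_from(corr, 1)]).mean()
    if mean_abs_r < 0.1:
        warnings.warn("items share almost no common variance; a single factor is not supported", stacklevel=2)
    return FactorModel(lam, psi, means, sds, items=item_names, heywood=heywood)


def factor_score(z_row: np.ndarray, model: FactorModel) -> float:
    """Regression-method score from the observed-item submodel.

    For observed items o: f = lambda_o' (lambda_o lambda_o' + Psi_o)^-1 z_o,
    i.e. the posterior mean of the factor given the observed items under the
    fitted Gaussian model.  NaN when no item is observed.
    """
    obs = np.isfinite(z_row)
    if not obs.any():
        return np.nan
    lam = model.loadings[obs]
    psi = model.uniquenesses[obs]
    sigma = np.outer(lam, lam) + np.diag(psi)
    return float(lam @ np.linalg.solve(sigma, z_row[obs]))


def score_fs(
    items: pd.DataFrame,
    model: FactorModel,
    sample_labels: pd.Series | None = None,
) -> pd.DataFrame:
    """Score financial strain and translate to the T-metric within sample.

    Parameters
    ----------
    items : DataFrame
        Rows = respondents, columns include the model's items; missing items
        allowed (scored from the observed subset), all-missing rows get NaN.
    model : FactorModel
        Frozen measurement model.
    sample_labels : Series, optional
        Study labels; T-scoring (mean 50, SD 10) is done within each label.
        Without labels the whole table is one sample.

    Returns
    -------
    DataFrame with ``fs`` (T-score units, higher = more strain) and
    ``n_items_used``.
    """
    X = items[model.items].astype(float).to_numpy()
    Z = (X - model.item_means) / model.item_sds
    raw = np.array([factor_score(z, model) for z in Z])
    n_used = np.isfinite(Z).sum(axis=1)

    fs = np.full(len(raw), np.nan)
    labels = (
        pd.Series(["_all"] * len(raw), index=items.index)
        if sample_labels is None
        else sample_labels.fillna("_all")
    )
    for lab in labels.unique():
        m = (labels == lab).to_numpy() & np.isfinite(raw)
        if m.sum() < 2:
            fs[m] = 50.0
            continue
        mu, sd = raw[m].mean(), raw[m].std(ddof=1)
        if sd <= 0:
            fs[m] = 50.0
        else:
            fs[m] = 50.0 + 10.0 * (raw[m] - mu) / sd
    return pd.DataFrame({"fs": fs, "n_items_used": n_used}, index=items.index)
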