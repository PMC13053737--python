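"""Two-slope age-based latent growth curve model for twin data.

The outcome (FAI, T-score units) is modelled as a linear spline in age with a
knot and intercept at age 75, time scaled per decade:

    t  = (age - 75) / 10,   s1 = min(t, 0),   s2 = max(t, 0)

so slope 1 is the rate of change per decade before 75 and slope 2 the rate
after 75.  Random effects live at two levels: the twin **pair** (shared by
both members) and the **individual within pair**, each over a configurable
subset of {intercept, s1, s2} with unstructured, diagonal or reduced
covariance.  For a pair p with stacked outcome vector y_p,

    y_p ~ N(X_p beta,  Z_p G_P Z_p' + sum_m Z_pm G_I Z_pm' + sigma^2 I)

where the inner sum runs over the pair's members.  Estimation is exact
maximum likelihood: the two covariance matrices are log-Cholesky
parameterized, fixed effects are profiled out by generalized least squares
inside the variance optimization, and pair blocks are padded to a common size
so the whole likelihood evaluates as one batched Cholesky/solve.

Nested ML fits are compared with the likelihood ratio test, df = difference
in parameter count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "age_basis",
    "add_age_basis",
    "ModelSpec",
    "FitResult",
    "DesignBlocks",
    "build_design",
    "fit_lgcm",
    "fit_model",
    "lrt",
    "ConvergenceError",
]

AGE_CENTER = 75.0
AGE_SCALE = 10.0

_BIG = 1e10


class ConvergenceError(RuntimeError):
    """The variance optimization failed to converge; carries the best iterate."""

    def __init__(self, msg, result=None):
        super().__init__(msg)
        self.result = result


def age_basis(age, center: float = AGE_CENTER, scale: float = AGE_SCALE):
    """Centered, per-decade two-slope age basis (t, s1, s2).

    s1 = min(t, 0) carries change up to the centering age, s2 = max(t, 0)
    change after it; s1 + s2 = t and the intercept refers to age ``center``.
    """
    t = (np.asarray(age, float) - center) / scale
    return t, np.minimum(t, 0.0), np.maximum(t, 0.0)


def add_age_basis(frame: pd.DataFrame, age_col: str = "age_years") -> pd.DataFrame:
    frame = frame.copy()
    t, s1, s2 = age_basis(frame[age_col].to_numpy(float))
    frame["t"], frame["s1"], frame["s2"] = t, s1, s2
    return frame


# ---------------------------------------------------------------------------
# model specification


@dataclass
class ModelSpec:
    """Fixed- and random-effect structure of one LGCM fit.

    ``fixed`` is a list of term names; a term is either "1" (intercept), a
    column of the analysis frame, or a product "a:b" of columns ("1" allowed
    as a factor).  ``random_pair`` / ``random_individual`` list the random
    basis terms (subset of ["1", "s1", "s2"]); the matching covariance is
    "us" (unstructured) or "diag".
    """

    outcome: str = "fai"
    fixed: list[str] = field(default_factory=lambda: ["1", "s1", "s2", "sex_male"])
    random_pair: tuple[str, ...] = ("1",)
    random_individual: tuple[str, ...] = ("1",)
    pair_cov: str = "us"
    individual_cov: str = "us"

    def n_variance_params(self) -> int:
        def n(q, kind):
            if q == 0:
                return 0
            return q * (q + 1) // 2 if kind == "us" else q

        return n(len(self.random_pair), self.pair_cov) + n(len(self.random_individual), self.individual_cov) + 1

    def n_params(self) -> int:
        return len(self.fixed) + self.n_variance_params()


def _term_column(frame: pd.DataFrame, term: str) -> np.ndarray:
    out = np.ones(len(frame))
    for factor in term.split(":"):
        if factor != "1":
            out = out * frame[factor].to_numpy(float)
    return out


def design_matrix(frame: pd.DataFrame, terms) -> np.ndarray:
    return np.column_stack([_term_column(frame, t) for t in terms]) if len(terms) else np.zeros((len(frame), 0))


# ---------------------------------------------------------------------------
# design blocks


@dataclass
class DesignBlocks:
    """Pair-grouped, padded design arrays for the batched likelihood.

    Shapes: y (B, n), X (B, n, p), Zp (B, n, qp), Zi (B, n, 2*qi) with the two
    member blocks occupying disjoint column ranges, mask (B, n) with 1 for real
    rows.  Padded rows have X = Z = y = 0 and unit marginal variance, so they
    contribute nothing to the likelihood.
    """

    y: np.ndarray
    X: np.ndarray
    Zp: np.ndarray
    Zi: np.ndarray
    mask: np.ndarray
    spec: ModelSpec
    fixed_names: list[str]
    pair_ids: list
    n_obs: int
    n_persons: int
    n_pairs: int


def build_design(frame: pd.DataFrame, spec: ModelSpec) -> DesignBlocks:
    """Group observations by pair and assemble padded design arrays.

    Rows with a missing outcome or any missing fixed-effect column are dropped
    listwise.  Requires ``pair_id``, ``person_id`` and the age-basis columns
    (added automatically when absent).
    """
    if "s1" not in frame.columns:
        frame = add_age_basis(frame)
    needed = {spec.outcome}
    for t in spec.fixed:
        needed.update(f for f in t.split(":") if f != "1")
    cols = list(needed)
    keep = frame[cols].notna().all(axis=1)
    frame = frame.loc[keep].sort_values(["pair_id", "person_id", "age_years"], kind="mergesort")
    if len(frame) == 0:
        raise ValueError("empty design after missingness filtering")

    Xall = design_matrix(frame, spec.fixed)
    rank = np.linalg.matrix_rank(Xall)
    if rank < Xall.shape[1]:
        raise ValueError(f"rank-deficient fixed design: rank {rank} < {Xall.shape[1]} terms {spec.fixed}")
    Zp_all = design_matrix(frame, list(spec.random_pair))
    Zi_all = design_matrix(frame, list(spec.random_individual))
    yall = frame[spec.outcome].to_numpy(float)

    pair_codes, pair_ids = pd.factorize(frame["pair_id"].to_numpy(), sort=False)
    qp, qi = Zp_all.shape[1], Zi_all.shape[1]
    p = Xall.shape[1]

    counts = np.bincount(pair_codes)
    B, n = len(pair_ids), int(counts.max())
    y = np.zeros((B, n))
    X = np.zeros((B, n, p))
    Zp = np.zeros((B, n, qp))
    Zi = np.zeros((B, n, 2 * qi))
    mask = np.zeros((B, n))

    pos = np.zeros(B, int)
    person_of_pair: list[dict] = [dict() for _ in range(B)]
    persons_f = frame["person_id"].to_numpy()
    for r in range(len(frame)):
        b = pair_codes[r]
        j = pos[b]
        pos[b] += 1
        y[b, j] = yall[r]
        X[b, j] = Xall[r]
        Zp[b, j] = Zp_all[r]
        mask[b, j] = 1.0
        slot_map = person_of_pair[b]
        pid = persons_f[r]
        if pid not in slot_map:
            if len(slot_map) >= 2:
                raise ValueError(f"pair {pair_ids[b]!r} has more than 2 members")
            slot_map[pid] = len(slot_map)
        if qi:
            s = slot_map[pid]
            Zi[b, j, s * qi : (s + 1) * qi] = Zi_all[r]

    return DesignBlocks(
        y=y,
        X=X,
        Zp=Zp,
        Zi=Zi,
        mask=mask,
        spec=spec,
        fixed_names=list(spec.fixed),
        pair_ids=list(pair_ids),
        n_obs=int(mask.sum()),
        n_persons=int(frame["person_id"].nunique()),
        n_pairs=B,
    )


# ---------------------------------------------------------------------------
# covariance parameterization (log-Cholesky)


def _unpack_cov(theta: np.ndarray, q: int, kind: str) -> tuple[np.ndarray, int]:
    """theta segment -> PSD covariance via log-Cholesky; returns (G, n_used)."""
    if q == 0:
        return np.zeros((0, 0)), 0
    if kind == "diag":
        d = np.exp(theta[:q])
        return np.diag(d * d), q
    m = q * (q + 1) // 2
    L = np.zeros((q, q))
    k = 0
    for i in range(q):
        for j in range(i + 1):
            L[i, j] = np.exp(theta[k]) if i == j else theta[k]
            k += 1
    return L @ L.T, m


def _pack_start(spec: ModelSpec, var0: float) -> np.ndarray:
    """Start values: equal split of the residual variance across components."""
    parts = []
    s0 = np.sqrt(max(var0, 1e-6) / 3.0)
    for q, kind in ((len(spec.random_pair), spec.pair_cov), (len(spec.random_individual), spec.individual_cov)):
        if q == 0:
            continue
        if kind == "diag":
            parts.append(np.full(q, np.log(s0)))
        else:
            seg = np.zeros(q * (q + 1) // 2)
            k = 0
            for i in range(q):
                for j in range(i + 1):
                    if i == j:
                        seg[k] = np.log(s0 if i == 0 else s0 / 2.0)
                    k += 1
            parts.append(seg)
    parts.append(np.array([np.log(s0)]))
    return np.concatenate(parts)


# ---------------------------------------------------------------------------
# likelihood


def _profile_nll(theta: np.ndarray, blocks: DesignBlocks, want_beta: bool = False):
    """Negative profile log-likelihood at variance parameters theta.

    Fixed effects are solved by GLS given V(theta); padded rows carry unit
    variance and zero design so they drop out of every sum.
    """
    spec = blocks.spec
    qp, qi2 = blocks.Zp.shape[2], blocks.Zi.shape[2]
    qi = qi2 // 2
    Gp, k = _unpack_cov(theta, qp, spec.pair_cov)
    Gi, k2 = _unpack_cov(theta[k:], qi, spec.individual_cov)
    sigma2 = float(np.exp(2.0 * theta[k + k2]))
    if not np.isfinite(sigma2) or sigma2 > 1e12:
        return (_BIG, None, None) if want_beta else _BIG

    mask = blocks.mask
    V = np.einsum("bni,ij,bmj->bnm", blocks.Zp, Gp, blocks.Zp) if qp else 0.0
    if qi:
        Gi2 = np.kron(np.eye(2), Gi)
        Vi = np.einsum("bni,ij,bmj->bnm", blocks.Zi, Gi2, blocks.Zi)
        V = V + Vi if qp else Vi
    B, n = mask.shape
    if qp == 0 and qi == 0:
        V = np.zeros((B, n, n))
    diag = sigma2 * mask + (1.0 - mask)
    V[:, np.arange(n), np.arange(n)] += diag

    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        return (_BIG, None, None) if want_beta else _BIG
    logdet = 2.0 * np.log(np.diagonal(L, axis1=1, axis2=2)).sum()

    # whiten y and X: solve L w = [y X]
    p = blocks.X.shape[2]
    rhs = np.concatenate([blocks.y[:, :, None], blocks.X], axis=2)
    w = np.linalg.solve(L, rhs)
    wy, wX = w[:, :, 0], w[:, :, 1:]
    A = np.einsum("bni,bnj->ij", wX, wX)
    b = np.einsum("bni,bn->i", wX, wy)
    quad_y = float(np.einsum("bn,bn->", wy, wy))
    try:
        np.linalg.cholesky(A)  # PD guard: padded/degenerate thetas can break GLS
    except np.linalg.LinAlgError:
        return (_BIG, None, None) if want_beta else _BIG
    beta = np.linalg.solve(A, b) if p else np.zeros(0)
    quad = quad_y - float(b @ beta)
    N = blocks.n_obs
    ll = -0.5 * (logdet + quad + N * np.log(2.0 * np.pi))
    if not np.isfinite(ll):
        return (_BIG, None, None) if want_beta else _BIG
    if want_beta:
        cov_beta = np.linalg.inv(A) if p else np.zeros((0, 0))
        return -ll, beta, cov_beta
    return -ll


# ---------------------------------------------------------------------------
# fit result


@dataclass
class FitResult:
    """Maximum-likelihood fit of one LGCM.

    ``params``/``se``/``zvalues``/``pvalues`` cover the fixed effects; SEs come
    from the GLS information matrix at the variance optimum, p-values from a
    normal reference.  ``loglik`` is the exact marginal log-likelihood,
    ``n_params`` counts fixed plus variance parameters (for LRTs).
    """

    params: pd.Series
    se: pd.Series
    zvalues: pd.Series
    pvalues: pd.Series
    loglik: float
    n_params: int
    sigma2: float
    G_pair: pd.DataFrame
    G_individual: pd.DataFrame
    n_obs: int
    n_persons: int
    n_pairs: int
    spec: ModelSpec
    converged: bool
    n_iter: int
    grad_norm: float
    fallback: list[str] = field(default_factory=list)
    method: str = "ML"

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"estimate": self.params, "se": self.se, "z": self.zvalues, "p": self.pvalues}
        )


def _optimize(blocks: DesignBlocks, theta0: np.ndarray):
    res = optimize.minimize(
        _profile_nll,
        theta0,
        args=(blocks,),
        method="L-BFGS-B",
        options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-6},
    )
    return res


def fit_lgcm(blocks: DesignBlocks, allow_fallback: bool = True) -> FitResult:
    """Maximize the exact marginal likelihood over variance parameters.

    Quasi-Newton (L-BFGS-B) on the log-Cholesky variance parameters with
    GLS-profiled fixed effects.  On non-convergence the random structure falls
    back unstructured -> diagonal -> intercept-only (recorded in
    ``FitResult.fallback``); if everything fails a :class:`ConvergenceError`
    carrying the best iterate is raised.
    """
    spec = blocks.spec
    var0 = float(np.var(blocks.y[blocks.mask == 1.0]))
    theta0 = _pack_start(spec, var0)
    res = _optimize(blocks, theta0)
    fallback: list[str] = []
    if not res.success and allow_fallback:
        for reduction in _reductions(spec):
            rb = build_design_like(blocks, reduction)
            r2 = _optimize(rb, _pack_start(reduction, var0))
            if r2.success:
                fallback.append(f"random structure reduced to {reduction.random_pair}/{reduction.random_individual} "
                                f"({reduction.pair_cov}/{reduction.individual_cov})")
                blocks, spec, res = rb, reduction, r2
                break
    if not res.success and not np.isfinite(res.fun):
        raise ConvergenceError(f"LGCM optimization failed: {res.message}", res)

    nll, beta, cov_beta = _profile_nll(res.x, blocks, want_beta=True)
    names = blocks.fixed_names
    se = np.sqrt(np.diag(cov_beta))
    z = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    qp = len(spec.random_pair)
    qi = len(spec.random_individual)
    Gp, k = _unpack_cov(res.x, qp, spec.pair_cov)
    Gi, _ = _unpack_cov(res.x[k:], qi, spec.individual_cov)
    sigma2 = float(np.exp(2.0 * res.x[-1]))
    return FitResult(
        params=pd.Series(beta, index=names),
        se=pd.Series(se, index=names),
        zvalues=pd.Series(z, index=names),
        pvalues=pd.Series(pvals, index=names),
        loglik=-float(nll),
        n_params=len(names) + spec.n_variance_params(),
        sigma2=sigma2,
        G_pair=pd.DataFrame(Gp, index=list(spec.random_pair), columns=list(spec.random_pair)),
        G_individual=pd.DataFrame(Gi, index=list(spec.random_individual), columns=list(spec.random_individual)),
        n_obs=blocks.n_obs,
        n_persons=blocks.n_persons,
        n_pairs=blocks.n_pairs,
        spec=spec,
        converged=bool(res.success),
        n_iter=int(res.nit),
        grad_norm=float(np.max(np.abs(res.jac))) if res.jac is not None else np.nan,
        fallback=fallback,
    )


def _reductions(spec: ModelSpec):
    out = []
    if spec.pair_cov == "us" or spec.individual_cov == "us":
        out.append(
            ModelSpec(spec.outcome, list(spec.fixed), spec.random_pair, spec.random_individual, "diag", "diag")
        )
    if spec.random_pair != ("1",) or spec.random_individual != ("1",):
        out.append(ModelSpec(spec.outcome, list(spec.fixed), ("1",), ("1",), "diag", "diag"))
    return out


def build_design_like(blocks: DesignBlocks, spec: ModelSpec) -> DesignBlocks:
    """Re-slice existing padded arrays for a reduced random structure."""

    # columns of the original Zp/Zi follow blocks.spec ordering
    def cols(old_terms, new_terms):
        return [list(old_terms).index(t) for t in new_terms]

    Zp = blocks.Zp[:, :, cols(blocks.spec.random_pair, spec.random_pair)] if spec.random_pair else blocks.Zp[:, :, :0]
    qi_old = blocks.Zi.shape[2] // 2
    ci = cols(blocks.spec.random_individual, spec.random_individual)
    qi_new = len(ci)
    idx = ci + [qi_old + c for c in ci]
    Zi = blocks.Zi[:, :, idx] if qi_new else blocks.Zi[:, :, :0]
    return DesignBlocks(
        y=blocks.y,
        X=blocks.X,
        Zp=Zp,
        Zi=Zi,
        mask=blocks.mask,
        spec=spec,
        fixed_names=blocks.fixed_names,
        pair_ids=blocks.pair_ids,
        n_obs=blocks.n_obs,
        n_persons=blocks.n_persons,
        n_pairs=blocks.n_pairs,
    )


def fit_model(frame: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """Convenience wrapper: build the design from a long frame and fit."""
    return fit_lgcm(build_design(frame, spec))


def lrt(fit_null: FitResult, fit_full: FitResult, tol: float = 1e-6):
    """Likelihood ratio test of two nested ML fits.

    Returns (statistic, df, p) with statistic = 2(l_full - l_null) and p from
    the upper tail of chi-square(df).  Raises on non-nested inputs (df <= 0),
    REML fits, different data, or a negative statistic beyond tolerance.
    """
    for f in (fit_null, fit_full):
        if f.method != "ML":
            raise ValueError("LRT requires ML fits (not REML)")
    if fit_null.n_obs != fit_full.n_obs:
        raise ValueError("LRT requires the same observations in both fits")
    df = fit_full.n_params - fit_null.n_params
    if df <= 0:
        raise ValueError("models are not nested (full model has no extra parameters)")
    stat = 2.0 * (fit_full.loglik - fit_null.loglik)
    if stat < -tol * max(1.0, abs(fit_full.loglik)):
        raise ConvergenceError(f"negative LRT statistic {stat:.3g}: a fit did not converge")
    stat = max(stat, 0.0)
    return stat, df, float(stats.chi2.sf(stat, df))
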