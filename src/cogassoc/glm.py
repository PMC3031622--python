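"""Factorial and repeated-measures ANCOVA engine.

Least-squares machinery producing the F-statistics that the permutation
engine resamples.  Between-subject designs use sum-to-zero (effects)
factor coding with Type III sums of squares by default — appropriate for
the heavily unbalanced carrier/non-carrier split — computed by comparing
the residual sum of squares of the full model against the model with the
tested term's columns removed.

The repeated-measures path follows the classical split-plot
decomposition: between-subject terms are tested on subject means (so a
two-level genotype factor in a 2 x 3 ANCOVA with one covariate on n = 184
subjects yields the familiar F(1, 177) layout), within-subject terms on
orthonormal polynomial contrasts of the four blocks.  Sphericity is
assessed with Mauchly's test; Greenhouse-Geisser corrected degrees of
freedom are always computed and become the headline p-value when Mauchly
rejects at alpha = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AliasingError, DegenerateDesignError, DomainError

__all__ = [
    "ModelSpec",
    "AnovaResult",
    "fit_anova",
    "fit_rm_anova",
    "gg_epsilon",
    "polynomial_contrast_test",
    "ks_normality",
    "chi_square_test",
    "build_design",
]

_RTOL = 1e-10


@dataclass(frozen=True)
class ModelSpec:
    """Specification of one (A)N(C)OVA model.

    ``outcome`` is a column name, or a sequence of exactly four column
    names for the repeated-measures (block-matrix) path.  ``between``
    lists the between-subject factors; with ``interactions`` true, all
    pairwise interactions between them are included.  Covariates enter
    centered.
    """

    outcome: str | tuple[str, ...]
    between: tuple[str, ...] = ()
    covariates: tuple[str, ...] = ()
    interactions: bool = True
    ss_type: str = "III"

    def __post_init__(self):
        object.__setattr__(self, "between", tuple(self.between))
        object.__setattr__(self, "covariates", tuple(self.covariates))
        if not isinstance(self.outcome, str):
            object.__setattr__(self, "outcome", tuple(self.outcome))
        if self.ss_type not in ("II", "III"):
            raise ValueError("ss_type must be 'II' or 'III'")


@dataclass
class AnovaResult:
    """One tested model term.

    For within-subject terms ``epsilon`` carries the Greenhouse-Geisser
    estimate; ``df1_gg``/``df2_gg``/``p_gg`` the corrected test; and
    ``corrected`` says whether the headline ``p`` is the corrected one
    (it is when Mauchly's test rejected sphericity).
    """

    term: str
    F: float
    df1: float
    df2: float
    p: float
    ss: float = float("nan")
    epsilon: float | None = None
    df1_gg: float | None = None
    df2_gg: float | None = None
    p_gg: float | None = None
    mauchly_p: float | None = None
    corrected: bool = False


# ---------------------------------------------------------------------------
# design construction

def _effects_coding(values: np.ndarray) -> tuple[np.ndarray, list]:
    """Sum-to-zero coding: k levels -> k-1 columns; the last (sorted)
    level is coded -1 in every column."""
    levels = sorted(pd.unique(values).tolist())
    k = len(levels)
    if k < 2:
        raise DegenerateDesignError(
            f"factor has {k} observed level(s); need at least 2")
    X = np.zeros((len(values), k - 1))
    for j, lev in enumerate(levels[:-1]):
        X[values == lev, j] = 1.0
    X[np.isin(values, [levels[-1]]), :] = -1.0
    return X, levels


def build_design(data: pd.DataFrame, spec: ModelSpec) -> dict[str, np.ndarray]:
    """Columns of the full design, keyed by term name ('(intercept)',
    factor names, 'a:b' interactions, covariate names)."""
    n = len(data)
    cols: dict[str, np.ndarray] = {"(intercept)": np.ones((n, 1))}
    factor_cols: dict[str, np.ndarray] = {}
    for f in spec.between:
        X, _ = _effects_coding(data[f].to_numpy())
        factor_cols[f] = X
        cols[f] = X
    if spec.interactions:
        for i, a in enumerate(spec.between):
            for b in spec.between[i + 1:]:
                Xa, Xb = factor_cols[a], factor_cols[b]
                prod = np.einsum("ni,nj->nij", Xa, Xb).reshape(n, -1)
                cols[f"{a}:{b}"] = prod
    for c in spec.covariates:
        v = data[c].to_numpy(dtype=float)
        if np.ptp(v) == 0:
            raise DegenerateDesignError(f"covariate {c!r} is constant")
        cols[c] = (v - v.mean())[:, None]
    return cols


def _rss(X: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    """Residual sum of squares and rank of a least-squares fit."""
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid), int(rank)


def _term_order(term: str) -> int:
    return term.count(":") + 1


def fit_anova(data: pd.DataFrame, spec: ModelSpec) -> list[AnovaResult]:
    """Factorial ANOVA/ANCOVA F-tests for every non-intercept term.

    Type III (default): each term's sum of squares is the RSS increase
    from deleting its columns from the otherwise full model.  Type II:
    the comparison model excludes terms containing the tested factor.
    Listwise deletion of rows with missing values.
    """
    if not isinstance(spec.outcome, str):
        raise ValueError("fit_anova expects a single outcome column")
    used = [spec.outcome, *spec.between, *spec.covariates]
    sub = data[used].dropna()
    y = sub[spec.outcome].to_numpy(dtype=float)
    n = len(sub)

    cols = build_design(sub, spec)
    X_full = np.hstack(list(cols.values()))
    p_full = X_full.shape[1]
    rank_full = np.linalg.matrix_rank(X_full)
    if rank_full < p_full:
        # name an aliased term: one whose deletion does not reduce the rank
        for term in cols:
            if term == "(intercept)":
                continue
            X_red = np.hstack([v for t, v in cols.items() if t != term])
            if np.linalg.matrix_rank(X_red) == rank_full:
                raise AliasingError(term)
        raise AliasingError("(unidentified)")

    rss_full, _ = _rss(X_full, y)
    df2 = n - rank_full
    if df2 <= 0:
        raise DegenerateDesignError("no residual degrees of freedom")

    results = []
    for term, Xt in cols.items():
        if term == "(intercept)":
            continue
        if spec.ss_type == "III":
            X_red = np.hstack([v for t, v in cols.items() if t != term])
            rss_red, _ = _rss(X_red, y)
            ss_term = max(rss_red - rss_full, 0.0)
        else:  # Type II: SS(term | all terms not containing it)
            tf = set(term.split(":"))
            base = [t for t in cols if t == "(intercept)" or
                    (t != term and not tf.issubset(set(t.split(":"))))]
            X_red = np.hstack([cols[t] for t in base])
            X_aug = np.hstack([cols[t] for t in base] + [Xt])
            rss_red, _ = _rss(X_red, y)
            rss_aug, _ = _rss(X_aug, y)
            ss_term = max(rss_red - rss_aug, 0.0)
        df1 = Xt.shape[1]
        scale = max(abs(rss_red), abs(rss_full), float(y @ y), 1.0)
        if ss_term <= _RTOL * scale and rss_full <= _RTOL * scale:
            F = 0.0  # constant outcome: no variance anywhere
        elif rss_full <= _RTOL * scale:
            F = float("inf")
        else:
            F = (ss_term / df1) / (rss_full / df2)
        p = float(stats.f.sf(F, df1, df2)) if np.isfinite(F) else 0.0
        results.append(AnovaResult(term=term, F=float(F), df1=float(df1),
                                   df2=float(df2), p=p, ss=ss_term))
    return results


# ---------------------------------------------------------------------------
# repeated measures

def _orthonormal_poly(k: int) -> np.ndarray:
    """Orthonormal polynomial contrasts: k x (k-1), columns of unit norm,
    each orthogonal to the constant."""
    x = np.arange(k, dtype=float)
    V = np.vander(x, k, increasing=True)  # 1, x, x^2, ...
    Q, _ = np.linalg.qr(V)
    C = Q[:, 1:]
    # fix signs so the linear contrast is increasing
    for j in range(C.shape[1]):
        if C[-1, j] < 0 and j % 2 == 0:
            C[:, j] *= -1.0
    return C


def gg_epsilon(covariance: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon of a k x k within-subject covariance.

    Computed from the double-centered covariance; for k = 4,
    1/3 <= epsilon <= 1, with 1 under compound symmetry.
    """
    S = np.asarray(covariance, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise DomainError("covariance must be square")
    if not np.allclose(S, S.T, atol=1e-8 * max(1.0, float(np.abs(S).max()))):
        raise DomainError("covariance must be symmetric")
    k = S.shape[0]
    P = np.eye(k) - np.ones((k, k)) / k
    B = P @ S @ P
    lam = np.linalg.eigvalsh(B)
    lam = np.clip(lam, 0.0, None)
    num = lam.sum() ** 2
    den = (k - 1) * (lam ** 2).sum()
    if den == 0:
        return 1.0
    return float(min(max(num / den, 1.0 / (k - 1)), 1.0))


def _mauchly(Sigma: np.ndarray, n_e: int) -> float:
    """Mauchly's sphericity test p-value on the contrast-space covariance."""
    q = Sigma.shape[0]  # k - 1
    lam = np.linalg.eigvalsh(Sigma)
    if np.any(lam <= 0):
        return 0.0
    W = float(np.prod(lam) / (lam.mean() ** q))
    d = 1.0 - (2.0 * q * q + q + 2.0) / (6.0 * q * n_e)
    chi2 = -n_e * d * np.log(max(W, 1e-300))
    df = q * (q + 1) // 2 - 1
    return float(stats.chi2.sf(chi2, df))


def fit_rm_anova(data: pd.DataFrame, spec: ModelSpec) -> list[AnovaResult]:
    """Split-plot ANCOVA with a four-level within-subject block factor.

    Between-subject terms are tested on subject means; within-subject
    terms ('block', 'block:<factor>', 'block:<covariate>') on orthonormal
    polynomial contrasts, pooling the contrast variables in the classical
    univariate (averaged-F) fashion.  Rows with any missing block value
    are an error unless listwise deletion is requested via dropping them
    beforehand.
    """
    if isinstance(spec.outcome, str) or len(spec.outcome) != 4:
        raise ValueError("repeated-measures path needs exactly 4 outcome columns")
    used = [*spec.outcome, *spec.between, *spec.covariates]
    sub = data[used]
    if sub.isna().any().any():
        raise DegenerateDesignError(
            "missing block values; drop incomplete cases explicitly first")
    Y = sub[list(spec.outcome)].to_numpy(dtype=float)
    n = len(sub)

    # between part on subject means
    mean_col = "__subject_mean__"
    btw = sub.copy()
    btw[mean_col] = Y.mean(axis=1)
    btw_spec = ModelSpec(outcome=mean_col, between=spec.between,
                         covariates=spec.covariates,
                         interactions=spec.interactions, ss_type=spec.ss_type)
    results = fit_anova(btw, btw_spec)

    # within part on polynomial contrasts
    C = _orthonormal_poly(Y.shape[1])
    Z = Y @ C  # (n, 3)
    cols = build_design(sub, spec)
    X_full = np.hstack(list(cols.values()))
    rank_full = np.linalg.matrix_rank(X_full)
    if rank_full < X_full.shape[1]:
        raise AliasingError("(within design)")
    q = Z.shape[1]
    n_e = n - rank_full
    if n_e <= 0:
        raise DegenerateDesignError("no residual degrees of freedom")

    beta, _, _, _ = np.linalg.lstsq(X_full, Z, rcond=None)
    resid = Z - X_full @ beta
    E = resid.T @ resid
    Sigma = E / n_e
    eps = gg_epsilon(C @ Sigma @ C.T)  # back to k x k space (equivalent)
    mauchly_p = _mauchly(Sigma, n_e)

    tr_E = float(np.trace(E))
    for term, Xt in cols.items():
        X_red = np.hstack([v for t, v in cols.items() if t != term]) \
            if len(cols) > 1 else np.zeros((n, 0))
        if X_red.shape[1]:
            beta_r, _, _, _ = np.linalg.lstsq(X_red, Z, rcond=None)
            resid_r = Z - X_red @ beta_r
        else:
            resid_r = Z
        H = resid_r.T @ resid_r - E
        ss_h = max(float(np.trace(H)), 0.0)
        df_t = Xt.shape[1]
        df1 = q * df_t
        df2 = q * n_e
        scale = max(tr_E, ss_h, float(np.trace(Z.T @ Z)), 1.0)
        if ss_h <= _RTOL * scale and tr_E <= _RTOL * scale:
            F = 0.0
        elif tr_E <= _RTOL * scale:
            F = float("inf")
        else:
            F = (ss_h / df1) / (tr_E / df2)
        wname = "block" if term == "(intercept)" else f"block:{term}"
        p_unc = float(stats.f.sf(F, df1, df2)) if np.isfinite(F) else 0.0
        df1_gg, df2_gg = df1 * eps, df2 * eps
        p_gg = float(stats.f.sf(F, df1_gg, df2_gg)) if np.isfinite(F) else 0.0
        corrected = mauchly_p < 0.05
        results.append(AnovaResult(
            term=wname, F=float(F), df1=float(df1), df2=float(df2),
            p=(p_gg if corrected else p_unc), ss=ss_h, epsilon=eps,
            df1_gg=df1_gg, df2_gg=df2_gg, p_gg=p_gg,
            mauchly_p=mauchly_p, corrected=corrected))
    return results


LINEAR_TREND_WEIGHTS = np.array([-3.0, -1.0, 1.0, 3.0]) / np.sqrt(20.0)


def polynomial_contrast_test(data: pd.DataFrame, spec: ModelSpec,
                             factor: str = "carrier") -> AnovaResult:
    """Linear-trend-across-blocks test of one between-subject factor.

    Each subject's four block values are collapsed to a linear trend score
    with orthonormal weights (-3, -1, 1, 3)/sqrt(20); the factor's effect
    on the trend scores is then tested by univariate ANCOVA, which is the
    block-by-factor linear interaction test.
    """
    if isinstance(spec.outcome, str) or len(spec.outcome) != 4:
        raise ValueError("polynomial contrast needs exactly 4 outcome columns")
    sub = data.dropna(subset=[*spec.outcome, *spec.between, *spec.covariates])
    trend = sub[list(spec.outcome)].to_numpy(dtype=float) @ LINEAR_TREND_WEIGHTS
    tmp = sub.copy()
    tmp["__trend__"] = trend
    res = fit_anova(tmp, ModelSpec(outcome="__trend__", between=spec.between,
                                   covariates=spec.covariates,
                                   interactions=spec.interactions,
                                   ss_type=spec.ss_type))
    for r in res:
        if r.term == factor:
            r.term = f"block_linear:{factor}"
            return r
    raise ValueError(f"factor {factor!r} not in model")


# ---------------------------------------------------------------------------
# screening tests

def ks_normality(values: Sequence[float]) -> tuple[float, float]:
    """Kolmogorov-Smirnov normality screen with estimated parameters.

    One-sample KS distance against N(mean, sd) fitted from the data, with
    Lilliefors-calibrated p-values (table/Monte-Carlo based); the naive KS
    p would be grossly conservative when parameters are estimated.
    """
    from statsmodels.stats.diagnostic import lilliefors

    x = np.asarray(pd.Series(values).dropna(), dtype=float)
    if len(x) < 5:
        raise DegenerateDesignError("need at least 5 observations")
    if np.ptp(x) == 0:
        raise DegenerateDesignError("constant column")
    D, p = lilliefors(x, dist="norm", pvalmethod="table")
    return float(D), float(p)


def chi_square_test(table) -> tuple[float, int, float]:
    """Pearson chi-square of independence, no continuity correction."""
    t = np.asarray(table, dtype=float)
    if np.any(t < 0):
        raise DomainError("counts must be non-negative")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise DegenerateDesignError("zero marginal total")
    chi2, p, df, _ = stats.chi2_contingency(t, correction=False)
    return float(chi2), int(df), float(p)
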