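"""Effect sizes, Hardy-Weinberg testing, and additive-model power.

The power calculus answers: a biallelic locus explains a fraction ``r2``
of the phenotypic variance of a quantitative trait under an additive
(per-allele) model — how many participants are needed for the 1-df
genotype test to reach a target power?  The noncentral-F formulation
uses noncentrality lambda(N) = N * r2 / (1 - r2) with the critical value
from F(1, N - model_df_consumed); a likelihood-ratio (chi-square)
variant with lambda(N) = N * ln(1 / (1 - r2)) — the calculus used by the
classic genetic power calculators — is also provided.  Given ``r2``, the
required N does not depend on the allele frequency; the MAF enters only
when converting between the per-allele effect beta and ``r2``
(var explained = 2 p q beta^2 under additivity).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import BoundedSearchError, DegenerateDesignError, DomainError

__all__ = ["EffectSize", "PowerSpec", "HweResult", "cohens_d",
           "variance_explained", "d_to_r2", "power_at_n",
           "sample_size_for_power", "allele_effect", "hwe_test", "bonferroni"]


@dataclass(frozen=True)
class EffectSize:
    """Cohen's d with its ingredients.  Sign convention: positive =
    risk-carrier deficit (first sample = reference/non-carrier group on a
    higher-is-better outcome)."""

    d: float
    n0: int
    n1: int
    pooled_sd: float


@dataclass(frozen=True)
class PowerSpec:
    """An additive-single-locus power problem."""

    r2: float
    maf: float = 0.067
    model: str = "additive"
    alpha: float = 0.05
    power: float = 0.80
    model_df_consumed: int = 2  # intercept + genotype

    def __post_init__(self):
        if not (0.0 < self.r2 < 1.0):
            raise DomainError("r2 must lie in (0, 1)")
        if not (0.0 < self.maf < 0.5):
            raise DomainError("maf must lie in (0, 0.5)")
        if not (0.0 < self.alpha < 1.0 and 0.0 < self.power < 1.0):
            raise DomainError("alpha and power must lie in (0, 1)")
        if self.model not in ("additive", "dominant", "recessive"):
            raise DomainError(f"unknown genetic model {self.model!r}")


def cohens_d(values0, values1) -> EffectSize:
    """Pooled-SD standardized mean difference (mean0 - mean1) / s_pooled."""
    x0 = np.asarray(values0, dtype=float)
    x1 = np.asarray(values1, dtype=float)
    n0, n1 = len(x0), len(x1)
    if n0 < 2 or n1 < 2:
        raise DegenerateDesignError("each sample needs at least 2 values")
    sp2 = ((n0 - 1) * x0.var(ddof=1) + (n1 - 1) * x1.var(ddof=1)) / (n0 + n1 - 2)
    if sp2 <= 0:
        raise DegenerateDesignError("zero pooled variance")
    sp = math.sqrt(sp2)
    return EffectSize(d=float((x0.mean() - x1.mean()) / sp),
                      n0=n0, n1=n1, pooled_sd=sp)


def variance_explained(F: float, df1: float, df2: float) -> float:
    """Partial eta-squared from an observed F: F*df1 / (F*df1 + df2)."""
    if F < 0:
        raise DomainError("F must be non-negative")
    return float(F * df1 / (F * df1 + df2))


def d_to_r2(d: float, carrier_fraction: float) -> float:
    """Point-biserial conversion: variance explained by a two-class
    contrast with group fraction q and standardized difference d."""
    q = carrier_fraction
    if not (0.0 < q < 1.0):
        raise DomainError("carrier fraction must lie in (0, 1)")
    num = d * d * q * (1.0 - q)
    return float(num / (num + 1.0))


def power_at_n(N: int, spec: PowerSpec, method: str = "ncf") -> float:
    """Power of the 1-df genotype test at total sample size N.

    ``ncf``: exact noncentral-F power of the linear-model F test,
    lambda = N r2/(1-r2), denominator df = N - model_df_consumed.
    ``lrt``: chi-square likelihood-ratio approximation,
    lambda = N ln(1/(1-r2)).
    """
    if method == "lrt":
        lam = N * math.log(1.0 / (1.0 - spec.r2))
        crit = stats.chi2.isf(spec.alpha, 1)
        return float(stats.ncx2.sf(crit, 1, lam))
    if method != "ncf":
        raise ValueError(f"unknown method {method!r}")
    df2 = N - spec.model_df_consumed
    if df2 <= 0:
        raise DomainError("N must exceed model_df_consumed")
    lam = N * spec.r2 / (1.0 - spec.r2)
    crit = stats.f.isf(spec.alpha, 1, df2)
    return float(stats.ncf.sf(crit, 1, df2, lam))


def sample_size_for_power(spec: PowerSpec, method: str = "ncf",
                          ceiling: int = 10_000_000) -> int:
    """Smallest integer N whose power reaches ``spec.power``.

    Monotone bracketing + bisection; raises :class:`BoundedSearchError`
    when even ``ceiling`` participants fall short.
    """
    lo = spec.model_df_consumed + 2
    hi = lo
    while power_at_n(hi, spec, method=method) < spec.power:
        hi *= 2
        if hi > ceiling:
            if power_at_n(ceiling, spec, method=method) < spec.power:
                raise BoundedSearchError(
                    ceiling, f"required N exceeds {ceiling} at r2={spec.r2}")
            hi = ceiling
            break
    while lo < hi:
        mid = (lo + hi) // 2
        if power_at_n(mid, spec, method=method) >= spec.power:
            hi = mid
        else:
            lo = mid + 1
    return int(lo)


def allele_effect(spec: PowerSpec, sigma: float = 1.0) -> float:
    """Per-allele (additive), or genotype-class, effect size implied by r2.

    Under additivity, r2 = 2 p q beta^2 / sigma_total^2, hence
    beta = sqrt(r2 sigma^2 / (2 p q (1 - r2))) on the residual-sd scale.
    Dominant / recessive use the carrier-class variance q_c (1 - q_c).
    """
    p, q = 1.0 - spec.maf, spec.maf
    if spec.model == "additive":
        var_g = 2.0 * p * q
    elif spec.model == "dominant":
        qc = q * q + 2.0 * p * q
        var_g = qc * (1.0 - qc)
    else:
        qc = q * q
        var_g = qc * (1.0 - qc)
    return float(math.sqrt(spec.r2 * sigma * sigma / (var_g * (1.0 - spec.r2))))


# ---------------------------------------------------------------------------
# Hardy-Weinberg

@dataclass(frozen=True)
class HweResult:
    counts: tuple[int, int, int]       # (n_AA, n_Aa, n_aa), a = minor allele
    expected: tuple[float, float, float]
    allele_freq: float                 # minor (a) allele frequency
    chi2: float
    p_chi2: float
    p_exact: float


def hwe_exact_p(n_aa_major: int, n_het: int, n_aa_minor: int) -> float:
    """Exact conditional Hardy-Weinberg test (sum of heterozygote-count
    probabilities no larger than the observed one, given allele counts)."""
    n = n_aa_major + n_het + n_aa_minor
    n_rare = 2 * n_aa_minor + n_het
    # probabilities over all heterozygote counts with the same parity
    het_values = range(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2)
    logs = {}
    for h in het_values:
        rare_hom = (n_rare - h) // 2
        com_hom = n - h - rare_hom
        logs[h] = (h * math.log(2.0)
                   + math.lgamma(n + 1)
                   - math.lgamma(h + 1) - math.lgamma(rare_hom + 1)
                   - math.lgamma(com_hom + 1)
                   + math.lgamma(n_rare + 1) + math.lgamma(2 * n - n_rare + 1)
                   - math.lgamma(2 * n + 1))
    mx = max(logs.values())
    probs = {h: math.exp(v - mx) for h, v in logs.items()}
    total = sum(probs.values())
    obs = probs[n_het]
    p = sum(v for v in probs.values() if v <= obs * (1.0 + 1e-12)) / total
    return min(p, 1.0)


def hwe_test(counts) -> HweResult:
    """Pearson chi-square (df = 1) and exact conditional HWE tests.

    ``counts`` = (n_AA, n_Aa, n_aa) with ``a`` the minor allele; the
    expected counts come from the allele frequency estimated in-sample.
    """
    c = tuple(int(x) for x in counts)
    if len(c) != 3 or min(c) < 0:
        raise DomainError("counts must be three non-negative integers")
    n = sum(c)
    if n == 0:
        raise DegenerateDesignError("no genotyped individuals")
    q = (c[1] + 2 * c[2]) / (2.0 * n)
    p = 1.0 - q
    expected = (n * p * p, n * 2.0 * p * q, n * q * q)
    if q in (0.0, 1.0):
        return HweResult(c, expected, q, 0.0, 1.0, 1.0)
    chi2 = sum((o - e) ** 2 / e for o, e in zip(c, expected))
    p_chi2 = float(stats.chi2.sf(chi2, 1))
    return HweResult(counts=c, expected=expected, allele_freq=float(q),
                     chi2=float(chi2), p_chi2=p_chi2,
                     p_exact=float(hwe_exact_p(*c)))


def bonferroni(p_values, m: int | None = None) -> list[float]:
    """min(1, m * p) per entry; m defaults to the list length."""
    ps = list(p_values)
    if m is None:
        m = len(ps)
    if m < len(ps):
        raise DomainError("m must be at least the number of p-values")
    return [min(1.0, m * float(p)) for p in ps]
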