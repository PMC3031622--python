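"""Seeded synthetic cohorts for a family-based candidate-SNP cognition study.

The generator emulates a three-group design — bipolar-disorder (BD)
patients, their unaffected first-degree relatives, and unrelated controls
— genotyped at one rare biallelic SNP (risk allele T, population MAF
0.067), each completing a 480-trial degraded-stimulus CPT plus a battery
of summary cognitive outcomes.  Because the rare homozygote is expected
at most once per ~190 participants, all downstream analysis collapses TT
with CT into a single risk-carrier class.

Three layers:

* :func:`generate_cohort` — participants with family structure (relatives'
  genotypes follow Mendelian transmission from an implied parental pair
  consistent with the index patient), Hardy-Weinberg genotypes for the
  unrelated groups, and clinical scores (truncated-normal BPRS >= 24 with
  HDRS/YMRS as correlated ancillaries).
* :func:`generate_cpt_session` / :func:`generate_cpt_matrix` — trial-level
  CPT responses from a latent equal-variance signal-detection skeleton
  with subject-level criterion drift.  The carrier deficit is a
  hit-rate-preserving separation loss: the response criterion tracks the
  degraded target distribution, so the loss surfaces as extra false
  alarms and reduced sensitivity while hit rate stays genotype-null and
  the scored bias index moves only a little (the small residual is a
  geometric consequence of both indices being functions of the same
  (H, F) pair; see docs/methods.md).
* :func:`generate_phenotypes` — the non-CPT outcome columns with
  configurable carrier effect sizes; perseverative errors are drawn from
  a right-skewed (log-normal) law to exercise the permutation path.

Per-block carrier effects are specified as Cohen's d on the *scored*
sensitivity and false-alarm variables; a cached Monte-Carlo calibration
maps them onto latent separation shifts.
"""

from __future__ import annotations

import functools
import io
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm, truncnorm

from .errors import ConfigurationError, GenerationError
from .scoring import (BLOCK_LEN, N_BLOCKS, N_PRACTICE, N_TRIALS,
                      TARGETS_PER_BLOCK, score_counts)

__all__ = [
    "SdtParams",
    "CohortConfig",
    "Participant",
    "CptSession",
    "CohortCpt",
    "generate_cohort",
    "generate_cpt_session",
    "generate_cpt_matrix",
    "generate_phenotypes",
    "block_scores_from_matrix",
    "calibrate_carrier_shifts",
    "carrier_class",
    "OUTCOME_REGISTRY",
    "DEFAULT_CARRIER_EFFECTS",
]

STATUSES = ("patient", "relative", "control")

# ---------------------------------------------------------------------------
# demographic / clinical cell parameters, per status x carrier class
# (carrier class: "CC" vs "CT+TT")

AGE_PARAMS = {
    ("patient", 0): (43.88, 10.68), ("patient", 1): (45.43, 11.54),
    ("relative", 0): (32.94, 11.64), ("relative", 1): (32.80, 15.34),
    ("control", 0): (36.20, 13.17), ("control", 1): (37.56, 14.65),
}
EDUCATION_PARAMS = {
    ("patient", 0): (3.60, 0.99), ("patient", 1): (3.20, 0.82),
    ("relative", 0): (3.75, 0.87), ("relative", 1): (3.20, 0.84),
    ("control", 0): (3.59, 0.98), ("control", 1): (3.64, 1.12),
}
DEFAULT_BPRS_PARAMS = {
    ("patient", 0): (27.78, 3.77), ("patient", 1): (24.57, 0.98),
    ("relative", 0): (24.74, 1.71), ("relative", 1): (24.40, 0.89),
    ("control", 0): (24.24, 0.50), ("control", 1): (24.82, 0.98),
}
BPRS_FLOOR = 24.0  # 24 items, minimum rating 1 each
# HDRS / YMRS means and sds per status (remitted patients score < 7)
HDRS_PARAMS = {"patient": (4.0, 1.3), "relative": (1.2, 1.0), "control": (1.2, 1.0)}
YMRS_PARAMS = {"patient": (2.5, 1.2), "relative": (0.8, 0.8), "control": (0.8, 0.8)}
CLINICAL_BPRS_CORR = 0.73

# ---------------------------------------------------------------------------
# non-CPT cognitive outcomes: base mean/sd, orientation, distribution and
# affection-status deficits (in SD units: patient, relative)

OUTCOME_REGISTRY: dict[str, dict] = {
    "fsiq": dict(mean=105.0, sd=15.0, higher_better=True, dist="normal",
                 status_deficit=(0.35, 0.10)),
    "scwt_correct": dict(mean=52.0, sd=9.0, higher_better=True, dist="normal",
                         status_deficit=(0.50, 0.20)),
    "wcst_categories": dict(mean=4.8, sd=1.3, higher_better=True, dist="count6",
                            status_deficit=(0.40, 0.15)),
    "wcst_perseverative_errors": dict(mean=None, sd=None, higher_better=False,
                                      dist="lognormal", mu=2.30, sigma=0.70,
                                      status_deficit=(0.40, 0.15)),
    "wms_auditory_immediate": dict(mean=102.0, sd=15.0, higher_better=True,
                                   dist="normal", status_deficit=(0.45, 0.15)),
    "wms_visual_immediate": dict(mean=101.0, sd=15.0, higher_better=True,
                                 dist="normal", status_deficit=(0.45, 0.15)),
    "wms_immediate": dict(mean=102.0, sd=15.0, higher_better=True, dist="normal",
                          status_deficit=(0.45, 0.15)),
    "wms_auditory_delayed": dict(mean=103.0, sd=15.0, higher_better=True,
                                 dist="normal", status_deficit=(0.45, 0.15)),
    "wms_visual_delayed": dict(mean=101.0, sd=15.0, higher_better=True,
                               dist="normal", status_deficit=(0.45, 0.15)),
    "wms_auditory_recognition_delayed": dict(mean=102.0, sd=15.0,
                                             higher_better=True, dist="normal",
                                             status_deficit=(0.40, 0.15)),
    "wms_general_memory": dict(mean=102.0, sd=15.0, higher_better=True,
                               dist="normal", status_deficit=(0.45, 0.15)),
    "wms_working_memory": dict(mean=101.0, sd=15.0, higher_better=True,
                               dist="normal", status_deficit=(0.50, 0.20)),
    "igt_emotional_learning": dict(mean=0.35, sd=0.55, higher_better=True,
                                   dist="normal", status_deficit=(0.30, 0.10)),
}

# carrier deficits (Cohen's d, positive = carrier worse) on the non-CPT
# outcomes: negligible-to-small everywhere except working memory (0.35)
# and Stroop interference (0.44)
DEFAULT_CARRIER_EFFECTS: dict[str, float] = {
    "fsiq": 0.14,
    "scwt_correct": 0.44,
    "wcst_categories": 0.05,
    "wcst_perseverative_errors": 0.05,
    "wms_auditory_immediate": 0.17,
    "wms_visual_immediate": 0.13,
    "wms_immediate": 0.11,
    "wms_auditory_delayed": 0.13,
    "wms_visual_delayed": 0.03,
    "wms_auditory_recognition_delayed": 0.14,
    "wms_general_memory": 0.03,
    "wms_working_memory": 0.35,
    "igt_emotional_learning": 0.02,
}


@dataclass(frozen=True)
class SdtParams:
    """Latent structure of the CPT response model (probit scale).

    ``z_hit = a0 + shift_h[status] + b_i`` and
    ``z_fa  = f0[block] + shift_f[status] + coupling * b_i - u_i + nu_i
              + carrier_shift[block] * carrier``
    where ``b_i`` is shared criterion-placement heterogeneity, ``u_i``
    subject sensitivity and ``nu_i`` residual criterion drift on the
    non-target channel.  ``coupling < 1`` expresses that the criterion
    drifts between the two trial contexts rather than moving rigidly.
    """

    a0: float = 1.10
    f0: tuple[float, float, float, float] = (-1.30, -1.25, -1.20, -1.15)
    sigma_bias: float = 0.85
    bias_coupling: float = 0.70
    sigma_sens: float = 0.22
    sigma_fa: float = 0.25
    status_shift_hit: Mapping[str, float] = field(
        default_factory=lambda: {"patient": -0.08, "relative": -0.03, "control": 0.0})
    status_shift_fa: Mapping[str, float] = field(
        default_factory=lambda: {"patient": 0.12, "relative": 0.04, "control": 0.0})
    rt_mean_ms: float = 430.0
    rt_subject_sd_ms: float = 40.0
    rt_block_slowing_ms: float = 6.0
    rt_sdlog: float = 0.18


@dataclass(frozen=True)
class CohortConfig:
    """Study-design parameters of a synthetic cohort."""

    n_patients: int = 46
    n_relatives: int = 73
    n_controls: int = 67
    maf: float = 0.067
    carrier_effect_sensitivity: tuple[float, float, float, float] = (0.0, 0.31, 0.61, 0.92)
    carrier_effect_false_alarms: tuple[float, float, float, float] = (0.0, 0.28, 0.55, 0.83)
    carrier_effects_other: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CARRIER_EFFECTS))
    bprs_params: Mapping[tuple[str, int], tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BPRS_PARAMS))
    sdt: SdtParams = field(default_factory=SdtParams)
    genotype_missing_rate: float = 0.0
    outcome_missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if min(self.n_patients, self.n_relatives, self.n_controls) < 0:
            raise ConfigurationError("group counts must be non-negative")
        if not (0.0 <= self.maf < 1.0):
            raise ConfigurationError("maf must lie in [0, 1)")
        for name in ("carrier_effect_sensitivity", "carrier_effect_false_alarms"):
            arr = getattr(self, name)
            if len(arr) != N_BLOCKS:
                raise ConfigurationError(f"{name} must have exactly {N_BLOCKS} entries")
        unknown = set(self.carrier_effects_other) - set(OUTCOME_REGISTRY)
        if unknown:
            raise ConfigurationError(f"unknown outcome(s) in config: {sorted(unknown)}")
        if not (0.0 <= self.genotype_missing_rate < 1.0):
            raise ConfigurationError("genotype_missing_rate must lie in [0, 1)")

    # -- YAML round trip ----------------------------------------------------
    def to_yaml(self) -> str:
        d = {
            "n_patients": self.n_patients, "n_relatives": self.n_relatives,
            "n_controls": self.n_controls, "maf": self.maf,
            "carrier_effect_sensitivity": list(self.carrier_effect_sensitivity),
            "carrier_effect_false_alarms": list(self.carrier_effect_false_alarms),
            "carrier_effects_other": dict(self.carrier_effects_other),
            "bprs_params": {f"{s}:{c}": list(v) for (s, c), v in self.bprs_params.items()},
            "genotype_missing_rate": self.genotype_missing_rate,
            "outcome_missing_rate": self.outcome_missing_rate,
            "seed": self.seed,
        }
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "CohortConfig":
        d = yaml.safe_load(io.StringIO(text)) or {}
        if "bprs_params" in d:
            d["bprs_params"] = {
                (k.split(":")[0], int(k.split(":")[1])): tuple(v)
                for k, v in d["bprs_params"].items()}
        for k in ("carrier_effect_sensitivity", "carrier_effect_false_alarms"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass(frozen=True)
class Participant:
    """One study subject (the row schema of the participant table)."""

    id: str
    family_id: str
    status: str
    age: float
    sex: str
    education: int
    bprs: float
    hdrs: float
    ymrs: float
    genotype: str  # CC / CT / TT / missing


@dataclass
class CptSession:
    """Trial-level record of one 480-trial CPT run."""

    participant_id: str
    trials: pd.DataFrame  # columns: index, is_target, responded, rt_ms

    def write_csv(self, path) -> None:
        self.trials.to_csv(path, index=False)


@dataclass
class CohortCpt:
    """Vectorised CPT data for a whole cohort (one row per participant)."""

    participant_ids: list[str]
    is_target: np.ndarray   # (n, 480) bool
    responded: np.ndarray   # (n, 480) bool
    rt_ms: np.ndarray       # (n, 480) float, NaN where not responded

    def session(self, participant_id: str) -> CptSession:
        i = self.participant_ids.index(participant_id)
        trials = pd.DataFrame({
            "index": np.arange(1, N_TRIALS + 1),
            "is_target": self.is_target[i],
            "responded": self.responded[i],
            "rt_ms": self.rt_ms[i],
        })
        return CptSession(participant_id, trials)


def carrier_class(genotype) -> object:
    """Collapse TT with the heterozygotes: 1 = risk-allele carrier.

    Vectorised over pandas Series; 'missing' maps to NA/None.
    """
    if isinstance(genotype, pd.Series):
        out = pd.Series(np.where(genotype.isin(["CT", "TT"]), 1, 0),
                        index=genotype.index)
        return out.mask(~genotype.isin(["CC", "CT", "TT"]))
    if genotype in ("CT", "TT"):
        return 1
    if genotype == "CC":
        return 0
    return None


# ---------------------------------------------------------------------------
# genotype machinery

def _hwe_probs(maf: float) -> np.ndarray:
    p = 1.0 - maf
    return np.array([p * p, 2.0 * p * maf, maf * maf])


def _transmission_tensor() -> np.ndarray:
    """T[gf, gm, gc]: child genotype distribution given parents (T-allele counts)."""
    T = np.zeros((3, 3, 3))
    for gf in range(3):
        for gm in range(3):
            pf, pm = gf / 2.0, gm / 2.0
            T[gf, gm, 0] = (1 - pf) * (1 - pm)
            T[gf, gm, 1] = pf * (1 - pm) + (1 - pf) * pm
            T[gf, gm, 2] = pf * pm
    return T


_TRANS = _transmission_tensor()
_GENO_LABELS = np.array(["CC", "CT", "TT"])


def _sample_relative_genotypes(patient_g: int, n_rel: int, maf: float,
                               rng: np.random.Generator) -> np.ndarray:
    """Mendelian genotypes for relatives of one patient.

    An implied parental pair is drawn from its Hardy-Weinberg posterior
    given the patient's genotype; each relative is then a sibling drawn by
    transmission from that pair (so relatives of the same patient are
    correlated, as in real families).
    """
    hwe = _hwe_probs(maf)
    prior = hwe[:, None] * hwe[None, :]
    post = prior * _TRANS[:, :, patient_g]
    total = post.sum()
    if total <= 0:  # impossible patient genotype at this maf (maf == 0, TT)
        raise GenerationError("patient genotype inconsistent with allele frequency")
    flat = rng.choice(9, p=(post / total).ravel())
    gf, gm = divmod(flat, 3)
    return rng.choice(3, size=n_rel, p=_TRANS[gf, gm])


def _truncnorm_at_floor(mean, sd, floor, size, rng):
    a = (floor - mean) / sd
    return truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size,
                         random_state=rng)


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Generate the participant table.

    Genotypes of patients and controls are Hardy-Weinberg draws at
    ``config.maf``; relatives' genotypes arise from Mendelian transmission
    within each family.  Each relative shares a ``family_id`` with exactly
    one patient; controls have their own families.  BPRS is truncated
    normal at the scale floor of 24 with per-status-by-carrier-class
    parameters; HDRS and YMRS are generated as ancillaries correlated with
    BPRS (r ~ 0.73) and are not used downstream.

    Reproducible: identical config (including seed) gives a bit-identical
    table.
    """
    rng = np.random.default_rng(config.seed)
    n_p, n_r, n_c = config.n_patients, config.n_relatives, config.n_controls

    rows = []
    hwe = _hwe_probs(config.maf)

    patient_g = rng.choice(3, size=n_p, p=hwe) if n_p else np.array([], int)
    control_g = rng.choice(3, size=n_c, p=hwe) if n_c else np.array([], int)

    # distribute relatives over patient families, 1-2 per family where possible
    rel_counts = np.zeros(n_p, dtype=int)
    if n_r and n_p:
        base = min(n_r // n_p, 2)
        rel_counts[:] = base
        extra = n_r - base * n_p
        if extra > 0:
            bump = rng.choice(n_p, size=min(extra, n_p), replace=False)
            rel_counts[bump] += 1
            overflow = extra - len(bump)
            while overflow > 0:  # more relatives than 2 per family: spread round-robin
                take = rng.choice(n_p, size=min(overflow, n_p), replace=False)
                rel_counts[take] += 1
                overflow -= len(take)
    elif n_r:
        raise ConfigurationError("relatives require at least one patient family")

    for i in range(n_p):
        rows.append(("P%03d" % (i + 1), "FAM%03d" % (i + 1), "patient",
                     int(patient_g[i])))
    rel_idx = 0
    for i in range(n_p):
        if rel_counts[i] == 0:
            continue
        rel_g = _sample_relative_genotypes(int(patient_g[i]), int(rel_counts[i]),
                                           config.maf, rng)
        for g in rel_g:
            rel_idx += 1
            rows.append(("R%03d" % rel_idx, "FAM%03d" % (i + 1), "relative", int(g)))
    for i in range(n_c):
        rows.append(("C%03d" % (i + 1), "CFAM%03d" % (i + 1), "control",
                     int(control_g[i])))

    df = pd.DataFrame(rows, columns=["id", "family_id", "status", "_g"])
    df["genotype"] = _GENO_LABELS[df["_g"].to_numpy()]
    df = df.drop(columns="_g")

    if config.genotype_missing_rate > 0:
        miss = rng.random(len(df)) < config.genotype_missing_rate
        df.loc[miss, "genotype"] = "missing"

    carrier = carrier_class(df["genotype"]).fillna(0).astype(int)

    age = np.empty(len(df))
    edu = np.empty(len(df), dtype=int)
    bprs = np.empty(len(df))
    for (status, carr), sub in df.groupby([df["status"], carrier]):
        idx = sub.index.to_numpy()
        m, s = AGE_PARAMS[(status, carr)]
        age[idx] = np.clip(rng.normal(m, s, len(idx)), 17.0, 65.0)
        m, s = EDUCATION_PARAMS[(status, carr)]
        edu[idx] = np.clip(np.rint(rng.normal(m, s, len(idx))), 1, 5).astype(int)
        m, s = config.bprs_params[(status, carr)]
        bprs[idx] = _truncnorm_at_floor(m, s, BPRS_FLOOR, len(idx), rng)

    df["age"] = np.round(age, 1)
    df["sex"] = rng.choice(["male", "female"], size=len(df))
    df["education"] = edu
    df["bprs"] = np.round(bprs, 1)

    hdrs = np.empty(len(df))
    ymrs = np.empty(len(df))
    lam = CLINICAL_BPRS_CORR
    resid = np.sqrt(1.0 - lam * lam)
    for status, sub in df.groupby("status"):
        idx = sub.index.to_numpy()
        m_b, s_b = config.bprs_params[(status, 0)]
        zb = (df.loc[idx, "bprs"].to_numpy() - m_b) / max(s_b, 1e-9)
        m, s = HDRS_PARAMS[status]
        hdrs[idx] = np.clip(m + s * (lam * zb + resid * rng.standard_normal(len(idx))), 0, None)
        m, s = YMRS_PARAMS[status]
        ymrs[idx] = np.clip(m + s * (lam * zb + resid * rng.standard_normal(len(idx))), 0, None)
    df["hdrs"] = np.round(hdrs, 1)
    df["ymrs"] = np.round(ymrs, 1)

    return df[["id", "family_id", "status", "age", "sex", "education",
               "bprs", "hdrs", "ymrs", "genotype"]]


# ---------------------------------------------------------------------------
# carrier-effect calibration: scored Cohen's d target -> latent shift

_CAL_M = 20000
_CAL_SEED = 987654321


@functools.lru_cache(maxsize=1)
def _calibration_draws() -> tuple:
    """Common random numbers for the calibration Monte Carlo."""
    rng = np.random.default_rng(_CAL_SEED)
    b = rng.standard_normal(_CAL_M)
    u = rng.standard_normal(_CAL_M)
    nu = rng.standard_normal(_CAL_M)
    u_hit = rng.random((_CAL_M, TARGETS_PER_BLOCK))
    u_fa = rng.random((_CAL_M, BLOCK_LEN - TARGETS_PER_BLOCK))
    return b, u, nu, u_hit, u_fa


def _sdt_cal_key(sdt: SdtParams, maf: float) -> tuple:
    """The latent parameters the calibration depends on (status shifts are
    zero in the calibration population) plus the Hardy-Weinberg carrier
    fraction, which sets the pooled-SD weighting."""
    cf = round(1.0 - (1.0 - maf) ** 2, 6)
    return (sdt.a0, tuple(sdt.f0), sdt.sigma_bias, sdt.bias_coupling,
            sdt.sigma_sens, sdt.sigma_fa, cf)


def _scored_d(cal_key: tuple, block: int, shift: float) -> tuple[float, float]:
    """(d_sensitivity, d_false_alarms) between non-carriers and carriers
    for a latent shift applied to the false-alarm channel of one block.

    The pooled SD weights the two groups by the carrier fraction the
    config implies, mirroring the pooled-SD Cohen's d an analyst computes
    on a cohort where carriers are the small group.
    """
    a0, f0_blocks, sigma_bias, bias_coupling, sigma_sens, sigma_fa, cf = cal_key
    b, u, nu, u_hit, u_fa = _calibration_draws()
    z_hit = a0 + sigma_bias * b
    hits = (u_hit < norm.cdf(z_hit)[:, None]).sum(axis=1)
    base_fa = (f0_blocks[block] + bias_coupling * sigma_bias * b
               - sigma_sens * u + sigma_fa * nu)
    out = []
    for delta in (0.0, shift):
        fas = (u_fa < norm.cdf(base_fa + delta)[:, None]).sum(axis=1)
        _, f, sens, _ = score_counts(hits, TARGETS_PER_BLOCK, fas,
                                     BLOCK_LEN - TARGETS_PER_BLOCK)
        out.append((sens, f))
    (s0, f0), (s1, f1) = out

    def _d(x_nc, x_c, sign):
        sp = np.sqrt((1.0 - cf) * x_nc.var(ddof=1) + cf * x_c.var(ddof=1))
        return float(sign * (x_c.mean() - x_nc.mean()) / sp) if sp > 0 else 0.0

    # deficit-positive: sensitivity drops, false alarms rise for carriers
    return _d(s0, s1, -1.0), _d(f0, f1, +1.0)


@functools.lru_cache(maxsize=64)
def _calibrated_shifts(cal_key: tuple, sens_targets: tuple, fa_targets: tuple) -> tuple:
    """Latent false-alarm-channel shifts achieving the configured per-block
    Cohen's d targets (balanced between the sensitivity and false-alarm
    targets when both are non-zero)."""
    from scipy.optimize import brentq

    shifts = []
    for blk in range(N_BLOCKS):
        ts, tf = sens_targets[blk], fa_targets[blk]
        if ts == 0.0 and tf == 0.0:
            shifts.append(0.0)
            continue

        def g(delta, blk=blk, ts=ts, tf=tf):
            ds, df_ = _scored_d(cal_key, blk, delta)
            return 0.5 * (ds - ts) + 0.5 * (df_ - tf)

        hi = 1.0
        while g(hi) < 0 and hi < 8.0:
            hi *= 1.5
        shifts.append(float(brentq(g, 0.0, hi, xtol=1e-3)))
    return tuple(shifts)


def calibrate_carrier_shifts(config: CohortConfig) -> np.ndarray:
    """Per-block latent shifts implied by the config's Cohen's d targets."""
    return np.asarray(_calibrated_shifts(
        _sdt_cal_key(config.sdt, config.maf),
        tuple(config.carrier_effect_sensitivity),
        tuple(config.carrier_effect_false_alarms)))


# ---------------------------------------------------------------------------
# CPT generation

def _target_schedule(n: int, rng: np.random.Generator) -> np.ndarray:
    """Quasi-random target placement: per 80-trial segment, 20 targets
    placed uniformly among the non-adjacent subsets (no two consecutive
    targets within a segment), 25% overall."""
    n_seg = N_TRIALS // BLOCK_LEN
    k, slots = TARGETS_PER_BLOCK, BLOCK_LEN - TARGETS_PER_BLOCK + 1
    r = rng.random((n, n_seg, slots))
    picks = np.argpartition(r, k, axis=-1)[..., :k]
    picks.sort(axis=-1)
    pos = picks + np.arange(k)[None, None, :]  # classic non-adjacency bijection
    is_target = np.zeros((n, n_seg, BLOCK_LEN), dtype=bool)
    np.put_along_axis(is_target, pos, True, axis=-1)
    return is_target.reshape(n, N_TRIALS)


def generate_cpt_matrix(participants: pd.DataFrame, config: CohortConfig,
                        rng: np.random.Generator | None = None) -> CohortCpt:
    """Trial-level CPT responses for a whole cohort, vectorised.

    Participants with missing genotype are simulated as non-carriers (the
    phenotype model is genotype-driven only through carrier class).
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    sdt = config.sdt
    n = len(participants)
    carrier = carrier_class(participants["genotype"]).fillna(0).to_numpy(dtype=float)
    status = participants["status"].to_numpy()

    shifts = calibrate_carrier_shifts(config)

    b = rng.standard_normal(n) * sdt.sigma_bias
    u = rng.standard_normal(n) * sdt.sigma_sens
    nu = rng.standard_normal(n) * sdt.sigma_fa
    sh_h = np.array([sdt.status_shift_hit[s] for s in status])
    sh_f = np.array([sdt.status_shift_fa[s] for s in status])

    z_hit = sdt.a0 + sh_h + b                       # block-independent
    p_hit = norm.cdf(z_hit)
    # per block false-alarm probability (block 0 parameters also drive practice)
    z_fa = (np.asarray(sdt.f0)[None, :] + sh_f[:, None]
            + sdt.bias_coupling * b[:, None] - u[:, None] + nu[:, None]
            + shifts[None, :] * carrier[:, None])
    p_fa = norm.cdf(z_fa)                           # (n, 4)

    is_target = _target_schedule(n, rng)

    # map each trial to the block whose parameters drive it (practice -> block 1)
    blk_of_trial = np.maximum(
        (np.arange(N_TRIALS) - N_PRACTICE) // BLOCK_LEN, 0)
    p_resp = np.where(is_target, p_hit[:, None],
                      np.take_along_axis(
                          p_fa, np.broadcast_to(blk_of_trial[None, :], (n, N_TRIALS)),
                          axis=1))
    responded = rng.random((n, N_TRIALS)) < p_resp

    subj_rt = sdt.rt_mean_ms + rng.standard_normal(n) * sdt.rt_subject_sd_ms
    slow = sdt.rt_block_slowing_ms * blk_of_trial
    rt = (subj_rt[:, None] + slow[None, :]) * np.exp(
        rng.standard_normal((n, N_TRIALS)) * sdt.rt_sdlog)
    rt = np.clip(rt, 150.0, None)
    rt_ms = np.where(responded, np.round(rt, 1), np.nan)

    return CohortCpt(list(participants["id"]), is_target, responded, rt_ms)


def generate_cpt_session(participant, config: CohortConfig,
                         rng: np.random.Generator | None = None) -> CptSession:
    """Trial-level CPT session for one participant.

    Raises :class:`GenerationError` when the genotype is missing, since the
    response model is conditioned on carrier status.
    """
    if isinstance(participant, Participant):
        row = pd.DataFrame([participant.__dict__])
    else:
        row = pd.DataFrame([dict(participant)])
    genotype = row.iloc[0]["genotype"]
    if genotype not in ("CC", "CT", "TT"):
        raise GenerationError(
            f"participant {row.iloc[0]['id']!r} has no genotype call")
    if rng is None:
        rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, 2,
                                    abs(hash(row.iloc[0]["id"])) % (2 ** 31)]))
    cpt = generate_cpt_matrix(row, config, rng)
    return cpt.session(row.iloc[0]["id"])


def block_scores_from_matrix(cpt: CohortCpt, method: str = "nonparametric",
                             wide: bool = True) -> pd.DataFrame:
    """Score every participant's four blocks at once.

    Returns a wide table (one row per participant, columns
    ``hit_rate_b1`` ... ``criterion_b4``) or a long one when ``wide`` is
    False; numerically identical to :func:`cogassoc.scoring.score_blocks`
    applied per session.
    """
    n = len(cpt.participant_ids)
    tgt = cpt.is_target[:, N_PRACTICE:].reshape(n, N_BLOCKS, BLOCK_LEN)
    resp = cpt.responded[:, N_PRACTICE:].reshape(n, N_BLOCKS, BLOCK_LEN)
    rt = cpt.rt_ms[:, N_PRACTICE:].reshape(n, N_BLOCKS, BLOCK_LEN)
    n_t = tgt.sum(axis=2)
    hits = (tgt & resp).sum(axis=2)
    fas = (~tgt & resp).sum(axis=2)
    h, f, sens, crit = score_counts(hits, n_t, fas, BLOCK_LEN - n_t, method=method)
    hit_mask = tgt & resp
    rt_sum = np.where(hit_mask, np.nan_to_num(rt), 0.0).sum(axis=2)
    n_hit_rt = hit_mask.sum(axis=2)
    mean_rt = np.divide(rt_sum, n_hit_rt, out=np.full(rt_sum.shape, np.nan),
                        where=n_hit_rt > 0)

    if not wide:
        long = []
        for i, pid in enumerate(cpt.participant_ids):
            for bidx in range(N_BLOCKS):
                long.append({"participant_id": pid, "block": bidx + 1,
                             "hit_rate": h[i, bidx], "false_alarm_rate": f[i, bidx],
                             "sensitivity": sens[i, bidx], "criterion": crit[i, bidx],
                             "mean_rt": mean_rt[i, bidx]})
        return pd.DataFrame(long)

    data = {"id": cpt.participant_ids}
    for bidx in range(N_BLOCKS):
        data[f"hit_rate_b{bidx+1}"] = h[:, bidx]
        data[f"false_alarm_b{bidx+1}"] = f[:, bidx]
        data[f"sensitivity_b{bidx+1}"] = sens[:, bidx]
        data[f"criterion_b{bidx+1}"] = crit[:, bidx]
        data[f"mean_rt_b{bidx+1}"] = mean_rt[:, bidx]
    return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# non-CPT phenotypes

def generate_phenotypes(participants: pd.DataFrame, config: CohortConfig,
                        rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Summary cognitive outcomes with configured carrier effect sizes.

    Effects are standardized mean shifts on the outcome's own scale
    (positive configured d = risk-carrier deficit), with affection-status
    main effects on top.  ``wcst_perseverative_errors`` is log-normal
    (right-skewed) by design.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    carrier = carrier_class(participants["genotype"]).fillna(0).to_numpy(dtype=float)
    status = participants["status"].to_numpy()
    n = len(participants)
    pat = (status == "patient").astype(float)
    rel = (status == "relative").astype(float)

    out = {"id": participants["id"].to_numpy()}
    for name, info in OUTCOME_REGISTRY.items():
        d_carrier = float(config.carrier_effects_other.get(name, 0.0))
        dp, dr = info["status_deficit"]
        deficit = d_carrier * carrier + dp * pat + dr * rel
        noise = rng.standard_normal(n)
        if info["dist"] == "lognormal":
            base = np.exp(info["mu"] + info["sigma"] * noise)
            sd = float(np.sqrt((np.exp(info["sigma"] ** 2) - 1.0))
                       * np.exp(info["mu"] + info["sigma"] ** 2 / 2.0))
            vals = base + sd * deficit  # higher = worse
            vals = np.clip(vals, 0.0, None)
        else:
            sign = -1.0 if info["higher_better"] else 1.0
            vals = info["mean"] + info["sd"] * (noise + sign * deficit)
            if info["dist"] == "count6":
                vals = np.clip(np.rint(vals), 0, 6)
        if config.outcome_missing_rate > 0:
            vals = np.where(rng.random(n) < config.outcome_missing_rate,
                            np.nan, vals)
        out[name] = vals
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# table writers

def write_participants_tsv(participants: pd.DataFrame, path) -> None:
    participants.to_csv(path, sep="\t", index=False)


def write_phenotypes_tsv(phenotypes: pd.DataFrame, path) -> None:
    phenotypes.to_csv(path, sep="\t", index=False)
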