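"""Signal-detection scoring of degraded-stimulus CPT sessions.

A session is 480 one-second trials; a quarter of them present the target.
The first 160 trials are practice and are never scored; the remaining 320
are split, in presentation order, into four blocks of 80 (20 targets, 60
non-targets each).  Per block we report the four classic dependent
variables of sustained-attention research:

* hit rate ``H`` — responses on target trials / targets;
* false-alarm rate ``F`` — responses on non-target trials / non-targets;
* a sensitivity index — non-parametric A' (default) or parametric d';
* a response-criterion (bias) index — B''D (default) or parametric c.

The non-parametric pair (A', B''D) makes no distributional assumption and
is well defined at perfect or empty response counts; the parametric pair
(d', c) assumes equal-variance Gaussian evidence and uses a log-linear
boundary correction (add 0.5 to each count, 1 to each trial total) so that
rates of exactly 0 or 1 stay finite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import DomainError, MalformedSessionError

N_TRIALS = 480
N_PRACTICE = 160
BLOCK_LEN = 80
N_BLOCKS = 4
TARGETS_PER_BLOCK = 20

__all__ = [
    "CptBlockScore",
    "a_prime",
    "b_double_prime",
    "d_prime",
    "criterion_c",
    "sensitivity_index",
    "response_criterion",
    "loglinear_rates",
    "score_blocks",
    "score_counts",
    "read_session_csv",
    "write_block_scores_tsv",
]


@dataclass(frozen=True)
class CptBlockScore:
    """Per-block summary of a CPT session."""

    block: int
    hit_rate: float
    false_alarm_rate: float
    sensitivity: float
    criterion: float
    mean_rt: float
    method: str = "nonparametric"


def _check_rates(h, f) -> tuple[np.ndarray, np.ndarray]:
    h = np.asarray(h, dtype=float)
    f = np.asarray(f, dtype=float)
    if np.any((h < 0) | (h > 1)) or np.any((f < 0) | (f > 1)):
        raise DomainError("hit and false-alarm rates must lie in [0, 1]")
    return h, f


def a_prime(h, f):
    """Non-parametric sensitivity A' in [0, 1]; 0.5 is chance.

    For H >= F:  A' = 0.5 + (H-F)(1+H-F) / (4H(1-F)); below-chance
    performance uses the reflected form so that A'(H,F) + A'(F,H) = 1.
    """
    h, f = _check_rates(h, f)
    above = 4.0 * h * (1.0 - f)
    below = 4.0 * f * (1.0 - h)
    with np.errstate(divide="ignore", invalid="ignore"):
        upper = 0.5 + ((h - f) * (1.0 + h - f)) / above
        lower = 0.5 - ((f - h) * (1.0 + f - h)) / below
    out = np.where(h >= f, upper, lower)
    # H == F is chance whatever the common value (covers 0/0 at corners)
    out = np.where(np.isclose(h, f, atol=1e-12), 0.5, out)
    return out if out.ndim else float(out)


def b_double_prime(h, f):
    """Non-parametric response criterion B''D in [-1, 1].

    Positive values indicate a conservative criterion (much perceptual
    evidence required before responding); 0 is unbiased.
    """
    h, f = _check_rates(h, f)
    num = (1.0 - h) * (1.0 - f) - h * f
    den = (1.0 - h) * (1.0 - f) + h * f
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(den == 0, 0.0, num / np.where(den == 0, 1.0, den))
    return out if out.ndim else float(out)


def d_prime(h, f):
    """Parametric sensitivity d' = z(H) - z(F); caller supplies corrected
    rates when counts may sit on the boundary."""
    h, f = _check_rates(h, f)
    out = norm.ppf(h) - norm.ppf(f)
    return out if out.ndim else float(out)


def criterion_c(h, f):
    """Parametric criterion c = -(z(H) + z(F)) / 2; 0 is unbiased."""
    h, f = _check_rates(h, f)
    out = -(norm.ppf(h) + norm.ppf(f)) / 2.0
    return out if out.ndim else float(out)


def loglinear_rates(hits, n_targets, false_alarms, n_nontargets):
    """Boundary-safe rates: (count + 0.5) / (n + 1) for both rates."""
    hits = np.asarray(hits, dtype=float)
    false_alarms = np.asarray(false_alarms, dtype=float)
    h = (hits + 0.5) / (np.asarray(n_targets, dtype=float) + 1.0)
    f = (false_alarms + 0.5) / (np.asarray(n_nontargets, dtype=float) + 1.0)
    return h, f


def sensitivity_index(h, f, method: str = "nonparametric"):
    """Sensitivity from rates: A' (``nonparametric``) or d' (``parametric``)."""
    if method == "nonparametric":
        return a_prime(h, f)
    if method == "parametric":
        return d_prime(h, f)
    raise ValueError(f"unknown method {method!r}")


def response_criterion(h, f, method: str = "nonparametric"):
    """Response bias from rates: B''D (``nonparametric``) or c (``parametric``)."""
    if method == "nonparametric":
        return b_double_prime(h, f)
    if method == "parametric":
        return criterion_c(h, f)
    raise ValueError(f"unknown method {method!r}")


def score_counts(hits, n_targets, false_alarms, n_nontargets,
                 method: str = "nonparametric"):
    """Vectorised (H, F, sensitivity, criterion) from response counts.

    The non-parametric indices use the raw rates; the parametric ones use
    log-linear corrected rates so boundary counts stay finite.
    """
    hits = np.asarray(hits, dtype=float)
    false_alarms = np.asarray(false_alarms, dtype=float)
    h = hits / np.asarray(n_targets, dtype=float)
    f = false_alarms / np.asarray(n_nontargets, dtype=float)
    if method == "nonparametric":
        sens = a_prime(h, f)
        crit = b_double_prime(h, f)
    elif method == "parametric":
        hc, fc = loglinear_rates(hits, n_targets, false_alarms, n_nontargets)
        sens = d_prime(hc, fc)
        crit = criterion_c(hc, fc)
    else:
        raise ValueError(f"unknown method {method!r}")
    return h, f, sens, crit


def _session_frame(session) -> pd.DataFrame:
    """Accept a CptSession dataclass or a bare trials DataFrame."""
    trials = getattr(session, "trials", session)
    if not isinstance(trials, pd.DataFrame):
        raise MalformedSessionError("session must carry a trials DataFrame")
    return trials


def score_blocks(session, method: str = "nonparametric") -> list[CptBlockScore]:
    """Score one 480-trial session into its four block summaries.

    Practice trials (1-160) are dropped entirely, including any responses
    landing on them; trials 161-480 are partitioned in presentation order
    into four consecutive 80-trial blocks.  ``mean_rt`` is the mean reaction
    time over hits in the block (NaN when there are none).
    """
    trials = _session_frame(session)
    if len(trials) != N_TRIALS:
        raise MalformedSessionError(
            f"expected {N_TRIALS} trials, got {len(trials)}")
    scored = trials.iloc[N_PRACTICE:]
    is_target = scored["is_target"].to_numpy(dtype=bool)
    responded = scored["responded"].to_numpy(dtype=bool)
    rt = scored["rt_ms"].to_numpy(dtype=float)

    out: list[CptBlockScore] = []
    for b in range(N_BLOCKS):
        sl = slice(b * BLOCK_LEN, (b + 1) * BLOCK_LEN)
        tgt = is_target[sl]
        resp = responded[sl]
        n_t = int(tgt.sum())
        n_n = BLOCK_LEN - n_t
        hits = int((tgt & resp).sum())
        fas = int((~tgt & resp).sum())
        h, f, sens, crit = score_counts(hits, n_t, fas, n_n, method=method)
        hit_rt = rt[sl][tgt & resp]
        mean_rt = float(np.mean(hit_rt)) if hit_rt.size else float("nan")
        out.append(CptBlockScore(block=b + 1, hit_rate=float(h),
                                 false_alarm_rate=float(f),
                                 sensitivity=float(sens),
                                 criterion=float(crit),
                                 mean_rt=mean_rt, method=method))
    return out


def read_session_csv(path) -> pd.DataFrame:
    """Read a per-participant session CSV (index, is_target, responded, rt_ms)."""
    df = pd.read_csv(path)
    required = {"index", "is_target", "responded", "rt_ms"}
    missing = required - set(df.columns)
    if missing:
        raise MalformedSessionError(f"session file lacks columns {sorted(missing)}")
    df["is_target"] = df["is_target"].astype(bool)
    df["responded"] = df["responded"].astype(bool)
    return df


def write_block_scores_tsv(scores: dict[str, Iterable[CptBlockScore]], path) -> None:
    """Write a long-format block-score table (one row per participant x block)."""
    rows = []
    for pid, blocks in scores.items():
        for s in blocks:
            rows.append({"participant_id": pid, "block": s.block,
                         "hit_rate": s.hit_rate,
                         "false_alarm_rate": s.false_alarm_rate,
                         "sensitivity": s.sensitivity,
                         "criterion": s.criterion,
                         "mean_rt": s.mean_rt})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
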