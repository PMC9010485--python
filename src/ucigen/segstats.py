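"""Goodness-of-fit, exact tests, power, and ratio model comparison for
segregation count data.

The canonical goodness-of-fit statistic is the standard Pearson chi-square
(optionally Yates-corrected at df=1); the exact test sums multinomial
probabilities of outcomes no more probable than the observed one (the
"at least as extreme in probability" two-sided convention).  Conclusions
(reject / not reject at alpha=0.05) are the comparison currency, not any
particular printed statistic.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "CountData",
    "GoFResult",
    "PowerResult",
    "chi2_gof",
    "exact_test",
    "ratio_power",
    "best_fit_ratio",
    "parse_ratio",
]

_EXACT_BUDGET = 2_000_000  # max multinomial outcomes to enumerate


@dataclass(frozen=True)
class CountData:
    """Observed (or simulated) class counts for one design."""

    design_id: str
    classes: tuple[str, ...]
    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.classes) != len(self.counts):
            raise ValueError("classes and counts must align")
        if any(c < 0 or int(c) != c for c in self.counts):
            raise ValueError("counts must be non-negative integers")

    @property
    def n(self) -> int:
        return int(sum(self.counts))


@dataclass(frozen=True)
class GoFResult:
    statistic: float
    df: int
    p_value: float
    method: str


@dataclass(frozen=True)
class PowerResult:
    null_ratio: tuple[float, ...]
    true_ratio: tuple[float, ...]
    n: int
    alpha: float
    power: float
    method: str
    seed: Optional[int] = None


def parse_ratio(spec: str | Sequence[float]) -> tuple[float, ...]:
    """Normalize a ratio spec ("7:1" or class probabilities) to probabilities."""
    if isinstance(spec, str):
        parts = [float(x) for x in spec.split(":")]
    else:
        parts = [float(x) for x in spec]
    if any(p < 0 for p in parts) or sum(parts) <= 0:
        raise ValueError(f"invalid ratio {spec!r}")
    total = sum(parts)
    return tuple(p / total for p in parts)


def _probs(ratio) -> tuple[float, ...]:
    if hasattr(ratio, "probabilities"):  # ExpectedOutcome
        return tuple(ratio.probabilities)
    return parse_ratio(ratio)


def chi2_gof(obs: CountData, ratio, yates: bool = False) -> GoFResult:
    """Pearson chi-square goodness of fit against a hypothesized ratio.

    ``ratio`` may be a ratio string ("1:1"), a probability sequence, or an
    ExpectedOutcome.  Raises when any expected count is zero (use
    :func:`exact_test` instead).
    """
    p = _probs(ratio)
    if len(p) != len(obs.counts):
        raise ValueError("ratio arity does not match observed classes")
    e = np.asarray(p) * obs.n
    if np.any(e <= 0):
        raise ValueError(
            "zero expected count in some class; use exact_test for such ratios"
        )
    o = np.asarray(obs.counts, dtype=float)
    dev = np.abs(o - e)
    if yates:
        dev = np.maximum(dev - 0.5, 0.0)
    stat = float(np.sum(dev**2 / e))
    df = len(p) - 1
    return GoFResult(stat, df, float(stats.chi2.sf(stat, df)),
                     "pearson_yates" if yates else "pearson")


def _exact_p_binomial(k: int, n: int, p0: float) -> float:
    pmf = stats.binom.pmf(np.arange(n + 1), n, p0)
    return float(pmf[pmf <= pmf[k] * (1 + 1e-9)].sum())


def exact_test(obs: CountData, ratio) -> GoFResult:
    """Exact multinomial two-sided test.

    The p-value is the total probability of outcomes whose multinomial
    probability does not exceed that of the observed table.  Binomial for
    two classes at any n; full enumeration otherwise, bounded by an
    enumeration budget.
    """
    p = _probs(ratio)
    if len(p) != len(obs.counts):
        raise ValueError("ratio arity does not match observed classes")
    n, k = obs.n, len(p)
    if k == 2:
        pv = _exact_p_binomial(obs.counts[0], n, p[0])
        return GoFResult(float("nan"), k - 1, min(pv, 1.0), "exact_multinomial")
    if math.comb(n + k - 1, k - 1) > _EXACT_BUDGET:
        raise ValueError(
            "exact multinomial enumeration over budget; use a monte_carlo method"
        )
    logp = np.log(np.asarray(p))
    obs_lp = stats.multinomial.logpmf(obs.counts, n, p)
    total = 0.0
    for combo in itertools.combinations(range(n + k - 1), k - 1):
        cuts = (-1,) + combo + (n + k - 1,)
        cell = [cuts[i + 1] - cuts[i] - 1 for i in range(k)]
        lp = stats.multinomial.logpmf(cell, n, p)
        if lp <= obs_lp + 1e-9:
            total += math.exp(lp)
    return GoFResult(float("nan"), k - 1, min(total, 1.0), "exact_multinomial")


def ratio_power(
    null_ratio,
    true_ratio,
    n: int,
    alpha: float = 0.05,
    method: str = "exact_enumeration",
    seed: Optional[int] = None,
    n_mc: int = 5000,
) -> PowerResult:
    """Probability that the exact test rejects ``null_ratio`` at ``alpha``
    when counts are generated under ``true_ratio``.

    ``exact_enumeration`` (two classes) sums true-distribution binomial
    masses over the rejection region; ``monte_carlo`` simulates.
    """
    p0, p1 = _probs(null_ratio), _probs(true_ratio)
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if method == "exact_enumeration":
        if len(p0) != 2 or len(p1) != 2:
            raise ValueError("exact_enumeration power supports two classes")
        ks = np.arange(n + 1)
        pmf0 = stats.binom.pmf(ks, n, p0[0])
        # p-value of k = sum of null pmf over outcomes no more probable
        pvals = np.minimum(
            np.array([pmf0[pmf0 <= pmf0[k] * (1 + 1e-9)].sum() for k in ks]), 1.0
        )
        reject = pvals <= alpha
        power = float(stats.binom.pmf(ks, n, p1[0])[reject].sum())
        return PowerResult(p0, p1, n, alpha, power, method)
    if method == "monte_carlo":
        rng = np.random.default_rng(seed)
        draws = rng.multinomial(n, p1, size=n_mc)
        rejections = 0
        for row in draws:
            cd = CountData("mc", tuple(f"c{i}" for i in range(len(p1))), tuple(row))
            if exact_test(cd, p0).p_value <= alpha:
                rejections += 1
        return PowerResult(p0, p1, n, alpha, rejections / n_mc, method, seed)
    raise ValueError(f"unknown power method {method!r}")


def best_fit_ratio(obs: CountData, candidates: list) -> list[dict]:
    """Rank candidate ratios by multinomial log-likelihood.

    Returns one record per candidate with its log-likelihood and Pearson
    GoF result, sorted best first; exact ties are flagged, not broken.
    """
    if not candidates:
        raise ValueError("need at least one candidate ratio")
    rows = []
    for cand in candidates:
        p = _probs(cand)
        ll = float(stats.multinomial.logpmf(obs.counts, obs.n, p))
        rows.append(
            {
                "ratio": cand if isinstance(cand, str) else ratio_label(p),
                "probabilities": p,
                "log_likelihood": ll,
                "gof": chi2_gof(obs, p),
            }
        )
    rows.sort(key=lambda r: -r["log_likelihood"])
    for i, r in enumerate(rows):
        r["rank"] = i + 1
        r["tied_with_best"] = math.isclose(
            r["log_likelihood"], rows[0]["log_likelihood"], abs_tol=1e-12
        )
    return rows


def ratio_label(p: Sequence[float]) -> str:
    return ":".join(f"{x:.6g}" for x in p)
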