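"""Storey-style FDR estimation, Bonferroni FWER, and true-FDP counting.

Given M per-set p-values, the proportion of true nulls is estimated from
the p-value mass above a tuning point ``lambda``::

    pi0_hat = #{p_i > lambda} / (M * (1 - lambda)),

capped at 1.  The FDR of the rejection region [0, c] is then estimated as

    FDR_hat(c) = M * pi0_hat * c / #{p_i <= c}.

Validity rests on the null p-values being roughly uniform; a
Kolmogorov-Smirnov diagnostic on the p-values above 0.05 is provided
(conservative sup-type p-values sit below uniform, which only makes the
estimate conservative).

For simulations, where each hypothesis' truth is known, the realized
false-discovery proportion can be computed directly, and
``true_fdp_rejections`` reports the largest rejection set whose realized
FDP stays at or below a target level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.stats import kstest

__all__ = [
    "FDRCurve",
    "TrueFdpResult",
    "estimate_pi0",
    "estimate_fdr",
    "significance_vs_fdr_curve",
    "bonferroni_rejections",
    "true_fdp_rejections",
    "uniformity_diagnostic",
]


def _validate_pvalues(p) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size < 1:
        raise ValueError("expected a nonempty 1-d array of p-values")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return p


def estimate_pi0(p, lam: float = 0.7) -> float:
    """Estimated proportion of true null hypotheses, capped at 1."""
    p = _validate_pvalues(p)
    if not 0.0 < lam < 1.0:
        raise ValueError("lambda must lie strictly between 0 and 1")
    pi0 = np.count_nonzero(p > lam) / (p.size * (1.0 - lam))
    return float(min(1.0, pi0))


def estimate_fdr(p, c: float, pi0: float) -> float:
    """Estimated FDR of the rejection region [0, c].

    ``M * pi0 * c / #{p_i <= c}``.  Returns ``nan`` when the cutoff
    rejects nothing (the "no rejections" sentinel; such cutoffs are
    excluded from curves).
    """
    p = _validate_pvalues(p)
    if not 0.0 < c < 1.0:
        raise ValueError("cutoff c must lie strictly between 0 and 1")
    if not 0.0 < pi0 <= 1.0:
        raise ValueError("pi0 must lie in (0, 1]")
    rejections = np.count_nonzero(p <= c)
    if rejections == 0:
        return float("nan")
    return float(p.size * pi0 * c / rejections)


@dataclass
class FDRCurve:
    """Rejection counts and estimated FDR along a grid of p-value cutoffs."""

    cutoffs: np.ndarray
    rejections: np.ndarray
    fdr_hat: np.ndarray
    pi0: float
    lam: float


def significance_vs_fdr_curve(p, lam: float = 0.7, cutoffs=None) -> FDRCurve:
    """Number of significant sets versus estimated FDR.

    ``pi0`` is estimated once at ``lam``; each cutoff contributes its
    rejection count and FDR estimate.  Cutoffs with no rejections are
    dropped.  The default cutoff grid spans (0, 0.05].
    """
    p = _validate_pvalues(p)
    if cutoffs is None:
        cutoffs = np.linspace(0.0005, 0.05, 100)
    cutoffs = np.sort(np.asarray(cutoffs, dtype=float))
    if np.any((cutoffs <= 0) | (cutoffs >= 1)):
        raise ValueError("cutoffs must lie strictly between 0 and 1")
    pi0 = estimate_pi0(p, lam)
    rejections = np.array([np.count_nonzero(p <= c) for c in cutoffs])
    keep = rejections > 0
    cutoffs, rejections = cutoffs[keep], rejections[keep]
    with np.errstate(divide="ignore"):
        fdr_hat = p.size * pi0 * cutoffs / rejections
    return FDRCurve(cutoffs=cutoffs, rejections=rejections, fdr_hat=fdr_hat,
                    pi0=pi0, lam=lam)


def bonferroni_rejections(p, alpha: float = 0.05) -> int:
    """Count of tests rejected under Bonferroni FWER control: p < alpha / M."""
    p = _validate_pvalues(p)
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie strictly between 0 and 1")
    return int(np.count_nonzero(p < alpha / p.size))


class TrueFdpResult(NamedTuple):
    count: int
    attainable: bool


def true_fdp_rejections(p, is_null, level: float = 0.05) -> TrueFdpResult:
    """Largest rejection count whose realized FDP stays at or below ``level``.

    Cutoffs run over the observed p-values (any rejection set achievable
    by a region [0, c] is achievable at an observed p-value); ties share a
    cutoff, so a tied block is rejected in full or not at all.  If no
    nonempty rejection set has FDP <= level the level is unattainable and
    the count is 0.
    """
    p = _validate_pvalues(p)
    is_null = np.asarray(is_null, dtype=bool)
    if is_null.shape != p.shape:
        raise ValueError("truth flags must align with the p-values")
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie strictly between 0 and 1")

    order = np.argsort(p, kind="stable")
    p_sorted = p[order]
    false_cum = np.cumsum(is_null[order])
    k = np.arange(1, p.size + 1)
    # position i is a legal cutoff only if it absorbs the whole tie block
    legal = np.ones(p.size, dtype=bool)
    legal[:-1] = p_sorted[1:] > p_sorted[:-1]
    ok = legal & (false_cum / k <= level)
    if not np.any(ok):
        return TrueFdpResult(count=0, attainable=False)
    return TrueFdpResult(count=int(k[ok].max()), attainable=True)


def uniformity_diagnostic(p, above: float = 0.05):
    """KS statistic and p-value for uniformity of the p-values above a floor.

    Checks the Storey-estimator validity condition that null p-values are
    roughly uniform, using the p-values greater than ``above`` rescaled to
    (0, 1).  Purely diagnostic — nothing is enforced.
    """
    p = _validate_pvalues(p)
    tail = p[p > above]
    if tail.size < 2:
        return float("nan"), float("nan")
    rescaled = (tail - above) / (1.0 - above)
    res = kstest(rescaled, "uniform")
    return float(res.statistic), float(res.pvalue)
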