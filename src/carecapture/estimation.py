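"""Two-list capture-recapture estimation of the event universe.

With ``r1`` and ``r2`` events on the two lists and ``m`` events on both,
the union ``r1 + r2 - m`` is the observed universe and the overlap share
``100 * m / union`` measures how little the lists agree. The total number
of (publicly reportable) events is estimated with the bias-corrected
two-list (Chapman) estimator

    N_hat = (r1 + 1)(r2 + 1) / (m + 1) - 1            (standard)

and with a printed-source variant that divides by ``(m - 1)`` instead,
which is more conservative (larger) for m >= 2 and is the form used to
reproduce the published headline estimate. Uncertainty uses the standard
Chapman variance

    var = (r1+1)(r2+1)(r1-m)(r2-m) / ((m+1)^2 (m+2))

with a normal-approximation confidence interval clipped below at the
observed union (an estimated universe cannot be smaller than what was
seen). Both estimators assume the two lists are independent samples with
homogeneous capture probabilities; the synthetic module exists to measure
how violations (capture dependence) bias them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Optional

from scipy import stats

VARIANTS = ("paper", "standard")


def _validate_counts(r1: int, r2: int, m: int) -> None:
    if r1 < 0 or r2 < 0 or m < 0:
        raise ValueError("counts must be non-negative")
    if m > min(r1, r2):
        raise ValueError(f"overlap m={m} exceeds min(r1, r2)={min(r1, r2)}")


def truncate_pct(value: float, decimals: int = 1) -> float:
    """Truncate (not round) a percentage to ``decimals`` places."""
    factor = 10 ** decimals
    return math.floor(value * factor) / factor


def overlap_stats(r1: int, r2: int, m: int, *, truncate: bool = True) -> tuple[int, float]:
    """Observed union size and overlap percentage 100*m/union.

    The replication convention truncates the percentage to one decimal
    (100*33/254 = 12.99... prints as 12.9); pass ``truncate=False`` for
    round-half-up instead.
    """
    _validate_counts(r1, r2, m)
    union_n = r1 + r2 - m
    if union_n == 0:
        raise ZeroDivisionError("overlap percentage undefined for an empty union")
    pct = 100.0 * m / union_n
    if truncate:
        return union_n, truncate_pct(pct)
    return union_n, round_half_up(pct)


def round_half_up(value: float, decimals: int = 1) -> float:
    factor = 10 ** decimals
    return math.floor(value * factor + 0.5) / factor


def chapman(r1: int, r2: int, m: int, variant: str = "standard") -> float:
    """Two-list population-size estimate.

    ``standard`` is the bias-corrected Chapman form dividing by (m+1),
    defined for any m >= 0. ``paper`` divides by (m-1) and requires
    m >= 2; it always exceeds the standard form and serves as the more
    conservative (larger) published variant.
    """
    _validate_counts(r1, r2, m)
    if variant == "standard":
        return (r1 + 1) * (r2 + 1) / (m + 1) - 1
    if variant == "paper":
        if m <= 1:
            raise ValueError("paper variant requires m >= 2 (divides by m - 1)")
        return (r1 + 1) * (r2 + 1) / (m - 1) - 1
    raise ValueError(f"variant must be one of {VARIANTS}, got {variant!r}")


def chapman_uncertainty(r1: int, r2: int, m: int, level: float = 0.95) -> tuple[float, float, float]:
    """Chapman variance and normal-approximation CI, clipped at the union."""
    _validate_counts(r1, r2, m)
    if m < 1:
        raise ValueError("uncertainty requires m >= 1")
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0, 1), got {level}")
    variance = ((r1 + 1) * (r2 + 1) * (r1 - m) * (r2 - m)) / ((m + 1) ** 2 * (m + 2))
    n_hat = chapman(r1, r2, m, "standard")
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * math.sqrt(variance)
    union_n = r1 + r2 - m
    return variance, max(n_hat - half, float(union_n)), n_hat + half


@dataclass(frozen=True)
class CaptureEstimate:
    """Full two-list capture-recapture summary for one comparison."""

    r1: int
    r2: int
    m: int
    union_n: int
    overlap_pct: float
    overlap_rule: str
    n_hat_paper: Optional[float]
    n_hat_standard: float
    variance: float
    ci_level: float
    ci_low: float
    ci_high: float
    coverage_1: float
    coverage_2: float
    coverage_combined_raw: float

    def to_dict(self) -> dict:
        return asdict(self)


def estimate(r1: int, r2: int, m: int, *, variant: str = "standard",
             level: float = 0.95, truncate_overlap: bool = True) -> CaptureEstimate:
    """Compute the complete estimate block from the three counts.

    ``variant`` selects which estimator the coverage fractions refer to
    (the replication profile uses ``paper``). Coverage is reported three
    ways because the bases differ: each list against the estimate, and the
    summed raw list sizes against the estimate.
    """
    union_n, overlap_pct = overlap_stats(r1, r2, m, truncate=truncate_overlap)
    n_std = chapman(r1, r2, m, "standard")
    n_paper = chapman(r1, r2, m, "paper") if m >= 2 else None
    variance, ci_low, ci_high = chapman_uncertainty(r1, r2, m, level)
    n_ref = n_paper if (variant == "paper" and n_paper is not None) else n_std
    return CaptureEstimate(
        r1=r1, r2=r2, m=m,
        union_n=union_n,
        overlap_pct=overlap_pct,
        overlap_rule="truncate" if truncate_overlap else "round_half_up",
        n_hat_paper=n_paper,
        n_hat_standard=n_std,
        variance=variance,
        ci_level=level,
        ci_low=ci_low,
        ci_high=ci_high,
        coverage_1=r1 / n_ref,
        coverage_2=r2 / n_ref,
        coverage_combined_raw=(r1 + r2) / n_ref,
    )
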