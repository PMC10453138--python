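"""Poisson quantification: droplet calls → absolute copy estimates.

With template molecules Poisson-partitioned over droplets, the fraction
of negative (empty) droplets estimates e^{−λ}, so

    λ̂ = −ln(n_negative / n_total)   copies per droplet,

and copies per reaction = λ̂ · n_total.  The confidence interval comes
from a binomial interval (Wilson score by default) on the negative
fraction mapped through −ln: the upper fraction bound gives the lower λ
bound and vice versa.  Copies per reaction is deliberately the primary
downstream quantity — it does not depend on the droplet volume constant,
which varies by instrument and is only needed for copies/µL.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from statsmodels.stats.proportion import proportion_confint

from .droplets import DropletCall

__all__ = ["CopyEstimate", "SaturationError", "estimate_lambda", "pool_wells"]

#: Default droplet volume in nanolitres (instrument-class standard).
DEFAULT_DROPLET_VOLUME_NL = 0.85


class SaturationError(ValueError):
    """Every droplet positive: the target is above the dynamic range."""


@dataclass(frozen=True)
class CopyEstimate:
    """Absolute quantification of one well (or pool of wells)."""

    lambda_hat: float
    ci_low: float
    ci_high: float
    copies_per_reaction: float
    copies_per_ul: float
    droplet_volume_nl: float
    n_total: int
    n_negative: int
    label: str = ""
    flags: frozenset[str] = frozenset()

    @property
    def n_positive(self) -> int:
        return self.n_total - self.n_negative

    def __post_init__(self) -> None:
        if self.n_total < 1 or not 0 <= self.n_negative <= self.n_total:
            raise ValueError("invalid droplet counts")
        if math.isfinite(self.lambda_hat):
            if self.lambda_hat < 0:
                raise ValueError("lambda_hat must be >= 0")
            if not (self.ci_low <= self.lambda_hat <= self.ci_high):
                raise ValueError("CI must bracket lambda_hat")


def estimate_lambda(
    call: DropletCall,
    droplet_volume_nl: float = DEFAULT_DROPLET_VOLUME_NL,
    ci_level: float = 0.95,
    ci_method: str = "wilson",
    saturated_ok: bool = False,
) -> CopyEstimate:
    """Estimate mean copies per droplet from a droplet call.

    Raises :class:`SaturationError` when no negative droplets remain
    (``saturated_ok=True`` instead returns an infinite, flagged
    estimate, which lets saturated wells take part in pooling).  A well
    with no positive droplets yields λ̂ = 0 with a one-sided interval
    and a ``not_detected`` flag.
    """
    n, neg = call.n_total, call.n_negative
    if n < 1:
        raise ValueError("n_total must be >= 1")
    flags = set()
    if neg == 0:
        if not saturated_ok:
            raise SaturationError(
                f"well {call.well_id}: all {n} droplets positive — "
                "above dynamic range"
            )
        return CopyEstimate(
            lambda_hat=math.inf, ci_low=math.inf, ci_high=math.inf,
            copies_per_reaction=math.inf, copies_per_ul=math.inf,
            droplet_volume_nl=droplet_volume_nl, n_total=n, n_negative=0,
            label=call.well_id, flags=frozenset({"saturated"}),
        )
    p_lo, p_hi = proportion_confint(neg, n, alpha=1.0 - ci_level, method=ci_method)
    lam = -math.log(neg / n)
    ci_low = -math.log(p_hi) if p_hi > 0 else math.inf
    ci_high = -math.log(p_lo)
    if call.n_positive == 0:
        flags.add("not_detected")
        lam, ci_low = 0.0, 0.0  # guard rounding; one-sided interval
    return CopyEstimate(
        lambda_hat=lam,
        ci_low=min(ci_low, lam),
        ci_high=max(ci_high, lam),
        copies_per_reaction=lam * n,
        copies_per_ul=lam / (droplet_volume_nl * 1e-3),
        droplet_volume_nl=droplet_volume_nl,
        n_total=n,
        n_negative=neg,
        label=call.well_id,
        flags=frozenset(flags),
    )


def pool_wells(
    estimates: Sequence[CopyEstimate],
    ci_level: float = 0.95,
    ci_method: str = "wilson",
) -> CopyEstimate:
    """Pool replicate wells by merging their droplet partitions.

    Negative and total droplet counts are summed before re-estimating,
    i.e. the replicates are treated as one large partition set.  A
    saturated component propagates a ``saturated_component`` flag.
    """
    if not estimates:
        raise ValueError("cannot pool an empty list of estimates")
    volumes = {e.droplet_volume_nl for e in estimates}
    if len(volumes) > 1:
        raise ValueError("all pooled wells must share droplet_volume_nl")
    n = sum(e.n_total for e in estimates)
    neg = sum(e.n_negative for e in estimates)
    pooled_call = DropletCall(
        well_id="+".join(e.label or "?" for e in estimates),
        channel=0, n_total=n, n_positive=n - neg, n_negative=neg,
        threshold=None, n_rain_reassigned=0,
    )
    pooled = estimate_lambda(
        pooled_call, droplet_volume_nl=next(iter(volumes)),
        ci_level=ci_level, ci_method=ci_method, saturated_ok=True,
    )
    extra = set(pooled.flags)
    if any("saturated" in e.flags for e in estimates):
        extra.add("saturated_component")
    return CopyEstimate(
        lambda_hat=pooled.lambda_hat, ci_low=pooled.ci_low, ci_high=pooled.ci_high,
        copies_per_reaction=pooled.copies_per_reaction,
        copies_per_ul=pooled.copies_per_ul,
        droplet_volume_nl=pooled.droplet_volume_nl,
        n_total=n, n_negative=neg, label=pooled.label, flags=frozenset(extra),
    )
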