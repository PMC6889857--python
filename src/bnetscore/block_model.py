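"""Fractional channel block from concentration-response parameters.

Two functional forms:

* static Hill block, ``100 * C^h / (C^h + IC50^h)``;
* dynamic-hERG block, the same curve scaled by a maximal-inhibition
  ceiling, ``100 * Emax * C^h / (C^h + IC50^h)``.

A missing Hill coefficient defaults to 1.0 with an explicit
``hill_defaulted`` flag; a censored IC50 is evaluated at its bound with an
``ic50_censored_bound`` flag (the result is then an upper bound on the true
block). Outputs are clamped to [0, 100] to absorb floating-point rounding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .panel_io import Channel, DynamicHergFit, HillFit

__all__ = [
    "BlockResult",
    "percent_block",
    "dynamic_percent_block",
    "FLAG_HILL_DEFAULTED",
    "FLAG_IC50_CENSORED",
    "FLAG_DYNAMIC",
]

FLAG_HILL_DEFAULTED = "hill_defaulted"
FLAG_IC50_CENSORED = "ic50_censored_bound"
FLAG_DYNAMIC = "dynamic"


@dataclass(frozen=True)
class BlockResult:
    """Percent block of one channel by one drug at one concentration."""

    drug: str
    channel: Channel | None
    concentration: float
    percent_block: float
    flags: frozenset[str] = frozenset()


def _hill_fraction(concentration: float, ic50: float, hill: float) -> float:
    # Evaluated via the ratio form for numerical stability across the
    # ~6 orders of magnitude spanned by literature IC50 tables.
    ratio = ic50 / concentration
    try:
        denom = 1.0 + ratio**hill
    except OverflowError:
        return 0.0
    return 1.0 / denom


def _check_concentration(concentration: float) -> None:
    if not math.isfinite(concentration) or concentration <= 0:
        raise ValueError(
            f"concentration must be positive and finite, got {concentration}"
        )


def percent_block(
    concentration: float,
    fit: HillFit,
    *,
    drug: str = "",
    channel: Channel | None = None,
) -> BlockResult:
    """Static Hill-equation percent block at an unbound concentration (µM)."""
    _check_concentration(concentration)
    flags = set()
    hill = fit.hill
    if hill is None:
        hill = 1.0
        flags.add(FLAG_HILL_DEFAULTED)
    if fit.ic50_censored:
        flags.add(FLAG_IC50_CENSORED)
    value = 100.0 * _hill_fraction(concentration, fit.ic50, hill)
    value = min(max(value, 0.0), 100.0)
    return BlockResult(
        drug=drug,
        channel=channel,
        concentration=concentration,
        percent_block=value,
        flags=frozenset(flags),
    )


def dynamic_percent_block(
    concentration: float,
    fit: DynamicHergFit,
    *,
    drug: str = "",
) -> BlockResult:
    """Dynamic-hERG percent block: Emax-scaled Hill curve.

    The ceiling ``max_inhibition`` bounds the block from above, so the
    result never exceeds ``100 * max_inhibition``.
    """
    _check_concentration(concentration)
    flags = {FLAG_DYNAMIC}
    hill = fit.dyn_hill
    if hill is None:
        hill = 1.0
        flags.add(FLAG_HILL_DEFAULTED)
    value = 100.0 * fit.max_inhibition * _hill_fraction(concentration, fit.dyn_ic50, hill)
    value = min(max(value, 0.0), 100.0)
    return BlockResult(
        drug=drug,
        channel=Channel.IKR,
        concentration=concentration,
        percent_block=value,
        flags=frozenset(flags),
    )
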