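"""Net repolarization-minus-depolarization block scores.

``bnet`` evaluates each fitted channel at ``multiple * cmax_free`` and
returns the IKr percent block minus the summed percent blocks of the
depolarizing channels (INaL, ICaL, INa). Channels without a fit contribute
zero and are reported in ``missing_channels``. Higher scores indicate
higher predicted torsadogenic risk; this orientation is fixed here and
consumed by the evaluation module.

``dynamic_bnet`` replaces the static IKr term with the dynamic-hERG block
and evaluates everything at 1x Cmax.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

from . import block_model
from .errors import IncompleteRecordError
from .panel_io import Channel, DrugPanel, DrugRecord

logger = logging.getLogger(__name__)

__all__ = ["BnetResult", "bnet", "bnet_panel", "dynamic_bnet", "DEFAULT_MULTIPLE"]

#: Headline exposure multiple; 1x and 10x remain available via parameter.
DEFAULT_MULTIPLE = 5.0


@dataclass(frozen=True)
class BnetResult:
    """Per-drug net-block score with its per-channel breakdown."""

    drug: str
    multiple: float
    bnet: float
    channel_blocks: Mapping[Channel, float]
    missing_channels: frozenset[Channel]
    flags: frozenset[str]
    variant: str  # "static" | "dynamic"


def _require(drug: DrugRecord, condition: bool, what: str) -> None:
    if not condition:
        raise IncompleteRecordError(f"drug {drug.name!r}: {what}")


def _assemble(
    drug: DrugRecord,
    multiple: float,
    blocks: dict[Channel, block_model.BlockResult],
    variant: str,
) -> BnetResult:
    total = 0.0
    flags: set[str] = set()
    for channel, result in blocks.items():
        sign = 1.0 if channel.repolarizing else -1.0
        total += sign * result.percent_block
        flags |= result.flags
    return BnetResult(
        drug=drug.name,
        multiple=multiple,
        bnet=total,
        channel_blocks={ch: res.percent_block for ch, res in blocks.items()},
        missing_channels=frozenset(set(Channel) - set(blocks)),
        flags=frozenset(flags),
        variant=variant,
    )


def bnet(drug: DrugRecord, multiple: float = DEFAULT_MULTIPLE) -> BnetResult:
    """Static net-block score at ``multiple`` times the unbound Cmax.

    Requires ``cmax_free`` and an IKr fit (the score is undefined without
    its repolarizing term).
    """
    if multiple <= 0:
        raise ValueError(f"multiple must be positive, got {multiple}")
    _require(drug, drug.cmax_free is not None, "cmax_free is required to compute bnet")
    _require(drug, Channel.IKR in drug.fits, "an IKr fit is required to compute bnet")
    concentration = multiple * drug.cmax_free
    blocks = {
        channel: block_model.percent_block(
            concentration, fit, drug=drug.name, channel=channel
        )
        for channel, fit in drug.fits.items()
    }
    return _assemble(drug, multiple, blocks, "static")


def dynamic_bnet(drug: DrugRecord) -> BnetResult:
    """Net-block score with the dynamic-hERG term, at 1x Cmax.

    The IKr term comes from the dynamic fit (IC50 + maximal inhibition);
    depolarizing terms use the static fits, all at 1x Cmax.
    """
    _require(drug, drug.cmax_free is not None, "cmax_free is required to compute bnet")
    _require(
        drug,
        drug.dynamic_herg is not None,
        "dynamic-hERG parameters are required for dynamic bnet",
    )
    concentration = 1.0 * drug.cmax_free
    blocks: dict[Channel, block_model.BlockResult] = {
        Channel.IKR: block_model.dynamic_percent_block(
            concentration, drug.dynamic_herg, drug=drug.name
        )
    }
    for channel, fit in drug.fits.items():
        if channel.repolarizing:
            continue
        blocks[channel] = block_model.percent_block(
            concentration, fit, drug=drug.name, channel=channel
        )
    return _assemble(drug, 1.0, blocks, "dynamic")


def bnet_panel(
    panel: DrugPanel,
    multiple: float = DEFAULT_MULTIPLE,
    *,
    variant: str = "static",
    lenient: bool = False,
) -> list[BnetResult]:
    """Score every drug in a panel, sorted most risk-indicative first.

    Sort is descending by score with a stable alphabetical tie-break on
    drug name. In lenient mode incomplete records are skipped and logged;
    otherwise they raise.
    """
    if variant not in ("static", "dynamic"):
        raise ValueError(f"variant must be 'static' or 'dynamic', got {variant!r}")
    results = []
    for drug in panel:
        try:
            if variant == "static":
                results.append(bnet(drug, multiple))
            else:
                results.append(dynamic_bnet(drug))
        except IncompleteRecordError as exc:
            if not lenient:
                raise
            logger.warning("skipping drug: %s", exc)
    if not results:
        logger.warning("no scorable drugs in panel")
    results.sort(key=lambda r: (-r.bnet, r.drug.lower()))
    return results
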