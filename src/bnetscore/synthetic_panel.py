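"""Seeded generator of drug panels with known risk structure.

Panels emulate a multi-channel patch-clamp screening campaign: each drug
belongs to a generating risk category that sets the distribution of its
hERG potency margin (log10 of IC50 over unbound Cmax), while depolarizing
channels get category-dependent margins of their own and may be missing.
A noisy linear companion metric (a stand-in for an externally computed
reference score, oriented lower-is-riskier by default via a negative
slope) is attached to every drug, and a configurable fraction of drugs
receive dynamic-hERG parameters consistent with their static fit.

Risk labels come from the generating category, not from the realized
score, so labels stay noisy relative to scores; overlap is controlled by
the margin standard deviations.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Mapping

import numpy as np

from . import bnet_metric
from .errors import ValidationError
from .panel_io import (
    Channel,
    DEPOLARIZING_CHANNELS,
    DrugPanel,
    DrugRecord,
    DynamicHergFit,
    HillFit,
    Risk,
)

__all__ = ["SyntheticConfig", "generate_panel", "reference_config"]

_CATEGORY_ORDER = (Risk.HIGH, Risk.INTERMEDIATE, Risk.LOW)
_DEPOL_ORDER = (Channel.INAL, Channel.ICAL, Channel.INA)


@dataclass(frozen=True)
class SyntheticConfig:
    """Generative settings for one synthetic panel.

    Margins are distributions of ``log10(IC50 / Cmax)``: smaller hERG
    margins mean stronger repolarization block at a given exposure
    multiple, hence riskier drugs.
    """

    seed: int = 0
    n_per_category: Mapping[str, int] = field(
        default_factory=lambda: {"low": 9, "intermediate": 11, "high": 8}
    )
    cmax_log10_range: tuple[float, float] = (-2.5, 0.5)
    herg_margin_log10: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "high": (-0.5, 0.45),
            "intermediate": (0.7, 0.45),
            "low": (2.0, 0.45),
        }
    )
    depol_margin_log10: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "high": (1.5, 0.5),
            "intermediate": (1.5, 0.5),
            "low": (1.5, 0.5),
        }
    )
    hill_range: tuple[float, float] = (0.7, 1.7)
    missing_depol_prob: float = 0.25
    companion_slope: float = -0.8
    companion_intercept: float = 20.0
    companion_noise_sd: float = 20.0
    dynamic_fraction: float = 0.5

    def __post_init__(self) -> None:
        for cat in ("low", "intermediate", "high"):
            if cat not in self.n_per_category:
                raise ValidationError(f"n_per_category missing category {cat!r}")
            if self.n_per_category[cat] < 0:
                raise ValidationError("category counts must be >= 0")
            for mapping, label in (
                (self.herg_margin_log10, "herg_margin_log10"),
                (self.depol_margin_log10, "depol_margin_log10"),
            ):
                if cat not in mapping:
                    raise ValidationError(f"{label} missing category {cat!r}")
                if mapping[cat][1] < 0:
                    raise ValidationError(f"{label} sd must be >= 0")
        if not (0.0 <= self.missing_depol_prob <= 1.0):
            raise ValidationError("missing_depol_prob must lie in [0, 1]")
        if not (0.0 <= self.dynamic_fraction <= 1.0):
            raise ValidationError("dynamic_fraction must lie in [0, 1]")
        if self.companion_noise_sd < 0:
            raise ValidationError("companion_noise_sd must be >= 0")
        lo, hi = self.hill_range
        if not (0 < lo <= hi):
            raise ValidationError("hill_range must satisfy 0 < lo <= hi")

    @property
    def total(self) -> int:
        return sum(self.n_per_category.values())

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(asdict(self), indent=indent)

    @classmethod
    def from_dict(cls, data: Mapping) -> "SyntheticConfig":
        data = dict(data)
        for key in ("cmax_log10_range", "hill_range"):
            if key in data:
                data[key] = tuple(data[key])
        for key in ("herg_margin_log10", "depol_margin_log10"):
            if key in data:
                data[key] = {k: tuple(v) for k, v in data[key].items()}
        return cls(**data)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticConfig":
        return cls.from_dict(json.loads(text))


def reference_config(seed: int = 0) -> SyntheticConfig:
    """The committed default: 28 drugs split 8 high / 11 intermediate / 9 low.

    Category sizes mirror the standard 28-drug CiPA panel; all other
    settings are the dataclass defaults. Used by all recovery tests.
    """
    return SyntheticConfig(seed=seed)


def generate_panel(config: SyntheticConfig) -> DrugPanel:
    """Draw one panel from the configured generative model.

    Deterministic given the config (one shared random stream per panel).
    Every drug gets a Cmax, an IKr fit, up to three depolarizing fits
    (each dropped independently with ``missing_depol_prob``), its
    generating category as risk label, a companion metric that is linear
    in the realized 5x net-block score plus Gaussian noise, and — for a
    ``dynamic_fraction`` subset — dynamic-hERG parameters with
    ``dyn_ic50 >= ic50`` and ``max_inhibition < 1``.
    """
    if config.total == 0:
        raise ValidationError("all category counts are zero; nothing to generate")
    rng = np.random.default_rng(config.seed)
    drugs: list[DrugRecord] = []
    index = 0
    for category in _CATEGORY_ORDER:
        herg_mu, herg_sd = config.herg_margin_log10[category.value]
        depol_mu, depol_sd = config.depol_margin_log10[category.value]
        for _ in range(config.n_per_category[category.value]):
            index += 1
            name = f"SYN-{index:03d}-{category.value[:3]}"
            cmax = 10.0 ** rng.uniform(*config.cmax_log10_range)
            fits: dict[Channel, HillFit] = {}
            herg_margin = rng.normal(herg_mu, herg_sd)
            herg_hill = rng.uniform(*config.hill_range)
            fits[Channel.IKR] = HillFit(
                ic50=cmax * 10.0**herg_margin, hill=herg_hill
            )
            for channel in _DEPOL_ORDER:
                margin = rng.normal(depol_mu, depol_sd)
                hill = rng.uniform(*config.hill_range)
                if rng.uniform() < config.missing_depol_prob:
                    continue  # drawn then dropped: stream length is fixed per drug
                fits[channel] = HillFit(ic50=cmax * 10.0**margin, hill=hill)
            dynamic = None
            dyn_draw = rng.uniform()
            dyn_shift = rng.uniform(0.0, 0.5)
            dyn_ceiling = rng.uniform(0.55, 0.95)
            if dyn_draw < config.dynamic_fraction:
                dynamic = DynamicHergFit(
                    dyn_ic50=fits[Channel.IKR].ic50 * 10.0**dyn_shift,
                    max_inhibition=dyn_ceiling,
                    dyn_hill=herg_hill,
                )
            noise = rng.normal(0.0, config.companion_noise_sd)
            record = DrugRecord(
                name=name,
                cmax_free=cmax,
                fits=fits,
                risk=category,
                dynamic_herg=dynamic,
            )
            latent = bnet_metric.bnet(record, bnet_metric.DEFAULT_MULTIPLE).bnet
            companion = (
                config.companion_slope * latent + config.companion_intercept + noise
            )
            drugs.append(
                DrugRecord(
                    name=record.name,
                    cmax_free=record.cmax_free,
                    fits=record.fits,
                    risk=record.risk,
                    dynamic_herg=record.dynamic_herg,
                    external_metric=float(companion),
                )
            )
    return DrugPanel(drugs=drugs)
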