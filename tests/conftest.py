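import numpy as np
import pytest

from bnetscore.panel_io import (
    Channel,
    DrugPanel,
    DrugRecord,
    DynamicHergFit,
    HillFit,
    Risk,
)


@pytest.fixture
def herg_only_drug():
    """A drug with a single IKr fit, half-blocked at 5x Cmax."""
    return DrugRecord(
        name="soloherg",
        cmax_free=0.4,
        fits={Channel.IKR: HillFit(ic50=2.0, hill=1.0)},
    )


@pytest.fixture
def four_channel_drug():
    """All four channels fitted; 5x Cmax concentration is 5.0 µM.

    With hill = 1, ic50 = C * (100/block - 1) forces the block
    percentages {IKr: 80, INaL: 10, ICaL: 20, INa: 5}, so bnet = 45.
    """
    conc = 5.0
    forced = {Channel.IKR: 80.0, Channel.INAL: 10.0, Channel.ICAL: 20.0, Channel.INA: 5.0}
    fits = {
        ch: HillFit(ic50=conc * (100.0 / blk - 1.0), hill=1.0)
        for ch, blk in forced.items()
    }
    return DrugRecord(name="forced45", cmax_free=1.0, fits=fits)


def random_drug(rng: np.random.Generator, name: str, with_dynamic: bool = False) -> DrugRecord:
    """Random but valid drug record spanning realistic potency ranges."""
    cmax = 10.0 ** rng.uniform(-3, 1)
    fits = {
        Channel.IKR: HillFit(
            ic50=10.0 ** rng.uniform(-3, 3),
            hill=None if rng.uniform() < 0.2 else float(rng.uniform(0.5, 2.5)),
            ic50_censored=bool(rng.uniform() < 0.1),
        )
    }
    for channel in (Channel.INAL, Channel.ICAL, Channel.INA):
        if rng.uniform() < 0.7:
            fits[channel] = HillFit(
                ic50=10.0 ** rng.uniform(-3, 3),
                hill=None if rng.uniform() < 0.2 else float(rng.uniform(0.5, 2.5)),
            )
    dynamic = None
    if with_dynamic:
        dynamic = DynamicHergFit(
            dyn_ic50=10.0 ** rng.uniform(-3, 3),
            max_inhibition=float(rng.uniform(0, 1)),
            dyn_hill=None if rng.uniform() < 0.2 else float(rng.uniform(0.5, 2.5)),
        )
    risk = rng.choice([None, Risk.LOW, Risk.INTERMEDIATE, Risk.HIGH])
    return DrugRecord(
        name=name,
        cmax_free=float(cmax),
        fits=fits,
        risk=risk,
        dynamic_herg=dynamic,
        external_metric=float(rng.normal()) if rng.uniform() < 0.5 else None,
    )


@pytest.fixture
def random_panel():
    rng = np.random.default_rng(42)
    return DrugPanel(
        drugs=[random_drug(rng, f"rand{i:03d}", with_dynamic=(i % 2 == 0)) for i in range(20)]
    )
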