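"""Drug/channel panel data model and CSV round-trip I/O.

The universal input is a long-format table: one row per drug-channel
concentration-response fit, with per-drug attributes (unbound Cmax, risk
label, dynamic-hERG parameters, an optional external reference metric)
repeated on each of the drug's rows and required to agree.

All concentrations are in µM; no unit auto-detection is performed.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

from .errors import SchemaError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "Channel",
    "Risk",
    "Dataset",
    "HillFit",
    "DynamicHergFit",
    "DrugRecord",
    "DrugPanel",
    "read_panel",
    "write_panel",
    "table1_fixture",
    "CSV_COLUMNS",
    "REPOLARIZING_CHANNELS",
    "DEPOLARIZING_CHANNELS",
]


class Channel(str, Enum):
    """The four ion channels scored by the net-block metric.

    IKr is the sole repolarizing channel; the other three are
    depolarizing. The enumeration is closed: unknown channel codes in
    input are rejected.
    """

    IKR = "IKr"
    INAL = "INaL"
    ICAL = "ICaL"
    INA = "INa"

    @property
    def repolarizing(self) -> bool:
        return self is Channel.IKR

    @classmethod
    def parse(cls, text: str) -> "Channel":
        try:
            return cls(text.strip())
        except ValueError:
            raise ValidationError(
                f"unknown channel code {text!r}; expected one of "
                f"{[c.value for c in cls]}"
            ) from None


REPOLARIZING_CHANNELS = frozenset({Channel.IKR})
DEPOLARIZING_CHANNELS = frozenset({Channel.INAL, Channel.ICAL, Channel.INA})


class Risk(str, Enum):
    """Three-level torsadogenic risk category."""

    LOW = "low"
    INTERMEDIATE = "intermediate"
    HIGH = "high"


class Dataset(str, Enum):
    TRAINING = "training"
    VALIDATION = "validation"


def _check_positive_finite(value: float, what: str, drug: str = "") -> None:
    tag = f" for drug {drug!r}" if drug else ""
    if not math.isfinite(value) or value <= 0:
        raise ValidationError(f"{what} must be positive and finite{tag}, got {value}")


@dataclass(frozen=True)
class HillFit:
    """One channel's concentration-response parameters for one drug.

    ``ic50_censored=True`` records a literature value reported as
    "> ic50"; the stored ic50 is then a lower bound on the true value.
    A missing Hill coefficient is ``None`` — distinct from 1.0.
    """

    ic50: float
    hill: float | None = None
    ic50_censored: bool = False

    def __post_init__(self) -> None:
        _check_positive_finite(self.ic50, "ic50")
        if self.hill is not None:
            _check_positive_finite(self.hill, "hill")


@dataclass(frozen=True)
class DynamicHergFit:
    """Dynamic-hERG block parameters: IC50 plus a maximal-inhibition ceiling."""

    dyn_ic50: float
    max_inhibition: float
    dyn_hill: float | None = None

    def __post_init__(self) -> None:
        _check_positive_finite(self.dyn_ic50, "dyn_ic50")
        if not (0.0 <= self.max_inhibition <= 1.0):
            raise ValidationError(
                f"max_inhibition must lie in [0, 1], got {self.max_inhibition}"
            )
        if self.dyn_hill is not None:
            _check_positive_finite(self.dyn_hill, "dyn_hill")


@dataclass(frozen=True)
class DrugRecord:
    """All inputs for one drug: per-channel fits plus drug-level attributes.

    ``cmax_free`` (unbound Cmax, µM) may be absent — such records are
    incomplete for net-block scoring but valid for storage (literature
    potency tables often omit exposure). ``metadata`` carries free-text
    provenance (cell model, temperature, technique) and never enters any
    computation; it is not serialized by the CSV writer.
    """

    name: str
    cmax_free: float | None = None
    fits: Mapping[Channel, HillFit] = field(default_factory=dict)
    risk: Risk | None = None
    dataset: Dataset | None = None
    dynamic_herg: DynamicHergFit | None = None
    external_metric: float | None = None
    metadata: Mapping[str, str] = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if not self.name or not self.name.strip():
            raise ValidationError("drug name must be non-empty")
        if self.cmax_free is not None:
            _check_positive_finite(self.cmax_free, "cmax_free", self.name)
        for channel in self.fits:
            if not isinstance(channel, Channel):
                raise ValidationError(
                    f"fits keys must be Channel members, got {channel!r}"
                )
        object.__setattr__(self, "fits", dict(self.fits))

    @property
    def key(self) -> str:
        """Case-insensitive, whitespace-trimmed identity used for matching."""
        return self.name.strip().lower()


@dataclass
class DrugPanel:
    """Ordered collection of drug records with unique (case-insensitive) names."""

    drugs: list[DrugRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for drug in self.drugs:
            if drug.key in seen:
                raise ValidationError(f"duplicate drug name {drug.name!r} in panel")
            seen.add(drug.key)

    def __len__(self) -> int:
        return len(self.drugs)

    def __iter__(self):
        return iter(self.drugs)

    def get(self, name: str) -> DrugRecord:
        key = name.strip().lower()
        for drug in self.drugs:
            if drug.key == key:
                return drug
        raise KeyError(name)


# --------------------------------------------------------------------------
# CSV schema
# --------------------------------------------------------------------------

CSV_COLUMNS = (
    "drug",
    "channel",
    "ic50_uM",
    "ic50_censored",
    "hill",
    "cmax_free_uM",
    "risk",
    "dataset",
    "dyn_ic50_uM",
    "dyn_max_inhib",
    "dyn_hill",
    "external_metric",
)

_REQUIRED_COLUMNS = ("drug", "channel", "ic50_uM", "cmax_free_uM")


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        return repr(value)  # shortest round-trippable decimal
    if isinstance(value, Enum):
        return value.value
    return str(value)


def _parse_float(text: str, what: str, drug: str) -> float | None:
    text = text.strip()
    if not text:
        return None
    try:
        return float(text)
    except ValueError:
        raise ValidationError(f"{what} for drug {drug!r} is not a number: {text!r}") from None


def _parse_bool(text: str, what: str, drug: str) -> bool:
    text = text.strip().lower()
    if text in ("", "false", "0", "no"):
        return False
    if text in ("true", "1", "yes"):
        return True
    raise ValidationError(f"{what} for drug {drug!r} is not a boolean: {text!r}")


def write_panel(panel: DrugPanel, path: str | Path) -> Path:
    """Write a panel in the long CSV schema; inverse of :func:`read_panel`.

    Missing values are written as empty cells, floats with ``repr`` so
    read(write(p)) is field-level identity. A drug with no channel fits
    is preserved as a single row with blank channel/ic50 cells.
    """
    path = Path(path)
    try:
        handle = path.open("w", newline="", encoding="utf-8")
    except OSError as exc:
        raise OSError(f"cannot write panel to {path}: {exc}") from exc
    with handle:
        writer = csv.writer(handle)
        writer.writerow(CSV_COLUMNS)
        for drug in panel:
            shared = (
                _fmt(drug.cmax_free),
                _fmt(drug.risk),
                _fmt(drug.dataset),
                _fmt(drug.dynamic_herg.dyn_ic50 if drug.dynamic_herg else None),
                _fmt(drug.dynamic_herg.max_inhibition if drug.dynamic_herg else None),
                _fmt(drug.dynamic_herg.dyn_hill if drug.dynamic_herg else None),
                _fmt(drug.external_metric),
            )
            if not drug.fits:
                writer.writerow((drug.name, "", "", "", "") + shared)
                continue
            for channel in Channel:  # stable channel order
                fit = drug.fits.get(channel)
                if fit is None:
                    continue
                writer.writerow(
                    (
                        drug.name,
                        channel.value,
                        _fmt(fit.ic50),
                        _fmt(fit.ic50_censored),
                        _fmt(fit.hill),
                    )
                    + shared
                )
    return path


class _DrugAccumulator:
    """Collects a drug's rows and checks cross-row agreement."""

    def __init__(self, name: str):
        self.name = name
        self.fits: dict[Channel, HillFit] = {}
        self.shared: dict[str, str] | None = None
        self.rows_ok = 0  # rows fully parsed; lenient reads drop drugs at 0

    def add(self, row: dict[str, str], rownum: int) -> None:
        shared = {
            key: row.get(key, "").strip()
            for key in (
                "cmax_free_uM",
                "risk",
                "dataset",
                "dyn_ic50_uM",
                "dyn_max_inhib",
                "dyn_hill",
                "external_metric",
            )
        }
        if self.shared is None:
            self.shared = shared
        elif shared != self.shared:
            conflicting = sorted(k for k in shared if shared[k] != self.shared[k])
            raise ValidationError(
                f"row {rownum}: drug-level fields {conflicting} for {self.name!r} "
                "disagree with an earlier row"
            )
        channel_text = row.get("channel", "").strip()
        ic50_text = row.get("ic50_uM", "").strip()
        if not channel_text and not ic50_text:
            self.rows_ok += 1
            return  # stub row for a fit-less drug
        channel = Channel.parse(channel_text)
        if channel in self.fits:
            raise ValidationError(
                f"row {rownum}: duplicate ({self.name!r}, {channel.value}) fit"
            )
        ic50 = _parse_float(ic50_text, "ic50_uM", self.name)
        if ic50 is None:
            raise ValidationError(f"row {rownum}: missing ic50_uM for {self.name!r}")
        self.fits[channel] = HillFit(
            ic50=ic50,
            hill=_parse_float(row.get("hill", ""), "hill", self.name),
            ic50_censored=_parse_bool(
                row.get("ic50_censored", ""), "ic50_censored", self.name
            ),
        )
        self.rows_ok += 1

    def build(self) -> DrugRecord:
        assert self.shared is not None
        shared = self.shared
        dyn_ic50 = _parse_float(shared["dyn_ic50_uM"], "dyn_ic50_uM", self.name)
        dyn_max = _parse_float(shared["dyn_max_inhib"], "dyn_max_inhib", self.name)
        dynamic = None
        if dyn_ic50 is not None or dyn_max is not None:
            if dyn_ic50 is None or dyn_max is None:
                raise ValidationError(
                    f"drug {self.name!r}: dyn_ic50_uM and dyn_max_inhib must be "
                    "given together"
                )
            dynamic = DynamicHergFit(
                dyn_ic50=dyn_ic50,
                max_inhibition=dyn_max,
                dyn_hill=_parse_float(shared["dyn_hill"], "dyn_hill", self.name),
            )
        risk = Risk(shared["risk"].lower()) if shared["risk"] else None
        dataset = Dataset(shared["dataset"].lower()) if shared["dataset"] else None
        return DrugRecord(
            name=self.name,
            cmax_free=_parse_float(shared["cmax_free_uM"], "cmax_free_uM", self.name),
            fits=self.fits,
            risk=risk,
            dataset=dataset,
            dynamic_herg=dynamic,
            external_metric=_parse_float(
                shared["external_metric"], "external_metric", self.name
            ),
        )


def read_panel(path: str | Path, strict: bool = True) -> DrugPanel:
    """Read a long-format panel CSV into a validated :class:`DrugPanel`.

    In strict mode any malformed row aborts the read. In lenient mode
    malformed rows are skipped and logged with their row numbers;
    drug-level conflicts skip the offending row only.
    """
    path = Path(path)
    if not path.exists():
        raise OSError(f"panel file not found: {path}")
    with path.open(newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle)
        header = reader.fieldnames or []
        missing = [c for c in _REQUIRED_COLUMNS if c not in header]
        if missing:
            raise SchemaError(
                f"{path}: missing required column(s) {missing}; "
                f"expected header {list(CSV_COLUMNS)}"
            )
        unknown = [c for c in header if c not in CSV_COLUMNS]
        if unknown:
            raise SchemaError(f"{path}: unknown column(s) {unknown}")
        accumulators: dict[str, _DrugAccumulator] = {}
        order: list[str] = []
        for rownum, row in enumerate(reader, start=2):
            name = (row.get("drug") or "").strip()
            try:
                if not name:
                    raise ValidationError(f"row {rownum}: empty drug name")
                key = name.lower()
                if key not in accumulators:
                    accumulators[key] = _DrugAccumulator(name)
                    order.append(key)
                accumulators[key].add(row, rownum)
            except ValidationError:
                if strict:
                    raise
                logger.warning("skipping malformed row %d in %s", rownum, path)
    drugs = []
    for key in order:
        if not strict and accumulators[key].rows_ok == 0:
            logger.warning(
                "dropping drug %r: no valid rows in %s", accumulators[key].name, path
            )
            continue
        try:
            drugs.append(accumulators[key].build())
        except ValidationError:
            if strict:
                raise
            logger.warning("skipping malformed drug %r in %s", accumulators[key].name, path)
    return DrugPanel(drugs=drugs)


# --------------------------------------------------------------------------
# Packaged hERG potency fixture (16 validation drugs, literature values)
# --------------------------------------------------------------------------

# (name, ic50 µM, censored, hill, cell model, temperature °C, technique)
_HERG_VALIDATION_ROWS: tuple[tuple, ...] = (
    ("Ibutilide", 2.0, False, 1.0, "XO", "21.5", "Voltage-clamp 2-electrode"),
    ("Azimilide", 0.61, False, 1.0, "CHO", "22", "Whole-cell PC"),
    ("Disopyramide", 7.23, False, 0.89, "CHO", "36", "Whole-cell PC"),
    ("Domperidone", 0.057, False, 0.99, "HEK", "21", "Whole-cell PC"),
    ("Droperidol", 0.0322, False, 1.39, "HEK", "22.5", "Whole-cell PC"),
    ("Pimozide", 0.001, False, 1.1, "HEK", "35", "Whole-cell PC"),
    ("Astemizole", 0.0013, False, 0.95, "HEK", "35", "Whole-cell PC"),
    ("Clozapine", 2.5, False, 0.82, "HEK", "35", "Whole-cell PC"),
    ("Clarithromycin", 750.0, False, 1.7, "CHO", "", "Whole-cell PC"),
    ("Risperidone", 0.167, False, 1.0, "CHO", "23", "Whole-cell PC"),
    ("Metoprolol", 145.0, False, 1.1, "HEK", "23", "Whole-cell PC"),
    ("Tamoxifen", 1.2, False, 1.4, "HEK", "23", "Whole-cell PC"),
    ("Nifedipine", 50.0, True, None, "HEK", "23", "Whole-cell PC"),
    ("Nitrendipine", 10.0, False, None, "", "", ""),
    ("Loratadine", 173.0, False, None, "HEK", "36 ± 1", "Whole-cell PC"),
    ("Vandetanib", 1.15, False, 0.76, "HEK", "37 ± 0.5", "Whole-cell PC"),
)


def table1_fixture() -> DrugPanel:
    """Packaged hERG IC50/Hill literature values for the 16 validation drugs.

    Each record carries only an IKr fit; unbound Cmax is absent (the source
    table does not report exposure), so the records are incomplete for
    net-block scoring until Cmax values are supplied. Censored entries
    (">X") are stored at their bound with ``ic50_censored=True``; the
    "≒1" Hill entry is stored as 1.0 and blank Hills as absent.
    Cell model / temperature / technique ride along as free-text metadata.
    """
    drugs = []
    for name, ic50, censored, hill, model, temperature, technique in _HERG_VALIDATION_ROWS:
        drugs.append(
            DrugRecord(
                name=name,
                fits={Channel.IKR: HillFit(ic50=ic50, hill=hill, ic50_censored=censored)},
                dataset=Dataset.VALIDATION,
                metadata={
                    "cell_model": model,
                    "temperature_C": temperature,
                    "technique": technique,
                },
            )
        )
    return DrugPanel(drugs=drugs)
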