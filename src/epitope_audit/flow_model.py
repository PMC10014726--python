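"""Shared domain types, tabular I/O, and bundled reference tables.

This module holds the containers the rest of the pipeline passes around:
per-sample flow-cytometry event tables (one row per acquired cell event, one
column per channel, with sample metadata), and the two bundled reference
tables that summarise the published digestion-sensitivity screen (per-clone
replicate category proportions) and the 3-point antibody titration series
(three tested concentrations per antibody and the concentration selected for
CITE-seq staining).

Event tables are stored as plain CSV with a ``#key: value`` metadata
preamble: self-describing, diffable, and free of binary dependencies.
"""

from __future__ import annotations

import hashlib
import io
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EpitopeAuditError",
    "MetadataError",
    "ParseError",
    "SchemaError",
    "PairingError",
    "GatingError",
    "UndefinedRCError",
    "ClassificationError",
    "NoSignalError",
    "FixtureError",
    "ConfigError",
    "DataError",
    "ValidationError",
    "Condition",
    "Activation",
    "Lineage",
    "SampleMeta",
    "EventTable",
    "Table2Row",
    "Table3Row",
    "PaperFixtures",
    "read_event_table",
    "write_event_table",
    "load_fixtures",
]


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class EpitopeAuditError(Exception):
    """Base class for all errors raised by this package."""


class MetadataError(EpitopeAuditError):
    """A required sample-metadata field is missing or malformed."""


class ParseError(EpitopeAuditError):
    """An event-table body could not be parsed (reported with row number)."""


class SchemaError(EpitopeAuditError):
    """A referenced channel/antibody/column does not exist."""


class PairingError(EpitopeAuditError):
    """Two samples offered as an undigested/digested pair do not match."""


class GatingError(EpitopeAuditError):
    """A gate could not be fit or applied."""


class UndefinedRCError(EpitopeAuditError):
    """Relative change is undefined (zero undigested positivity)."""


class ClassificationError(EpitopeAuditError):
    """A clone-level call was requested with no included replicates."""


class NoSignalError(EpitopeAuditError):
    """No titration point shows an acceptable positive peak."""


class FixtureError(EpitopeAuditError):
    """A bundled reference table is missing, corrupt, or inconsistent."""


class ConfigError(EpitopeAuditError):
    """Invalid configuration value."""


class DataError(EpitopeAuditError):
    """Input data violate a stated precondition."""


class ValidationError(EpitopeAuditError):
    """A domain object failed its invariants."""


# ---------------------------------------------------------------------------
# Enumerations
# ---------------------------------------------------------------------------

class _LooseEnum(Enum):
    """Enum whose members parse case-insensitively from hand-edited text."""

    @classmethod
    def parse(cls, value: "str | _LooseEnum") -> "_LooseEnum":
        if isinstance(value, cls):
            return value
        key = str(value).strip().lower()
        for member in cls:
            if member.value == key:
                return member
        raise MetadataError(
            f"{cls.__name__}: unrecognized value {value!r} "
            f"(expected one of {[m.value for m in cls]})"
        )

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class Condition(_LooseEnum):
    UNDIGESTED = "undigested"
    DIGESTED = "digested"
    UNSTAINED = "unstained"
    CONTROL = "control"


class Activation(_LooseEnum):
    NONE = "none"
    POLYCLONAL_48H = "polyclonal_48h"
    LPS_IFNG_6H = "lps_ifng_6h"
    PMA_IONO_6H = "pma_iono_6h"


class Lineage(_LooseEnum):
    LYMPHOID = "lymphoid"
    MYELOID = "myeloid"


# ---------------------------------------------------------------------------
# Sample metadata and event tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one stained sample.

    ``concentration`` is the staining concentration in µg per 100 µL per
    10^6 cells; it is present only for samples belonging to a titration
    series.
    """

    donor_id: str
    marker: str
    clone: str
    condition: Condition
    parent_lineage: Lineage
    activation: Activation = Activation.NONE
    concentration: float | None = None
    experiment_day: str = ""

    def __post_init__(self) -> None:
        # Text fields are case-folded so hand-edited inputs and generated
        # samples compare equal; enums parse case-insensitively.
        for name in ("donor_id", "marker", "clone", "experiment_day"):
            object.__setattr__(self, name, str(getattr(self, name)).lower())
        object.__setattr__(self, "condition", Condition.parse(self.condition))
        object.__setattr__(self, "parent_lineage", Lineage.parse(self.parent_lineage))
        object.__setattr__(self, "activation", Activation.parse(self.activation))
        if self.concentration is not None and not self.concentration > 0:
            raise ValidationError("concentration must be positive when present")


@dataclass
class EventTable:
    """Per-cell fluorescence intensities for one sample.

    ``events`` has one row per acquired cell event and one column per entry
    of ``channels`` (arbitrary fluorescence units, linear scale).
    """

    sample_id: str
    channels: list[str]
    events: np.ndarray
    meta: SampleMeta

    def __post_init__(self) -> None:
        self.events = np.asarray(self.events, dtype=float)
        if self.events.size == 0:
            self.events = self.events.reshape(0, len(self.channels))
        if self.events.ndim != 2 or self.events.shape[1] != len(self.channels):
            raise ValidationError(
                f"events must be 2-D with {len(self.channels)} columns, "
                f"got shape {self.events.shape}"
            )
        if len(set(self.channels)) != len(self.channels):
            raise ValidationError("channel names must be unique")
        if self.events.size and not np.all(np.isfinite(self.events)):
            raise ValidationError("all intensities must be finite")

    @property
    def n_events(self) -> int:
        return self.events.shape[0]

    def channel_values(self, channel: str) -> np.ndarray:
        """Intensity column for ``channel``; SchemaError if absent."""
        try:
            idx = self.channels.index(channel)
        except ValueError:
            raise SchemaError(
                f"channel {channel!r} not in sample {self.sample_id!r} "
                f"(has {self.channels})"
            ) from None
        return self.events[:, idx]


# ---------------------------------------------------------------------------
# Event-table I/O (CSV with '#key: value' preamble)
# ---------------------------------------------------------------------------

_REQUIRED_META = ("sample_id", "donor_id", "marker", "clone", "condition",
                  "parent_lineage")


def read_event_table(path: str | Path, dialect: dict | None = None) -> EventTable:
    """Read one sample's event table from a self-describing CSV file.

    The file starts with a ``#key: value`` preamble carrying the sample
    metadata, followed by a header row of channel names and one row per
    event.  Metadata text fields are case-folded to lower case; enums parse
    case-insensitively.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    body_lines: list[str] = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#"):
                key, sep, value = line[1:].partition(":")
                if sep:
                    meta[key.strip().lower()] = value.strip().lower()
            else:
                body_lines.append(line)
    for field_name in _REQUIRED_META:
        if field_name not in meta or not meta[field_name]:
            raise MetadataError(
                f"{path.name}: missing required metadata field {field_name!r}"
            )
    if not body_lines:
        raise ParseError(f"{path.name}: no header row of channel names")
    df = pd.read_csv(io.StringIO("".join(body_lines)), dtype=str,
                     skip_blank_lines=True)
    channels = [str(c).strip() for c in df.columns]
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        row = int(np.argwhere(bad.to_numpy())[0, 0])
        raise ParseError(
            f"{path.name}: non-numeric intensity in data row {row + 1}"
        )
    if numeric.isna().to_numpy().any():
        row = int(np.argwhere(numeric.isna().to_numpy())[0, 0])
        raise ParseError(f"{path.name}: missing intensity in data row {row + 1}")
    conc = meta.get("concentration", "")
    sample_meta = SampleMeta(
        donor_id=meta["donor_id"],
        marker=meta["marker"],
        clone=meta["clone"],
        condition=Condition.parse(meta["condition"]),
        parent_lineage=Lineage.parse(meta["parent_lineage"]),
        activation=Activation.parse(meta.get("activation", "none")),
        concentration=float(conc) if conc else None,
        experiment_day=meta.get("experiment_day", ""),
    )
    return EventTable(
        sample_id=meta["sample_id"],
        channels=channels,
        events=numeric.to_numpy(dtype=float),
        meta=sample_meta,
    )


def write_event_table(table: EventTable, path: str | Path) -> Path:
    """Write ``table`` so that :func:`read_event_table` round-trips it.

    Intensities are formatted at 9 significant digits, so values
    round-trip well within 1e-6 relative error.
    """
    path = Path(path)
    m = table.meta
    lines = [
        f"#sample_id: {table.sample_id}",
        f"#donor_id: {m.donor_id}",
        f"#marker: {m.marker}",
        f"#clone: {m.clone}",
        f"#condition: {m.condition.value}",
        f"#parent_lineage: {m.parent_lineage.value}",
        f"#activation: {m.activation.value}",
        f"#experiment_day: {m.experiment_day}",
    ]
    if m.concentration is not None:
        lines.append(f"#concentration: {m.concentration:.6g}")
    lines.append(",".join(table.channels))
    for row in table.events:
        lines.append(",".join(f"{v:.9g}" for v in row))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


# ---------------------------------------------------------------------------
# Bundled reference tables
# ---------------------------------------------------------------------------

_TABLE2_SHA256 = "15680e18e803413de5fa5641cf7b5182462cb2c3b02f462c45920ba11ef60a3c"
_TABLE3_SHA256 = "3b3b4d6a99c3593808902c34ccd701c242d397fa72dfa8e194db5884a0f56658"

#: The eight TotalSeq-C clones flagged in the digestion-sensitivity table.
TOTALSEQC_CLONES = frozenset(
    {"RPA-T4", "RPA-T8", "BC96", "O323", "3G7A02", "L291H4", "G034E3",
     "EH12.2H7"}
)


@dataclass(frozen=True)
class Table2Row:
    """One clone of the digestion-sensitivity screen.

    Percentages are the published proportion of included replicates falling
    in each sensitivity category (integers; they sum to 100 up to rounding).
    """

    marker: str
    clone: str
    is_totalseqc: bool
    n_donors: int
    n_replicates: int
    pct_sensitive: float
    pct_partial: float
    pct_not: float


@dataclass(frozen=True)
class Table3Row:
    """One antibody of the 3-point titration series.

    Concentrations are µg per 100 µL per 10^6 cells; ``chosen_index`` is the
    1-based tested concentration selected for CITE-seq staining.
    ``transcription_uncertain`` flags the one row whose published chosen
    value contains a typographical artifact.
    """

    antibody: str
    stimulation: str
    titration1: float
    titration2: float
    titration3: float
    chosen_index: int
    transcription_uncertain: bool = False

    @property
    def concentrations(self) -> tuple[float, float, float]:
        return (self.titration1, self.titration2, self.titration3)


@dataclass(frozen=True)
class PaperFixtures:
    table2: tuple[Table2Row, ...]
    table3: tuple[Table3Row, ...]


def _fixture_text(name: str, expected_sha: str) -> str:
    ref = resources.files("epitope_audit").joinpath("data").joinpath(name)
    try:
        raw = ref.read_bytes()
    except FileNotFoundError as exc:  # pragma: no cover - packaging failure
        raise FixtureError(f"bundled fixture {name} is missing") from exc
    digest = hashlib.sha256(raw).hexdigest()
    if digest != expected_sha:
        raise FixtureError(
            f"bundled fixture {name} fails its checksum "
            f"(got {digest[:12]}..., expected {expected_sha[:12]}...)"
        )
    return raw.decode("utf-8")


def load_fixtures() -> PaperFixtures:
    """Load and validate the bundled sensitivity and titration tables."""
    t2 = pd.read_csv(io.StringIO(_fixture_text("table2.csv", _TABLE2_SHA256)))
    t3 = pd.read_csv(io.StringIO(_fixture_text("table3.csv", _TABLE3_SHA256)))

    table2 = tuple(
        Table2Row(
            marker=r.marker, clone=r.clone, is_totalseqc=bool(r.is_totalseqc),
            n_donors=int(r.n_donors), n_replicates=int(r.n_replicates),
            pct_sensitive=float(r.pct_sensitive),
            pct_partial=float(r.pct_partial), pct_not=float(r.pct_not),
        )
        for r in t2.itertuples()
    )
    table3 = tuple(
        Table3Row(
            antibody=r.antibody, stimulation=r.stimulation,
            titration1=float(r.titration1), titration2=float(r.titration2),
            titration3=float(r.titration3), chosen_index=int(r.chosen_index),
            transcription_uncertain=bool(r.transcription_uncertain),
        )
        for r in t3.itertuples()
    )

    if len(table2) != 20:
        raise FixtureError(f"expected 20 clone rows, found {len(table2)}")
    if len({r.marker for r in table2}) != 8:
        raise FixtureError("expected 8 distinct markers in the clone table")
    flagged = {r.clone for r in table2 if r.is_totalseqc}
    if flagged != set(TOTALSEQC_CLONES):
        raise FixtureError(f"TotalSeq-C flags inconsistent: {sorted(flagged)}")
    for r in table2:
        total = r.pct_sensitive + r.pct_partial + r.pct_not
        if abs(total - 100.0) > 1.0:
            raise FixtureError(
                f"clone {r.clone}: category percentages sum to {total}, not 100"
            )
    if len(table3) != 63:
        raise FixtureError(f"expected 63 antibody rows, found {len(table3)}")
    for r in table3:
        if not (r.titration1 < r.titration2 < r.titration3):
            raise FixtureError(
                f"antibody {r.antibody}: concentrations not strictly increasing"
            )
        if r.chosen_index not in (1, 2, 3):
            raise FixtureError(f"antibody {r.antibody}: bad chosen_index")
    return PaperFixtures(table2=table2, table3=table3)
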