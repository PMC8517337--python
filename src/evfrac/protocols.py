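"""Rule-based classification of EV proteomic datasets from centrifugation protocols.

Differential ultracentrifugation (DUC) protocols pre-clear debris and larger
vesicles at low speed and then pellet the retained EV fraction at a target
speed. A dataset is assigned to the small-EV (sEV, exosome-enriched) fraction
when the pellet was spun at >= 100,000 x g after pre-clearance of >= 10,000 x g,
and to the large-EV (lEV, ectosome-enriched) fraction when the pellet was spun
at <= 20,000 x g with all pre-clearing below 10,000 x g. Protocols outside both
windows are excluded from the meta-analysis.

Speeds must be relative centrifugal force in units of x g; rpm values are
rotor-dependent and are rejected as malformed rather than converted.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: sEV pellet window lower bound (inclusive), x g
SEV_PELLET_MIN = 100_000.0
#: lEV pellet window upper bound (inclusive), x g
LEV_PELLET_MAX = 20_000.0
#: pre-clearance threshold: >= for sEV, < for lEV, x g
PRECLEAR_CUT = 10_000.0


class Role(str, enum.Enum):
    PRECLEAR = "PRECLEAR"
    PELLET = "PELLET"


class Label(str, enum.Enum):
    SEV = "SEV"
    LEV = "LEV"
    EXCLUDED = "EXCLUDED"


class Reason(str, enum.Enum):
    OK = "OK"
    NO_PRECLEAR_FOR_SEV = "NO_PRECLEAR_FOR_SEV"
    PELLET_BETWEEN_WINDOWS = "PELLET_BETWEEN_WINDOWS"
    PRECLEAR_TOO_FAST_FOR_LEV = "PRECLEAR_TOO_FAST_FOR_LEV"
    MALFORMED = "MALFORMED"


@dataclass(frozen=True)
class CentrifugationStep:
    """One spin in a DUC protocol.

    Parameters
    ----------
    order : int
        Rank of the step within the protocol (1-based, unique).
    speed : float
        Relative centrifugal force in x g; must be positive.
    role : Role
        PRECLEAR (discard pellet) or PELLET (retain pellet = the EV fraction).
    """

    order: int
    speed: float
    role: Role


@dataclass(frozen=True)
class ProtocolRecord:
    """Structured DUC protocol metadata for one proteomic dataset."""

    dataset_id: str
    species: str
    steps: tuple[CentrifugationStep, ...]
    note: str = ""


@dataclass(frozen=True)
class FractionLabel:
    label: Label
    reason: Reason

    def __post_init__(self) -> None:
        ok = self.reason is Reason.OK
        if ok != (self.label in (Label.SEV, Label.LEV)):
            raise ValueError("reason OK iff label is SEV or LEV")


class MalformedProtocolError(ValueError):
    """Protocol violates structural invariants (no pellet step, bad speed...)."""


@dataclass
class ClassificationSummary:
    """Counts per label and per exclusion reason for one classified table."""

    n_input: int = 0
    n_non_human_dropped: int = 0
    label_counts: dict = field(default_factory=dict)
    reason_counts: dict = field(default_factory=dict)


def _validate(record: ProtocolRecord) -> tuple[float, float]:
    """Return (pellet speed P, max pre-clear speed C); raise MalformedProtocolError."""
    if not record.steps:
        raise MalformedProtocolError(f"{record.dataset_id}: protocol has no steps")
    orders = [s.order for s in record.steps]
    if len(set(orders)) != len(orders):
        raise MalformedProtocolError(f"{record.dataset_id}: duplicate step orders")
    pellets = [s for s in record.steps if s.role is Role.PELLET]
    if len(pellets) != 1:
        raise MalformedProtocolError(
            f"{record.dataset_id}: expected exactly one PELLET step, got {len(pellets)}"
        )
    pellet = pellets[0]
    preclears = [s for s in record.steps if s.role is Role.PRECLEAR]
    for s in record.steps:
        if not (s.speed > 0):
            raise MalformedProtocolError(f"{record.dataset_id}: non-positive speed {s.speed}")
    if any(s.order >= pellet.order for s in preclears):
        raise MalformedProtocolError(
            f"{record.dataset_id}: pre-clear step after the retained pellet"
        )
    c_max = max((s.speed for s in preclears), default=0.0)
    return pellet.speed, c_max


def classify_protocol(record: ProtocolRecord) -> FractionLabel:
    """Assign a DUC protocol to the sEV or lEV window, or exclude it.

    With P the retained-pellet speed and C the maximum pre-clearance speed
    (0 when no pre-clear step is present):

    * SEV  iff P >= 100,000 x g and C >= 10,000 x g
    * LEV  iff P <= 20,000 x g and C < 10,000 x g
    * otherwise EXCLUDED, with the first applicable reason.

    Raises
    ------
    MalformedProtocolError
        If the protocol has no single retained pellet or a non-positive speed.
    """
    p, c = _validate(record)
    if p >= SEV_PELLET_MIN:
        if c >= PRECLEAR_CUT:
            return FractionLabel(Label.SEV, Reason.OK)
        return FractionLabel(Label.EXCLUDED, Reason.NO_PRECLEAR_FOR_SEV)
    if p <= LEV_PELLET_MAX:
        if c < PRECLEAR_CUT:
            return FractionLabel(Label.LEV, Reason.OK)
        return FractionLabel(Label.EXCLUDED, Reason.PRECLEAR_TOO_FAST_FOR_LEV)
    return FractionLabel(Label.EXCLUDED, Reason.PELLET_BETWEEN_WINDOWS)


def classify_table(
    records: Iterable[ProtocolRecord], species: str = "human"
) -> tuple[pd.DataFrame, ClassificationSummary]:
    """Classify a study table of protocols, restricted to one species.

    Returns a DataFrame with columns ``dataset_id, label, reason`` (one row per
    retained record) and a :class:`ClassificationSummary`. Non-matching species
    are dropped with a logged count; malformed protocols are labelled
    EXCLUDED/MALFORMED rather than aborting the table.

    Raises
    ------
    ValueError
        On duplicate dataset ids.
    """
    records = list(records)
    summary = ClassificationSummary(n_input=len(records))
    ids = [r.dataset_id for r in records]
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        raise ValueError(f"duplicate dataset_id(s): {sorted(dupes)}")

    kept = [r for r in records if r.species.lower() == species.lower()]
    summary.n_non_human_dropped = len(records) - len(kept)
    if summary.n_non_human_dropped:
        logger.info("dropped %d non-%s datasets", summary.n_non_human_dropped, species)

    rows = []
    for rec in kept:
        try:
            fl = classify_protocol(rec)
        except MalformedProtocolError:
            fl = FractionLabel(Label.EXCLUDED, Reason.MALFORMED)
        rows.append((rec.dataset_id, fl.label.value, fl.reason.value))
    table = pd.DataFrame(rows, columns=["dataset_id", "label", "reason"])
    for lab in Label:
        summary.label_counts[lab.value] = int((table["label"] == lab.value).sum()) if len(table) else 0
    for reason in Reason:
        summary.reason_counts[reason.value] = (
            int((table["reason"] == reason.value).sum()) if len(table) else 0
        )
    return table, summary


def read_protocols(path) -> list[ProtocolRecord]:
    """Read protocols from TSV with columns dataset_id, species, step_order, speed_xg, role."""
    df = pd.read_csv(path, sep="\t", dtype={"dataset_id": str, "species": str},
                     float_precision="round_trip")
    required = {"dataset_id", "species", "step_order", "speed_xg", "role"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"protocol table missing columns: {sorted(missing)}")
    records = []
    for (ds, sp), grp in df.groupby(["dataset_id", "species"], sort=False):
        steps = tuple(
            CentrifugationStep(int(r.step_order), float(r.speed_xg), Role(r.role))
            for r in grp.sort_values("step_order").itertuples()
        )
        records.append(ProtocolRecord(dataset_id=ds, species=sp, steps=steps))
    return records


def protocols_to_frame(records: Sequence[ProtocolRecord]) -> pd.DataFrame:
    """Long-format TSV frame, inverse of :func:`read_protocols`."""
    rows = [
        (r.dataset_id, r.species, s.order, s.speed, s.role.value)
        for r in records
        for s in r.steps
    ]
    return pd.DataFrame(rows, columns=["dataset_id", "species", "step_order", "speed_xg", "role"])
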