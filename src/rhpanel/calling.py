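"""Three-valued genotype calling from qPCR Ct/Tm readouts.

A hybrid is called *present* when it amplifies no later than the negative
control (Ct <= negative-control Ct, minus an optional safety margin) AND its
product melts at the marker-specific temperature (|Tm - positive-control Tm|
within ``tm_tol``).  Discordant evidence (early Ct but shifted Tm, or late Ct
with a matching Tm) is *unknown*; a strongly shifted Tm (beyond twice the
tolerance, i.e. a non-specific product) with late amplification, or no
amplification at all, is *absent*.  Markers whose duck positive control fails
to amplify, or amplifies outside the accepted Ct window, are discarded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import ABSENT, PRESENT, UNKNOWN, GenotypeMatrix, ValidationError
from .simulate import NEG_CONTROL, POS_CONTROL


@dataclass(frozen=True)
class QPCRReading:
    """One well: Ct (NaN = no amplification) and Tm (None = not measured)."""

    marker_id: str
    sample_id: str
    replicate: int
    ct: float  # NaN means no amplification
    tm: float | None = None

    @property
    def amplified(self) -> bool:
        return not math.isnan(self.ct)

    def __post_init__(self) -> None:
        if self.amplified and self.ct <= 0:
            raise ValidationError(
                f"{self.marker_id}/{self.sample_id}: Ct must be > 0 when present"
            )


@dataclass
class CallingConfig:
    """Decision thresholds for Ct/Tm calling.

    ``ct_pos_min``/``ct_pos_max`` bound the accepted positive-control Ct
    (markers outside the window are discarded).  ``tm_tol`` is the melting
    temperature tolerance for a specific product; beyond ``2 * tm_tol`` the
    product is treated as non-specific.  ``ct_call_margin`` tightens the
    "no later than the negative control" rule for noisy data (default 0,
    the rule as stated).
    """

    ct_pos_min: float = 10.0
    ct_pos_max: float = 16.0
    tm_tol: float = 1.5
    ct_call_margin: float = 0.0
    strict_replicates: bool = False

    def __post_init__(self) -> None:
        if not self.ct_pos_min < self.ct_pos_max:
            raise ValidationError("ct_pos_min must be < ct_pos_max")
        if self.tm_tol <= 0:
            raise ValidationError("tm_tol must be > 0")
        if self.ct_call_margin < 0:
            raise ValidationError("ct_call_margin must be >= 0")


def qc_marker(pos_control: QPCRReading, config: CallingConfig) -> str:
    """``'pass'`` or ``'discard'`` from the duck positive control alone."""
    if pos_control is None:
        raise ValidationError("missing positive-control reading")
    if not pos_control.amplified:
        return "discard"
    if not config.ct_pos_min <= pos_control.ct <= config.ct_pos_max:
        return "discard"
    return "pass"


def call_genotype(
    hybrid: QPCRReading,
    pos_control: QPCRReading,
    neg_control: QPCRReading,
    config: CallingConfig,
) -> int:
    """Call one hybrid well against the marker's controls.

    Decision table (Ct relative to the negative control, Tm relative to the
    positive control): early+matching = present; early+shifted = unknown
    (absent when the shift exceeds ``2*tm_tol``); late+matching = unknown;
    late+shifted or no amplification = absent.
    """
    if not hybrid.amplified:
        return ABSENT
    # a missing negative-control amplification means any hybrid Ct is "early"
    neg_ct = neg_control.ct if neg_control.amplified else math.inf
    low_ct = hybrid.ct <= neg_ct - config.ct_call_margin
    if hybrid.tm is None or pos_control.tm is None:
        # Tm evidence missing: an early Ct alone is ambiguous
        return UNKNOWN
    dtm = abs(hybrid.tm - pos_control.tm)
    tm_match = dtm <= config.tm_tol
    if low_ct and tm_match:
        return PRESENT
    if low_ct and not tm_match:
        # non-specific product when far beyond tolerance, else ambiguous
        return ABSENT if dtm > 2.0 * config.tm_tol else UNKNOWN
    if tm_match:  # late Ct, specific Tm
        return UNKNOWN
    return ABSENT


def consolidate_replicates(
    call1: int, call2: int, strict_replicates: bool = False
) -> int:
    """Resolve duplicate wells into one call.

    Agreement passes through; a present/absent conflict is unknown; a pair
    with one unknown takes the decisive call unless ``strict_replicates``.
    """
    if call1 == call2:
        return call1
    if UNKNOWN in (call1, call2):
        other = call2 if call1 == UNKNOWN else call1
        return UNKNOWN if strict_replicates else other
    return UNKNOWN  # present vs absent


@dataclass
class QCReport:
    """Marker-level QC outcome of a calling run."""

    discarded_markers: list[str] = field(default_factory=list)
    passed_markers: list[str] = field(default_factory=list)
    missing_wells: int = 0

    @property
    def n_discarded(self) -> int:
        return len(self.discarded_markers)

    @property
    def discard_fraction(self) -> float:
        total = len(self.discarded_markers) + len(self.passed_markers)
        return self.n_discarded / total if total else 0.0


def readings_from_table(df: pd.DataFrame) -> list[QPCRReading]:
    """Long-format readout table (marker_id, sample_id, replicate, ct, tm)."""
    required = {"marker_id", "sample_id", "replicate", "ct", "tm"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"qPCR table missing column(s): {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        ct = float(row.ct) if not pd.isna(row.ct) else math.nan
        tm = float(row.tm) if not pd.isna(row.tm) else None
        out.append(
            QPCRReading(
                marker_id=str(row.marker_id),
                sample_id=str(row.sample_id),
                replicate=int(row.replicate),
                ct=ct,
                tm=tm,
            )
        )
    return out


def build_matrix(
    readings: Iterable[QPCRReading] | pd.DataFrame,
    config: CallingConfig | None = None,
    pos_control_id: str = POS_CONTROL,
    neg_control_id: str = NEG_CONTROL,
    sample_ids: Sequence[str] | None = None,
) -> tuple[GenotypeMatrix, QCReport]:
    """QC markers, call every well and consolidate replicates into a matrix.

    Markers failing positive-control QC are excluded from the matrix and
    listed in the report.  Grid gaps (missing wells) become unknown calls and
    are counted.
    """
    config = config or CallingConfig()
    if isinstance(readings, pd.DataFrame):
        readings = readings_from_table(readings)
    readings = list(readings)
    if not readings:
        raise ValidationError("no qPCR readings provided")

    by_marker: dict[str, dict[str, dict[int, QPCRReading]]] = {}
    marker_order: list[str] = []
    sample_order: list[str] = []
    seen_samples: set[str] = set()
    for rd in readings:
        if rd.marker_id not in by_marker:
            by_marker[rd.marker_id] = {}
            marker_order.append(rd.marker_id)
        by_marker[rd.marker_id].setdefault(rd.sample_id, {})[rd.replicate] = rd
        if rd.sample_id not in seen_samples:
            seen_samples.add(rd.sample_id)
            if rd.sample_id not in (pos_control_id, neg_control_id):
                sample_order.append(rd.sample_id)
    if sample_ids is not None:
        sample_order = list(sample_ids)

    report = QCReport()
    kept_markers: list[str] = []
    rows: list[np.ndarray] = []
    for marker in marker_order:
        wells = by_marker[marker]
        pos_wells = wells.get(pos_control_id)
        if not pos_wells:
            raise ValidationError(f"marker {marker}: no positive-control reading")
        neg_wells = wells.get(neg_control_id)
        if not neg_wells:
            raise ValidationError(f"marker {marker}: no negative-control reading")
        # per-replicate QC: the marker survives if any replicate's control passes
        rep_ok = {rep: qc_marker(rd, config) == "pass" for rep, rd in pos_wells.items()}
        if not any(rep_ok.values()):
            report.discarded_markers.append(marker)
            continue
        report.passed_markers.append(marker)
        kept_markers.append(marker)
        row = np.full(len(sample_order), UNKNOWN, dtype=np.int8)
        for j, sample in enumerate(sample_order):
            sample_wells = wells.get(sample, {})
            rep_calls = []
            for rep, pos_rd in pos_wells.items():
                if not rep_ok.get(rep, False):
                    continue
                rd = sample_wells.get(rep)
                if rd is None:
                    report.missing_wells += 1
                    continue
                neg_rd = neg_wells.get(rep) or next(iter(neg_wells.values()))
                rep_calls.append(call_genotype(rd, pos_rd, neg_rd, config))
            if not rep_calls:
                row[j] = UNKNOWN
            elif len(rep_calls) == 1:
                row[j] = rep_calls[0]
            else:
                final = rep_calls[0]
                for c in rep_calls[1:]:
                    final = consolidate_replicates(final, c, config.strict_replicates)
                row[j] = final
        rows.append(row)

    if not kept_markers:
        raise ValidationError("all markers failed positive-control QC")
    matrix = GenotypeMatrix(
        marker_ids=kept_markers,
        hybrid_ids=sample_order,
        calls=np.vstack(rows),
    )
    return matrix, report
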