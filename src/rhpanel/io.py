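"""Tabular readers/writers for marker tables, genotype matrices and alignments.

All bp coordinates are 1-based and inclusive on both ends.  Genotype calls are
three-valued (present / absent / unknown) and encoded internally as int8 codes
``1 / 0 / -1``.  File tokens default to ``1 / 0 / ?`` but are configurable, and
the CarthaGene-style export uses ``1 / 0 / -``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

PRESENT: int = 1
ABSENT: int = 0
UNKNOWN: int = -1

#: default file tokens for the three call values
DEFAULT_TOKENS: dict[str, int] = {"1": PRESENT, "0": ABSENT, "?": UNKNOWN}

CHROM_CLASSES = ("macro", "micro", "unknown")
MARKER_SOURCES = ("microsatellite", "scaffold", "est")


class FormatError(ValueError):
    """A file does not conform to the expected tabular layout."""


class ValidationError(ValueError):
    """Parsed content violates a domain invariant."""


@dataclass(frozen=True)
class MarkerRecord:
    """One genotyped marker: identity, expected location and provenance.

    ``position_bp`` / ``scaffold_offset_bp`` are 1-based; ``None`` marks
    unknown values (e.g. no-hit EST markers have no expected chromosome).
    """

    marker_id: str
    expected_chrom: str | None = None
    position_bp: int | None = None
    scaffold_id: str | None = None
    scaffold_offset_bp: int | None = None
    chrom_class: str = "unknown"
    source: str = "scaffold"

    def __post_init__(self) -> None:
        if not self.marker_id:
            raise ValidationError("marker_id must be non-empty")
        if self.position_bp is not None and self.position_bp < 1:
            raise ValidationError(
                f"marker {self.marker_id}: position_bp must be >= 1 (1-based)"
            )
        if self.scaffold_offset_bp is not None and self.scaffold_offset_bp < 1:
            raise ValidationError(
                f"marker {self.marker_id}: scaffold_offset_bp must be >= 1"
            )
        if self.chrom_class not in CHROM_CLASSES:
            raise ValidationError(
                f"marker {self.marker_id}: chrom_class {self.chrom_class!r} "
                f"not in {CHROM_CLASSES}"
            )
        if self.source not in MARKER_SOURCES:
            raise ValidationError(
                f"marker {self.marker_id}: source {self.source!r} "
                f"not in {MARKER_SOURCES}"
            )


@dataclass(frozen=True)
class AlignmentSegment:
    """One aligned interval of a scaffold on a reference chromosome."""

    scaffold_id: str
    scaffold_start_bp: int
    scaffold_end_bp: int
    ref_chrom: str
    ref_start_bp: int
    ref_end_bp: int
    orientation: str = "+"

    def __post_init__(self) -> None:
        if self.scaffold_start_bp > self.scaffold_end_bp:
            raise ValidationError(
                f"{self.scaffold_id}: scaffold_start_bp > scaffold_end_bp"
            )
        if self.ref_start_bp > self.ref_end_bp:
            raise ValidationError(f"{self.scaffold_id}: ref_start_bp > ref_end_bp")
        if self.orientation not in ("+", "-"):
            raise FormatError(
                f"{self.scaffold_id}: orientation must be '+' or '-', "
                f"got {self.orientation!r}"
            )


@dataclass
class GenotypeMatrix:
    """Markers x hybrids three-valued calls, the panel's central object.

    ``calls[i, j]`` is the call for ``marker_ids[i]`` in ``hybrid_ids[j]``,
    coded ``1`` present, ``0`` absent, ``-1`` unknown.  ``replicate_calls``
    optionally keeps the per-replicate layer the consolidated calls came from.
    """

    marker_ids: list[str]
    hybrid_ids: list[str]
    calls: np.ndarray
    replicate_calls: np.ndarray | None = None  # shape (n_rep, markers, hybrids)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.marker_ids), len(self.hybrid_ids)):
            raise ValidationError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.marker_ids)} markers x {len(self.hybrid_ids)} hybrids"
            )
        bad = ~np.isin(self.calls, (PRESENT, ABSENT, UNKNOWN))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"call at marker {self.marker_ids[i]!r}, hybrid "
                f"{self.hybrid_ids[j]!r} outside the present/absent/unknown domain"
            )
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise ValidationError("duplicate marker_id in genotype matrix")
        if len(set(self.hybrid_ids)) != len(self.hybrid_ids):
            raise ValidationError("duplicate hybrid_id in genotype matrix")

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @property
    def n_hybrids(self) -> int:
        return len(self.hybrid_ids)

    def row(self, marker_id: str) -> np.ndarray:
        return self.calls[self.marker_ids.index(marker_id)]

    def subset(self, marker_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.marker_ids.index(m) for m in marker_ids]
        return GenotypeMatrix(
            marker_ids=list(marker_ids),
            hybrid_ids=list(self.hybrid_ids),
            calls=self.calls[idx].copy(),
        )

    def to_dataframe(self, tokens: Mapping[str, int] = DEFAULT_TOKENS) -> pd.DataFrame:
        rev = {v: k for k, v in tokens.items()}
        data = np.vectorize(rev.get)(self.calls)
        return pd.DataFrame(data, index=self.marker_ids, columns=self.hybrid_ids)


# ---------------------------------------------------------------------------
# marker tables

_MARKER_COLUMNS = (
    "marker_id",
    "expected_chrom",
    "position_bp",
    "scaffold_id",
    "scaffold_offset_bp",
    "chrom_class",
    "source",
)

_NA_TOKENS = ("", "NA", "na", "none", "None", ".", "unknown")


def _opt_str(v) -> str | None:
    if pd.isna(v) or str(v) in _NA_TOKENS:
        return None
    return str(v)


def _opt_int(v, col: str, row: int) -> int | None:
    if pd.isna(v) or str(v) in _NA_TOKENS:
        return None
    try:
        return int(v)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"row {row}: column {col!r} value {v!r} is not an integer") from exc


def read_marker_table(path) -> list[MarkerRecord]:
    """Read a TSV marker table into :class:`MarkerRecord` rows, order preserved."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in ("marker_id",) if c not in df.columns]
    if missing:
        raise FormatError(f"marker table missing required column(s): {missing}")
    records: list[MarkerRecord] = []
    seen: set[str] = set()
    for i, row in df.iterrows():
        mid = str(row["marker_id"])
        if mid in seen:
            raise ValidationError(f"duplicate marker_id {mid!r}")
        seen.add(mid)
        records.append(
            MarkerRecord(
                marker_id=mid,
                expected_chrom=_opt_str(row.get("expected_chrom")),
                position_bp=_opt_int(row.get("position_bp"), "position_bp", i),
                scaffold_id=_opt_str(row.get("scaffold_id")),
                scaffold_offset_bp=_opt_int(
                    row.get("scaffold_offset_bp"), "scaffold_offset_bp", i
                ),
                chrom_class=_opt_str(row.get("chrom_class")) or "unknown",
                source=_opt_str(row.get("source")) or "scaffold",
            )
        )
    return records


def write_marker_table(records: Iterable[MarkerRecord], path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "marker_id": r.marker_id,
                "expected_chrom": r.expected_chrom if r.expected_chrom is not None else "NA",
                "position_bp": r.position_bp if r.position_bp is not None else "NA",
                "scaffold_id": r.scaffold_id if r.scaffold_id is not None else "NA",
                "scaffold_offset_bp": (
                    r.scaffold_offset_bp if r.scaffold_offset_bp is not None else "NA"
                ),
                "chrom_class": r.chrom_class,
                "source": r.source,
            }
        )
    pd.DataFrame(rows, columns=_MARKER_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# genotype matrices

def read_genotype_matrix(
    path, tokens: Mapping[str, int] = DEFAULT_TOKENS, sep: str = "\t"
) -> GenotypeMatrix:
    """Read a markers-x-hybrids call table.

    First column holds marker ids, header row holds hybrid ids.  Cell tokens
    are mapped through ``tokens``; anything unmapped raises :class:`FormatError`
    with the offending cell's coordinates.
    """
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValidationError(f"{path}: empty genotype matrix")
    calls = np.empty(df.shape, dtype=np.int8)
    values = df.to_numpy()
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            tok = values[i, j].strip()
            if tok not in tokens:
                raise FormatError(
                    f"unrecognized genotype token {tok!r} at marker "
                    f"{df.index[i]!r}, hybrid {df.columns[j]!r}"
                )
            calls[i, j] = tokens[tok]
    return GenotypeMatrix(
        marker_ids=[str(m) for m in df.index],
        hybrid_ids=[str(h) for h in df.columns],
        calls=calls,
    )


def write_genotype_matrix(
    matrix: GenotypeMatrix, path, tokens: Mapping[str, int] = DEFAULT_TOKENS, sep: str = "\t"
) -> None:
    matrix.to_dataframe(tokens).to_csv(path, sep=sep, index_label="marker_id")


def export_carthagene(matrix: GenotypeMatrix) -> str:
    """Render a matrix in the CarthaGene RH flat-text dialect.

    Header line ``data type radiated hybrid`` then marker count / hybrid count,
    then one line per marker with a ``1/0/-`` call string.  Marker order is the
    matrix order (deterministic).
    """
    if matrix.n_markers == 0 or matrix.n_hybrids == 0:
        raise ValidationError("cannot export an empty matrix")
    symbol = {PRESENT: "1", ABSENT: "0", UNKNOWN: "-"}
    lines = [
        "data type radiated hybrid",
        f"{matrix.n_hybrids} {matrix.n_markers} 0 0",
    ]
    for mid, row in zip(matrix.marker_ids, matrix.calls):
        lines.append(f"*{mid} {''.join(symbol[int(c)] for c in row)}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# alignment tables

_ALIGNMENT_COLUMNS = (
    "scaffold_id",
    "scaffold_start_bp",
    "scaffold_end_bp",
    "ref_chrom",
    "ref_start_bp",
    "ref_end_bp",
    "orientation",
)


def read_alignment_table(path) -> list[AlignmentSegment]:
    """Read scaffold-to-reference alignment segments (Narcisse-style TSV)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _ALIGNMENT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"alignment table missing required column(s): {missing}")
    segments: list[AlignmentSegment] = []
    for i, row in df.iterrows():
        try:
            seg = AlignmentSegment(
                scaffold_id=str(row["scaffold_id"]),
                scaffold_start_bp=int(row["scaffold_start_bp"]),
                scaffold_end_bp=int(row["scaffold_end_bp"]),
                ref_chrom=str(row["ref_chrom"]),
                ref_start_bp=int(row["ref_start_bp"]),
                ref_end_bp=int(row["ref_end_bp"]),
                orientation=str(row["orientation"]),
            )
        except (TypeError, ValueError) as exc:
            if isinstance(exc, (FormatError, ValidationError)):
                raise
            raise FormatError(f"alignment table row {i}: {exc}") from exc
        segments.append(seg)
    return segments


def write_alignment_table(segments: Iterable[AlignmentSegment], path) -> None:
    rows = [
        {
            "scaffold_id": s.scaffold_id,
            "scaffold_start_bp": s.scaffold_start_bp,
            "scaffold_end_bp": s.scaffold_end_bp,
            "ref_chrom": s.ref_chrom,
            "ref_start_bp": s.ref_start_bp,
            "ref_end_bp": s.ref_end_bp,
            "orientation": s.orientation,
        }
        for s in segments
    ]
    pd.DataFrame(rows, columns=_ALIGNMENT_COLUMNS).to_csv(path, sep="\t", index=False)
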