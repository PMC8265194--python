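"""Data model and readers for curated ASO exon-skipping experiment records.

An :class:`AsoRecord` is one antisense oligonucleotide (ASO) together with one
experimentally measured exon-skipping efficacy, the chemistry and concentration
at which it was tested, and enough provenance to trace the measurement back to
its source. Training data are assembled from heterogeneous literature tables,
so parsing is tolerant: malformed rows are rejected with a logged reason rather
than aborting the whole file, while structurally missing columns are fatal.

Sequences are stored in the RNA alphabet (U) internally; T on input is treated
as synonymous with U because morpholino (PMO) and 2'-O-methyl (2OMe) sequences
are reported in both alphabets in the literature.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGU")

#: Reference cell line used to normalise experimental conditions when
#: filtering training data. Configurable in :func:`filter_for_training`.
DEFAULT_CELL_LINE = "RD"

#: Canonical column names for the tabular interchange format.
CANONICAL_COLUMNS = (
    "aso_sequence",
    "chemistry",
    "gene",
    "species",
    "target_exon",
    "target_start",
    "target_end",
    "concentration_uM",
    "efficacy_pct",
    "efficacy_is_absolute",
    "efficacy_is_ec50",
    "is_sequential",
    "cell_type",
    "source",
)

MANDATORY_COLUMNS = ("aso_sequence", "chemistry", "concentration_uM", "efficacy_pct")


class Chemistry(str, enum.Enum):
    """ASO backbone chemistry."""

    PMO = "PMO"
    TWO_OME = "2OMe"

    @classmethod
    def parse(cls, value: "str | Chemistry") -> "Chemistry":
        if isinstance(value, Chemistry):
            return value
        text = str(value).strip()
        for member in cls:
            if member.value.lower() == text.lower():
                return member
        aliases = {"2'ome": cls.TWO_OME, "2-ome": cls.TWO_OME, "2o-me": cls.TWO_OME}
        if text.lower() in aliases:
            return aliases[text.lower()]
        raise ValueError(f"unknown chemistry {value!r} (expected PMO or 2OMe)")


def normalize_sequence(seq: str) -> str:
    """Uppercase, strip whitespace, and map T to U (RNA alphabet)."""
    cleaned = "".join(str(seq).split()).upper().replace("T", "U")
    bad = set(cleaned) - VALID_BASES
    if bad:
        pos = next(i for i, c in enumerate(cleaned) if c in bad)
        raise ValueError(
            f"invalid base {cleaned[pos]!r} at position {pos + 1} in sequence {seq!r}"
        )
    if not cleaned:
        raise ValueError("empty sequence")
    return cleaned


@dataclass(frozen=True)
class AsoRecord:
    """One ASO and one experimental skipping measurement.

    Coordinates are 1-based inclusive positions of the complementary target
    site on the exon; ``target_end - target_start + 1`` must equal the ASO
    length when both are given.
    """

    aso_sequence: str
    chemistry: Chemistry
    concentration_uM: float | None
    efficacy_pct: float
    gene: str = ""
    species: str = ""
    target_exon: int | None = None
    target_start: int | None = None
    target_end: int | None = None
    efficacy_is_absolute: bool = True
    efficacy_is_ec50: bool = False
    is_sequential: bool = True
    cell_type: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "aso_sequence", normalize_sequence(self.aso_sequence))
        object.__setattr__(self, "chemistry", Chemistry.parse(self.chemistry))
        # None = concentration not reported (legal to store, excluded from training)
        if self.concentration_uM is not None and not self.concentration_uM > 0:
            raise ValueError(f"concentration_uM must be > 0, got {self.concentration_uM}")
        if not 0.0 <= self.efficacy_pct <= 100.0:
            raise ValueError(f"efficacy_pct must lie in [0, 100], got {self.efficacy_pct}")
        if self.target_exon is not None and self.target_exon < 1:
            raise ValueError(f"target_exon must be >= 1, got {self.target_exon}")
        if self.target_start is not None and self.target_end is not None:
            span = self.target_end - self.target_start + 1
            if span != len(self.aso_sequence):
                raise ValueError(
                    f"target site span {span} (positions {self.target_start}-"
                    f"{self.target_end}) does not match ASO length {len(self.aso_sequence)}"
                )

    @property
    def normalized_sequence(self) -> str:
        return self.aso_sequence


@dataclass
class RecordSet:
    """Ordered collection of records plus a parse report."""

    records: list[AsoRecord]
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[AsoRecord]:
        return iter(self.records)

    def __getitem__(self, idx: int) -> AsoRecord:
        return self.records[idx]

    @property
    def rejected(self) -> list[tuple[int, str]]:
        return self.provenance.get("rejected", [])


def _parse_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    if pd.isna(value):
        raise ValueError("missing boolean value")
    text = str(value).strip().lower()
    if text in {"true", "1", "yes", "y", "t", "1.0"}:
        return True
    if text in {"false", "0", "no", "n", "f", "0.0"}:
        return False
    raise ValueError(f"cannot interpret {value!r} as boolean")


def _row_to_record(row: Mapping) -> AsoRecord:
    def opt_int(key):
        v = row.get(key)
        if v is None or (isinstance(v, float) and pd.isna(v)) or v == "":
            return None
        return int(float(v))

    def opt_bool(key, default):
        v = row.get(key)
        if v is None or (isinstance(v, float) and pd.isna(v)) or v == "":
            return default
        return _parse_bool(v)

    def opt_str(key):
        v = row.get(key)
        if v is None or (isinstance(v, float) and pd.isna(v)):
            return ""
        return str(v)

    conc = row["concentration_uM"]
    return AsoRecord(
        aso_sequence=row["aso_sequence"],
        chemistry=row["chemistry"],
        concentration_uM=None if pd.isna(conc) else float(conc),
        efficacy_pct=float(row["efficacy_pct"]),
        gene=opt_str("gene"),
        species=opt_str("species"),
        target_exon=opt_int("target_exon"),
        target_start=opt_int("target_start"),
        target_end=opt_int("target_end"),
        efficacy_is_absolute=opt_bool("efficacy_is_absolute", True),
        efficacy_is_ec50=opt_bool("efficacy_is_ec50", False),
        is_sequential=opt_bool("is_sequential", True),
        cell_type=opt_str("cell_type"),
        source=opt_str("source"),
    )


def read_records(
    path: str | Path,
    format: str | None = None,
    column_map: Mapping[str, str] | None = None,
) -> RecordSet:
    """Read ASO records from a CSV or TSV file.

    Parameters
    ----------
    path
        Input file with a header row.
    format
        ``"csv"`` or ``"tsv"``; inferred from the suffix when omitted.
    column_map
        Optional mapping from canonical field name to the header used in the
        source file, for ingesting third-party tables without renaming.

    Malformed rows (invalid bases, out-of-range efficacy, inconsistent
    coordinates, ...) are rejected individually and reported in
    ``provenance["rejected"]``; missing mandatory columns are a hard error.
    """
    path = Path(path)
    if format is None:
        format = "tsv" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else "csv"
    sep = "\t" if format == "tsv" else ","
    frame = pd.read_csv(path, sep=sep, dtype=object)
    if column_map:
        frame = frame.rename(columns={v: k for k, v in column_map.items()})
    missing = [c for c in MANDATORY_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"mandatory column(s) missing from {path.name}: {', '.join(missing)}")

    records: list[AsoRecord] = []
    rejected: list[tuple[int, str]] = []
    for idx, row in frame.iterrows():
        try:
            records.append(_row_to_record(row))
        except (ValueError, TypeError, KeyError) as exc:
            rejected.append((int(idx) + 2, str(exc)))  # +2: header + 1-based
            logger.warning("rejected row %d of %s: %s", int(idx) + 2, path.name, exc)
    return RecordSet(
        records=records,
        provenance={
            "path": str(path),
            "rows_parsed": int(len(frame)),
            "rejected": rejected,
        },
    )


def write_records(rs: RecordSet, path: str | Path, format: str | None = None) -> None:
    """Write records using the canonical column set (round-trips with
    :func:`read_records`)."""
    path = Path(path)
    if format is None:
        format = "tsv" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else "csv"
    rows = []
    for r in rs:
        rows.append(
            {
                "aso_sequence": r.aso_sequence,
                "chemistry": r.chemistry.value,
                "gene": r.gene,
                "species": r.species,
                "target_exon": r.target_exon,
                "target_start": r.target_start,
                "target_end": r.target_end,
                "concentration_uM": r.concentration_uM,
                "efficacy_pct": r.efficacy_pct,
                "efficacy_is_absolute": r.efficacy_is_absolute,
                "efficacy_is_ec50": r.efficacy_is_ec50,
                "is_sequential": r.is_sequential,
                "cell_type": r.cell_type,
                "source": r.source,
            }
        )
    pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS)).to_csv(
        path, sep="\t" if format == "tsv" else ",", index=False
    )


def filter_for_training(
    rs: RecordSet,
    chemistry: Chemistry | str,
    cell_line: str = DEFAULT_CELL_LINE,
) -> RecordSet:
    """Apply the training-data inclusion criteria for one chemistry.

    A record is kept only if all of the following hold:

    1. the skipping efficacy is an absolute numerical value;
    2. the ASO concentration is given (non-null and positive);
    3. the experiment used the reference cell line (default RD,
       rhabdomyosarcoma), matched case-insensitively;
    4. the efficacy is not an EC50 value;
    5. the ASO is sequential (a single contiguous target site, not
       dual-targeting);

    and the record's chemistry equals ``chemistry``. Order is preserved and
    the operation is idempotent.
    """
    chem = Chemistry.parse(chemistry)
    kept = [
        r
        for r in rs
        if r.chemistry is chem
        and r.efficacy_is_absolute
        and r.concentration_uM is not None
        and r.concentration_uM > 0
        and r.cell_type.strip().lower() == cell_line.strip().lower()
        and not r.efficacy_is_ec50
        and r.is_sequential
    ]
    return RecordSet(
        records=kept,
        provenance={
            **rs.provenance,
            "filter": {
                "chemistry": chem.value,
                "cell_line": cell_line,
                "n_in": len(rs),
                "n_kept": len(kept),
            },
        },
    )


def group_by_sequence(rs: RecordSet | Iterable[AsoRecord]) -> dict[str, list[AsoRecord]]:
    """Partition records by normalised (uppercase, U/T-merged) ASO sequence.

    Replicate measurements of one ASO — at any concentration — share a group;
    grouping is the unit of every train/validation/test split so that no
    sequence ever appears on both sides of a split.
    """
    groups: dict[str, list[AsoRecord]] = {}
    for r in rs:
        groups.setdefault(r.normalized_sequence, []).append(r)
    return groups
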