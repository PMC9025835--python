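"""Reading and standardizing miRNA target-prediction database exports.

Five prediction resources are supported out of the box, in two families:

* *binary* databases (miRWalk, TargetScan) list a miRNA–gene pair either as
  predicted or not; the listing is converted to a numeric evaluation of 1
  (predicted) or 0 (explicitly not predicted).
* *numeric* databases (DIANA microT, miRDB, miRmap) attach a native score to
  each pair.  The score is mapped onto a common scale by a linear transform
  ``evaluation = raw × scale_factor + offset``: miRDB and miRmap scores live
  on a 0–100 scale and are rescaled by 0.01, DIANA microT scores are already
  in 0–1, and all three receive a +0.5 offset to correct systematic
  differences between resources, so a present entry evaluates in [0.5, 1.5].

The standardized unit of data is the :class:`InteractionRecord`: a
4-dimensional vector (miRNA identifier, gene symbol, evaluation, database
name).  An absent pair contributes nothing — in particular the +0.5 offset
applies only to entries actually listed by an offset database.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import pandas as pd
import yaml

logger = logging.getLogger("mirank")

#: column names of the standardized record table
RECORD_COLUMNS = ["mirna_key", "gene_symbol", "evaluation", "database_name"]

#: category labels accepted in binary-mode score cells
_PREDICTED_LABELS = {"predicted", "1", "yes", "true"}
_NOT_PREDICTED_LABELS = {"not_predicted", "not predicted", "0", "no", "false"}


class IngestError(ValueError):
    """Fatal ingest problem: missing file/column or a dialect mismatch."""


@dataclass(frozen=True)
class RawDatabaseEntry:
    """One row of a database export, prior to standardization."""

    mirna_name: str
    gene_symbol: str
    raw_value: str | float
    database_name: str


@dataclass(frozen=True)
class DatabaseDialect:
    """How to parse and rescale one database's export format.

    ``value_mode`` is ``"binary"`` (categorical predicted / not-predicted)
    or ``"numeric"`` (native score rescaled by ``scale_factor`` and shifted
    by ``offset``).  ``native_range`` bounds the raw numeric scores the
    database can legitimately emit; out-of-range values are rejected rather
    than rescaled.
    """

    database_name: str
    value_mode: str  # "binary" | "numeric"
    scale_factor: float = 1.0
    offset: float = 0.0
    column_map: dict = field(
        default_factory=lambda: {"mirna": "mirna", "gene": "gene", "score": "score"}
    )
    delimiter: str = "\t"
    native_range: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self):
        if self.value_mode not in ("binary", "numeric"):
            raise IngestError(f"unknown value_mode {self.value_mode!r}")
        if self.value_mode == "binary" and (self.scale_factor != 1 or self.offset != 0):
            raise IngestError("binary dialects must have scale_factor 1 and offset 0")


def default_dialects() -> dict[str, DatabaseDialect]:
    """The five stock dialects keyed by database name.

    DIANA microT scores are native 0–1 (scale 1, offset 0.5); miRDB and
    miRmap are native 0–100 (scale 0.01, offset 0.5); miRWalk and
    TargetScan are binary.
    """
    return {
        "diana_microt": DatabaseDialect(
            "diana_microt", "numeric", scale_factor=1.0, offset=0.5,
            native_range=(0.0, 1.0),
        ),
        "mirdb": DatabaseDialect(
            "mirdb", "numeric", scale_factor=0.01, offset=0.5,
            native_range=(0.0, 100.0),
        ),
        "mirmap": DatabaseDialect(
            "mirmap", "numeric", scale_factor=0.01, offset=0.5,
            native_range=(0.0, 100.0),
        ),
        "mirwalk": DatabaseDialect("mirwalk", "binary"),
        "targetscan": DatabaseDialect("targetscan", "binary"),
    }


def load_dialects(path) -> dict[str, DatabaseDialect]:
    """Load dialect definitions from a YAML config, merged over the defaults.

    The file maps database names to dialect fields; any field omitted falls
    back to that database's stock dialect (or the dataclass default for a
    new database).
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    dialects = default_dialects()
    for name, spec in raw.items():
        spec = dict(spec or {})
        if "native_range" in spec:
            spec["native_range"] = tuple(spec["native_range"])
        base = dialects.get(name, DatabaseDialect(name, "binary"))
        dialects[name] = replace(base, database_name=name, **spec)
    return dialects


# ---------------------------------------------------------------------------
# reading

def _parse_score_cell(cell, mode: str):
    """Return the parsed score or None when the cell is unparseable.

    Decimal commas are deliberately not coerced: a locale-mismatched export
    should fail the >50%-unparseable check, not be silently misread.
    """
    if cell is None or (isinstance(cell, float) and pd.isna(cell)):
        return None
    if mode == "binary":
        label = str(cell).strip().lower()
        if label in _PREDICTED_LABELS or label in _NOT_PREDICTED_LABELS:
            return label
        return None
    text = str(cell).strip()
    if not text or "," in text:
        return None
    try:
        value = float(text)
    except ValueError:
        return None
    if not pd.notna(value) or value != value or value in (float("inf"), float("-inf")):
        return None
    if value < 0:
        return None
    return value


def read_database_export(path, dialect: DatabaseDialect) -> list[RawDatabaseEntry]:
    """Parse one export file into raw entries under the given dialect.

    Rows whose score cell cannot be parsed are skipped and counted; more
    than 50% unparseable rows is treated as a dialect mismatch and is fatal,
    as are a missing file or missing mandatory columns.
    """
    try:
        frame = pd.read_csv(path, sep=dialect.delimiter, dtype=str,
                            keep_default_na=False)
    except FileNotFoundError:
        raise IngestError(f"export file not found: {path}")
    cmap = dialect.column_map
    for role in ("mirna", "gene", "score"):
        if cmap[role] not in frame.columns:
            raise IngestError(
                f"{dialect.database_name}: mandatory column {cmap[role]!r} "
                f"missing from {path}"
            )
    entries: list[RawDatabaseEntry] = []
    skipped = 0
    for _, row in frame.iterrows():
        gene = str(row[cmap["gene"]]).strip()
        mirna = str(row[cmap["mirna"]]).strip()
        parsed = _parse_score_cell(row[cmap["score"]], dialect.value_mode)
        if not gene or not mirna or parsed is None:
            skipped += 1
            continue
        entries.append(RawDatabaseEntry(mirna, gene, parsed, dialect.database_name))
    total = len(frame)
    logger.info("%s: read %d rows, kept %d, skipped %d",
                dialect.database_name, total, len(entries), skipped)
    if total and skipped > total / 2:
        raise IngestError(
            f"{dialect.database_name}: {skipped}/{total} rows unparseable — "
            "likely dialect mismatch"
        )
    return entries


# ---------------------------------------------------------------------------
# standardization

def standardize_entry(entry: RawDatabaseEntry, dialect: DatabaseDialect) -> dict:
    """Map one raw entry onto the common evaluation scale.

    Binary mode: predicted → 1.0, explicit non-prediction → 0.0 (retained,
    so presence and absence stay distinguishable downstream).  Numeric
    mode: ``raw × scale_factor + offset`` after a native-range check.
    """
    if entry.database_name != dialect.database_name:
        raise IngestError(
            f"entry from {entry.database_name!r} standardized with "
            f"{dialect.database_name!r} dialect"
        )
    if dialect.value_mode == "binary":
        label = str(entry.raw_value).strip().lower()
        if label in _PREDICTED_LABELS:
            evaluation = 1.0
        elif label in _NOT_PREDICTED_LABELS:
            evaluation = 0.0
        else:
            raise IngestError(f"unrecognized binary category {entry.raw_value!r}")
    else:
        raw = float(entry.raw_value)
        lo, hi = dialect.native_range
        if not lo <= raw <= hi:
            raise IngestError(
                f"{dialect.database_name}: raw score {raw} outside native "
                f"range [{lo}, {hi}]"
            )
        evaluation = raw * dialect.scale_factor + dialect.offset
    return {
        "mirna_key": entry.mirna_name,
        "gene_symbol": entry.gene_symbol.upper(),
        "evaluation": evaluation,
        "database_name": entry.database_name,
    }


def standardize_records(entries, dialect: DatabaseDialect) -> pd.DataFrame:
    """Standardize a collection of raw entries into a record table."""
    rows = [standardize_entry(e, dialect) for e in entries]
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def deduplicate_records(records: pd.DataFrame) -> pd.DataFrame:
    """Collapse duplicate (miRNA, gene, database) rows to the max evaluation.

    Databases may list several binding sites for one pair; the evaluation
    encodes prediction strength, not site count, so the strongest entry
    wins.  The number of collapsed rows is logged.
    """
    if records.empty:
        return records.copy()
    keys = ["mirna_key", "gene_symbol", "database_name"]
    out = (records.groupby(keys, as_index=False, sort=True)["evaluation"].max()
           [RECORD_COLUMNS])
    collapsed = len(records) - len(out)
    if collapsed:
        logger.info("deduplicate: collapsed %d duplicate rows", collapsed)
    return out


# ---------------------------------------------------------------------------
# record-table I/O

def write_records(records: pd.DataFrame, path) -> None:
    records.to_csv(path, sep="\t", index=False)


def read_records(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    missing = set(RECORD_COLUMNS) - set(frame.columns)
    if missing:
        raise IngestError(f"record table missing columns: {sorted(missing)}")
    return frame[RECORD_COLUMNS]
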