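"""Coded verb-token tables: reading, validation, writing, summaries.

The ingestion boundary is a flat CSV/TSV table with one row per verb
token (or per pre-aggregated token count): dyad, session index, child
age in days, speaker stratum (CS = child speech, CDS = child-directed
speech), root, binyan, temporal category and agreement features.  Rows
are validated against the closed morphological inventories before any
network is built.
"""

from __future__ import annotations

import dataclasses
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from . import inventory as inv

#: Canonical column order of the on-disk schema.
COLUMNS: tuple[str, ...] = (
    "dyad_id",
    "session_index",
    "age_days",
    "speaker",
    "root",
    "binyan",
    "temporal",
    "person",
    "number",
    "gender",
    "count",
)

SPEAKERS: tuple[str, str] = ("CS", "CDS")

_ROOT_RE = re.compile(r"^[a-zA-Z?]{1,2}(-[a-zA-Z?]{1,2}){1,3}$")

#: Valid (binyan, temporal, person, number, gender) keys, as strings.
_VALID_AGREEMENT: frozenset[tuple[str, str, str, str, str]] = frozenset(
    (
        ip.pattern.binyan.value,
        ip.pattern.temporal.value,
        str(ip.agreement.person) if ip.agreement.person else "",
        ip.agreement.number or "",
        ip.agreement.gender or "",
    )
    for ip in inv.full_inflection_inventory()
)


class CorpusValidationError(ValueError):
    """Raised when a coded verb-token table violates the schema."""


@dataclass
class CorpusTable:
    """A validated verb-token table plus free-text provenance."""

    df: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def dyads(self) -> list[str]:
        return sorted(self.df["dyad_id"].unique())


@dataclass
class CorpusSummary:
    """Per-speaker corpus totals in the style of a corpus-details table."""

    dyad_id: str
    n_sessions: int
    age_range: tuple[int, int]
    verb_tokens: dict[str, int]
    verb_types: dict[str, int]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for speaker in SPEAKERS:
            rows.append(
                {
                    "dyad_id": self.dyad_id,
                    "speaker": speaker,
                    "n_sessions": self.n_sessions,
                    "age_start_days": self.age_range[0],
                    "age_end_days": self.age_range[1],
                    "verb_tokens": self.verb_tokens.get(speaker, 0),
                    "verb_types": self.verb_types.get(speaker, 0),
                }
            )
        return pd.DataFrame(rows)


def _normalize(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    for col in ("person", "number", "gender"):
        if col not in df.columns:
            df[col] = ""
        df[col] = df[col].fillna("").astype(str).str.strip()
        df[col] = df[col].replace({"nan": "", "None": "", "<NA>": ""})
    df["person"] = df["person"].str.replace(r"\.0$", "", regex=True)
    if "count" not in df.columns:
        df["count"] = 1
    for col in ("dyad_id", "speaker", "root", "binyan", "temporal"):
        df[col] = df[col].astype(str).str.strip()
    df["root"] = df["root"].map(_romanize_root)
    return df[list(COLUMNS)]


def _romanize_root(label: str) -> str:
    for glyph, ascii_ in inv.ROMANIZATION_MAP.items():
        label = label.replace(glyph, ascii_)
    return label


def validate_table(df: pd.DataFrame, lenient: bool = False) -> tuple[pd.DataFrame, list[str]]:
    """Validate a raw token table; return (valid rows, error messages).

    Errors name the offending 0-based row and the violated rule.  With
    ``lenient=False`` any error raises :class:`CorpusValidationError`.
    """
    missing = [c for c in COLUMNS if c not in df.columns and c not in ("person", "number", "gender", "count")]
    if missing:
        raise CorpusValidationError(f"missing required columns: {missing}")
    df = _normalize(df)

    errors: list[str] = []
    bad = pd.Series(False, index=df.index)

    def flag(mask: pd.Series, rule: str) -> None:
        nonlocal bad
        for idx in df.index[mask & ~bad]:
            errors.append(f"row {idx}: {rule}")
        bad |= mask

    sess = pd.to_numeric(df["session_index"], errors="coerce")
    age = pd.to_numeric(df["age_days"], errors="coerce")
    cnt = pd.to_numeric(df["count"], errors="coerce")
    flag(sess.isna() | (sess < 1) | (sess != sess.round()), "session_index must be a positive integer")
    flag(age.isna() | (age < 1), "age_days must be a positive integer")
    flag(cnt.isna() | (cnt < 1), "count must be a positive integer")
    flag(~df["speaker"].isin(SPEAKERS), "speaker must be CS or CDS")
    flag(~df["root"].str.match(_ROOT_RE), "root is not a canonical hyphen-joined radical string")
    key = list(zip(df["binyan"], df["temporal"], df["person"], df["number"], df["gender"]))
    flag(
        pd.Series([k not in _VALID_AGREEMENT for k in key], index=df.index),
        "binyan/temporal/agreement combination is not a valid inflected-pattern category",
    )

    ok = df[~bad].copy()
    ok["session_index"] = sess[~bad].astype(int)
    ok["age_days"] = age[~bad].astype(int)
    ok["count"] = cnt[~bad].astype(int)

    # session_index must be strictly ordered by age within each dyad
    for dyad, grp in ok.groupby("dyad_id"):
        ages = grp.groupby("session_index")["age_days"].agg(["min", "max"]).sort_index()
        if (ages["min"] != ages["max"]).any():
            errors.append(f"dyad {dyad}: a session_index maps to more than one age_days")
            bad |= df["dyad_id"] == dyad
        elif not ages["min"].is_monotonic_increasing:
            errors.append(f"dyad {dyad}: session_index not ordered by age_days")
            bad |= df["dyad_id"] == dyad
    ok = ok[~bad.reindex(ok.index, fill_value=False)]

    if errors and not lenient:
        raise CorpusValidationError(
            f"{len(errors)} invalid rows/rules: " + "; ".join(errors[:20])
        )
    return ok.reset_index(drop=True), errors


def from_records(records: Iterable[Mapping], provenance: Optional[dict] = None) -> CorpusTable:
    """Build a validated :class:`CorpusTable` from dict-like records.

    Missing agreement fields default to unexpressed; ``count`` defaults
    to 1.
    """
    df = pd.DataFrame(list(records))
    defaults = {"person": "", "number": "", "gender": "", "count": 1}
    for col, val in defaults.items():
        if col not in df.columns:
            df[col] = val
    ok, _ = validate_table(df, lenient=False)
    if ok.empty:
        raise CorpusValidationError("corpus table is empty")
    return CorpusTable(ok, provenance or {})


def read_session_tokens(
    path, dialect: Optional[str] = None, lenient: bool = False
) -> CorpusTable:
    """Read a coded verb-token CSV/TSV and validate every row.

    ``dialect`` is "csv" or "tsv"; inferred from the extension when
    omitted.  In lenient mode invalid rows are dropped and reported in
    ``provenance["validation_errors"]``; otherwise any invalid row
    raises.
    """
    path = Path(path)
    if dialect is None:
        dialect = "tsv" if path.suffix.lower() in (".tsv", ".tab") else "csv"
    sep = "\t" if dialect == "tsv" else ","
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    ok, errors = validate_table(raw, lenient=lenient)
    if ok.empty:
        raise CorpusValidationError(f"{path}: no valid rows")
    return CorpusTable(ok, {"source": str(path), "validation_errors": errors})


def write_session_tokens(table: CorpusTable, path, dialect: Optional[str] = None) -> None:
    """Write the canonical CSV/TSV dialect (round-trips through read)."""
    path = Path(path)
    if dialect is None:
        dialect = "tsv" if path.suffix.lower() in (".tsv", ".tab") else "csv"
    sep = "\t" if dialect == "tsv" else ","
    table.df[list(COLUMNS)].to_csv(path, sep=sep, index=False)


def summarize_corpus(table: CorpusTable, dyad_id: Optional[str] = None) -> CorpusSummary:
    """Per-speaker verb tokens, verb types (lemmas) and session counts.

    A lemma is a distinct (root, binyan) pair: the same root in two
    binyanim counts as two lemmas.
    """
    df = table.df
    if dyad_id is not None:
        df = df[df["dyad_id"] == dyad_id]
        if df.empty:
            raise CorpusValidationError(f"dyad {dyad_id!r} not present")
    else:
        dyads = sorted(df["dyad_id"].unique())
        if len(dyads) != 1:
            raise CorpusValidationError(f"pass dyad_id to summarize one of {dyads}")
        dyad_id = dyads[0]
    tokens = {s: 0 for s in SPEAKERS}
    types = {s: 0 for s in SPEAKERS}
    for speaker, grp in df.groupby("speaker"):
        tokens[str(speaker)] = int(grp["count"].sum())
        types[str(speaker)] = int(grp[["root", "binyan"]].drop_duplicates().shape[0])
    return CorpusSummary(
        dyad_id=dyad_id,
        n_sessions=int(df["session_index"].nunique()),
        age_range=(int(df["age_days"].min()), int(df["age_days"].max())),
        verb_tokens=tokens,
        verb_types=types,
    )
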