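"""Data model, FASTA/TSV I/O, configuration and logging.

Internal coordinates are 0-based half-open; everything user-facing is
1-based inclusive, matching the protein-residue convention (the canonical
motif occupies residues 17-27 of the reference thioredoxin, i.e. the
half-open span [16, 27)).
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")

TAXA = ("plant", "animal", "fungus", "other", "unknown")
LOCALISATIONS = ("secreted", "cytoplasmic", "mitochondrial", "membrane", "none")

logger = logging.getLogger("nbetascan")


def configure_logging(verbose: bool = False) -> None:
    """Send log records to stderr so result streams stay clean."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(logging.DEBUG if verbose else logging.WARNING)


class FastaParseError(ValueError):
    """Raised on malformed FASTA input; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(f"{message}" + (f" (line {line})" if line else ""))


class MetadataError(ValueError):
    pass


@dataclass(frozen=True)
class SequenceRegion:
    """Half-open residue span, 0-based."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid region [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def to_one_based(self) -> tuple[int, int]:
        """1-based inclusive coordinates for reports."""
        return self.start + 1, self.end

    @classmethod
    def from_one_based(cls, first: int, last: int) -> "SequenceRegion":
        return cls(first - 1, last)


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence plus optional localisation annotation.

    ``annotation_score`` follows the UniProtKB 1-5 evidence convention,
    with 0 meaning no annotation is attached.
    """

    id: str
    sequence: str
    description: str = ""
    taxon: str = "unknown"
    annotated_localisation: str = "none"
    annotation_score: int = 0

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - ALPHABET
        if bad:
            raise ValueError(
                f"record {self.id!r}: illegal residue(s) {sorted(bad)!r}"
            )
        if self.taxon not in TAXA:
            raise ValueError(f"record {self.id!r}: unknown taxon {self.taxon!r}")
        if self.annotated_localisation not in LOCALISATIONS:
            raise ValueError(
                f"record {self.id!r}: unknown localisation "
                f"{self.annotated_localisation!r}"
            )
        if not 0 <= int(self.annotation_score) <= 5:
            raise ValueError(
                f"record {self.id!r}: annotation_score {self.annotation_score} "
                "outside 0-5"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def _locate_illegal_residue(path: Path) -> int | None:
    """Find the 1-based line number of the first illegal residue character."""
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(">"):
                continue
            if set(line.upper()) - ALPHABET:
                return lineno
    return None


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a multi-record FASTA file into :class:`ProteinRecord` objects.

    Sequences are upper-cased; wrapped lines are concatenated. Taxon and
    annotation fields default to unknown/none/0 (use
    :func:`attach_metadata` to fill them from a sidecar table).
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise FastaParseError("FASTA header without an identifier")
        seq = str(rec.seq).upper()
        if not seq:
            raise FastaParseError(f"record {rec.id!r} has an empty sequence")
        if set(seq) - ALPHABET:
            raise FastaParseError(
                f"illegal residue in record {rec.id!r}",
                line=_locate_illegal_residue(path),
            )
        records.append(ProteinRecord(id=rec.id, sequence=seq, description=rec.description))
    if not records:
        raise FastaParseError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    seqrecords = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description or "")
        for r in records
    ]
    SeqIO.write(seqrecords, str(path), "fasta")


def attach_metadata(
    records: Sequence[ProteinRecord], table: str | Path | pd.DataFrame
) -> list[ProteinRecord]:
    """Join a sidecar annotation table onto FASTA records by id.

    The table (TSV path or DataFrame) must carry columns
    ``id, taxon, localisation, score``. Matched records get their
    annotation fields replaced; unmatched records pass through unchanged
    and unmatched table rows are logged.
    """
    if isinstance(table, pd.DataFrame):
        meta = table.copy()
    else:
        meta = pd.read_csv(table, sep="\t", dtype={"id": str})
    required = {"id", "taxon", "localisation", "score"}
    missing = required - set(meta.columns)
    if missing:
        raise MetadataError(f"metadata table missing column(s): {sorted(missing)}")
    if meta["id"].duplicated().any():
        dupes = meta.loc[meta["id"].duplicated(), "id"].tolist()
        raise MetadataError(f"duplicate id(s) in metadata table: {dupes}")
    bad_scores = meta.loc[~meta["score"].astype(int).between(0, 5), "id"].tolist()
    if bad_scores:
        raise MetadataError(f"score outside 0-5 for id(s): {bad_scores}")

    by_id = meta.set_index("id")
    out: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in records:
        if rec.id in by_id.index:
            row = by_id.loc[rec.id]
            seen.add(rec.id)
            out.append(
                replace(
                    rec,
                    taxon=str(row["taxon"]),
                    annotated_localisation=str(row["localisation"]),
                    annotation_score=int(row["score"]),
                )
            )
        else:
            out.append(rec)
    unmatched = sorted(set(by_id.index) - seen)
    if unmatched:
        logger.warning("metadata rows with no matching FASTA record: %s", unmatched)
    return out


def write_report(
    frame: pd.DataFrame, path: str | Path, format: str = "tsv"
) -> None:
    """Write a result table as TSV or JSON with a deterministic column order.

    The caller is responsible for having already converted coordinates to
    1-based inclusive (see :func:`matches_to_frame` in ``motif_scan``).
    An empty frame yields a header-only file.
    """
    path = Path(path)
    if format == "tsv":
        frame.to_csv(path, sep="\t", index=False)
    elif format == "json":
        path.write_text(json.dumps(frame.to_dict(orient="records"), indent=1) + "\n")
    else:
        raise ValueError(f"unknown report format {format!r}")


def read_report(path: str | Path, format: str = "tsv") -> pd.DataFrame:
    path = Path(path)
    if format == "tsv":
        return pd.read_csv(path, sep="\t")
    if format == "json":
        return pd.DataFrame(json.loads(path.read_text()))
    raise ValueError(f"unknown report format {format!r}")


# -- configuration -----------------------------------------------------------

DEFAULT_CONFIG: dict = {
    "min_score": 8,          # strict: all 8 core positions must match
    "relaxed_min_score": 6,
    "allow_inverted": True,
    "allow_core_only": False,
    "taxon_mode": "plant",
}


def load_config(path: str | Path | None = None) -> dict:
    """Load a YAML-or-JSON config file, overlaying the defaults."""
    cfg = dict(DEFAULT_CONFIG)
    if path is None:
        return cfg
    text = Path(path).read_text()
    data = yaml.safe_load(text)  # YAML is a superset of JSON
    if data is None:
        return cfg
    if not isinstance(data, dict):
        raise ValueError("config file must contain a mapping")
    unknown = set(data) - set(cfg)
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    cfg.update(data)
    return cfg
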