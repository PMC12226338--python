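"""FASTA/FASTQ/TSV input-output shared across the pipeline stages.

Pools travel as FASTA (record id optionally encoding class, cycle and
weight as ``id|class|cycle|weight``) with an optional sidecar TSV carrying
the same metadata plus lane intensities.  DNA-alphabet files are accepted
and T-normalised to U; any other non-ACGU character is rejected.  Tables
are tab-separated UTF-8 with '.' decimals; configs are JSON or YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .pools import PoolRecord, RibozymeReference, SequencePool
from .seqtools import AlphabetError, normalize_rna, validate_rna

__all__ = [
    "PoolParseError",
    "read_pool",
    "read_reference",
    "write_pool",
    "read_pool_tsv",
    "read_table",
    "write_table",
    "load_config_file",
]


class PoolParseError(ValueError):
    """A FASTA/FASTQ record failed validation; names the record."""


def _parse_dialect_id(raw_id: str):
    """Split an ``id|class|cycle|weight`` identifier; plain ids pass through."""
    parts = raw_id.split("|")
    if len(parts) == 4:
        ident, label, cycle_s, weight_s = parts
        try:
            return ident, (label or None), int(cycle_s), float(weight_s)
        except ValueError:
            pass
    return raw_id, None, 0, 1.0


def read_pool(path, fmt: str | None = None) -> SequencePool:
    """Read a pool from FASTA (or FASTQ; qualities are ignored).

    Record order is preserved.  T bases are normalised to U; other
    non-ACGU characters raise :class:`PoolParseError` naming the offending
    record.  Ids in the ``id|class|cycle|weight`` dialect populate the
    corresponding record fields; plain ids default to weight 1, cycle 0.
    """
    path = Path(path)
    if fmt is None:
        fmt = "fastq" if path.suffix.lower() in {".fastq", ".fq"} else "fasta"
    records = []
    for i, rec in enumerate(SeqIO.parse(str(path), fmt), start=1):
        seq = normalize_rna(str(rec.seq))
        try:
            validate_rna(seq, name=f"record {i} ({rec.id!r})")
        except AlphabetError as exc:
            raise PoolParseError(f"{path.name}: {exc}") from exc
        ident, label, cycle, weight = _parse_dialect_id(rec.id)
        records.append(
            PoolRecord(
                id=ident, sequence=seq, weight=weight, cycle=cycle, label=label
            )
        )
    if not records:
        raise PoolParseError(f"{path.name}: no records parsed")
    return SequencePool(records=records)


def read_reference(path) -> RibozymeReference:
    """Read ribozyme (+)-strand subunits from FASTA, keyed by record id."""
    path = Path(path)
    subunits: dict[str, str] = {}
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        seq = normalize_rna(str(rec.seq))
        try:
            validate_rna(seq, name=f"record {i} ({rec.id!r})")
        except AlphabetError as exc:
            raise PoolParseError(f"{path.name}: {exc}") from exc
        subunits[rec.id] = seq
    if not subunits:
        raise PoolParseError(f"{path.name}: no records parsed")
    return RibozymeReference(subunits=subunits)


def write_pool(pool: SequencePool, fasta_path, tsv_path=None) -> None:
    """Write a pool as dialect FASTA, optionally with a sidecar TSV.

    The FASTA id encodes ``id|class|cycle|weight``; the sidecar TSV adds
    the lane intensity (columns: id, sequence, class_truth, cycle, weight,
    lane_intensity).
    """
    seq_records = [
        SeqRecord(
            Seq(rec.sequence),
            id=f"{rec.id}|{rec.label or ''}|{rec.cycle}|{rec.weight:g}",
            description="",
        )
        for rec in pool
    ]
    SeqIO.write(seq_records, str(fasta_path), "fasta")
    if tsv_path is not None:
        write_table(pool.to_frame(), tsv_path)


def read_pool_tsv(path) -> SequencePool:
    """Read a pool from the sidecar TSV written by :func:`write_pool`."""
    df = pd.read_csv(path, sep="\t")
    records = []
    for row in df.itertuples(index=False):
        label = getattr(row, "class_truth", None)
        records.append(
            PoolRecord(
                id=str(row.id),
                sequence=normalize_rna(str(row.sequence)),
                weight=float(getattr(row, "weight", 1.0)),
                cycle=int(getattr(row, "cycle", 0)),
                lane_intensity=float(getattr(row, "lane_intensity", 1.0)),
                label=None if pd.isna(label) else str(label),
            )
        )
    return SequencePool(records=records)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def load_config_file(path) -> dict:
    """Load a JSON or YAML config into a plain dict."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)
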