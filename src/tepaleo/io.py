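"""FASTA and table I/O helpers (Biopython-backed, gzip-aware)."""

from __future__ import annotations

import gzip
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def _open_maybe_gzip(path, mode="rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path) -> dict[str, str]:
    """Read a (possibly gzipped) multi-record FASTA into {id: sequence}."""
    with _open_maybe_gzip(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(records: dict[str, str] | list[tuple[str, str]], path) -> None:
    """Write records wrapped at 80 columns."""
    if isinstance(records, dict):
        records = list(records.items())
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=80)
        writer.write_file(recs)


def read_flat_config(path) -> dict[str, str]:
    """Flat key=value config file; '#' starts a comment."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, sep, val = line.partition("=")
            if not sep:
                raise ValueError(f"malformed config line: {line!r}")
            out[key.strip()] = val.strip()
    return out


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
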