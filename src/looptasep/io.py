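"""Readers and writers for all external data the tool touches.

FASTA for coding sequences (via Biopython), tab-delimited text for codon
rate tables, per-transcript lifetimes and result tables, JSON for the run
manifest.  All writers round-trip losslessly through their paired readers.
RNA input (U instead of T) is accepted and converted on read.
"""

from __future__ import annotations

import hashlib
import json
import platform
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .rates import RateTable

__all__ = [
    "read_cds_fasta",
    "read_rate_table",
    "read_lifetimes",
    "write_summary_table",
    "read_summary_table",
    "write_manifest",
    "read_manifest",
    "config_hash",
]


def read_cds_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read (id, uppercase DNA sequence) pairs from a FASTA file.

    Duplicate identifiers and empty files are rejected.
    """
    path = Path(path)
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append((rec.id, str(rec.seq).upper().replace("U", "T")))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def read_rate_table(path: str | Path) -> RateTable:
    """Read a codon → decoding rate table from two-column delimited text.

    Columns are (codon, rate in s^-1); tab, comma or whitespace delimited;
    an optional header line is skipped.  Validation (61 sense codons, all
    rates positive, no stop codons) happens in :class:`RateTable`.
    """
    path = Path(path)
    rates: dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", "\t").split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected 'codon rate', got {line!r}")
            codon, rate_s = parts[0], parts[1]
            try:
                rate = float(rate_s)
            except ValueError:
                if lineno == 1:
                    continue  # header
                raise ValueError(f"{path}:{lineno}: non-numeric rate {rate_s!r}")
            if codon in rates:
                raise ValueError(f"{path}:{lineno}: duplicate codon {codon}")
            rates[codon] = rate
    return RateTable(rates)


def read_lifetimes(path: str | Path) -> dict[str, float]:
    """Read per-transcript lifetimes (seconds) from delimited text.

    Two schemas are accepted (detected from the header):

    * ``id  lifetime`` — direct lifetimes;
    * ``id  abundance  transcription_rate`` — lifetime computed as
      abundance / transcription rate (molecules per cell over molecules per
      cell per second).

    Non-positive lifetimes or transcription rates are rejected.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python")
    cols = [c.strip().lower() for c in df.columns]
    df.columns = cols
    id_col = cols[0]
    lt_cols = [c for c in cols if "lifetime" in c]
    ab_cols = [c for c in cols if "abundance" in c]
    tr_cols = [c for c in cols if "transcription" in c or c.endswith("rate")]
    if lt_cols:
        life = df[lt_cols[0]].astype(float)
    elif ab_cols and tr_cols:
        rate = df[tr_cols[0]].astype(float)
        if (rate <= 0).any():
            bad = df[id_col][rate <= 0].iloc[0]
            raise ValueError(f"non-positive transcription rate for {bad!r}")
        life = df[ab_cols[0]].astype(float) / rate
    else:
        raise ValueError(
            f"unknown lifetime schema in {path}: columns {cols!r} "
            "(need 'lifetime' or 'abundance' + 'transcription_rate')"
        )
    if (life <= 0).any():
        bad = df[id_col][life <= 0].iloc[0]
        raise ValueError(f"non-positive lifetime for {bad!r}")
    return dict(zip(df[id_col].astype(str), life.astype(float)))


def write_summary_table(rows: pd.DataFrame | list[dict], path: str | Path) -> None:
    """Write a result table as TSV with a fixed header (lossless round-trip)."""
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False)


def read_summary_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def config_hash(config: dict) -> str:
    """Stable short hash of a JSON-serialisable configuration."""
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def write_manifest(config: dict, path: str | Path) -> dict:
    """Write a JSON run manifest recording config, hash and versions."""
    from . import __version__

    manifest = {
        "config": config,
        "config_hash": config_hash(config),
        "package": "looptasep",
        "version": __version__,
        "python": platform.python_version(),
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return manifest


def read_manifest(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
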