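"""File formats: FASTA, TSV with provenance headers, tag tables, YAML config.

Every table written by the pipeline starts with comment lines carrying the
tool version, a hash of the run configuration and the master seed, so any
output file identifies the run that produced it.  MISSING per-CpG calls are
written as "." and absent table cells as "N/A".
"""

from __future__ import annotations

import hashlib
import io as _io
import json
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
import yaml
from Bio.SeqIO.FastaIO import SimpleFastaParser

from . import __version__
from .demultiplex import TaggedPrimerRecord
from .simulate import Locus

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_tsv",
    "write_tsv",
    "read_tag_table",
    "write_tag_table",
    "read_loci_fasta",
    "write_loci_fasta",
    "load_config",
    "config_hash",
]


def read_fasta(path) -> Iterator[tuple[str, str]]:
    """Stream FASTA records as (id, sequence), one record in memory at a time.

    Multi-line sequences and CRLF endings are handled; a file whose first
    non-blank line is not a header, or a record with an empty sequence,
    raises a ValueError naming the offending record.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    with open(path) as fh:
        pos = fh.tell()
        first = fh.readline()
        while first and not first.strip():
            first = fh.readline()
        if first and not first.startswith(">"):
            raise ValueError(f"{path}: malformed FASTA, expected '>' header, got {first[:30]!r}")
        fh.seek(pos)
        for title, seq in SimpleFastaParser(fh):
            rid = title.split()[0] if title.split() else title
            if not seq:
                raise ValueError(f"{path}: record {rid!r} has an empty sequence")
            yield rid, seq.upper()


def write_fasta(records: Iterable[tuple[str, str]], path, width: int = 70) -> int:
    """Write (id, sequence) records; returns the record count."""
    n = 0
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
            n += 1
    return n


def _header_lines(meta: dict | None) -> str:
    lines = [f"# amplimeth {__version__}"]
    for k, v in (meta or {}).items():
        lines.append(f"# {k}={v}")
    return "\n".join(lines) + "\n"


def write_tsv(table: pd.DataFrame, path, meta: dict | None = None, index: bool = False) -> None:
    """TSV with a comment-line provenance header; NaN cells render 'N/A'."""
    buf = _io.StringIO()
    table.to_csv(buf, sep="\t", index=index, na_rep="N/A")
    with open(path, "w") as fh:
        fh.write(_header_lines(meta))
        fh.write(buf.getvalue())


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", na_values=["N/A"], **kwargs)


def write_tag_table(records: Iterable[TaggedPrimerRecord], path, meta: dict | None = None) -> None:
    df = pd.DataFrame(
        [
            {"sample_id": r.sample_id, "locus": r.locus_name, "tag": r.tag, "primer": r.primer}
            for r in records
        ]
    )
    write_tsv(df, path, meta)


def read_tag_table(path) -> list[TaggedPrimerRecord]:
    df = read_tsv(path)
    return [
        TaggedPrimerRecord(str(r.sample_id), str(r.locus), str(r.tag), str(r.primer))
        for r in df.itertuples()
    ]


def write_loci_fasta(loci: Iterable[Locus], path) -> None:
    """Genomic (unconverted) reference amplicons; the primer extent travels in
    the header so CpG annotation can be rebuilt by scanning for CG."""
    with open(path, "w") as fh:
        for loc in loci:
            fh.write(f">{loc.name} primer_len={loc.primer_len}\n{loc.sequence}\n")


def read_loci_fasta(path, default_primer_len: int = 0) -> list[Locus]:
    loci = []
    with open(path) as fh:
        for title, seq in SimpleFastaParser(fh):
            parts = title.split()
            name = parts[0]
            primer_len = default_primer_len
            for p in parts[1:]:
                if p.startswith("primer_len="):
                    primer_len = int(p.split("=", 1)[1])
            loci.append(Locus.from_sequence(name, seq, primer_len))
    return loci


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    return cfg


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
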