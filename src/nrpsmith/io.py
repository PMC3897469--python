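"""Readers and writers for the package's on-disk formats.

Domain tables are TSV with header ``protein_id  kind  start  end  source``
using 1-based inclusive coordinates on disk (converted to the internal
0-based half-open convention on read).  Protein sequences are standard
FASTA.  Architecture files carry one ``id<TAB>architecture`` pair per line.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .archmodel import (
    ArchitectureError,
    DomainAnnotation,
    DomainToken,
    normalize_token,
    parse_architecture,
)

TABLE_COLUMNS = ["protein_id", "kind", "start", "end", "source"]


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read protein FASTA into an id -> sequence mapping."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise ArchitectureError(f"no FASTA records in {path}")
    return records


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_domain_table(path: str | Path) -> list[DomainAnnotation]:
    """Read a domain table TSV; 1-based inclusive coordinates on disk."""
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "source": str})
    missing = [c for c in TABLE_COLUMNS[:4] if c not in df.columns]
    if missing:
        raise ArchitectureError(f"domain table missing columns {missing}")
    if "source" not in df.columns:
        df["source"] = ""
    anns = []
    for row in df.itertuples(index=False):
        anns.append(
            DomainAnnotation(
                protein_id=row.protein_id,
                kind=normalize_token(row.kind),
                start=int(row.start) - 1,  # to 0-based half-open
                end=int(row.end),
                source="" if pd.isna(row.source) else str(row.source),
            )
        )
    return anns


def write_domain_table(annotations: list[DomainAnnotation], path: str | Path) -> None:
    rows = [
        {
            "protein_id": a.protein_id,
            "kind": str(a.kind),
            "start": a.start + 1,  # to 1-based inclusive
            "end": a.end,
            "source": a.source,
        }
        for a in annotations
    ]
    pd.DataFrame(rows, columns=TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_architectures(path: str | Path) -> list[tuple[str, list[DomainToken]]]:
    """Read ``id<TAB>architecture`` lines into tokenized synthetases."""
    out = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        try:
            ident, arch = line.split("\t", 1)
        except ValueError:
            raise ArchitectureError(
                f"{path}:{lineno}: expected 'id<TAB>architecture'"
            ) from None
        out.append((ident, parse_architecture(arch)))
    if not out:
        raise ArchitectureError(f"no architectures in {path}")
    return out


def read_monomer_predictions(path: str | Path) -> list[list[str]]:
    """One line per module: candidate monomer names separated by ``|``."""
    preds = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        preds.append([c.strip() for c in line.split("|") if c.strip()])
    return preds
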