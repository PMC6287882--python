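"""Readers, writers and run manifests.

TSV is the native dialect; CSV is accepted on read by sniffing the
delimiter.  Malformed numerics are reported with their row and column
rather than coerced.  A run manifest (YAML) echoes the exact command,
configuration, seed and input checksums so any statistical output can
be regenerated byte-for-byte.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .genesets import DifferentialTable


def _sniff_read(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python")


def read_de_table(
    path: str | Path,
    gene_column: str | None = None,
    fc_column: str | None = None,
    fdr_column: str | None = None,
    label: str = "",
) -> DifferentialTable:
    """Read a differential-expression summary table.

    The fold-change column may be linear (``fc``, converted with log2)
    or already log2 (``log2fc``); auto-detected by header name when not
    given explicitly.  A ``fc_column`` whose name contains "log2" is
    treated as log-scale.
    """
    df = _sniff_read(path)
    cols = {c.lower(): c for c in df.columns}

    gene_col = gene_column or cols.get("gene_id") or cols.get("gene")
    if gene_col is None or gene_col not in df.columns:
        raise ValueError(f"{path}: no gene id column found (looked for gene_id/gene)")
    fc_col = fc_column or cols.get("log2fc") or cols.get("fc") or cols.get("fold_change")
    if fc_col is None or fc_col not in df.columns:
        raise ValueError(f"{path}: no fold-change column found (looked for log2fc/fc)")
    fdr_col = fdr_column or cols.get("fdr") or cols.get("padj")
    if fdr_col is None or fdr_col not in df.columns:
        raise ValueError(f"{path}: no FDR column found (looked for fdr/padj)")

    is_log = "log2" in fc_col.lower()
    out = pd.DataFrame({"gene_id": df[gene_col].astype(str)})
    for src, dst in ((fc_col, "log2fc"), (fdr_col, "fdr")):
        vals = pd.to_numeric(df[src], errors="coerce")
        bad = vals.isna() & df[src].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0]) + 2  # 1-based, after header
            raise ValueError(
                f"{path}: non-numeric value {df[src][bad].iloc[0]!r} "
                f"in column {src!r}, line {row}"
            )
        if vals.isna().any():
            row = int(np.flatnonzero(vals.isna())[0]) + 2
            raise ValueError(f"{path}: missing value in column {src!r}, line {row}")
        out[dst] = vals
    if not is_log:
        if (out["log2fc"] <= 0).any():
            row = int(np.flatnonzero(out["log2fc"] <= 0)[0]) + 2
            raise ValueError(
                f"{path}: linear fold change must be positive, line {row}"
            )
        out["log2fc"] = np.log2(out["log2fc"])
    return DifferentialTable(out, label=label or Path(path).stem)


def write_de_table(table: DifferentialTable, path: str | Path) -> None:
    table.frame.to_csv(path, sep="\t", index=False)


def read_gene_list(path: str | Path) -> list[str]:
    """One gene id per line; blank lines and '#' comments ignored."""
    genes = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            genes.append(line)
    return genes


def write_gene_list(genes: Sequence[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in sorted(genes)))


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """TSV with stable full-precision float formatting."""
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(
    path: str | Path,
    command: str,
    argv: Sequence[str],
    config: Mapping,
    inputs: Mapping[str, str | Path],
    seed: int | None = None,
) -> None:
    """Record everything needed to reproduce a run byte-for-byte."""
    from . import __version__

    manifest = {
        "tool": "funcat",
        "version": __version__,
        "command": command,
        "argv": list(argv),
        "seed": seed,
        "config": dict(config),
        "input_checksums": {
            str(name): sha256_file(p) for name, p in inputs.items()
        },
    }
    Path(path).write_text(yaml.safe_dump(manifest, sort_keys=True))


def read_manifest(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())
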