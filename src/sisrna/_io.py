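"""Tabular I/O helpers.

Every table the package writes starts with a schema comment line
(``# sisrna/<name>/v1``) followed by a ``#``-prefixed header line with the
column names, so files are self-describing while remaining plain TSV.
"""

from __future__ import annotations

import os
from pathlib import Path

import pandas as pd

SCHEMA_VERSION = 1


def write_table(df: pd.DataFrame, path: str | os.PathLike, name: str) -> None:
    """Write ``df`` as TSV with a schema comment and ``#``-prefixed header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# sisrna/{name}/v{SCHEMA_VERSION}\n")
        fh.write("#" + "\t".join(map(str, df.columns)) + "\n")
        df.to_csv(fh, sep="\t", header=False, index=False)


def read_table(path: str | os.PathLike, **kwargs) -> pd.DataFrame:
    """Read a table written by :func:`write_table` (or a bare headered TSV)."""
    with open(path) as fh:
        first = fh.readline()
    skip = 1 if first.startswith("# sisrna/") else 0
    df = pd.read_csv(path, sep="\t", skiprows=skip, header=0, **kwargs)
    df.columns = [str(df.columns[0]).lstrip("#")] + list(df.columns[1:])
    return df
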