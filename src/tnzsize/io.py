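"""CSV helpers: every output table can carry a provenance comment line."""

from __future__ import annotations

from pathlib import Path

import pandas as pd


def write_csv(df: pd.DataFrame, path: str | Path, header: str | None = None) -> None:
    """Write ``df`` as RFC-4180 CSV, optionally preceded by a ``#`` comment."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        if header:
            fh.write(f"# {header}\n")
        df.to_csv(fh, index=False, lineterminator="\n")


def read_csv(path: str | Path) -> pd.DataFrame:
    """Read a CSV written by :func:`write_csv`, skipping comment lines."""
    return pd.read_csv(path, comment="#")
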