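"""Tabular-text helpers.

Every table the pipeline writes carries a comment header naming the stage
that produced it and a short hash of the configuration, so that a run
directory is auditable after the fact.  Readers skip ``#`` comment lines.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any

import pandas as pd


def config_hash(obj: Any) -> str:
    """Short stable hash of a configuration mapping (or dataclass dict)."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    stage: str,
    conf_hash: str = "",
    index: bool = True,
) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# stage={stage} config={conf_hash or 'n/a'}\n")
        df.to_csv(fh, index=index)
    return path


def read_table(path: str | Path, index_col: int | None = 0) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", index_col=index_col)
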