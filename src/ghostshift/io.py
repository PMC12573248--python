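"""TSV output with provenance headers."""

from __future__ import annotations

import hashlib
import json
from typing import Mapping, Sequence

import pandas as pd


def config_hash(config: Mapping) -> str:
    """Short stable hash of a resolved run configuration."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_tsv(df: pd.DataFrame, path: str, header_lines: Sequence[str] = ()) -> None:
    """Write a DataFrame as TSV, preceded by '# ' provenance comment lines."""
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g", lineterminator="\n")


def read_tsv(path: str) -> pd.DataFrame:
    """Read a TSV written by :func:`write_tsv`, skipping comment lines."""
    return pd.read_csv(path, sep="\t", comment="#")
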