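"""TSV / GMT readers and writers with provenance headers.

All tabular artifacts are tab-separated text. Files written by the
pipeline start with ``#``-prefixed provenance lines (version, seed, config
hash) which every reader skips; numeric columns are formatted with six
significant digits so repeated runs are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import __version__

FLOAT_FORMAT = "%.6g"


def config_hash(params: Mapping) -> str:
    """Short stable hash of a parameter mapping, for provenance headers."""
    blob = json.dumps({k: repr(v) for k, v in sorted(params.items())}, sort_keys=True)
    return hashlib.sha1(blob.encode()).hexdigest()[:12]


def provenance_lines(seed=None, params: Mapping | None = None) -> list[str]:
    lines = [f"# tmmeta {__version__}"]
    if seed is not None:
        lines.append(f"# seed={seed}")
    if params is not None:
        lines.append(f"# config_hash={config_hash(params)}")
    return lines


def write_tsv(df: pd.DataFrame, path, *, index=True, seed=None, params=None) -> None:
    """Write a DataFrame as TSV with a provenance header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in provenance_lines(seed=seed, params=params):
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=index, float_format=FLOAT_FORMAT, lineterminator="\n")


def read_tsv(path, *, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


def write_expression(matrix, path, *, seed=None, params=None) -> None:
    """Write an ExpressionMatrix's values (probes x samples) as TSV."""
    write_tsv(matrix.values, path, index=True, seed=seed, params=params)


def write_metadata(matrix, path, *, seed=None, params=None) -> None:
    write_tsv(matrix.metadata, path, index=True, seed=seed, params=params)
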