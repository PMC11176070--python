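"""Tabular I/O for the count matrices the pipeline consumes and emits.

Matrices travel as (optionally gzipped) TSV with cells as rows and features as
columns; ground-truth records as JSON. Pandas infers gzip from the ``.gz``
suffix, so one code path covers both.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd


def gz_compression(path):
    """pandas ``compression`` argument for reproducible output files.

    Gzip embeds a modification time by default, which breaks byte-identical
    reruns; pinning mtime=0 makes the archive deterministic. Non-.gz paths
    fall back to pandas' inference.
    """
    return {"method": "gzip", "mtime": 0} if str(path).endswith(".gz") else "infer"


def write_matrix_tsv(path, values: np.ndarray, cells, features) -> None:
    df = pd.DataFrame(values, index=pd.Index(cells, name="cell"), columns=features)
    df.to_csv(path, sep="\t")


def read_matrix_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_json(path, obj) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, set):
            return sorted(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=1, default=_default))


def read_json(path):
    return json.loads(Path(path).read_text())
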