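"""List-mode containers and report files.

List-mode tables (hits, singles, coincidences) are stored as columnar
parquet with a JSON header embedded in the file metadata; reports are
JSON with a provenance block (seed, package version, config hash).
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import pyarrow as pa
import pyarrow.parquet as pq

_META_KEY = b"petbench"


def save_listmode(df: pd.DataFrame, path: str | Path, metadata: dict | None = None) -> None:
    table = pa.Table.from_pandas(df, preserve_index=False)
    meta = dict(table.schema.metadata or {})
    meta[_META_KEY] = json.dumps(metadata or {}).encode()
    pq.write_table(table.replace_schema_metadata(meta), str(path))


def load_listmode(path: str | Path) -> tuple[pd.DataFrame, dict]:
    table = pq.read_table(str(path))
    raw = (table.schema.metadata or {}).get(_META_KEY, b"{}")
    return table.to_pandas(), json.loads(raw.decode())


def save_report(report: dict, path: str | Path, provenance: dict | None = None) -> None:
    payload = {"provenance": provenance or {}, **report}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def load_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
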