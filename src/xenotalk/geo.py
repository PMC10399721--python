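"""Optional import path for GEO series-matrix files.

The real xenograft arrays live in GEO (series GSE69754); a downloaded
series-matrix file can be fed into the pipeline with this parser plus a
user-supplied probe annotation and sample sheet.  Parse only — the
pipeline itself never touches the network.  The format is plain text:
``!``-prefixed metadata lines, then a tab-separated probe × sample table
between ``!series_matrix_table_begin`` and ``!series_matrix_table_end``
with quoted identifiers.
"""

from __future__ import annotations

import io
from pathlib import Path

import pandas as pd


def read_series_matrix(path: str | Path) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Parse a GEO series-matrix file.

    Returns the probe × sample expression table (floats, probe ids as
    index, GSM accessions as columns) and a dict of the ``!Sample_*`` /
    ``!Series_*`` metadata lines (key → list of unquoted values).
    """
    text = Path(path).read_text()
    meta: dict[str, list[str]] = {}
    table_lines: list[str] = []
    in_table = False
    for line in text.splitlines():
        if line.startswith("!series_matrix_table_begin"):
            in_table = True
            continue
        if line.startswith("!series_matrix_table_end"):
            in_table = False
            continue
        if in_table:
            table_lines.append(line)
        elif line.startswith("!"):
            key, _, rest = line[1:].partition("\t")
            values = [v.strip().strip('"') for v in rest.split("\t")] if rest else []
            meta.setdefault(key, []).extend(values)
    if not table_lines:
        raise ValueError(f"{path}: no series_matrix_table block found")
    table = pd.read_csv(io.StringIO("\n".join(table_lines)), sep="\t", index_col=0)
    table.index = table.index.astype(str).str.strip('"')
    table.index.name = "probe_id"
    table.columns = [str(c).strip('"') for c in table.columns]
    return table.astype(float), meta
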