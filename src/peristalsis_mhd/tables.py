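"""Deterministic delimited-text writers.

Every table carries a commented header with the package version and the full
resolved parameter set, so an output file is self-describing and two runs of
the same configuration are byte-identical (no timestamps).
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import numpy as np

from . import __version__
from .params import DimensionlessParams

__all__ = ["format_table", "write_table"]


def _metadata_lines(params: DimensionlessParams | None, extra: dict) -> list[str]:
    lines = [f"# peristalsis-mhd version = {__version__}"]
    if params is not None:
        for key, val in asdict(params).items():
            lines.append(f"# {key} = {val!r}")
    for key, val in extra.items():
        lines.append(f"# {key} = {val!r}")
    return lines


def format_table(columns: dict, params: DimensionlessParams | None = None,
                 **metadata) -> str:
    """Render named columns as a tab-separated table with a commented header."""
    names = list(columns)
    arrays = [np.atleast_1d(np.asarray(columns[k])) for k in names]
    n = len(arrays[0])
    if any(len(a) != n for a in arrays):
        raise ValueError("columns must have equal length")
    lines = _metadata_lines(params, metadata)
    lines.append("\t".join(names))
    for i in range(n):
        lines.append("\t".join(_fmt(a[i]) for a in arrays))
    return "\n".join(lines) + "\n"


def _fmt(v) -> str:
    if isinstance(v, (str, np.str_)):
        return str(v)
    if isinstance(v, (int, np.integer)):
        return str(int(v))
    return format(float(v), ".12g")


def write_table(path, columns: dict, params: DimensionlessParams | None = None,
                **metadata) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(format_table(columns, params, **metadata))
    return path
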