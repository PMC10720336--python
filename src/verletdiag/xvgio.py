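"""Reading and writing GROMACS xvg (Grace) column files.

The xvg dialect written by MD energy tools is plain whitespace-separated
numeric columns preceded by ``#`` comment lines and ``@`` Grace metadata
lines (title, axis labels, ``s<k> legend "name"``).  This module parses
exactly that dialect — enough to ingest pressure/box time series exported
with ``gmx energy`` — and writes it back losslessly at full precision.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .pressurediag import PressureSeries

__all__ = ["XvgData", "read_xvg", "write_xvg", "pressure_series_from_xvg"]

_LEGEND_RE = re.compile(r"^s(\d+)\s+legend\s+\"(.*)\"\s*$")
_LABEL_RE = re.compile(r"^(title|xaxis\s+label|yaxis\s+label)\s+\"(.*)\"\s*$")


@dataclass
class XvgData:
    """A parsed xvg table: data columns plus Grace metadata.

    Column 0 is conventionally the time axis; ``legends[k]`` names data set
    ``k``, i.e. column ``k + 1``.  Columns without a legend get positional
    names ``col<j>``.
    """

    data: np.ndarray
    legends: list[str]
    title: str = ""
    xlabel: str = ""
    ylabel: str = ""

    @property
    def n_rows(self) -> int:
        return len(self.data)

    def column_names(self) -> list[str]:
        names = ["time" if self.xlabel or self.data.shape[1] > 1 else "col0"]
        for j in range(1, self.data.shape[1]):
            k = j - 1
            names.append(self.legends[k] if k < len(self.legends) else f"col{j}")
        return names

    def column(self, name: str) -> np.ndarray:
        names = self.column_names()
        if name not in names:
            raise KeyError(f"no column {name!r}; have {names}")
        return self.data[:, names.index(name)]


def read_xvg(path: str | Path) -> XvgData:
    """Parse an xvg file: ``#`` comments, ``@`` metadata, numeric columns.

    Raises ``ValueError`` (with the line number) on a non-numeric data row,
    and on files containing no data rows at all.
    """
    path = Path(path)
    legends: dict[int, str] = {}
    title = xlabel = ylabel = ""
    rows: list[list[float]] = []
    ncol: Optional[int] = None
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("@"):
            meta = line[1:].strip()
            m = _LEGEND_RE.match(meta)
            if m:
                legends[int(m.group(1))] = m.group(2)
                continue
            m = _LABEL_RE.match(meta)
            if m:
                key = m.group(1).split()[0]
                if key == "title":
                    title = m.group(2)
                elif key == "xaxis":
                    xlabel = m.group(2)
                else:
                    ylabel = m.group(2)
            continue
        if line == "&":  # Grace data-set separator
            continue
        try:
            row = [float(tok) for tok in line.split()]
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-numeric data row: {raw!r}") from exc
        if ncol is None:
            ncol = len(row)
        elif len(row) != ncol:
            raise ValueError(
                f"{path}:{lineno}: expected {ncol} columns, got {len(row)}"
            )
        rows.append(row)
    if not rows:
        raise ValueError(f"{path}: no numeric data rows")
    legend_list = [legends.get(k, f"col{k + 1}") for k in range(max(legends, default=-1) + 1)]
    return XvgData(
        data=np.asarray(rows, dtype=float),
        legends=legend_list,
        title=title,
        xlabel=xlabel,
        ylabel=ylabel,
    )


def write_xvg(
    path: str | Path,
    data: np.ndarray,
    legends: Sequence[str] = (),
    title: str = "",
    xlabel: str = "",
    ylabel: str = "",
    comments: Sequence[str] = (),
) -> None:
    """Write a column table in xvg format (full float precision)."""
    data = np.atleast_2d(np.asarray(data, dtype=float))
    lines = [f"# {c}" for c in comments]
    if title:
        lines.append(f'@    title "{title}"')
    if xlabel:
        lines.append(f'@    xaxis  label "{xlabel}"')
    if ylabel:
        lines.append(f'@    yaxis  label "{ylabel}"')
    for k, name in enumerate(legends):
        lines.append(f'@ s{k} legend "{name}"')
    for row in data:
        lines.append(" ".join(f"{v:.17g}" for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


_PRES_NAMES = {
    "pressure": "P",
    "pres-xx": "P_xx",
    "pres-yy": "P_yy",
    "pres-zz": "P_zz",
}


def pressure_series_from_xvg(
    xvg: XvgData,
    dt: Optional[float] = None,
    nstlist: Optional[int] = None,
    start_step: int = 0,
) -> PressureSeries:
    """Build a :class:`PressureSeries` from a parsed xvg table.

    Diagonal-tensor legends (``Pres-XX``/``Pres-YY``/``Pres-ZZ``) are used
    when all three are present; otherwise a ``Pressure`` legend, and
    failing that the first data column, is taken as the scalar pressure.
    ``dt`` defaults to the spacing of the time column (column 0).
    """
    names = [lg.strip().lower() for lg in xvg.legends]
    if dt is None:
        t = xvg.data[:, 0]
        if len(t) < 2:
            raise ValueError("cannot infer dt from fewer than 2 rows")
        dt = float(np.mean(np.diff(t)))
        if dt <= 0:
            raise ValueError("time column is not increasing; pass dt explicitly")
    diag_idx = [
        names.index(k) + 1 for k in ("pres-xx", "pres-yy", "pres-zz") if k in names
    ]
    if len(diag_idx) == 3:
        values = xvg.data[:, diag_idx]
    elif "pressure" in names:
        values = xvg.data[:, names.index("pressure") + 1]
    else:
        values = xvg.data[:, min(1, xvg.data.shape[1] - 1)]
    return PressureSeries(
        values=values,
        dt=dt,
        start_step=start_step,
        nstlist=nstlist,
        provenance=f"xvg:{xvg.title}" if xvg.title else "xvg",
    )
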