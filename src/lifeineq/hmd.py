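"""Reader and writer for the Human Mortality Database period 1×1 life-table text layout.

The dialect: an arbitrary preamble (title line, blank lines), a header line
starting with ``Year``, then whitespace-delimited rows with the columns
``Year Age mx qx ax lx dx Lx Tx ex``.  The open age group is written
``110+`` (more generally ``<age>+``) and ``.`` marks a missing value.
"""

from __future__ import annotations

import io
from typing import Dict, TextIO, Union

import numpy as np

from .lifetable import LifeTable, LifeTableError

__all__ = ["read_hmd_lifetable", "write_hmd_lifetable", "HmdParseError"]

_COLUMNS = ("Year", "Age", "mx", "qx", "ax", "lx", "dx", "Lx", "Tx", "ex")


class HmdParseError(ValueError):
    """Raised when an HMD-format file cannot be parsed."""


def _parse_age(token: str, lineno: int) -> tuple[int, bool]:
    open_flag = token.endswith("+")
    raw = token[:-1] if open_flag else token
    try:
        return int(raw), open_flag
    except ValueError:
        raise HmdParseError(f"line {lineno}: malformed age token {token!r}") from None


def _parse_value(token: str) -> float:
    return np.nan if token == "." else float(token)


def read_hmd_lifetable(source: Union[str, TextIO]) -> Dict[int, LifeTable]:
    """Parse an HMD period 1×1 life-table file into a ``year -> LifeTable`` mapping.

    ``source`` may be a path, a string containing the file body, or an open
    text stream.  The radix is detected from ``l0`` of each year.
    """
    if isinstance(source, str):
        if "\n" in source:
            stream: TextIO = io.StringIO(source)
        else:
            stream = open(source, "r", encoding="utf-8")
    else:
        stream = source

    rows_by_year: Dict[int, list] = {}
    header_seen = False
    try:
        for lineno, line in enumerate(stream, start=1):
            tokens = line.split()
            if not tokens:
                continue
            if not header_seen:
                if tokens[0] == "Year":
                    missing = [c for c in _COLUMNS if c not in tokens]
                    if missing:
                        raise HmdParseError(
                            f"line {lineno}: header missing column(s) {missing}"
                        )
                    header_seen = True
                continue
            if len(tokens) != len(_COLUMNS):
                raise HmdParseError(
                    f"line {lineno}: expected {len(_COLUMNS)} fields, got {len(tokens)}"
                )
            try:
                year = int(tokens[0])
            except ValueError:
                raise HmdParseError(f"line {lineno}: malformed year {tokens[0]!r}") from None
            age, open_flag = _parse_age(tokens[1], lineno)
            values = [_parse_value(t) for t in tokens[2:]]
            rows_by_year.setdefault(year, []).append((age, open_flag, values, lineno))
    finally:
        if stream is not source:
            stream.close()

    if not header_seen:
        raise HmdParseError("no header line starting with 'Year' found")

    tables: Dict[int, LifeTable] = {}
    for year, rows in rows_by_year.items():
        rows.sort(key=lambda r: r[0])
        ages = np.array([r[0] for r in rows])
        if ages[0] != 0 or np.any(np.diff(ages) != 1):
            raise HmdParseError(f"year {year}: ages are not contiguous from 0")
        if not rows[-1][1]:
            raise HmdParseError(f"year {year}: last age group is not open ('+')")
        if any(r[1] for r in rows[:-1]):
            raise HmdParseError(f"year {year}: open age group before the last row")
        data = np.array([r[2] for r in rows], dtype=float)
        mx, qx, ax, lx, dx, Lx, Tx, ex = data.T
        try:
            tables[year] = LifeTable(
                year=year, ages=ages, mx=mx, qx=qx, ax=ax, lx=lx, dx=dx,
                Lx=Lx, Tx=Tx, ex=ex, radix=float(lx[0]),
            )
        except LifeTableError as err:
            raise LifeTableError(f"year {year}: {err}") from None
    return tables


def write_hmd_lifetable(
    tables: Union[LifeTable, Dict[int, LifeTable]],
    destination: Union[str, TextIO, None] = None,
    *,
    title: str = "Synthetic population, Life tables (period 1x1)",
) -> str | None:
    """Serialize life tables in the HMD period 1×1 layout.

    Numeric precision follows the HMD convention: rates and ``ax`` to five
    and two decimals, counts to integers, ``ex`` to two decimals.  Returns
    the text when ``destination`` is None.
    """
    if isinstance(tables, LifeTable):
        tables = {tables.year: tables}
    lines = [title, "", "  Year          Age             mx       qx    ax      lx      dx      Lx       Tx     ex"]
    for year in sorted(tables):
        lt = tables[year]
        for i, age in enumerate(lt.ages):
            age_tok = f"{age}+" if i == len(lt.ages) - 1 else str(age)
            lines.append(
                f"  {year}  {age_tok:>11s}  {lt.mx[i]:13.5f} {lt.qx[i]:8.5f} "
                f"{lt.ax[i]:5.2f} {lt.lx[i]:7.0f} {lt.dx[i]:6.0f} {lt.Lx[i]:7.0f} "
                f"{lt.Tx[i]:8.0f} {lt.ex[i]:6.2f}"
            )
    text = "\n".join(lines) + "\n"
    if destination is None:
        return text
    if isinstance(destination, str):
        with open(destination, "w", encoding="utf-8") as fh:
            fh.write(text)
        return None
    destination.write(text)
    return None
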