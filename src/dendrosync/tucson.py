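"""Reader/writer for Tucson ("rwl") decadal ring-width files.

The Tucson interchange format stores one measurement series per core as
decadal blocks: an 8-character series id, the calendar year of the first
value on the line, then up to ten 6-character value fields in units of
0.01 mm. A series ends with a terminator value, either ``999`` (classic
0.01 mm dialect) or ``-9999``; both are accepted and the dialect seen is
recorded on the parsed series.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["RingWidthSeries", "read_rwl", "write_rwl"]

#: one 0.01 mm unit — the resolution of the storage format
WIDTH_FLOOR_MM = 0.01

_TERMINATORS = {999: "999", -9999: "-9999"}


@dataclass
class RingWidthSeries:
    """Annual raw ring widths of a single core, anchored at a first calendar year."""

    core_id: str
    site_id: str
    first_year: int
    widths: np.ndarray  # mm, contiguous years
    terminator: str = "999"

    def __post_init__(self) -> None:
        self.widths = np.asarray(self.widths, dtype=float)
        if self.widths.size == 0:
            raise ValueError(f"series {self.core_id!r}: empty widths")
        if np.any(~np.isfinite(self.widths)) or np.any(self.widths <= 0):
            raise ValueError(f"series {self.core_id!r}: widths must be positive finite")

    @property
    def last_year(self) -> int:
        return self.first_year + len(self.widths) - 1

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.first_year, self.last_year + 1)

    def __len__(self) -> int:
        return len(self.widths)


def read_rwl(path: str | Path, site_id: str | None = None) -> list[RingWidthSeries]:
    """Parse a Tucson decadal file into a list of :class:`RingWidthSeries`.

    Values are converted from 0.01 mm to mm. ``site_id`` defaults to the file
    stem. Raises ``ValueError`` on a malformed decade line (naming the line
    number) or a duplicate core id.
    """
    path = Path(path)
    if site_id is None:
        site_id = path.stem
    open_series: dict[str, dict] = {}
    finished: dict[str, RingWidthSeries] = {}
    order: list[str] = []

    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        if not raw.strip():
            continue
        core_id = raw[:8].strip()
        rest = raw[8:].split()
        if not core_id or len(rest) < 2:
            # tolerate leading header lines before any data block
            if not open_series and not finished:
                continue
            raise ValueError(f"{path.name}:{lineno}: malformed decade line: {raw!r}")
        try:
            year = int(rest[0])
            values = [int(v) for v in rest[1:]]
        except ValueError as exc:
            if not open_series and core_id not in finished:
                continue  # header junk before this core started
            raise ValueError(f"{path.name}:{lineno}: malformed decade line: {raw!r}") from exc

        if core_id in finished:
            raise ValueError(f"{path.name}:{lineno}: duplicate core id {core_id!r}")
        state = open_series.get(core_id)
        if state is None:
            state = {"first_year": year, "values": [], "next_year": year}
            open_series[core_id] = state
            order.append(core_id)
        elif year != state["next_year"]:
            raise ValueError(
                f"{path.name}:{lineno}: decade line year {year} does not continue "
                f"series {core_id!r} (expected {state['next_year']})"
            )
        for v in values:
            if v in _TERMINATORS:
                widths = np.asarray(state["values"], dtype=float) / 100.0
                finished[core_id] = RingWidthSeries(
                    core_id=core_id,
                    site_id=site_id,
                    first_year=state["first_year"],
                    widths=widths,
                    terminator=_TERMINATORS[v],
                )
                del open_series[core_id]
                break
            state["values"].append(v)
        else:
            state["next_year"] = year + len(values)

    if open_series:
        missing = ", ".join(sorted(open_series))
        raise ValueError(f"{path.name}: series without terminator: {missing}")
    return [finished[c] for c in order]


def write_rwl(series: list[RingWidthSeries], path: str | Path) -> Path:
    """Write series to a Tucson decadal file at 0.01 mm precision."""
    path = Path(path)
    if not series:
        raise ValueError("no series to write")
    lines: list[str] = []
    for s in series:
        if len(s.core_id) > 8:
            raise ValueError(f"core id {s.core_id!r} exceeds 8 characters")
        vals = np.round(s.widths * 100.0).astype(int)
        if np.any(vals <= 0):
            raise ValueError(f"series {s.core_id!r}: width below format resolution")
        year = s.first_year
        fields: list[str] = []
        line_year = year

        def _flush() -> None:
            nonlocal fields
            lines.append(f"{s.core_id:<8}{line_year:>4d}" + "".join(fields))
            fields = []

        for v in vals:
            if fields and year % 10 == 0:
                _flush()
                line_year = year
            fields.append(f"{int(v):>6d}")
            year += 1
        if fields and year % 10 == 0:
            _flush()
            line_year = year
        fields.append(f"{999:>6d}")
        _flush()
    path.write_text("\n".join(lines) + "\n")
    return path
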