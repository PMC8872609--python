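"""Risk register: the coded catalogue of risks that anchors the pipeline.

A register is an ordered list of (code, name, segment) records read from a
delimited text file (comma or tab, auto-detected). Codes are opaque labels;
the numeric suffix is used only for deterministic ordering in reports.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, TextIO

from .errors import FormatError, ValidationError

_REQUIRED_COLUMNS = ("code", "name", "segment")


def code_sort_key(code: str) -> tuple:
    """Sort key that orders R2 before R10 while staying total on any string."""
    m = re.fullmatch(r"([A-Za-z]+)(\d+)", code)
    if m:
        return (0, m.group(1), int(m.group(2)))
    return (1, code, 0)


@dataclass(frozen=True)
class Risk:
    """A single coded risk with its supply-chain segment label."""

    code: str
    name: str
    segment: str

    def __post_init__(self) -> None:
        if not self.code or not self.code.strip():
            raise ValidationError("risk code must be non-empty")
        if not self.name or not self.name.strip():
            raise ValidationError(f"risk {self.code!r}: name must be non-empty")


class RiskRegister:
    """Ordered, code-unique collection of :class:`Risk` records."""

    def __init__(self, risks: Iterable[Risk]) -> None:
        self.risks: tuple[Risk, ...] = tuple(risks)
        seen: set[str] = set()
        for r in self.risks:
            if r.code in seen:
                raise ValidationError(f"duplicate risk code {r.code!r}")
            seen.add(r.code)

    @property
    def codes(self) -> tuple[str, ...]:
        return tuple(r.code for r in self.risks)

    @property
    def segments(self) -> tuple[str, ...]:
        """Segment labels in first-appearance order."""
        out: list[str] = []
        for r in self.risks:
            if r.segment not in out:
                out.append(r.segment)
        return tuple(out)

    def by_segment(self, segment: str) -> tuple[Risk, ...]:
        return tuple(r for r in self.risks if r.segment == segment)

    def __len__(self) -> int:
        return len(self.risks)

    def __iter__(self) -> Iterator[Risk]:
        return iter(self.risks)

    def __getitem__(self, code: str) -> Risk:
        for r in self.risks:
            if r.code == code:
                return r
        raise KeyError(code)

    def __contains__(self, code: object) -> bool:
        return any(r.code == code for r in self.risks)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, RiskRegister) and self.risks == other.risks

    def __repr__(self) -> str:
        return f"RiskRegister({len(self)} risks, {len(self.segments)} segments)"


def sniff_delimiter(header: str) -> str:
    """Tab wins if present in the header line, else comma."""
    return "\t" if "\t" in header else ","


def _as_lines(source: str | Path | TextIO) -> list[str]:
    if isinstance(source, (str, Path)):
        text = Path(source).read_text(encoding="utf-8")
    else:
        text = source.read()
    return [ln for ln in text.splitlines() if ln.strip()]


def parse_register(source: str | Path | TextIO) -> RiskRegister:
    """Read a register from delimited text with code/name/segment columns.

    Leading/trailing whitespace in fields is stripped; input row order is
    preserved. Duplicate codes raise :class:`ValidationError`, a missing
    required column raises :class:`FormatError`.
    """
    import csv

    lines = _as_lines(source)
    if not lines:
        raise FormatError("empty input: expected a header with code,name,segment")
    delim = sniff_delimiter(lines[0])
    reader = csv.DictReader(io.StringIO("\n".join(lines)), delimiter=delim)
    fields = [f.strip().lower() for f in (reader.fieldnames or [])]
    missing = [c for c in _REQUIRED_COLUMNS if c not in fields]
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(missing)}")
    key = {f.strip().lower(): f for f in reader.fieldnames or []}
    risks = []
    for row in reader:
        risks.append(
            Risk(
                code=(row[key["code"]] or "").strip(),
                name=(row[key["name"]] or "").strip(),
                segment=(row[key["segment"]] or "").strip(),
            )
        )
    return RiskRegister(risks)


def write_register(register: RiskRegister, dest: str | Path | TextIO, *, delimiter: str = "\t") -> None:
    """Write a register so that :func:`parse_register` round-trips it."""
    import csv

    def _emit(fh: TextIO) -> None:
        w = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        w.writerow(_REQUIRED_COLUMNS)
        for r in register:
            w.writerow([r.code, r.name, r.segment])

    if isinstance(dest, (str, Path)):
        with open(dest, "w", encoding="utf-8") as fh:
            _emit(fh)
    else:
        _emit(dest)
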