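"""Integer calendar-month arithmetic.

Months are represented internally as an integer index ``year * 12 + (month - 1)``
and displayed as ISO ``"YYYY-MM"``. All ranges are inclusive. The integer
representation keeps release-calendar arithmetic (lags, spans) exact and free
of date-library edge cases.
"""

from __future__ import annotations

import re

_ISO_RE = re.compile(r"^(\d{4})-(\d{2})$")


def month_index(year: int, month: int) -> int:
    """Return the integer index of a calendar month (January = 1)."""
    if not 1 <= month <= 12:
        raise ValueError(f"month must be in 1..12, got {month}")
    return year * 12 + (month - 1)


def parse_month(text: str) -> int:
    """Parse an ISO ``"YYYY-MM"`` string into a month index."""
    m = _ISO_RE.match(str(text).strip())
    if m is None:
        raise ValueError(f"not an ISO YYYY-MM month: {text!r}")
    return month_index(int(m.group(1)), int(m.group(2)))


def format_month(index: int) -> str:
    """Format a month index as ISO ``"YYYY-MM"``."""
    year, month0 = divmod(int(index), 12)
    return f"{year:04d}-{month0 + 1:02d}"


def year_of(index: int) -> int:
    return int(index) // 12


def month_of(index: int) -> int:
    """Calendar month number (1..12) of a month index."""
    return int(index) % 12 + 1


def month_range(start: int, end: int) -> range:
    """Inclusive range of month indices."""
    if end < start:
        raise ValueError(f"end month {format_month(end)} before start {format_month(start)}")
    return range(int(start), int(end) + 1)


def as_index(value) -> int:
    """Coerce an ISO string or integer index to a month index."""
    if isinstance(value, str):
        return parse_month(value)
    return int(value)
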