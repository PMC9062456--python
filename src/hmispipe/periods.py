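"""YYYYMM period arithmetic.

Periods are plain integers like 201701.  Keeping them as integers (rather
than pandas Periods) makes CSV round-trips lossless and comparisons cheap.
"""

from __future__ import annotations


def check_period(period: int) -> int:
    """Validate a YYYYMM integer and return it."""
    year, month = divmod(int(period), 100)
    if not (1 <= month <= 12) or year < 1900 or year > 2200:
        raise ValueError(f"invalid YYYYMM period: {period}")
    return int(period)


def period_range(start: int, end: int) -> list[int]:
    """Inclusive list of YYYYMM periods from start to end."""
    check_period(start)
    check_period(end)
    if start > end:
        raise ValueError(f"period range start {start} after end {end}")
    out = []
    y, m = divmod(start, 100)
    while y * 100 + m <= end:
        out.append(y * 100 + m)
        m += 1
        if m == 13:
            y, m = y + 1, 1
    return out


def months_between(start: int, period: int) -> int:
    """Number of whole months from start to period (0 when equal)."""
    sy, sm = divmod(check_period(start), 100)
    py, pm = divmod(check_period(period), 100)
    return (py - sy) * 12 + (pm - sm)


def period_year(period: int) -> int:
    return check_period(period) // 100


def period_month(period: int) -> int:
    return check_period(period) % 100
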