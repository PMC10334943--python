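"""Independent brute-force interpreter of cohort-definition semantics.

Used only as a test oracle: plain-python date loops that check every
criterion literally for one person at a time, with no shared code or data
structures with the engine under test.
"""

from __future__ import annotations

import datetime as dt


def brute_force_entry(
    code_dates: list[dt.date],
    periods: list[tuple[dt.date, dt.date]],
    *,
    incident: bool,
    washout_days: int,
    min_code_count: int,
    window: tuple[int, int],
    index_at: str = "first",
) -> dt.date | None:
    """Index date for one person under a literal reading of the criteria,
    or None if the person does not qualify."""

    # qualifying days: inside some observation period, distinct, sorted
    days = sorted(
        {d for d in code_dates if any(s <= d <= e for s, e in periods)}
    )
    if not days:
        return None
    candidates = days[:1] if incident else days
    low, high = window
    for entry in candidates:
        period = None
        for s, e in periods:
            if s <= entry <= e:
                period = (s, e)
                break
        assert period is not None
        prior_days = (entry - period[0]).days
        if prior_days < washout_days:
            if incident:
                return None
            continue
        confirmations = []
        for d in days:
            gap = (d - entry).days
            if low <= gap <= high and d <= period[1]:
                confirmations.append(d)
        if len(confirmations) < min_code_count - 1:
            if incident:
                return None
            continue
        if index_at == "confirmation" and min_code_count >= 2:
            return sorted(confirmations)[min_code_count - 2]
        return entry
    return None
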