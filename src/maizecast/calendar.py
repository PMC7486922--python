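"""Growing-season calendar for the US Corn Belt.

The season window is April 1 through October 31 inclusive: 214 days in every
year, since February (the only month whose length varies) never intersects it.
Day index 0 is April 1.
"""

from __future__ import annotations

import numpy as np

#: Calendar months inside the growing season, in order.
SEASON_MONTHS: tuple[int, ...] = (4, 5, 6, 7, 8, 9, 10)

#: Days in each season month (April..October).
MONTH_LENGTHS: tuple[int, ...] = (30, 31, 30, 31, 31, 30, 31)

#: Total days in the season window.
SEASON_DAYS: int = sum(MONTH_LENGTHS)  # 214

#: Hourly steps over the season.
SEASON_HOURS: int = SEASON_DAYS * 24  # 5136

#: Day index (0-based, inclusive) of the last day of each season month:
#: Apr 30 / May 31 / Jun 30 / Jul 31 / Aug 31 / Sep 30 / Oct 31.
MONTH_END_INDEX: tuple[int, ...] = tuple(np.cumsum(MONTH_LENGTHS) - 1)  # 29,60,90,121,152,182,213

#: Day index of the first day of each season month.
MONTH_START_INDEX: tuple[int, ...] = tuple(np.cumsum((0,) + MONTH_LENGTHS[:-1]))

#: Forecast cutoffs: prediction issued at the start of the named month uses
#: all days strictly before it.  aug -> through Jul 31 (122 days),
#: sep -> through Aug 31 (153), oct -> through Sep 30 (183), nov -> full season.
CUTOFF_DAYS: dict[str, int] = {"aug": 122, "sep": 153, "oct": 183, "nov": SEASON_DAYS}

#: month (4..10) containing each day of the window, shape (214,)
MONTH_OF_DAY: np.ndarray = np.repeat(SEASON_MONTHS, MONTH_LENGTHS)

#: slice of the window covered by July (the yield-critical month)
JULY_SLICE = slice(MONTH_START_INDEX[3], MONTH_END_INDEX[3] + 1)


def month_slice(month: int) -> slice:
    """Day-index slice of the window covered by a season month (4..10)."""
    if month not in SEASON_MONTHS:
        raise ValueError(f"month {month} outside the April-October window")
    i = SEASON_MONTHS.index(month)
    return slice(MONTH_START_INDEX[i], MONTH_END_INDEX[i] + 1)
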