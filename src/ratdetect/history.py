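"""Behavioural history indicators E* and I*.

Both indicators are deterministic functions of the observed event history:
an individual is "experienced" (indicator 1) on night t if it encountered
(respectively interacted with) any device, of any type, on at least one of
the previous RESET_WINDOW nights. Twenty consecutive event-free nights
therefore reset the animal to naive.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .kernels import RESET_WINDOW


def indicator_from_events(event_nights, query_nights, window: int = RESET_WINDOW) -> np.ndarray:
    """Indicator value at each query night given the nights events occurred.

    An event at night e sets the indicator for nights e+1 .. e+window.
    """
    events = np.unique(np.asarray(list(event_nights), dtype=int))
    query = np.asarray(query_nights, dtype=int)
    if events.size == 0:
        return np.zeros(query.shape, dtype=bool)
    # position of the latest event strictly before each query night
    idx = np.searchsorted(events, query, side="left") - 1
    has_prev = idx >= 0
    last = np.where(has_prev, events[np.clip(idx, 0, None)], -(10 * window))
    return has_prev & (query - last <= window)


def per_rat_indicators(log_df: pd.DataFrame, value_col: str, window: int = RESET_WINDOW) -> pd.Series:
    """Indicator for every record of a log, keyed by the log's row index.

    `log_df` needs columns rat_id, night and `value_col` (0/1); the event
    history of a rat pools nights where any device recorded a 1.
    """
    out = np.zeros(len(log_df), dtype=bool)
    for _, idx in log_df.groupby("rat_id").groups.items():
        sub = log_df.loc[idx]
        events = sub.loc[sub[value_col] == 1, "night"].to_numpy()
        out[log_df.index.get_indexer(idx)] = indicator_from_events(
            events, sub["night"].to_numpy(), window
        )
    return pd.Series(out, index=log_df.index)


class BehaviourState:
    """Streaming indicator for forward simulation of one individual."""

    __slots__ = ("last_event", "window")

    def __init__(self, window: int = RESET_WINDOW):
        self.last_event: int | None = None
        self.window = window

    def indicator(self, night: int) -> bool:
        return self.last_event is not None and 1 <= night - self.last_event <= self.window

    def record(self, night: int) -> None:
        if self.last_event is None or night > self.last_event:
            self.last_event = night
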