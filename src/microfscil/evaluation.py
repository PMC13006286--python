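"""Session accuracies and the two trajectory metrics.

Average Accuracy (AA) is the arithmetic mean of the per-session accuracies
over *all* sessions including the base session; Performance Drop (PD) is
the base-session accuracy minus the final-session accuracy. Accuracies are
carried in percent throughout, matching how FSCIL results are tabulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List

import numpy as np
import pandas as pd

from .errors import DataError, ProtocolError


@dataclass
class SessionResult:
    """Per-session accuracy trajectory (percent) for one method/run."""

    accs: List[float]
    method_label: str = ""
    details: dict = field(default_factory=dict)

    def __post_init__(self):
        self.accs = [float(a) for a in self.accs]
        if len(self.accs) < 1:
            raise ProtocolError("at least one session accuracy required")
        if any(a < 0 or a > 100 for a in self.accs):
            raise DataError("session accuracies must be in [0, 100] percent")

    @property
    def n_sessions(self) -> int:
        return len(self.accs)


def session_accuracy(predictions, labels) -> float:
    """Percent of predictions equal to labels."""
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    if predictions.shape != labels.shape or predictions.size == 0:
        raise DataError("predictions and labels must be equal-length and nonempty")
    return 100.0 * float((predictions == labels).mean())


def average_accuracy(result: SessionResult) -> float:
    """AA: mean of the per-session accuracies (all sessions, base included)."""
    return float(np.mean(result.accs))


def performance_drop(result: SessionResult) -> float:
    """PD: base-session accuracy minus final-session accuracy."""
    if result.n_sessions < 2:
        raise ProtocolError("PD requires at least two sessions")
    return result.accs[0] - result.accs[-1]


def results_table(results: List[SessionResult], decimals: int = 2) -> pd.DataFrame:
    """Table-style report: one row per method, per-session columns, AA and PD.

    Both raw and rounded values are kept (rounded columns suffixed); rounding
    at one decimal of a value like 73.55 is representation-dependent, so the
    raw column is authoritative.
    """
    n = max(r.n_sessions for r in results)
    rows = []
    for r in results:
        row = {"method": r.method_label or "run"}
        for s in range(n):
            row[f"session_{s}"] = r.accs[s] if s < r.n_sessions else np.nan
        row["AA"] = average_accuracy(r)
        row["PD"] = performance_drop(r) if r.n_sessions >= 2 else np.nan
        rows.append(row)
    df = pd.DataFrame(rows).set_index("method")
    df[[f"{c}_rounded" for c in ("AA", "PD")]] = df[["AA", "PD"]].round(decimals)
    return df
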