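"""Convergence bookkeeping shared by the global and hybrid evolutions.

An evolution is sampled every ``check_interval`` iterations; each sample
records the discrete contour length and interior area together with
their changes since the previous sample (the "error length" and "error
area").  The contour is declared converged once both changes stay within
the tolerance ``theta`` — in absolute value, so an oscillating contour is
not mistaken for a stationary one — for ``stable_checks`` consecutive
samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd


@dataclass(frozen=True)
class ConvergenceParams:
    """theta: tolerated change (pixels / pixel units) per check; a check
    happens every ``check_interval`` iterations and must pass
    ``stable_checks`` times in a row."""

    theta: float = 0.0
    check_interval: int = 10
    stable_checks: int = 3

    def __post_init__(self) -> None:
        if self.theta < 0:
            raise ValueError("theta must be >= 0")
        if self.check_interval < 1:
            raise ValueError("check interval must be >= 1")
        if self.stable_checks < 1:
            raise ValueError("stable checks must be >= 1")


@dataclass
class HistoryRow:
    iteration: int
    length: float
    area: float
    error_length: float | None  # None on the first sample of a run
    error_area: float | None
    alpha: int


@dataclass
class History:
    """Sequence of evolution samples with CSV-friendly export."""

    rows: list[HistoryRow] = field(default_factory=list)
    converged: bool = True

    def append(self, iteration: int, length: float, area: float, alpha: int) -> HistoryRow:
        prev = self.rows[-1] if self.rows else None
        row = HistoryRow(
            iteration=iteration,
            length=length,
            area=area,
            error_length=None if prev is None else length - prev.length,
            error_area=None if prev is None else area - prev.area,
            alpha=alpha,
        )
        self.rows.append(row)
        return row

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "iteration": r.iteration,
                    "length": r.length,
                    "area": r.area,
                    "error_length": r.error_length,
                    "error_area": r.error_area,
                    "alpha": r.alpha,
                }
                for r in self.rows
            ],
            columns=["iteration", "length", "area", "error_length", "error_area", "alpha"],
        )


def check_convergence(history, params: ConvergenceParams) -> bool:
    """True iff the last ``stable_checks`` samples all changed by at most
    theta in both contour length and interior area.

    ``history`` may be a History or a plain list of HistoryRow.  Samples
    without a predecessor (error fields None) never count as passing.
    """
    rows = history.rows if isinstance(history, History) else list(history)
    if len(rows) < params.stable_checks:
        return False
    for row in rows[-params.stable_checks :]:
        if row.error_length is None or row.error_area is None:
            return False
        if abs(row.error_length) > params.theta or abs(row.error_area) > params.theta:
            return False
    return True
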