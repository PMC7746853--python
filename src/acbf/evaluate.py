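"""Quantitative validation: Dice overlap and batch summaries.

The Dice coefficient of a predicted mask A and ground truth B is

    DC = 2 |A intersect B| / (|A| + |B|) * 100 %,

100 for identical nonempty masks, 0 for disjoint ones.  Batch summaries
report mean +/- sample (n-1) standard deviation per arm and, when both a
with-filter and a without-filter arm are present, the paired difference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


class UndefinedMetricError(ValueError):
    """Raised when the metric has no value (both masks empty)."""


@dataclass(frozen=True)
class EvalRecord:
    case_id: str
    dice: float  # percentage in [0, 100]
    pred_area: int
    truth_area: int
    iterations: int | None = None
    bf_used: bool | None = None


def _as_bool_mask(mask: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(mask)
    values = np.unique(arr)
    if not np.isin(values, (0, 1)).all():
        raise ValueError(f"{name} mask must be binary 0/1, got values {values[:5]}")
    return arr.astype(bool)


def dice(pred: np.ndarray, truth: np.ndarray) -> float:
    """Dice overlap of two binary masks, as a percentage."""
    a = _as_bool_mask(pred, "predicted")
    b = _as_bool_mask(truth, "truth")
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        raise UndefinedMetricError("Dice is undefined for two empty masks")
    return 200.0 * int((a & b).sum()) / denom


def evaluate_batch(cases) -> tuple[list[EvalRecord], dict]:
    """Per-case Dice records plus a mean +/- sd summary.

    ``cases`` is an iterable of (pred, truth, metadata) where metadata is
    a dict and may carry ``case_id``, ``iterations`` and ``bf_used``.
    When both bf arms are present the summary additionally reports
    per-arm statistics and the mean paired improvement of the with-filter
    arm over the without-filter arm (paired by case_id).
    """
    cases = list(cases)
    if not cases:
        raise ValueError("need at least one case")
    records: list[EvalRecord] = []
    for i, (pred, truth, meta) in enumerate(cases):
        meta = dict(meta or {})
        case_id = str(meta.get("case_id", i))
        try:
            dc = dice(pred, truth)
        except ValueError as exc:
            raise ValueError(f"case {case_id}: {exc}") from exc
        records.append(
            EvalRecord(
                case_id=case_id,
                dice=dc,
                pred_area=int(np.asarray(pred, dtype=bool).sum()),
                truth_area=int(np.asarray(truth, dtype=bool).sum()),
                iterations=meta.get("iterations"),
                bf_used=meta.get("bf_used"),
            )
        )

    def _stats(values: list[float]) -> dict:
        arr = np.asarray(values, dtype=float)
        sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
        return {"n": int(arr.size), "mean": float(arr.mean()), "sd": sd}

    summary = {"overall": _stats([r.dice for r in records])}
    with_bf = [r for r in records if r.bf_used is True]
    without_bf = [r for r in records if r.bf_used is False]
    if with_bf:
        summary["with_bf"] = _stats([r.dice for r in with_bf])
    if without_bf:
        summary["without_bf"] = _stats([r.dice for r in without_bf])
    if with_bf and without_bf:
        by_case = {r.case_id: r.dice for r in without_bf}
        paired = [r.dice - by_case[r.case_id] for r in with_bf if r.case_id in by_case]
        if paired:
            summary["paired_mean_improvement"] = float(np.mean(paired))
    return records, summary


def records_to_dataframe(records) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "case": r.case_id,
                "dice_pct": r.dice,
                "pred_area": r.pred_area,
                "truth_area": r.truth_area,
                "iterations": r.iterations,
                "bf_used": r.bf_used,
            }
            for r in records
        ],
        columns=["case", "dice_pct", "pred_area", "truth_area", "iterations", "bf_used"],
    )
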