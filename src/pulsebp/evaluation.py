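"""Error metrics and BHS/AAMI device grading.

Errors are signed, e = prediction - reference (mmHg).  STD is the
population standard deviation of the signed errors, which gives the
exact decomposition rmse^2 = me^2 + std^2 and matches the AAMI
criterion's use of ME and SD.

BHS grades by the cumulative share of absolute errors within 5, 10 and
15 mmHg (A: 60/85/95 %, B: 50/75/90 %, C: 40/65/85 %, all three columns
simultaneously; otherwise D).  AAMI requires |ME| < 5 mmHg and
STD < 8 mmHg on more than 85 subjects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ErrorSummary",
    "BHSResult",
    "AAMIResult",
    "summarize_errors",
    "bhs_grade",
    "aami_check",
]

BHS_THRESHOLDS_MMHG = (5.0, 10.0, 15.0)
BHS_GRADE_ROWS = {
    "A": (60.0, 85.0, 95.0),
    "B": (50.0, 75.0, 90.0),
    "C": (40.0, 65.0, 85.0),
}
AAMI_ME_LIMIT = 5.0
AAMI_STD_LIMIT = 8.0
AAMI_MIN_SUBJECTS = 85


@dataclass
class ErrorSummary:
    me_mmhg: float
    mae_mmhg: float
    std_mmhg: float
    rmse_mmhg: float
    n: int


def summarize_errors(pred: np.ndarray, truth: np.ndarray) -> ErrorSummary:
    """ME/MAE/STD/RMSE of signed errors pred - truth."""
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape or pred.size == 0:
        raise ValueError("pred and truth must be nonempty arrays of equal shape")
    e = pred - truth
    return ErrorSummary(
        me_mmhg=float(np.mean(e)),
        mae_mmhg=float(np.mean(np.abs(e))),
        std_mmhg=float(np.std(e)),  # population convention
        rmse_mmhg=float(np.sqrt(np.mean(e**2))),
        n=e.size,
    )


@dataclass
class BHSResult:
    pct_le_5: float
    pct_le_10: float
    pct_le_15: float
    grade: str

    @property
    def percentages(self) -> tuple[float, float, float]:
        return (self.pct_le_5, self.pct_le_10, self.pct_le_15)


def bhs_grade(abs_errors: np.ndarray) -> BHSResult:
    """Grade a vector of absolute errors (mmHg) against the BHS table."""
    e = np.asarray(abs_errors, dtype=float)
    if e.size == 0:
        raise ValueError("empty error vector")
    if np.any(e < 0):
        raise ValueError("absolute errors must be nonnegative")
    pct = tuple(100.0 * np.mean(e <= thr) for thr in BHS_THRESHOLDS_MMHG)
    grade = "D"
    for name, row in BHS_GRADE_ROWS.items():
        if all(p >= req for p, req in zip(pct, row)):
            grade = name
            break
    return BHSResult(pct_le_5=pct[0], pct_le_10=pct[1], pct_le_15=pct[2], grade=grade)


@dataclass
class AAMIResult:
    me_mmhg: float
    std_mmhg: float
    n_subjects: int
    passed: bool
    reasons: tuple[str, ...] = ()


def aami_check(summary: ErrorSummary, n_subjects: int) -> AAMIResult:
    """AAMI pass/fail: |ME| < 5 mmHg, STD < 8 mmHg, > 85 subjects."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be at least 1")
    reasons = []
    if not abs(summary.me_mmhg) < AAMI_ME_LIMIT:
        reasons.append("me")
    if not summary.std_mmhg < AAMI_STD_LIMIT:
        reasons.append("std")
    if not n_subjects > AAMI_MIN_SUBJECTS:
        reasons.append("n_subjects")
    return AAMIResult(
        me_mmhg=summary.me_mmhg,
        std_mmhg=summary.std_mmhg,
        n_subjects=n_subjects,
        passed=not reasons,
        reasons=tuple(reasons),
    )
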