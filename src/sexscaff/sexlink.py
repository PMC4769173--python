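"""Classification of scaffolds as X-candidate, Y-candidate or autosomal.

In an XY male / XX female comparison, X-derived scaffolds are sequenced at
about half depth in the male (log2 male/female near -1) while Y-derived
scaffolds are strongly male-biased (here >= 7-fold) but rarely female-free,
because repeats shared with the X and autosomes attract female reads.
Scaffolds below a minimum length are left unclassified: coverage ratios on
short scaffolds are too noisy to call.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import pandas as pd

from .coverage import RatioTable

__all__ = [
    "Call",
    "ClassifierParams",
    "LinkageCall",
    "CandidateSummary",
    "classify_scaffolds",
    "summarize_candidates",
    "rank_candidates",
]


class Call(str, Enum):
    AUTOSOMAL = "AUTOSOMAL"
    X_CANDIDATE = "X_CANDIDATE"
    Y_CANDIDATE = "Y_CANDIDATE"
    UNCLASSIFIED_SHORT = "UNCLASSIFIED_SHORT"


@dataclass(frozen=True)
class ClassifierParams:
    """Thresholds of the length/ratio classifier.

    min_length_bp: scaffolds shorter than this are not called (10 kb).
    x_log2_low..x_log2_high: closed log2(M/F) interval for X candidates
        (-1.25..-0.75, bracketing the one-copy expectation of -1).
    y_fold_min: minimum male/female linear fold for Y candidates (7), closed.
    min_male_normcov: Y calls additionally require male normalized coverage
        at or above this floor, so near-zero/near-zero noise is never called Y.
    """

    min_length_bp: int = 10_000
    x_log2_low: float = -1.25
    x_log2_high: float = -0.75
    y_fold_min: float = 7.0
    min_male_normcov: float = 0.1

    def __post_init__(self) -> None:
        if not (self.x_log2_low < self.x_log2_high < 0):
            raise ValueError("need x_log2_low < x_log2_high < 0")
        if self.y_fold_min <= 1:
            raise ValueError("y_fold_min must exceed 1")
        if self.min_length_bp < 1:
            raise ValueError("min_length_bp must be >= 1")


@dataclass(frozen=True)
class LinkageCall:
    scaffold_id: str
    call: Call
    log2_mf: float
    length_bp: int


@dataclass(frozen=True)
class CandidateSummary:
    n_x: int
    total_x_bp: int
    n_y: int
    total_y_bp: int


def classify_scaffolds(
    ratios: RatioTable,
    lengths: pd.Series,
    params: ClassifierParams = ClassifierParams(),
    male_normcov: pd.Series | None = None,
) -> list[LinkageCall]:
    """Call every scaffold in a male-over-female ratio table.

    Rules, in order: length < min_length_bp -> UNCLASSIFIED_SHORT;
    x_log2_low <= log2(M/F) <= x_log2_high -> X_CANDIDATE;
    2**log2(M/F) >= y_fold_min (and male coverage above the floor, when
    supplied) -> Y_CANDIDATE; otherwise AUTOSOMAL.  The X interval is
    negative and the Y threshold positive, so the calls cannot overlap.

    ``ratios`` must be oriented male (numerator) over female (denominator);
    the orientation cannot be detected here.  ``male_normcov`` is the male
    sample's normalized coverage, used only for the Y noise guard.
    """
    calls: list[LinkageCall] = []
    for sid, lf in ratios.log2_fold.items():
        if sid not in lengths.index:
            raise KeyError(f"no length for scaffold {sid!r}")
        length = int(lengths.loc[sid])
        lf = float(lf)
        if length < params.min_length_bp:
            call = Call.UNCLASSIFIED_SHORT
        elif params.x_log2_low <= lf <= params.x_log2_high:
            call = Call.X_CANDIDATE
        elif 2.0**lf >= params.y_fold_min and (
            male_normcov is None
            or float(male_normcov.loc[sid]) >= params.min_male_normcov
        ):
            call = Call.Y_CANDIDATE
        else:
            call = Call.AUTOSOMAL
        calls.append(LinkageCall(sid, call, lf, length))
    return calls


def summarize_candidates(calls: list[LinkageCall]) -> CandidateSummary:
    """Counts and summed lengths of the X and Y candidate sets."""
    xs = [c for c in calls if c.call is Call.X_CANDIDATE]
    ys = [c for c in calls if c.call is Call.Y_CANDIDATE]
    return CandidateSummary(
        n_x=len(xs),
        total_x_bp=sum(c.length_bp for c in xs),
        n_y=len(ys),
        total_y_bp=sum(c.length_bp for c in ys),
    )


def rank_candidates(calls: list[LinkageCall]) -> dict[str, list[LinkageCall]]:
    """Ordered candidate report for downstream validation.

    X candidates by length descending (the longest were taken forward for
    qPCR and probe design); Y candidates by fold descending then length
    descending.  Ties broken by scaffold id, lexicographic.
    """
    xs = [c for c in calls if c.call is Call.X_CANDIDATE]
    ys = [c for c in calls if c.call is Call.Y_CANDIDATE]
    xs.sort(key=lambda c: (-c.length_bp, c.scaffold_id))
    ys.sort(key=lambda c: (-c.log2_mf, -c.length_bp, c.scaffold_id))
    return {"X": xs, "Y": ys}
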