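"""Lithium-response phenotypes from the Alda scale.

The Alda scale rates long-term response to lithium: the A score (0-10)
measures symptom improvement, and five B criteria (each 0/1/2) penalize
confounding factors such as concomitant medication. The total score is
A minus the summed B score, clamped at 0. Two phenotypes are derived:

* dichotomous — "good" responder iff total score >= 7, else "poor";
* continuous — the raw A score, with subjects whose total B score exceeds 4
  excluded (their improvement rating is too confounded to use as a
  quantitative trait).

Because total >= 7 with A <= 10 forces sum(B) <= 3, every good responder is
automatically eligible for the continuous phenotype.

These derivations document the phenotypes behind the summary statistics the
pipeline consumes; per-SNP association itself is taken from the summary
statistics, not recomputed from phenotypes.
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

__all__ = ["alda_total", "dichotomize", "continuous_phenotype",
           "derive_phenotypes", "GOOD_RESPONSE_THRESHOLD",
           "CONTINUOUS_B_MAX"]

GOOD_RESPONSE_THRESHOLD = 7
CONTINUOUS_B_MAX = 4


def _validate(A: int, B: Sequence[int]) -> None:
    if not (isinstance(A, (int,)) and 0 <= A <= 10):
        raise ValueError(f"A score must be an integer in 0..10, got {A!r}")
    if len(B) != 5:
        raise ValueError(f"expected five B criteria, got {len(B)}")
    for i, b in enumerate(B, start=1):
        if not (isinstance(b, int) and 0 <= b <= 2):
            raise ValueError(f"B{i} must be 0, 1 or 2, got {b!r}")


def alda_total(A: int, B: Sequence[int]) -> int:
    """Total Alda score: max(0, A - sum(B)); negatives clamp to 0."""
    _validate(A, B)
    return max(0, A - sum(B))


def dichotomize(total_score: int) -> str:
    """'good' responder iff total score >= 7, else 'poor'."""
    return "good" if total_score >= GOOD_RESPONSE_THRESHOLD else "poor"


def continuous_phenotype(A: int, B: Sequence[int]) -> int | None:
    """The A score as a quantitative trait; None (excluded) if sum(B) > 4."""
    _validate(A, B)
    return None if sum(B) > CONTINUOUS_B_MAX else A


def derive_phenotypes(table: pd.DataFrame) -> pd.DataFrame:
    """Add derived phenotype columns to an Alda score table.

    Input columns: ``subject_id,A,B1,B2,B3,B4,B5``. Output adds ``total``,
    ``responder`` (good/poor), ``continuous`` (A score or empty) and
    ``excluded_continuous`` (bool).
    """
    required = ["subject_id", "A", "B1", "B2", "B3", "B4", "B5"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"phenotype table missing columns: {missing}")
    out = table.copy()
    totals, responders, cont, excl = [], [], [], []
    for row in out.itertuples(index=False):
        A = int(row.A)
        B = [int(row.B1), int(row.B2), int(row.B3), int(row.B4), int(row.B5)]
        t = alda_total(A, B)
        totals.append(t)
        responders.append(dichotomize(t))
        c = continuous_phenotype(A, B)
        cont.append(c)
        excl.append(c is None)
    out["total"] = totals
    out["responder"] = responders
    out["continuous"] = pd.array(cont, dtype="Int64")
    out["excluded_continuous"] = excl
    return out
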