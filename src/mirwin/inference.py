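"""Multiple-testing correction across miRNAs and SNP-category enrichment.

Per-miRNA empirical p-values are corrected with the Benjamini-Hochberg
step-up procedure, applied separately within each phenotype's scan (the
correction context is the set of windows tested in that scan).

Two one-sided Fisher exact tests ask whether nominally significant SNPs
(p < alpha, default 0.05) are over-represented (i) inside miRNA windows and
(ii) in an externally supplied cis-miR-eQTL SNP list. The unit of the 2x2
table is the SNP: a SNP inside several overlapping windows is counted once.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotations import WindowSnpSet

__all__ = ["ContingencyTable2x2", "bh_adjust", "fisher_exact_greater",
           "window_enrichment", "eqtl_enrichment"]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts for one enrichment test.

    Rows: SNP in category (miRNA window / eQTL list) yes, no.
    Columns: nominally significant (p < alpha) yes, no.
    a = in-category significant, b = in-category not, c/d analogous outside.
    """
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise ValueError(f"cell {name} must be a non-negative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def degenerate(self) -> bool:
        return 0 in (self.a + self.b, self.c + self.d,
                     self.a + self.c, self.b + self.d)

    @property
    def odds_ratio(self) -> float:
        """ad/bc, with 0.5 continuity applied only when a cell is zero."""
        a, b, c, d = self.a, self.b, self.c, self.d
        if 0 in (a, b, c, d):
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        return (a * d) / (b * c)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    Sort ascending, q_i = min_{j >= i} (m * p_j / j) capped at 1. All inputs
    must lie in (0, 1].
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("bh_adjust expects a non-empty 1-d array")
    if np.any((p <= 0.0) | (p > 1.0)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fisher_exact_greater(table: ContingencyTable2x2) -> float:
    """One-sided (greater) Fisher exact p: hypergeometric tail P(X >= a)."""
    _, p = stats.fisher_exact([[table.a, table.b], [table.c, table.d]],
                              alternative="greater")
    return float(p)


def _enrichment(sumstats: pd.DataFrame, in_category: np.ndarray,
                alpha: float) -> tuple[ContingencyTable2x2, float]:
    sig = sumstats["P"].to_numpy(dtype=float) < alpha
    table = ContingencyTable2x2(
        a=int((in_category & sig).sum()),
        b=int((in_category & ~sig).sum()),
        c=int((~in_category & sig).sum()),
        d=int((~in_category & ~sig).sum()),
    )
    if table.degenerate:
        warnings.warn("degenerate enrichment table (empty row or column); "
                      "p set to 1", stacklevel=3)
        return table, 1.0
    return table, fisher_exact_greater(table)


def window_enrichment(sumstats: pd.DataFrame,
                      window_snp_sets: Iterable[WindowSnpSet],
                      alpha: float = 0.05) -> tuple[ContingencyTable2x2, float]:
    """Are nominally significant SNPs enriched inside miRNA windows?

    Membership is the union over windows; each SNP counts once however many
    windows contain it.
    """
    in_window_ids: set[str] = set()
    for ws in window_snp_sets:
        in_window_ids.update(ws.snp_ids)
    mask = sumstats["SNP"].isin(in_window_ids).to_numpy()
    return _enrichment(sumstats, mask, alpha)


def eqtl_enrichment(sumstats: pd.DataFrame, eqtl_snp_ids: Iterable[str],
                    alpha: float = 0.05) -> tuple[ContingencyTable2x2, float]:
    """Are nominally significant SNPs enriched in a cis-miR-eQTL id list?

    The list is intersected with the summary-statistic SNPs first; an empty
    intersection raises, since it signals an id-space mismatch rather than
    absence of enrichment.
    """
    eqtl = set(eqtl_snp_ids)
    mask = sumstats["SNP"].isin(eqtl).to_numpy()
    if not mask.any():
        raise ValueError("no eQTL SNP id matches the summary statistics; "
                         "check the id spaces")
    return _enrichment(sumstats, mask, alpha)
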