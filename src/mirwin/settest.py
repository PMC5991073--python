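"""The window-based set test: top-fraction chi-square sum with an LD-aware
Monte-Carlo null.

For a window of m SNPs with association p-values p_1..p_m, each p-value is
transformed to its 1-df chi-square quantile q_i (the value whose upper-tail
probability is p_i). The observed statistic is the sum of the k = max(1,
ceil(f*m)) largest q_i — the "top-f" statistic, f = 0.1 by default, which
sums the 10% most significant SNPs of the window. Summing chi-square
quantiles of the *most significant* SNPs is the VEGAS construction: small
p-values map to large chi-square values, so stronger association increases
the statistic.

Because the k summands are data-selected, the null distribution is not a
chi-square; it is obtained by simulation. Each replicate draws a z-vector
from MVN(0, R), where R is the LD (dosage-correlation) matrix of the window's
SNPs, squares it componentwise, and — crucially — re-selects the top k values
*within that replicate* before summing. Re-selection reproduces the selection
step of the observed statistic under the null; keeping the observed SNPs'
indices fixed across replicates instead understates the null and inflates
type-I error under LD (that biased variant is retained behind
``fixed_indices`` purely as a regression target).

The empirical p-value is the add-one Monte-Carlo estimator
(1 + #{sim >= observed}) / (1 + nsim): it never returns 0 and counts ties
against the observed statistic. Simulation is staged (1e3 -> 1e6 draws by
default), escalating while the current estimate is within 10/nsim of zero,
as in VEGAS; the final stage bounds the attainable p at 1e-6.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .annotations import WindowSnpSet
from .ld import LDMatrix

__all__ = ["SetTestConfig", "SetTestResult", "p_to_chisq", "top_fraction_stat",
           "simulate_null_stats", "empirical_p", "test_window", "window_rng"]

#: chunk size (elements) for MVN draws, to bound memory at large nsim
_CHUNK_ELEMS = 20_000_000


@dataclass(frozen=True)
class SetTestConfig:
    """Tuning of the set test.

    top_fraction
        Fraction f of the window's SNPs summed into the statistic (default
        0.1: the top-10% most significant SNPs).
    sim_stages
        Strictly increasing cumulative simulation counts; the test escalates
        to the next stage while the empirical p is still within
        ``escalation_hits``/nsim of zero.
    escalation_hits
        Escalate when fewer than this many simulated statistics exceeded the
        observed one (default 10).
    k_rounding
        "ceil" (default) gives k = max(1, ceil(f*m)); "floor" gives
        k = max(1, floor(f*m)) for sensitivity analysis.
    """

    top_fraction: float = 0.1
    sim_stages: tuple[int, ...] = (1_000, 10_000, 100_000, 1_000_000)
    escalation_hits: int = 10
    k_rounding: str = "ceil"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.top_fraction <= 1.0):
            raise ValueError("top_fraction must be in (0, 1]")
        if any(b <= a for a, b in zip(self.sim_stages, self.sim_stages[1:])):
            raise ValueError("sim_stages must be strictly increasing")
        if self.k_rounding not in ("ceil", "floor"):
            raise ValueError("k_rounding must be 'ceil' or 'floor'")


@dataclass
class SetTestResult:
    """Per-window outcome of the set test."""
    mirna_name: str
    n_snps_tested: int
    observed_stat: float
    empirical_p: float
    n_sims_used: int
    top_snp_id: str | None
    top_snp_p: float | None
    untestable: bool = False


def p_to_chisq(p):
    """Map association p-values to 1-df chi-square quantiles.

    Returns the value q whose upper-tail probability under chi2(1) is p;
    p = 1 maps to 0, smaller p to larger q. p must lie in (0, 1] (exact
    zeros are clamped upstream, at 1e-300, to keep the transform finite).
    """
    arr = np.asarray(p, dtype=float)
    if np.any((arr <= 0.0) | (arr > 1.0)):
        raise ValueError("p-values must lie in (0, 1]")
    q = stats.chi2.isf(arr, df=1)
    return float(q) if np.isscalar(p) else q


def top_fraction_stat(chisq_values, f: float, k_rounding: str = "ceil",
                      ) -> tuple[int, float]:
    """Sum of the k largest chi-square values, k = max(1, ceil(f*m)).

    The ceiling (with a floor of one SNP) reads "the top 10% most
    significant SNPs" as at-least-10%, guaranteeing small windows still
    contribute one SNP.
    """
    vals = np.asarray(chisq_values, dtype=float)
    if vals.size == 0:
        raise ValueError("cannot compute a set statistic on an empty window")
    if not (0.0 < f <= 1.0):
        raise ValueError("top fraction must be in (0, 1]")
    m = vals.size
    rounder = np.ceil if k_rounding == "ceil" else np.floor
    k = max(1, int(rounder(f * m)))
    k = min(k, m)
    if k == m:
        return k, float(vals.sum())
    part = np.partition(vals, m - k)[m - k:]
    return k, float(part.sum())


def simulate_null_stats(R: LDMatrix | np.ndarray, f: float, nsim: int,
                        rng: np.random.Generator | int | None = None,
                        fixed_indices: np.ndarray | None = None,
                        k_rounding: str = "ceil") -> np.ndarray:
    """Draw ``nsim`` null set statistics under MVN(0, R).

    Each replicate squares an MVN(0, R) draw componentwise and sums the top
    k values re-selected within the replicate. ``fixed_indices`` switches to
    the biased variant that always sums the given (observed-top) indices —
    kept only so tests can demonstrate its type-I inflation.

    R may be an :class:`LDMatrix` (its cached factor is reused) or a raw
    PSD correlation matrix.
    """
    if isinstance(R, LDMatrix):
        factor = R.factor
        m = R.m
    else:
        Rm = np.asarray(R, dtype=float)
        w, V = np.linalg.eigh(Rm)
        if w.min() < -1e-8:
            raise ValueError("correlation matrix is not PSD; run ensure_psd first")
        factor = V * np.sqrt(np.clip(w, 0.0, None))
        m = Rm.shape[0]
    rng = np.random.default_rng(rng)

    if fixed_indices is None:
        rounder = np.ceil if k_rounding == "ceil" else np.floor
        k = min(m, max(1, int(rounder(f * m))))
    out = np.empty(nsim)
    chunk = max(1, _CHUNK_ELEMS // max(1, m))
    done = 0
    while done < nsim:
        n = min(chunk, nsim - done)
        z = rng.standard_normal((n, m)) @ factor.T
        np.square(z, out=z)
        if fixed_indices is not None:
            out[done:done + n] = z[:, np.asarray(fixed_indices, dtype=int)].sum(axis=1)
        elif k == m:
            out[done:done + n] = z.sum(axis=1)
        else:
            out[done:done + n] = np.partition(z, m - k, axis=1)[:, m - k:].sum(axis=1)
        done += n
    return out


def empirical_p(observed_stat: float, simulated_stats: np.ndarray) -> float:
    """Add-one Monte-Carlo p: (1 + #{sim >= observed}) / (1 + nsim)."""
    sims = np.asarray(simulated_stats)
    if sims.size < 1:
        raise ValueError("need at least one simulated statistic")
    return float((1 + int((sims >= observed_stat).sum())) / (1 + sims.size))


def window_rng(master_seed: int, window_name: str) -> np.random.Generator:
    """Window-specific RNG stream derived from (master seed, window name).

    Keyed by name so per-window results do not depend on processing order or
    parallel scheduling.
    """
    tag = zlib.crc32(window_name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, tag]))


def test_window(window_snp_set: WindowSnpSet, sumstats: pd.DataFrame,
                R: LDMatrix, config: SetTestConfig,
                rng: np.random.Generator | None = None,
                fixed_index_variant: bool = False) -> SetTestResult:
    """Run the set test for one window.

    ``R`` must cover exactly the SNPs to be tested (the window's SNPs minus
    panel-dropped ones); p-values are taken from ``sumstats`` (columns SNP,
    BP, P) in R's SNP order. Simulation escalates through
    ``config.sim_stages`` while the empirical p remains within
    ``escalation_hits``/nsim of zero; draws accumulate across stages.

    The reported top SNP is the tested SNP with the smallest p-value, ties
    broken by position then id.
    """
    name = window_snp_set.window.name
    if R.m == 0:
        return SetTestResult(mirna_name=name, n_snps_tested=0,
                             observed_stat=float("nan"), empirical_p=float("nan"),
                             n_sims_used=0, top_snp_id=None, top_snp_p=None,
                             untestable=True)
    sub = sumstats.set_index("SNP").loc[R.snp_ids]
    pvals = np.clip(sub["P"].to_numpy(dtype=float), 1e-300, 1.0)
    chisq = p_to_chisq(pvals)
    k, observed = top_fraction_stat(chisq, config.top_fraction, config.k_rounding)

    fixed_idx = None
    if fixed_index_variant:
        fixed_idx = np.argsort(chisq)[-k:]

    if rng is None:
        rng = window_rng(config.seed, name)

    exceed = 0
    total = 0
    for stage in config.sim_stages:
        ndraw = stage - total
        if ndraw > 0:
            sims = simulate_null_stats(R, config.top_fraction, ndraw, rng,
                                       fixed_indices=fixed_idx,
                                       k_rounding=config.k_rounding)
            exceed += int((sims >= observed).sum())
            total = stage
        if exceed >= config.escalation_hits:
            break
    p_emp = (1 + exceed) / (1 + total)

    # top SNP: smallest p, ties by position then id
    order = np.lexsort((sub.index.to_numpy(), sub["BP"].to_numpy(), pvals))
    top = order[0]
    return SetTestResult(mirna_name=name, n_snps_tested=R.m,
                         observed_stat=observed, empirical_p=float(p_emp),
                         n_sims_used=total,
                         top_snp_id=str(sub.index[top]),
                         top_snp_p=float(pvals[top]))
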