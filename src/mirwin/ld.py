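"""Linkage-disequilibrium estimation from a reference genotype panel.

The set test simulates its null from a multivariate normal whose correlation
matrix is the pairwise LD of the tested SNPs, estimated here as the Pearson
correlation of genotype dosages in a reference panel (the analysis that this
package reimplements used the 1000 Genomes phase 3 European panel for this
purpose; any VCF with the tested SNPs works).

Dosage correlation — rather than haplotype r — is used because it requires no
phasing and matches the standard r measure on unphased data. Near-monomorphic
SNPs give unstable correlations and are dropped (``maf_min``, default 0.01).
The estimated matrix is repaired to positive semidefiniteness by eigenvalue
clipping before it is used as an MVN covariance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["LDMatrix", "GenotypeMatrix", "LDError", "load_genotypes",
           "ld_correlation", "ensure_psd"]


class LDError(ValueError):
    """Raised when an LD matrix cannot be estimated or repaired."""


@dataclass
class GenotypeMatrix:
    """Dosage matrix (subjects x SNPs) with SNP coordinates.

    Dosages count alternate alleles, so they lie in {0, 1, 2}; missing
    genotypes are mean-imputed per SNP and may be fractional.
    """

    snp_ids: list[str]
    chroms: np.ndarray
    positions: np.ndarray
    dosages: np.ndarray  # float64, subjects x SNPs
    n_dropped: int = 0

    def subset(self, snp_ids: list[str]) -> "GenotypeMatrix":
        """Columns for the requested SNPs, preserving the requested order.

        SNPs absent from the panel are counted in ``n_dropped`` of the
        returned matrix.
        """
        index = {s: i for i, s in enumerate(self.snp_ids)}
        found = [s for s in snp_ids if s in index]
        cols = [index[s] for s in found]
        return GenotypeMatrix(
            snp_ids=found,
            chroms=self.chroms[cols],
            positions=self.positions[cols],
            dosages=self.dosages[:, cols],
            n_dropped=len(snp_ids) - len(found),
        )


@dataclass
class LDMatrix:
    """Pairwise dosage-correlation matrix for the SNPs of one window.

    ``R`` is symmetric with unit diagonal, entries in [-1, 1], and positive
    semidefinite (repaired if the sample estimate was not). ``snp_ids`` is the
    window's SNP list minus dropped SNPs, in the original order. A square-root
    factor for MVN sampling is computed lazily and cached.
    """

    snp_ids: list[str]
    R: np.ndarray
    n_dropped: int = 0
    _factor: np.ndarray | None = field(default=None, repr=False, compare=False)

    @property
    def m(self) -> int:
        return len(self.snp_ids)

    @property
    def factor(self) -> np.ndarray:
        """Matrix F with F F' = R, via eigendecomposition (PSD-safe)."""
        if self._factor is None:
            w, V = np.linalg.eigh(self.R)
            w = np.clip(w, 0.0, None)
            self._factor = V * np.sqrt(w)
        return self._factor


def _dosage_from_gt_types(gt_types: np.ndarray) -> np.ndarray:
    # cyvcf2 gt_types: 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
    out = np.array([0.0, 1.0, np.nan, 2.0])[gt_types]
    return out


def load_genotypes(vcf_path: str, region: tuple[str, int, int] | None = None,
                   snp_ids: list[str] | None = None) -> GenotypeMatrix:
    """Read diploid dosages from a VCF.

    Parameters
    ----------
    vcf_path
        Plain or bgzipped VCF. The whole file is scanned; ``region``
        (chromosome, start, end; 1-based closed) filters records.
    snp_ids
        If given, only these SNPs are returned (matched by ID, falling back
        to chromosome+position) and requested-but-absent SNPs are counted in
        ``n_dropped``.

    Missing genotypes are mean-imputed per SNP.
    """
    from cyvcf2 import VCF
    from .annotations import normalize_chrom

    try:
        vcf = VCF(vcf_path)
    except Exception as exc:  # pragma: no cover - cyvcf2 raises various types
        raise LDError(f"cannot read VCF {vcf_path!r}: {exc}") from exc

    wanted_ids = set(snp_ids) if snp_ids is not None else None
    pos_to_id: dict[tuple[str, int], str] = {}

    ids, chroms, positions, rows = [], [], [], []
    for rec in vcf:
        chrom = normalize_chrom(rec.CHROM)
        if region is not None:
            rchrom, rstart, rend = region
            if chrom != normalize_chrom(rchrom) or not (rstart <= rec.POS <= rend):
                continue
        rid = rec.ID
        if wanted_ids is not None:
            if rid not in wanted_ids:
                # fall back to positional match
                key = (chrom, rec.POS)
                if pos_to_id:
                    rid = pos_to_id.get(key)
                    if rid is None:
                        continue
                else:
                    continue
        ids.append(rid)
        chroms.append(chrom)
        positions.append(rec.POS)
        rows.append(_dosage_from_gt_types(np.asarray(rec.gt_types)))

    if not rows:
        warnings.warn(f"no requested SNPs found in {vcf_path!r}", stacklevel=2)
        dosages = np.empty((0, 0))
    else:
        dosages = np.array(rows).T

    # mean-impute missing per SNP
    if dosages.size:
        col_mean = np.nanmean(dosages, axis=0)
        nan_r, nan_c = np.nonzero(np.isnan(dosages))
        dosages[nan_r, nan_c] = col_mean[nan_c]

    n_dropped = 0
    if snp_ids is not None:
        found = set(ids)
        n_dropped = sum(1 for s in snp_ids if s not in found)
        # preserve requested order
        order = {s: i for i, s in enumerate(snp_ids)}
        perm = sorted(range(len(ids)), key=lambda i: order.get(ids[i], len(order)))
        ids = [ids[i] for i in perm]
        chroms = [chroms[i] for i in perm]
        positions = [positions[i] for i in perm]
        if dosages.size:
            dosages = dosages[:, perm]

    return GenotypeMatrix(snp_ids=ids, chroms=np.array(chroms),
                          positions=np.array(positions, dtype=int),
                          dosages=dosages, n_dropped=n_dropped)


def ld_correlation(geno: GenotypeMatrix, maf_min: float = 0.01) -> LDMatrix:
    """Pearson correlation of dosage columns, with MAF/monomorphic filtering.

    SNPs with minor-allele frequency below ``maf_min`` in the panel, or with
    zero dosage variance, are dropped with a warning and counted in
    ``n_dropped``. Raises :class:`LDError` if nothing usable remains.
    """
    X = np.asarray(geno.dosages, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise LDError("LD estimation needs a dosage matrix with >= 2 subjects")
    freq = X.mean(axis=0) / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    usable = (maf >= maf_min) & (X.std(axis=0) > 0)
    n_drop_here = int((~usable).sum())
    if n_drop_here:
        dropped = [s for s, u in zip(geno.snp_ids, usable) if not u]
        warnings.warn(
            f"dropping {n_drop_here} monomorphic/low-MAF SNPs from LD panel: "
            f"{dropped[:5]}{'...' if len(dropped) > 5 else ''}", stacklevel=2)
    if not usable.any():
        raise LDError("all window SNPs are monomorphic or below the MAF "
                      "threshold in the reference panel")
    kept_ids = [s for s, u in zip(geno.snp_ids, usable) if u]
    Xk = X[:, usable]
    if Xk.shape[1] == 1:
        R = np.ones((1, 1))
    else:
        R = np.corrcoef(Xk, rowvar=False)
        R = np.clip(R, -1.0, 1.0)
        np.fill_diagonal(R, 1.0)
        R = ensure_psd(R)
    return LDMatrix(snp_ids=kept_ids, R=R,
                    n_dropped=geno.n_dropped + n_drop_here)


def ensure_psd(R: np.ndarray, tol: float = 1e-8,
               max_change: float = 0.1) -> np.ndarray:
    """Repair a correlation matrix to positive semidefiniteness.

    Eigenvalues below ``tol`` are clipped up to ``tol``, the matrix is
    reassembled and rescaled back to unit diagonal. If the minimum eigenvalue
    is already nonnegative the input is returned unchanged. A repair that
    moves any entry by more than ``max_change`` signals an unusably small or
    inconsistent panel and raises :class:`LDError`.
    """
    R = np.asarray(R, dtype=float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise LDError("correlation matrix must be square")
    if not np.allclose(R, R.T, atol=1e-10):
        raise LDError("correlation matrix must be symmetric")
    w, V = np.linalg.eigh(R)
    if w.min() >= 0.0:
        return R
    w_clipped = np.clip(w, tol, None)
    R2 = (V * w_clipped) @ V.T
    d = np.sqrt(np.diag(R2))
    R2 = R2 / np.outer(d, d)
    R2 = (R2 + R2.T) / 2.0
    R2 = np.clip(R2, -1.0, 1.0)
    np.fill_diagonal(R2, 1.0)
    delta = float(np.abs(R2 - R).max())
    if delta > max_change:
        raise LDError(f"PSD repair changed an entry by {delta:.3f} "
                      f"(> {max_change}); panel too small or inconsistent")
    if delta > 1e-6:
        logger.info("PSD repair: max entry change %.2e", delta)
    return R2
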