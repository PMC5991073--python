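"""Synthetic cohort generator: reference panel, summary statistics, miRNA
annotations, Alda phenotypes and eQTL lists.

The original analysis ran on consortium GWAS summary statistics, miRBase
coordinates, a 1000 Genomes LD panel and a published cis-miR-eQTL catalogue,
none of which can be redistributed. This module generates inputs with the
statistical structure the pipeline assumes, so every downstream stage is
testable without a download:

* **Reference panel** — diploid genotypes in LD blocks. Haplotypes within a
  block follow a stationary binary Markov chain with a shared allele
  frequency, giving adjacent-SNP correlation exactly ``block_rho`` and
  lag-d correlation ``block_rho**d`` (PSD by construction); blocks are
  independent.
* **Summary statistics** — per-block z-scores drawn from the multivariate
  normal implied by the panel's genotype correlation, mean 0 under the null
  and shifted by a noncentrality at injected causal SNPs; p-values are
  two-sided normal tails. This matches the null model of the set test, so
  type-I-error calibration against these inputs is a sharp check.
* **Annotations** — miRNA hairpin records (60-150 bp) on the panel's
  chromosomes, a configurable fraction on chromosome X to exercise the
  autosome filter.
* **Alda phenotypes** — A in 0..10, five B criteria in {0,1,2} with
  configurable marginals.
* **eQTL list** — a SNP id subset, optionally biased into miRNA windows to
  create true enrichment for power tests.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .annotations import MirnaWindow
from .ld import LDError, ensure_psd

__all__ = ["PanelSpec", "SignalSpec", "ReferencePanel", "gen_reference_panel",
           "gen_summary_stats", "gen_mirna_annotations", "gen_alda_scores",
           "gen_eqtl_list", "write_sumstats", "read_sumstats"]

_AUTOSOMES = [str(i) for i in range(1, 23)]

#: p-values numerically equal to 0 are clamped here so the chi-square
#: transform stays finite
P_FLOOR = 1e-300


@dataclass(frozen=True)
class PanelSpec:
    """Layout and LD structure of a synthetic reference panel.

    ``chromosome_layout`` maps block index -> (chromosome, start position,
    inter-SNP spacing in bp); if omitted, blocks are laid out round-robin
    over the 22 autosomes with non-overlapping spans. ``maf_range`` bounds
    the (shared, per-block) allele frequency; blocks whose empirical MAF
    escapes the range are regenerated.
    """

    n_haplotypes: int = 2_000
    n_snps_per_block: int = 50
    n_blocks: int = 10
    block_rho: float = 0.5
    maf_range: tuple[float, float] = (0.05, 0.5)
    chromosome_layout: dict[int, tuple[str, int, int]] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_haplotypes < 4 or self.n_haplotypes % 2:
            raise ValueError("n_haplotypes must be even and >= 4 (diploid pairing)")
        if not (0.0 <= self.block_rho < 1.0):
            raise ValueError("block_rho must lie in [0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if self.n_snps_per_block < 1 or self.n_blocks < 1:
            raise ValueError("need at least one SNP per block and one block")

    def layout(self) -> dict[int, tuple[str, int, int]]:
        if self.chromosome_layout is not None:
            self._check_layout(self.chromosome_layout)
            return self.chromosome_layout
        spacing = 2_000
        span = self.n_snps_per_block * spacing + 100_000
        out = {}
        for b in range(self.n_blocks):
            chrom = _AUTOSOMES[b % len(_AUTOSOMES)]
            start = 1_000_000 + (b // len(_AUTOSOMES)) * span
            out[b] = (chrom, start, spacing)
        return out

    def _check_layout(self, layout: dict[int, tuple[str, int, int]]) -> None:
        if set(layout) != set(range(self.n_blocks)):
            raise ValueError("chromosome_layout must cover blocks 0..n_blocks-1")
        spans: dict[str, list[tuple[int, int]]] = {}
        for b, (chrom, start, spacing) in layout.items():
            if start < 1 or spacing < 1:
                raise ValueError(f"block {b}: start and spacing must be >= 1")
            end = start + (self.n_snps_per_block - 1) * spacing
            spans.setdefault(str(chrom), []).append((start, end))
        for chrom, ivs in spans.items():
            ivs.sort()
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                if s2 <= e1:
                    raise ValueError(f"overlapping blocks on chromosome {chrom}: "
                                     f"[{s1},{e1}] and [{s2},{e2}]")


@dataclass(frozen=True)
class SignalSpec:
    """Injected association signal: a mean shift of the z-score at causal SNPs."""

    causal_snp_ids: frozenset[str] = frozenset()
    noncentrality: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noncentrality < 0:
            raise ValueError("noncentrality must be >= 0")


@dataclass
class ReferencePanel:
    """Diploid genotypes plus SNP map (columns SNP, CHR, BP, block)."""

    genotypes: np.ndarray  # subjects x SNPs, int8 in {0,1,2}
    snp_map: pd.DataFrame
    spec: PanelSpec

    @property
    def n_subjects(self) -> int:
        return self.genotypes.shape[0]

    def block_columns(self, block: int) -> np.ndarray:
        return np.flatnonzero((self.snp_map["block"] == block).to_numpy())

    def to_vcf(self, path: str) -> None:
        """Write the panel as an uncompressed VCF v4.2 with unphased GT."""
        gt_strings = np.array(["0/0", "0/1", "1/1"])
        samples = [f"S{i:04d}" for i in range(self.n_subjects)]
        chroms = sorted(self.snp_map["CHR"].unique(), key=_chrom_sort_key)
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write("##source=mirwin-synthetic-panel\n")
            for c in chroms:
                fh.write(f"##contig=<ID={c}>\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                     + "\t".join(samples) + "\n")
            order = self.snp_map.sort_values(
                ["CHR", "BP"], key=lambda s: s.map(_chrom_sort_key)
                if s.name == "CHR" else s).index
            for i in order:
                row = self.snp_map.loc[i]
                gts = gt_strings[self.genotypes[:, i]]
                fh.write(f"{row.CHR}\t{row.BP}\t{row.SNP}\tA\tG\t.\tPASS\t.\tGT\t"
                         + "\t".join(gts) + "\n")


def _chrom_sort_key(c: str):
    c = str(c)
    return (0, int(c)) if c.isdigit() else (1, c)


def _simulate_block_haplotypes(rng: np.random.Generator, n_hap: int, m: int,
                               rho: float, p: float) -> np.ndarray:
    """Stationary binary Markov chain over SNPs, marginal Bern(p) alleles.

    Transitions P(1|1) = p + rho(1-p), P(1|0) = p(1-rho) give adjacent-allele
    correlation exactly rho; binary Markov chains make lag-d correlation
    rho**d.
    """
    x = np.empty((n_hap, m), dtype=np.int8)
    x[:, 0] = rng.random(n_hap) < p
    pr_stay = p + rho * (1.0 - p)
    pr_gain = p * (1.0 - rho)
    for j in range(1, m):
        prob = np.where(x[:, j - 1] == 1, pr_stay, pr_gain)
        x[:, j] = rng.random(n_hap) < prob
    return x


def gen_reference_panel(spec: PanelSpec) -> ReferencePanel:
    """Generate a blockwise-LD diploid panel (deterministic for spec.seed)."""
    rng = np.random.default_rng(spec.seed)
    layout = spec.layout()
    lo, hi = spec.maf_range
    m = spec.n_snps_per_block
    blocks, rows = [], []
    snp_counter = 0
    for b in range(spec.n_blocks):
        chrom, start, spacing = layout[b]
        for attempt in range(100):
            p = rng.uniform(lo, hi)
            hap = _simulate_block_haplotypes(rng, spec.n_haplotypes, m,
                                             spec.block_rho, p)
            freq = hap.mean(axis=0)
            maf = np.minimum(freq, 1.0 - freq)
            if np.all((maf >= lo) & (maf <= hi)):
                break
        else:
            raise RuntimeError(f"block {b}: could not generate SNPs with MAF in "
                               f"{spec.maf_range} after 100 attempts")
        geno = hap[0::2] + hap[1::2]
        blocks.append(geno.astype(np.int8))
        for j in range(m):
            rows.append({"SNP": f"rs{1_000_000 + snp_counter}",
                         "CHR": str(chrom).removeprefix("chr"),
                         "BP": start + j * spacing, "block": b})
            snp_counter += 1
    genotypes = np.concatenate(blocks, axis=1)
    snp_map = pd.DataFrame(rows)
    return ReferencePanel(genotypes=genotypes, snp_map=snp_map, spec=spec)


def gen_summary_stats(panel: ReferencePanel, signal: SignalSpec | None = None,
                      seed: int = 0) -> pd.DataFrame:
    """Simulate a GWAS summary-statistic table over the panel's SNPs.

    Per block, z ~ MVN(mu, R) with R the block's genotype dosage correlation
    (PSD-repaired) and mu the signal noncentrality at causal SNPs, 0
    elsewhere; p = two-sided normal tail of z, clamped below at 1e-300.
    Returns a DataFrame with columns SNP, CHR, BP, P (plus Z).
    """
    signal = signal or SignalSpec()
    unknown = set(signal.causal_snp_ids) - set(panel.snp_map["SNP"])
    if unknown:
        raise ValueError(f"causal SNPs not in panel: {sorted(unknown)[:5]}")
    rng = np.random.default_rng(seed)
    z_all = np.empty(len(panel.snp_map))
    snp_ids = panel.snp_map["SNP"].to_numpy()
    for b in range(panel.spec.n_blocks):
        cols = panel.block_columns(b)
        G = panel.genotypes[:, cols].astype(float)
        if len(cols) == 1:
            R = np.ones((1, 1))
        else:
            R = np.corrcoef(G, rowvar=False)
            R = np.clip(R, -1.0, 1.0)
            np.fill_diagonal(R, 1.0)
            try:
                R = ensure_psd(R)
            except LDError as exc:
                raise LDError(f"block {b}: correlation matrix not PSD after "
                              f"repair ({exc})") from exc
        w, V = np.linalg.eigh(R)
        factor = V * np.sqrt(np.clip(w, 0.0, None))
        mu = np.isin(snp_ids[cols], list(signal.causal_snp_ids)) * signal.noncentrality
        z_all[cols] = mu + factor @ rng.standard_normal(len(cols))
    p = np.clip(2.0 * stats.norm.sf(np.abs(z_all)), P_FLOOR, 1.0)
    out = panel.snp_map[["SNP", "CHR", "BP"]].copy()
    out["P"] = p
    out["Z"] = z_all
    return out


def write_sumstats(sumstats: pd.DataFrame, path: str) -> None:
    """Write a summary-statistic table as TSV (columns SNP, CHR, BP, P)."""
    sumstats[["SNP", "CHR", "BP", "P"]].to_csv(path, sep="\t", index=False)


def read_sumstats(path: str) -> pd.DataFrame:
    """Read a summary-statistic TSV; requires columns SNP, CHR, BP, P."""
    df = pd.read_csv(path, sep="\t", dtype={"CHR": str})
    missing = [c for c in ("SNP", "CHR", "BP", "P") if c not in df.columns]
    if missing:
        raise ValueError(f"summary statistics {path!r} missing columns {missing}")
    return df


def gen_mirna_annotations(n_mirnas: int, snp_map: pd.DataFrame, seed: int = 0,
                          non_autosomal_fraction: float = 0.1,
                          out_path: str | None = None) -> pd.DataFrame:
    """Scatter synthetic miRNA hairpin records over the panel's chromosomes.

    Transcripts are 60-150 bp, placed near a randomly chosen panel SNP so
    windows are usually covered; round(non_autosomal_fraction * n) records go
    to chromosome X to exercise the autosome filter. Writes GFF3
    (``miRNA_primary_transcript`` features with ``Name=``) when ``out_path``
    is given.
    """
    if n_mirnas < 1:
        raise ValueError("n_mirnas must be >= 1")
    if not (0.0 <= non_autosomal_fraction <= 1.0):
        raise ValueError("non_autosomal_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_x = int(round(non_autosomal_fraction * n_mirnas))
    rows = []
    for i in range(n_mirnas):
        length = int(rng.integers(60, 151))
        if i < n_mirnas - n_x:
            anchor = snp_map.iloc[int(rng.integers(len(snp_map)))]
            chrom = str(anchor.CHR)
            tx_start = max(1, int(anchor.BP) + int(rng.integers(-15_000, 15_001)))
        else:
            chrom = "X"
            tx_start = int(rng.integers(1_000_000, 50_000_000))
        rows.append({"name": f"syn-mir-{i + 1}", "chrom": chrom,
                     "tx_start": tx_start, "tx_end": tx_start + length - 1})
    df = pd.DataFrame(rows)
    if out_path is not None:
        with open(out_path, "w") as fh:
            fh.write("##gff-version 3\n")
            for r in df.itertuples(index=False):
                fh.write(f"chr{r.chrom}\tmirwin-synthetic\tmiRNA_primary_transcript\t"
                         f"{r.tx_start}\t{r.tx_end}\t.\t+\t.\t"
                         f"ID={r.name};Name={r.name}\n")
    return df


def gen_alda_scores(n_subjects: int, seed: int = 0,
                    a_weights: np.ndarray | None = None,
                    b_weights: np.ndarray | None = None,
                    out_path: str | None = None) -> pd.DataFrame:
    """Simulate Alda-scale records: A in 0..10, five B criteria in {0,1,2}.

    Default marginals — A ~ Binomial(10, 0.6), each B criterion with
    probabilities (0.6, 0.3, 0.1) — put roughly a fifth of subjects at a
    total score >= 7, a plausible good-responder rate for a lithium cohort.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    rng = np.random.default_rng(seed)
    if a_weights is None:
        a_weights = stats.binom.pmf(np.arange(11), 10, 0.6)
    a_weights = np.asarray(a_weights, dtype=float)
    a_weights = a_weights / a_weights.sum()
    if b_weights is None:
        b_weights = np.array([0.6, 0.3, 0.1])
    b_weights = np.asarray(b_weights, dtype=float)
    b_weights = b_weights / b_weights.sum()
    A = rng.choice(11, size=n_subjects, p=a_weights)
    B = rng.choice(3, size=(n_subjects, 5), p=b_weights)
    df = pd.DataFrame({"subject_id": [f"SUBJ{i:05d}" for i in range(n_subjects)],
                       "A": A})
    for j in range(5):
        df[f"B{j + 1}"] = B[:, j]
    if out_path is not None:
        df.to_csv(out_path, index=False)
    return df


def gen_eqtl_list(snp_map: pd.DataFrame, fraction: float, seed: int = 0,
                  windows: list[MirnaWindow] | None = None,
                  window_bias: float = 0.0,
                  out_path: str | None = None) -> list[str]:
    """Sample a cis-miR-eQTL-like SNP id subset of size round(fraction * n).

    ``window_bias`` > 0 up-weights SNPs inside the given windows by
    (1 + bias), creating true enrichment for power tests; 0 gives a uniform
    subset. Writes one id per line when ``out_path`` is given.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must lie in (0, 1]")
    if window_bias < 0:
        raise ValueError("window_bias must be >= 0")
    rng = np.random.default_rng(seed)
    n = len(snp_map)
    size = max(1, int(round(fraction * n)))
    weights = np.ones(n)
    if windows and window_bias > 0:
        chroms = snp_map["CHR"].astype(str).to_numpy()
        pos = snp_map["BP"].to_numpy()
        in_win = np.zeros(n, dtype=bool)
        for w in windows:
            in_win |= (chroms == w.chrom) & (pos >= w.win_start) & (pos <= w.win_end)
        weights[in_win] += window_bias
    ids = snp_map["SNP"].to_numpy()
    chosen = rng.choice(ids, size=size, replace=False, p=weights / weights.sum())
    chosen = sorted(chosen.tolist())
    if out_path is not None:
        with open(out_path, "w") as fh:
            fh.write("\n".join(chosen) + "\n")
    return chosen
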