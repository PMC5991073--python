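"""miRNA annotation loading, autosome filtering and test-window construction.

Each miRNA locus is tested as its hairpin (primary-transcript) coordinates
extended by a symmetric flank — 20 kb on each side by default, which covers
the majority of the regulatory sequence of a miRNA gene. Coordinates are
1-based fully closed throughout; BED input is converted at the reader
boundary. Only autosomal (chr1-22) miRNAs are tested.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["MirnaRecord", "MirnaWindow", "WindowSnpSet", "AnnotationError",
           "normalize_chrom", "load_mirna_annotations", "filter_autosomal",
           "expand_window", "assign_snps", "DEFAULT_FLANK_BP"]

DEFAULT_FLANK_BP = 20_000

_AUTOSOMES = {str(i) for i in range(1, 23)}
_KNOWN = _AUTOSOMES | {"X", "Y", "MT"}


class AnnotationError(ValueError):
    """Malformed or inconsistent annotation input."""


class MirnaRecord(NamedTuple):
    """A miRNA transcript: name and 1-based closed genomic coordinates."""
    name: str
    chrom: str
    tx_start: int
    tx_end: int


@dataclass(frozen=True)
class MirnaWindow:
    """A miRNA transcript plus its flanked test window (1-based closed)."""
    name: str
    chrom: str
    tx_start: int
    tx_end: int
    win_start: int
    win_end: int

    @property
    def position_str(self) -> str:
        return f"chr{self.chrom}:{self.tx_start}-{self.tx_end}"


@dataclass
class WindowSnpSet:
    """The summary-statistic SNPs falling inside one window, position-sorted."""
    window: MirnaWindow
    snp_ids: list[str] = field(default_factory=list)
    positions: list[int] = field(default_factory=list)

    @property
    def covered(self) -> bool:
        return len(self.snp_ids) > 0


def normalize_chrom(label: str) -> str:
    """Harmonize a chromosome label: strip 'chr' prefix, map M -> MT."""
    c = str(label).strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    c = c.upper()
    if c == "M":
        c = "MT"
    return c


def load_mirna_annotations(path: str, fmt: str = "gff3",
                           feature_types: Iterable[str] = ("miRNA_primary_transcript",),
                           ) -> list[MirnaRecord]:
    """Read miRNA coordinates from a GFF3 or BED4 file.

    GFF3 records are filtered to ``feature_types`` (default: the hairpin
    ``miRNA_primary_transcript`` records, the convention miRBase uses for the
    preprocessed transcript; mature ``miRNA`` records can be requested
    instead). BED intervals (0-based half-open) are converted to 1-based
    closed. Duplicate miRNA names are rejected.
    """
    fmt = fmt.lower()
    if fmt == "gff3":
        records = _load_gff3(path, set(feature_types))
    elif fmt == "bed":
        records = _load_bed(path)
    else:
        raise AnnotationError(f"unknown annotation format {fmt!r}")

    seen: dict[str, int] = {}
    for rec in records:
        if rec.name in seen:
            raise AnnotationError(f"duplicate miRNA name {rec.name!r} in {path}")
        seen[rec.name] = 1
    return records


def _load_gff3(path: str, feature_types: set[str]) -> list[MirnaRecord]:
    from gffutils.feature import feature_from_line

    records: list[MirnaRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            try:
                feat = feature_from_line(line)
            except Exception as exc:
                raise AnnotationError(f"{path}:{lineno}: malformed GFF3 line "
                                      f"({exc})") from exc
            if feat.featuretype not in feature_types:
                continue
            names = feat.attributes.get("Name") or [feat.id]
            records.append(MirnaRecord(name=names[0],
                                       chrom=normalize_chrom(feat.seqid),
                                       tx_start=int(feat.start),
                                       tx_end=int(feat.end)))
    return records


def _load_bed(path: str) -> list[MirnaRecord]:
    # BED4: chrom, chromStart (0-based), chromEnd (half-open), name
    records: list[MirnaRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.rstrip("\n")
            if not stripped or stripped.startswith(("#", "track", "browser")):
                continue
            fields = stripped.split("\t") if "\t" in stripped else stripped.split()
            if len(fields) < 4:
                raise AnnotationError(f"{path}:{lineno}: BED4 needs >= 4 "
                                      f"columns, got {len(fields)}")
            try:
                start0, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise AnnotationError(f"{path}:{lineno}: non-integer BED "
                                      f"coordinate") from exc
            records.append(MirnaRecord(name=fields[3],
                                       chrom=normalize_chrom(fields[0]),
                                       tx_start=start0 + 1, tx_end=end))
    return records


def filter_autosomal(records: list[MirnaRecord]) -> tuple[list[MirnaRecord], int]:
    """Keep miRNAs on chromosomes 1-22; return (kept, n_removed).

    Unrecognized chromosome labels (not 1-22/X/Y/MT) raise, since they
    usually indicate an assembly or naming mismatch rather than a sex
    chromosome.
    """
    kept = []
    n_removed = 0
    for rec in records:
        c = normalize_chrom(rec.chrom)
        if c not in _KNOWN:
            raise AnnotationError(f"unrecognized chromosome label {rec.chrom!r} "
                                  f"for miRNA {rec.name!r}")
        if c in _AUTOSOMES:
            kept.append(rec)
        else:
            n_removed += 1
    if n_removed:
        logger.info("removed %d non-autosomal miRNAs", n_removed)
    return kept, n_removed


def expand_window(record: MirnaRecord, flank_bp: int = DEFAULT_FLANK_BP) -> MirnaWindow:
    """Build the test window: transcript extended by ``flank_bp`` on each side.

    The left edge is clamped at 1 (positions are 1-based).
    """
    if record.tx_start > record.tx_end:
        raise AnnotationError(f"{record.name}: tx_start > tx_end")
    return MirnaWindow(name=record.name, chrom=normalize_chrom(record.chrom),
                       tx_start=record.tx_start, tx_end=record.tx_end,
                       win_start=max(1, record.tx_start - flank_bp),
                       win_end=record.tx_end + flank_bp)


def assign_snps(windows: list[MirnaWindow], sumstats: pd.DataFrame,
                ) -> tuple[list[WindowSnpSet], int]:
    """Assign summary-statistic SNPs to windows (closed-interval containment).

    A SNP belongs to a window iff it is on the same chromosome and
    ``win_start <= BP <= win_end``; a SNP may belong to several overlapping
    windows. Returns one :class:`WindowSnpSet` per input window (SNPs sorted
    by position, ties by id) and the count of covered windows (>= 1 SNP);
    uncovered windows are flagged by ``covered == False`` and excluded from
    testing downstream.
    """
    ss = sumstats.copy()
    ss["CHR"] = ss["CHR"].map(normalize_chrom)
    by_chrom: dict[str, pd.DataFrame] = {
        str(c): g.sort_values(["BP", "SNP"], kind="mergesort")
        for c, g in ss.groupby("CHR")
    }
    out: list[WindowSnpSet] = []
    n_covered = 0
    for win in windows:
        sets = WindowSnpSet(window=win)
        g = by_chrom.get(win.chrom)
        if g is not None:
            pos = g["BP"].to_numpy()
            lo = pos.searchsorted(win.win_start, side="left")
            hi = pos.searchsorted(win.win_end, side="right")
            if hi > lo:
                sub = g.iloc[lo:hi]
                sets.snp_ids = sub["SNP"].tolist()
                sets.positions = sub["BP"].tolist()
        if sets.covered:
            n_covered += 1
        else:
            logger.debug("window %s not covered by summary statistics", win.name)
        out.append(sets)
    return out, n_covered
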