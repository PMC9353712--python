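"""Layer-specific quantification: gene-body windows, eRNA loci, densities.

Nascent-transcription (GRO-seq style) signal is quantified over a gene-body
window that skips promoter-proximal pausing (+2 kb) and is capped at 12 kb;
enhancer RNA over +/-500 bp around the locus center; both are normalised to
reads per kb per ten million mapped reads (RPKTM).  Mature RNA / ribosome
footprints use exonic RPKM.  Translation rate is the footprint/mRNA density
ratio.  All internal coordinates are 0-based half-open.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import TimeCourseMatrix

__all__ = [
    "GeneModel",
    "GenomicInterval",
    "EnhancerLocus",
    "gene_body_window",
    "erna_window",
    "rpktm",
    "rpkm",
    "quantify_features",
    "filter_erna_peaks",
    "translation_rate",
]


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"empty interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneModel:
    """Strand-aware gene: ``tss``/``tes`` are 5'/3' genomic coordinates.

    For a minus-strand gene tss > tes; ``body_length = |tes - tss|``.
    ``exons`` is an optional list of (start, end) tuples within the body.
    """

    id: str
    chrom: str
    strand: str
    tss: int
    tes: int
    exons: tuple = ()

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.id}: strand must be '+' or '-'")
        if self.tss == self.tes:
            raise ValueError(f"{self.id}: zero-length gene")
        if self.strand == "+" and self.tss > self.tes:
            raise ValueError(f"{self.id}: plus-strand gene with tss > tes")
        if self.strand == "-" and self.tss < self.tes:
            raise ValueError(f"{self.id}: minus-strand gene with tss < tes")
        lo, hi = self.span
        for s, e in self.exons:
            if not (lo <= s < e <= hi):
                raise ValueError(f"{self.id}: exon [{s},{e}) outside gene body")

    @property
    def body_length(self) -> int:
        return abs(self.tes - self.tss)

    @property
    def span(self) -> tuple:
        """(start, end) of the gene body in genomic order."""
        return (min(self.tss, self.tes), max(self.tss, self.tes))

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons) if self.exons else self.body_length


@dataclass(frozen=True)
class EnhancerLocus:
    id: str
    chrom: str
    strand: str
    center: int
    fdr: float
    fold_change: float

    def __post_init__(self):
        if not (0.0 <= self.fdr <= 1.0):
            raise ValueError(f"{self.id}: fdr must lie in [0, 1]")
        if not self.fold_change > 0:
            raise ValueError(f"{self.id}: fold_change must be positive")


# ---------------------------------------------------------------------------
# quantification windows
# ---------------------------------------------------------------------------

_PAUSE_OFFSET = 2_000  # skip promoter-proximal region
_WINDOW_CAP = 12_000  # long genes: quantify +2 kb .. +12 kb only
_ERNA_HALF = 500


def gene_body_window(gene: GeneModel) -> GenomicInterval:
    """Nascent-transcription quantification window of a gene.

    Body > 12 kb: the 10 kb window from +2 kb to +12 kb downstream of the
    TSS.  Body in [2 kb, 12 kb]: +2 kb to the TES.  Body < 2 kb: the whole
    gene body.  Offsets run in the 5'->3' direction, so minus-strand genes
    are mirrored.
    """
    L = gene.body_length
    if L > _WINDOW_CAP:
        lo5, hi5 = _PAUSE_OFFSET, _WINDOW_CAP
    elif L > _PAUSE_OFFSET:
        lo5, hi5 = _PAUSE_OFFSET, L
    else:
        # at exactly +2 kb the "+2 kb to TES" window would be empty,
        # so genes up to 2 kb are quantified over the whole body
        lo5, hi5 = 0, L
    if gene.strand == "+":
        start, end = gene.tss + lo5, gene.tss + hi5
    else:
        start, end = gene.tss - hi5, gene.tss - lo5
    return GenomicInterval(gene.chrom, start, end, gene.strand)


def erna_window(locus: EnhancerLocus) -> GenomicInterval:
    """+/-500 bp window around an enhancer RNA locus center."""
    return GenomicInterval(
        locus.chrom, locus.center - _ERNA_HALF, locus.center + _ERNA_HALF, locus.strand
    )


# ---------------------------------------------------------------------------
# density normalisations
# ---------------------------------------------------------------------------


def rpktm(count: float, length_bp: float, total_mapped: float) -> float:
    """Reads per kilobase per ten million mapped reads."""
    if length_bp <= 0:
        raise ValueError("window length must be positive")
    if total_mapped <= 0:
        raise ValueError("library size must be positive")
    return count / (length_bp / 1_000.0) / (total_mapped / 1e7)


def rpkm(count: float, exon_length_bp: float, total_mapped: float) -> float:
    """Reads per kilobase of exon per million mapped reads."""
    if exon_length_bp <= 0:
        raise ValueError("exonic length must be positive")
    if total_mapped <= 0:
        raise ValueError("library size must be positive")
    return count / (exon_length_bp / 1_000.0) / (total_mapped / 1e6)


# ---------------------------------------------------------------------------
# coverage -> matrix
# ---------------------------------------------------------------------------


def quantify_features(
    coverage: dict,
    windows: dict,
    totals: dict,
    zt=None,
    unit: str = "RPKTM",
    chrom_bounds: dict | None = None,
) -> TimeCourseMatrix:
    """Sum same-strand coverage in each window per timepoint, normalise.

    Parameters
    ----------
    coverage
        ``{timepoint label: {strand: BedGraph}}`` (see :mod:`rhythmlayers.io`);
        a window whose strand is missing from a timepoint is an error.
    windows
        ``{feature id: GenomicInterval}`` with strand '+' or '-'.
    totals
        ``{timepoint label: mapped reads}``; must be positive.
    zt
        ZT hour per timepoint label (parsed from labels like ``ZT3`` when
        omitted).
    chrom_bounds
        Optional ``{chrom: length}``; windows extending past a boundary are
        clipped with a warning.
    """
    labels = list(coverage.keys())
    for lab in labels:
        if lab not in totals or totals[lab] <= 0:
            raise ValueError(f"missing or non-positive library total for {lab}")
    if zt is None:
        zt = [float(str(lab)[2:].split("_")[0]) for lab in labels]
    ids = list(windows.keys())
    values = np.zeros((len(ids), len(labels)))
    for i, fid in enumerate(ids):
        win = windows[fid]
        start, end = win.start, win.end
        if chrom_bounds is not None and win.chrom in chrom_bounds:
            bound = chrom_bounds[win.chrom]
            if start < 0 or end > bound:
                warnings.warn(f"{fid}: window clipped to chromosome bounds")
                start, end = max(start, 0), min(end, bound)
        for j, lab in enumerate(labels):
            strands = coverage[lab]
            if win.strand not in strands:
                raise ValueError(f"no {win.strand} strand coverage for timepoint {lab}")
            count = strands[win.strand].window_sum(win.chrom, start, end)
            values[i, j] = rpktm(count, win.length, totals[lab])
    df = pd.DataFrame(values, index=ids, columns=labels)
    return TimeCourseMatrix(df, np.asarray(zt, dtype=float), unit)


# ---------------------------------------------------------------------------
# enhancer RNA locus filtering
# ---------------------------------------------------------------------------

_ERNA_FDR = 1e-3
_ERNA_FOLD = 3.0
_TSS_EXCLUSION = 300


def filter_erna_peaks(peaks, tss_list) -> list:
    """Keep candidate eRNA loci passing significance and TSS-distance rules.

    A peak is retained iff FDR < 0.001, fold change > 3, and its center lies
    more than 300 bp from every annotated TSS.
    """
    tss = np.sort(np.asarray(list(tss_list), dtype=float))
    kept = []
    for pk in peaks:
        if pk.fdr is None or not np.isfinite(pk.fdr):
            raise ValueError(f"{pk.id}: missing score column 'fdr'")
        if pk.fold_change is None or not np.isfinite(pk.fold_change):
            raise ValueError(f"{pk.id}: missing score column 'fold_change'")
        if not (pk.fdr < _ERNA_FDR and pk.fold_change > _ERNA_FOLD):
            continue
        if tss.size:
            idx = np.searchsorted(tss, pk.center)
            dist = min(
                abs(pk.center - tss[max(idx - 1, 0)]),
                abs(pk.center - tss[min(idx, tss.size - 1)]),
            )
            if dist <= _TSS_EXCLUSION:
                continue
        kept.append(pk)
    return kept


# ---------------------------------------------------------------------------
# translation rate
# ---------------------------------------------------------------------------


def translation_rate(
    ribo: TimeCourseMatrix,
    rna: TimeCourseMatrix,
    floor: float = 0.1,
    max_missing_frac: float = 0.25,
):
    """Per-gene translation rate: footprint density over mRNA density.

    TE(g, t) = ribo(g, t) / rna(g, t) where rna >= ``floor`` (RPKM); below
    the floor the ratio is left missing rather than exploding.  The two
    matrices are intersected on shared ZT labels and feature ids.  Returns
    ``(te_matrix, usable)`` where ``usable`` flags genes with at most
    ``max_missing_frac`` missing timepoints.
    """
    shared_cols = [c for c in ribo.data.columns if c in set(rna.data.columns)]
    if not shared_cols:
        raise ValueError("ribo and rna matrices share no ZT timepoints")
    shared_ids = [g for g in ribo.feature_ids if g in set(rna.feature_ids)]
    col_idx = [list(ribo.data.columns).index(c) for c in shared_cols]
    zt = ribo.zt[col_idx]
    r = ribo.data.loc[shared_ids, shared_cols].to_numpy(dtype=float)
    m = rna.data.loc[shared_ids, shared_cols].to_numpy(dtype=float)
    te = np.full_like(r, np.nan)
    ok = np.isfinite(m) & np.isfinite(r) & (m >= floor)
    te[ok] = r[ok] / m[ok]
    df = pd.DataFrame(te, index=shared_ids, columns=shared_cols)
    usable = pd.Series(
        (~np.isfinite(te)).mean(axis=1) <= max_missing_frac, index=shared_ids, name="usable"
    )
    return TimeCourseMatrix(df, zt, "TE"), usable
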