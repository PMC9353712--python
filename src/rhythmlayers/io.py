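"""File formats: bedGraph coverage, GTF annotation, BED peak tables, TSV.

Internal coordinates are 0-based half-open; GTF is read and written in its
native 1-based closed convention and converted at the boundary.  BED and
bedGraph are natively 0-based half-open and pass through unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .core import TimeCourseMatrix
from .quantify import EnhancerLocus, GeneModel

__all__ = [
    "BedGraph",
    "read_bedgraph",
    "write_bedgraph",
    "read_gtf",
    "write_gtf",
    "read_bed",
    "read_peaks",
    "write_peaks",
    "read_matrix",
    "write_matrix",
    "read_pairs",
    "write_pairs",
    "load_config",
]


# ---------------------------------------------------------------------------
# bedGraph coverage
# ---------------------------------------------------------------------------


class BedGraph:
    """Single-strand coverage as merged, non-overlapping intervals.

    Overlapping input intervals are merged by summing their values (depth
    addition), so ``window_sum`` is linear in the input lines.
    """

    def __init__(self, df: pd.DataFrame):
        cols = ["chrom", "start", "end", "value"]
        if list(df.columns) != cols:
            df = df.copy()
            df.columns = cols
        self._by_chrom = {}
        for chrom, grp in df.groupby("chrom", sort=True):
            self._by_chrom[chrom] = self._merge(grp)

    @staticmethod
    def _merge(grp: pd.DataFrame):
        # sweep line: breakpoints where summed depth changes
        starts = grp["start"].to_numpy(dtype=np.int64)
        ends = grp["end"].to_numpy(dtype=np.int64)
        vals = grp["value"].to_numpy(dtype=float)
        if np.any(starts >= ends):
            raise ValueError("bedGraph interval with start >= end")
        pos = np.concatenate([starts, ends])
        delta = np.concatenate([vals, -vals])
        order = np.argsort(pos, kind="stable")
        pos, delta = pos[order], delta[order]
        uniq, idx = np.unique(pos, return_index=True)
        depth = np.add.reduceat(delta, idx)
        cum = np.cumsum(depth)
        return uniq, cum  # depth of [uniq[i], uniq[i+1]) is cum[i]

    def window_sum(self, chrom: str, start: int, end: int) -> float:
        """Sum of value x overlapped bp within [start, end)."""
        if chrom not in self._by_chrom or start >= end:
            return 0.0
        edges, cum = self._by_chrom[chrom]
        if edges.size == 0:
            return 0.0
        bounds = np.clip(edges, start, end)
        widths = np.diff(np.append(bounds, end))
        return float(np.sum(widths * cum))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for chrom in sorted(self._by_chrom):
            edges, cum = self._by_chrom[chrom]
            for i in range(edges.size - 1):
                if cum[i] != 0:
                    rows.append((chrom, int(edges[i]), int(edges[i + 1]), float(cum[i])))
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


def read_bedgraph(path) -> BedGraph:
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=["chrom", "start", "end", "value"],
            dtype={"chrom": str, "start": np.int64, "end": np.int64, "value": float},
        )
    except (ValueError, pd.errors.ParserError) as exc:
        raise ValueError(f"{path}: malformed bedGraph ({exc})") from exc
    return BedGraph(df)


def write_bedgraph(bg: BedGraph | pd.DataFrame, path) -> None:
    df = bg.to_frame() if isinstance(bg, BedGraph) else bg
    df.to_csv(path, sep="\t", header=False, index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# GTF annotation
# ---------------------------------------------------------------------------


def _gtf_attributes(raw: str) -> dict:
    out = {}
    for field in raw.rstrip(";").split(";"):
        field = field.strip()
        if not field:
            continue
        key, _, val = field.partition(" ")
        out[key] = val.strip().strip('"')
    return out


def read_gtf(path) -> list:
    """Parse gene (and exon) records into :class:`GeneModel` objects.

    GTF is 1-based closed; internal coordinates are 0-based half-open, so
    ``start -> start - 1`` and ``end`` stays.  Strand is required.
    """
    genes, exons = {}, {}
    order = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GTF columns")
            chrom, _, feature, start1, end1, _, strand, _, attrs = parts[:9]
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{lineno}: unknown strand {strand!r}")
            start = int(start1) - 1
            end = int(end1)
            if start < 0 or start >= end:
                raise ValueError(f"{path}:{lineno}: invalid coordinates after conversion")
            gid = _gtf_attributes(attrs).get("gene_id")
            if gid is None:
                raise ValueError(f"{path}:{lineno}: missing gene_id attribute")
            if feature == "gene":
                genes[gid] = (chrom, strand, start, end)
                order.append(gid)
            elif feature == "exon":
                exons.setdefault(gid, []).append((start, end))
    models = []
    for gid in order:
        chrom, strand, start, end = genes[gid]
        tss, tes = (start, end) if strand == "+" else (end, start)
        models.append(
            GeneModel(
                id=gid, chrom=chrom, strand=strand, tss=tss, tes=tes,
                exons=tuple(sorted(exons.get(gid, ()))),
            )
        )
    return models


def write_gtf(genes, path, source: str = "rhythmlayers") -> None:
    with open(path, "w") as fh:
        for g in genes:
            start, end = g.span
            fh.write(
                "\t".join(
                    [
                        g.chrom, source, "gene", str(start + 1), str(end), ".",
                        g.strand, ".", f'gene_id "{g.id}";',
                    ]
                )
                + "\n"
            )
            for s, e in g.exons:
                fh.write(
                    "\t".join(
                        [
                            g.chrom, source, "exon", str(s + 1), str(e), ".",
                            g.strand, ".", f'gene_id "{g.id}";',
                        ]
                    )
                    + "\n"
                )


def read_bed(path) -> list:
    """BED (>= 3 columns, native 0-based half-open) -> interval list.

    Strand is taken from column 6 when present, '.' otherwise.
    """
    from .quantify import GenomicInterval

    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected at least 3 BED columns")
            strand = parts[5] if len(parts) >= 6 else "."
            if strand not in ("+", "-", "."):
                raise ValueError(f"{path}:{lineno}: unknown strand {strand!r}")
            intervals.append(
                GenomicInterval(parts[0], int(parts[1]), int(parts[2]), strand)
            )
    return intervals


# ---------------------------------------------------------------------------
# peak tables (BED6 + fdr + fold_change)
# ---------------------------------------------------------------------------

_PEAK_COLS = ["chrom", "start", "end", "name", "score", "strand", "fdr", "fold_change"]


def read_peaks(path) -> list:
    """BED6+2 peak table -> :class:`EnhancerLocus` list (center = midpoint)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < len(_PEAK_COLS):
        missing = _PEAK_COLS[df.shape[1]:]
        raise ValueError(f"{path}: missing score column(s) {', '.join(missing)}")
    df = df.iloc[:, : len(_PEAK_COLS)]
    df.columns = _PEAK_COLS
    loci = []
    for row in df.itertuples(index=False):
        center = (int(row.start) + int(row.end)) // 2
        loci.append(
            EnhancerLocus(
                id=str(row.name), chrom=str(row.chrom), strand=str(row.strand),
                center=center, fdr=float(row.fdr), fold_change=float(row.fold_change),
            )
        )
    return loci


def write_peaks(loci, path, half_width: int = 500) -> None:
    rows = [
        (
            l.chrom, l.center - half_width, l.center + half_width, l.id, 0,
            l.strand, l.fdr, l.fold_change,
        )
        for l in loci
    ]
    pd.DataFrame(rows, columns=_PEAK_COLS).to_csv(
        path, sep="\t", header=False, index=False, float_format="%.6g"
    )


# ---------------------------------------------------------------------------
# matrices, pair maps, config
# ---------------------------------------------------------------------------


def read_matrix(path) -> TimeCourseMatrix:
    return TimeCourseMatrix.from_tsv(path)


def write_matrix(matrix: TimeCourseMatrix, path) -> None:
    matrix.to_tsv(path)


def read_pairs(path) -> list:
    """Two-column TSV (id_a, id_b) -> list of tuples; header optional."""
    pairs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected two tab-separated columns")
            if lineno == 1 and parts[0].lower() in ("id_a", "from"):
                continue
            pairs.append((parts[0], parts[1]))
    return pairs


def write_pairs(pairs, path) -> None:
    with open(path, "w") as fh:
        for a, b in pairs:
            fh.write(f"{a}\t{b}\n")


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a key/value mapping")
    return cfg
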