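"""Shared containers: sampling designs and feature-by-timepoint matrices.

Every omics layer in the pipeline is reduced to a :class:`TimeCourseMatrix`
(features x samples), where each sample column carries a Zeitgeber-time (ZT)
label in hours.  ZT0 is lights-on, ZT12 lights-off.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SamplingDesign", "TimeCourseMatrix"]


@dataclass(frozen=True)
class SamplingDesign:
    """Time-course sampling scheme over one light-dark cycle.

    Parameters
    ----------
    timepoints
        Strictly increasing ZT hours, all in ``[0, period_day)``.
        Default: 8 timepoints every 3 h (ZT0..ZT21).
    period_day
        Length of the environmental cycle in hours (24).
    replicates
        Independent samples per timepoint (>= 1).
    """

    timepoints: tuple = (0.0, 3.0, 6.0, 9.0, 12.0, 15.0, 18.0, 21.0)
    period_day: float = 24.0
    replicates: int = 1

    def __post_init__(self):
        tp = tuple(float(t) for t in self.timepoints)
        object.__setattr__(self, "timepoints", tp)
        if len(tp) == 0:
            raise ValueError("design needs at least one timepoint")
        if any(b <= a for a, b in zip(tp, tp[1:])):
            raise ValueError("timepoints must be strictly increasing")
        if tp[0] < 0 or tp[-1] >= self.period_day:
            raise ValueError(f"timepoints must lie in [0, {self.period_day})")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    @property
    def n_samples(self) -> int:
        return len(self.timepoints) * self.replicates

    @property
    def sample_times(self) -> np.ndarray:
        """ZT hour of every sample column (replicates repeat the hour)."""
        return np.repeat(np.asarray(self.timepoints, dtype=float), self.replicates)

    @property
    def sample_labels(self) -> list:
        labels = []
        for t in self.timepoints:
            for r in range(self.replicates):
                base = f"ZT{t:g}"
                labels.append(base if self.replicates == 1 else f"{base}_r{r + 1}")
        return labels


@dataclass
class TimeCourseMatrix:
    """Features x samples abundance table with ZT hour per column.

    ``unit`` records the abundance scale (RPKM, RPKTM, activity, ratio, au).
    Ratio-type matrices may contain NaN (missing); abundance-type matrices
    must be non-negative.
    """

    data: pd.DataFrame
    zt: np.ndarray
    unit: str = "au"

    def __post_init__(self):
        self.zt = np.asarray(self.zt, dtype=float)
        if self.zt.shape[0] != self.data.shape[1]:
            raise ValueError(
                f"zt has {self.zt.shape[0]} entries for {self.data.shape[1]} columns"
            )

    # -- basic accessors -------------------------------------------------
    @property
    def feature_ids(self) -> list:
        return list(self.data.index)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    def subset(self, features) -> "TimeCourseMatrix":
        return TimeCourseMatrix(self.data.loc[list(features)], self.zt, self.unit)

    # -- TSV round-trip ---------------------------------------------------
    def to_tsv(self, path) -> None:
        """Write as TSV with ``# unit=`` / ``# zt=`` metadata header lines."""
        with open(path, "w") as fh:
            fh.write(f"# unit={self.unit}\n")
            fh.write("# zt=" + ",".join(f"{t:g}" for t in self.zt) + "\n")
            self.data.to_csv(fh, sep="\t", index_label="feature", float_format="%.10g")

    @classmethod
    def from_tsv(cls, path) -> "TimeCourseMatrix":
        unit = "au"
        zt = None
        lines = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if line.startswith("#"):
                    body = line[1:].strip()
                    if body.startswith("unit="):
                        unit = body[5:]
                    elif body.startswith("zt="):
                        try:
                            zt = np.array(
                                [float(x) for x in body[3:].split(",") if x != ""]
                            )
                        except ValueError as exc:
                            raise ValueError(
                                f"{path}:{lineno}: malformed zt header"
                            ) from exc
                    continue
                lines.append((lineno, line.rstrip("\n")))
        if not lines:
            return cls(pd.DataFrame(), np.empty(0), unit)
        header = lines[0][1].split("\t")
        ncol = len(header)
        rows, index = [], []
        for lineno, line in lines[1:]:
            parts = line.split("\t")
            if len(parts) != ncol:
                raise ValueError(f"{path}:{lineno}: expected {ncol} columns, got {len(parts)}")
            index.append(parts[0])
            try:
                rows.append([float(x) if x != "" else np.nan for x in parts[1:]])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric cell") from exc
        df = pd.DataFrame(rows, index=index, columns=header[1:])
        if zt is None:
            # fall back to parsing ZT labels like "ZT3" / "ZT3_r2"
            zt = np.array([float(c[2:].split("_")[0]) for c in df.columns])
        return cls(df, zt, unit)
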