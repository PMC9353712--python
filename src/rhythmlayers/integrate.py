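"""Cross-layer integration: rhythm conservation, disruption, enhancement.

Adjacent regulatory layers (transcription -> mature RNA -> protein -> DBP
activity) are compared gene by gene among genes detected in both layers:
rhythmic in both = conserved, upstream only = disrupted, downstream only =
enhanced.  Layer-specific rhythms are then attributed to mechanisms:
rhythmic translation rate for protein-specific genes, phosphosite presence
for DBP-specific genes, and rhythmic enhancer linkage for DBP -> enhancer ->
transcription triads.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "LayerComparison",
    "MechanismAttribution",
    "TeVariationResult",
    "detection_filter",
    "classify_pair",
    "te_variation_compare",
    "attribute_translation",
    "attribute_phosphorylation",
    "link_triads",
    "pair_enhancers_to_genes",
]

CATEGORIES = ("conserved", "disrupted", "enhanced", "neither")


# ---------------------------------------------------------------------------
# detection filter
# ---------------------------------------------------------------------------


def detection_filter(matrices, floor: float = 0.0) -> set:
    """Features whose mean abundance exceeds ``floor`` in every matrix.

    Used to keep only proteins detected in all independent datasets.
    """
    if not matrices:
        raise ValueError("at least one matrix is required")
    common: set | None = None
    for m in matrices:
        means = m.data.mean(axis=1, skipna=True)
        detected = set(means.index[means > floor])
        common = detected if common is None else common & detected
    if not common:
        logger.warning("detection filter: no feature detected in every dataset")
        return set()
    return common


# ---------------------------------------------------------------------------
# adjacent-layer classification
# ---------------------------------------------------------------------------


@dataclass
class LayerComparison:
    """Per-gene rhythm-category comparison between two adjacent layers.

    ``conserved_fraction`` is |conserved| / (|conserved| + |disrupted|): the
    share of upstream-rhythmic genes (detected in both layers) that stay
    rhythmic downstream.  NaN when no upstream-rhythmic gene exists.
    """

    up_layer: str
    down_layer: str
    categories: pd.Series
    counts: dict = field(default_factory=dict)

    def genes(self, category: str) -> list:
        if category not in CATEGORIES:
            raise ValueError(f"unknown category {category!r}")
        return list(self.categories.index[self.categories == category])

    @property
    def conserved_fraction(self) -> float:
        denom = self.counts.get("conserved", 0) + self.counts.get("disrupted", 0)
        if denom == 0:
            return float("nan")
        return self.counts["conserved"] / denom


def classify_pair(
    calls_up: pd.Series,
    calls_down: pd.Series,
    detected_both=None,
    up_layer: str = "up",
    down_layer: str = "down",
) -> LayerComparison:
    """Classify genes by rhythm retention between two adjacent layers.

    ``calls_up``/``calls_down`` are boolean rhythm flags indexed by gene.
    Only genes in ``detected_both`` (default: ids present in both call
    sets) are classified; genes missing a call in either layer are dropped
    with a log entry.
    """
    if detected_both is None:
        detected_both = set(calls_up.index) & set(calls_down.index)
    genes = [g for g in calls_up.index if g in set(detected_both)]
    missing = [g for g in genes if g not in calls_down.index]
    skipped = [
        g for g in genes
        if g in calls_down.index
        and (pd.isna(calls_up.loc[g]) or pd.isna(calls_down.loc[g]))
    ]
    if missing or skipped:
        logger.info(
            "%s->%s: excluded %d gene(s) lacking a call in one layer",
            up_layer, down_layer, len(missing) + len(skipped),
        )
    keep = [g for g in genes if g in calls_down.index and g not in set(skipped)]
    up = calls_up.loc[keep].astype(bool)
    down = calls_down.loc[keep].astype(bool)
    cats = pd.Series(
        np.select(
            [up & down, up & ~down, ~up & down],
            ["conserved", "disrupted", "enhanced"],
            default="neither",
        ),
        index=keep,
        name=f"category_{up_layer}_{down_layer}",
    )
    counts = {c: int((cats == c).sum()) for c in CATEGORIES}
    return LayerComparison(
        up_layer=up_layer, down_layer=down_layer, categories=cats, counts=counts
    )


# ---------------------------------------------------------------------------
# translation-rate variation (conserved vs disrupted)
# ---------------------------------------------------------------------------


@dataclass
class TeVariationResult:
    cv: pd.Series
    mean_conserved: float
    mean_disrupted: float
    t_statistic: float
    p_value: float
    n_conserved: int
    n_disrupted: int


def te_variation_compare(te, conserved, disrupted) -> TeVariationResult:
    """Compare translation-rate variability between two gene groups.

    Per gene the coefficient of variation (sd/mean over timepoints) of the
    translation-rate series; groups compared with a two-sided equal-variance
    Student's t-test.  Genes absent from the TE matrix or with undefined CV
    are dropped; each group needs at least two usable genes.
    """
    vals = te.data.to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv_arr = np.nanstd(vals, axis=1, ddof=1) / np.nanmean(vals, axis=1)
    cv = pd.Series(cv_arr, index=te.feature_ids, name="te_cv")

    def usable(group):
        g = [x for x in group if x in cv.index and np.isfinite(cv.loc[x])]
        return cv.loc[g]

    cv_c, cv_d = usable(conserved), usable(disrupted)
    if len(cv_c) < 2 or len(cv_d) < 2:
        raise ValueError("each group needs at least two genes with usable TE")
    t, p = stats.ttest_ind(cv_c, cv_d, equal_var=True)
    return TeVariationResult(
        cv=cv,
        mean_conserved=float(cv_c.mean()),
        mean_disrupted=float(cv_d.mean()),
        t_statistic=float(t),
        p_value=float(p),
        n_conserved=len(cv_c),
        n_disrupted=len(cv_d),
    )


# ---------------------------------------------------------------------------
# mechanism attribution
# ---------------------------------------------------------------------------


@dataclass
class MechanismAttribution:
    analyzed: list
    dependent: list
    unknown: list = field(default_factory=list)

    @property
    def fraction_dependent(self) -> float:
        denom = len(self.analyzed) - len(self.unknown)
        if denom == 0:
            return float("nan")
        return len(self.dependent) / denom


def attribute_translation(protein_specific, te_calls: pd.Series) -> MechanismAttribution:
    """Share of protein-specific rhythmic genes with rhythmic translation.

    ``protein_specific`` is the enhanced category of the mature-RNA ->
    protein comparison; ``te_calls`` boolean rhythm flags of the
    translation-rate series.  Genes without TE data stay in the analyzed
    set but are excluded from the fraction's denominator.
    """
    analyzed = list(protein_specific)
    unknown = [g for g in analyzed if g not in te_calls.index or pd.isna(te_calls.get(g))]
    if unknown:
        logger.info("translation attribution: %d gene(s) lack TE data", len(unknown))
    dependent = [
        g for g in analyzed if g not in set(unknown) and bool(te_calls.loc[g])
    ]
    return MechanismAttribution(analyzed=analyzed, dependent=dependent, unknown=unknown)


def attribute_phosphorylation(dbp_specific, phospho_detect: dict) -> MechanismAttribution:
    """Share of DBP-specific rhythmic genes carrying a detected phosphosite.

    Dependence is binary phosphosite presence; a DBP absent from the
    phosphorylation table counts as not phosphorylated (logged).
    """
    analyzed = list(dbp_specific)
    absent = [g for g in analyzed if g not in phospho_detect]
    if absent:
        logger.info("phospho attribution: %d gene(s) absent from the table", len(absent))
    dependent = [g for g in analyzed if bool(phospho_detect.get(g, False))]
    return MechanismAttribution(analyzed=analyzed, dependent=dependent)


# ---------------------------------------------------------------------------
# regulatory triads
# ---------------------------------------------------------------------------


def link_triads(
    dbp_calls: pd.Series,
    erna_calls: pd.Series,
    txn_calls: pd.Series,
    dbp_enhancer_pairs,
    enhancer_gene_pairs,
) -> pd.DataFrame:
    """DBP -> enhancer -> gene triads in which all three series are rhythmic.

    Pairing maps must reference ids present in the corresponding call
    tables; dangling ids are rejected wholesale so silent partial joins
    cannot occur.
    """
    dangling = [d for d, e in dbp_enhancer_pairs if d not in dbp_calls.index]
    dangling += [e for d, e in dbp_enhancer_pairs if e not in erna_calls.index]
    dangling += [e for e, g in enhancer_gene_pairs if e not in erna_calls.index]
    dangling += [g for e, g in enhancer_gene_pairs if g not in txn_calls.index]
    if dangling:
        raise ValueError(f"pairing maps reference unknown ids: {sorted(set(dangling))}")
    gene_by_enh: dict = {}
    for e, g in enhancer_gene_pairs:
        gene_by_enh.setdefault(e, []).append(g)
    rows = []
    for d, e in dbp_enhancer_pairs:
        for g in gene_by_enh.get(e, []):
            all_rhythmic = bool(dbp_calls.loc[d]) and bool(erna_calls.loc[e]) and bool(
                txn_calls.loc[g]
            )
            if all_rhythmic:
                rows.append((d, e, g))
    return pd.DataFrame(rows, columns=["dbp", "enhancer", "gene"])


def pair_enhancers_to_genes(enhancers, genes, max_dist: int = 100_000) -> list:
    """Default enhancer->gene pairing for real data: nearest TSS <= 100 kb."""
    gene_tss = [(g.tss, g.id, g.chrom) for g in genes]
    pairs = []
    for e in enhancers:
        best = None
        for tss, gid, chrom in gene_tss:
            if chrom != e.chrom:
                continue
            dist = abs(e.center - tss)
            if dist <= max_dist and (best is None or dist < best[0]):
                best = (dist, gid)
        if best is not None:
            pairs.append((e.id, best[1]))
    return pairs
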