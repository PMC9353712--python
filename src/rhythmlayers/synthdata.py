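"""Coupled multi-layer diurnal time-course generator with known ground truth.

The generator emulates seven omics profiles over one light-dark cycle --
nascent transcription, mature RNA, protein (three independent datasets), DNA
binding protein (DBP) activity, enhancer RNA, translation rate, and
phosphorylation -- each sampled at 8 timepoints (3 h apart) by default.

Each feature oscillates as a cosinor

    x(t) = baseline + amplitude * cos(2*pi*(t - phase)/period) + eps,
    eps ~ Normal(0, noise_sd^2), truncated at 0,

and layers are coupled through a regulatory cascade: mature RNA inherits the
transcription phase (plus an optional processing delay), protein is the
product of the realized mature RNA and translation-rate series (so rhythmic
protein can arise from rhythmic RNA or from rhythmic translation alone), and
DBP activity inherits the protein phase.  Planted per-gene labels (rhythmic
per layer, conserved/disrupted/enhanced per adjacent layer pair) make every
downstream stage testable without external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import SamplingDesign, TimeCourseMatrix
from .quantify import EnhancerLocus, GeneModel, erna_window, gene_body_window

__all__ = [
    "CosinorParams",
    "MultiLayerTruth",
    "LayerBundle",
    "SimulatedCoverage",
    "LAYER_CHAIN",
    "LAYERS",
    "generate_timecourse",
    "generate_multilayer",
    "generate_coverage",
    "truth_table",
    "make_truth",
    "make_gene_models",
    "make_enhancer_loci",
    "pair_categories",
]

LAYER_CHAIN = ("transcription", "mature_rna", "protein", "dbp")
LAYERS = LAYER_CHAIN + ("erna", "translation_rate", "phospho")

_UPSTREAM = {"mature_rna": "transcription", "protein": "mature_rna", "dbp": "protein"}


@dataclass(frozen=True)
class CosinorParams:
    """Oscillation parameters of one feature in one layer.

    ``amplitude <= baseline`` keeps the expected abundance positive;
    ``phase`` is the ZT hour of the peak.
    """

    baseline: float
    amplitude: float = 0.0
    phase: float = 0.0
    period: float = 24.0
    noise_sd: float = 0.0

    def __post_init__(self):
        vals = (self.baseline, self.amplitude, self.phase, self.period, self.noise_sd)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("non-finite cosinor parameter")
        if self.baseline <= 0:
            raise ValueError("baseline must be positive")
        if not (0 <= self.amplitude <= self.baseline):
            raise ValueError("amplitude must lie in [0, baseline]")
        if not (20.0 <= self.period <= 28.0):
            raise ValueError("period must lie in [20, 28] h")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        object.__setattr__(self, "phase", float(self.phase) % 24.0)

    def mean_series(self, times) -> np.ndarray:
        t = np.asarray(times, dtype=float)
        return self.baseline + self.amplitude * np.cos(
            2 * np.pi * (t - self.phase) / self.period
        )


def generate_timecourse(params: dict, design: SamplingDesign, seed: int) -> TimeCourseMatrix:
    """Simulate one omics profile: cosinor mean + truncated Gaussian noise.

    ``params`` maps feature id -> :class:`CosinorParams`.  Identical seeds
    give bitwise-identical matrices.
    """
    if not params:
        raise ValueError("params must be non-empty")
    for fid, p in params.items():
        vals = (p.baseline, p.amplitude, p.phase, p.period, p.noise_sd)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError(f"{fid}: non-finite cosinor parameter")
    times = design.sample_times
    ids = list(params.keys())
    means = np.stack([params[g].mean_series(times) for g in ids])
    sds = np.array([params[g].noise_sd for g in ids])[:, None]
    rng = np.random.default_rng(seed)
    values = np.maximum(0.0, means + rng.standard_normal(means.shape) * sds)
    df = pd.DataFrame(values, index=ids, columns=design.sample_labels)
    return TimeCourseMatrix(df, times, "au")


# ---------------------------------------------------------------------------
# multi-layer truth
# ---------------------------------------------------------------------------


@dataclass
class MultiLayerTruth:
    """Planted per-layer oscillation parameters plus the coupling wiring.

    ``rhythm_source`` per layer and gene is ``inherited`` (phase copied from
    the upstream layer), ``layer_specific`` (own phase) or ``none`` (flat).
    ``enhancer_gene_pairs`` and ``dbp_enhancer_pairs`` wire the regulatory
    triads; ``phospho_present`` marks genes with a detected phosphosite.
    """

    params: dict
    rhythm_source: dict
    phospho_present: dict = field(default_factory=dict)
    enhancer_gene_pairs: list = field(default_factory=list)
    dbp_enhancer_pairs: list = field(default_factory=list)
    processing_delay: float = 0.0

    @property
    def genes(self) -> list:
        return list(self.params.get("transcription", {}).keys())

    @property
    def erna_ids(self) -> list:
        return list(self.params.get("erna", {}).keys())

    def validate(self) -> None:
        genes = set(self.genes)
        ernas = set(self.erna_ids)
        for layer, sources in self.rhythm_source.items():
            if layer not in self.params:
                raise ValueError(f"rhythm_source for unknown layer {layer}")
            missing = set(sources) - set(self.params[layer])
            if missing:
                raise ValueError(f"{layer}: rhythm_source for unknown features {sorted(missing)}")
        for erna, gene in self.enhancer_gene_pairs:
            if erna not in ernas or gene not in genes:
                raise ValueError(f"enhancer_gene pair ({erna}, {gene}) references unknown ids")
        for dbp, erna in self.dbp_enhancer_pairs:
            if dbp not in genes or erna not in ernas:
                raise ValueError(f"dbp_enhancer pair ({dbp}, {erna}) references unknown ids")
        eff = resolve_effective(self)
        for layer, up in _UPSTREAM.items():
            for g, src in self.rhythm_source.get(layer, {}).items():
                if src != "inherited":
                    continue
                upstream_rhythmic = eff[up][g].amplitude > 0
                if layer == "protein":
                    te = eff.get("translation_rate", {}).get(g)
                    upstream_rhythmic = upstream_rhythmic or (te is not None and te.amplitude > 0)
                if not upstream_rhythmic:
                    raise ValueError(
                        f"{layer}/{g}: marked 'inherited' but no upstream rhythm exists"
                    )


def resolve_effective(truth: MultiLayerTruth) -> dict:
    """Planted params after inheritance resolution, per layer and feature.

    An ``inherited`` feature copies phase (plus the processing delay for
    mature RNA) and period from its upstream layer; a ``none`` feature has
    its amplitude forced to zero.  For protein the inherited phase follows
    mature RNA when the RNA is rhythmic, otherwise the translation rate
    (multiplicative coupling).
    """
    eff: dict = {}
    for layer in LAYERS:
        if layer not in truth.params:
            continue
        eff[layer] = {}
        up = _UPSTREAM.get(layer)
        for g, p in truth.params[layer].items():
            src = truth.rhythm_source.get(layer, {}).get(g, "layer_specific")
            if src == "none":
                eff[layer][g] = replace(p, amplitude=0.0)
            elif src == "inherited" and up is not None:
                upstream = eff[up][g]
                phase, period = upstream.phase, upstream.period
                if layer == "mature_rna":
                    phase = (phase + truth.processing_delay) % 24.0
                if layer == "protein" and upstream.amplitude == 0:
                    te = eff.get("translation_rate", {}).get(g)
                    if te is not None and te.amplitude > 0:
                        phase, period = te.phase, te.period
                eff[layer][g] = replace(p, phase=phase, period=period)
            else:
                eff[layer][g] = p
    return eff


@dataclass
class LayerBundle:
    """One TimeCourseMatrix per layer plus the truth that generated them."""

    matrices: dict
    truth: MultiLayerTruth
    design: SamplingDesign
    seed: int
    effective: dict = field(default_factory=dict)


def generate_multilayer(truth: MultiLayerTruth, design: SamplingDesign, seed: int) -> LayerBundle:
    """Simulate every layer of a :class:`MultiLayerTruth`, coupled.

    Transcription, mature RNA, eRNA, translation rate, DBP and
    phosphorylation are cosinor draws from the inheritance-resolved
    parameters.  Protein is generated from the *realized* mature RNA and
    translation-rate series (protein ~ RNA x TE, rescaled to the protein
    baseline) for ``inherited`` genes, so noise propagates through the
    cascade the way abundances do.
    """
    truth.validate()
    # resolve_effective already orders layers so that dependencies exist
    eff = resolve_effective(truth)
    seeds = {layer: s.generate_state(1)[0] % (2**31) for layer, s in
             zip(LAYERS, np.random.SeedSequence(seed).spawn(len(LAYERS)))}
    times = design.sample_times
    matrices: dict = {}
    unit = {"transcription": "RPKTM", "mature_rna": "RPKM", "protein": "intensity",
            "dbp": "activity", "erna": "RPKTM", "translation_rate": "TE",
            "phospho": "intensity"}
    for layer in ("transcription", "mature_rna", "erna", "translation_rate", "dbp", "phospho"):
        if layer not in eff or not eff[layer]:
            continue
        m = generate_timecourse(eff[layer], design, seeds[layer])
        m.unit = unit[layer]
        matrices[layer] = m

    if "protein" in eff and eff["protein"]:
        ids = list(eff["protein"].keys())
        rna = matrices["mature_rna"]
        te = matrices.get("translation_rate")
        means = np.empty((len(ids), times.shape[0]))
        for i, g in enumerate(ids):
            p = eff["protein"][g]
            src = truth.rhythm_source.get("protein", {}).get(g, "layer_specific")
            if src == "inherited":
                rna_row = rna.data.loc[g].to_numpy(dtype=float)
                rna_base = truth.params["mature_rna"][g].baseline
                scale = rna_row / rna_base
                if te is not None and g in te.data.index:
                    te_row = te.data.loc[g].to_numpy(dtype=float)
                    scale = scale * te_row / truth.params["translation_rate"][g].baseline
                means[i] = p.baseline * scale
            else:
                means[i] = p.mean_series(times)
        sds = np.array([eff["protein"][g].noise_sd for g in ids])[:, None]
        rng = np.random.default_rng(seeds["protein"])
        values = np.maximum(0.0, means + rng.standard_normal(means.shape) * sds)
        matrices["protein"] = TimeCourseMatrix(
            pd.DataFrame(values, index=ids, columns=design.sample_labels),
            times, unit["protein"],
        )
    return LayerBundle(matrices=matrices, truth=truth, design=design, seed=seed, effective=eff)


# ---------------------------------------------------------------------------
# truth table and planted categories
# ---------------------------------------------------------------------------


def pair_categories(up_rhythmic: bool, down_rhythmic: bool) -> str:
    if up_rhythmic and down_rhythmic:
        return "conserved"
    if up_rhythmic:
        return "disrupted"
    if down_rhythmic:
        return "enhanced"
    return "neither"


def truth_table(truth: MultiLayerTruth) -> pd.DataFrame:
    """Lossless per-gene label table: planted rhythmicity and categories.

    One row per gene; per layer the resolved phase/period/amplitude/
    baseline/noise, the rhythm source, and the planted rhythmic flag; plus
    the planted cross-layer category for every adjacent pair.
    """
    eff = resolve_effective(truth)
    rows = {}
    for g in truth.genes:
        row = {}
        for layer in LAYERS:
            if layer == "erna" or layer not in eff or g not in eff[layer]:
                continue
            p = eff[layer][g]
            row[f"{layer}_rhythmic"] = p.amplitude > 0
            row[f"{layer}_source"] = truth.rhythm_source.get(layer, {}).get(g, "layer_specific")
            row[f"{layer}_phase"] = p.phase
            row[f"{layer}_period"] = p.period
            row[f"{layer}_amplitude"] = p.amplitude
            row[f"{layer}_baseline"] = p.baseline
            row[f"{layer}_noise_sd"] = p.noise_sd
        for up, down in zip(LAYER_CHAIN, LAYER_CHAIN[1:]):
            if f"{up}_rhythmic" in row and f"{down}_rhythmic" in row:
                row[f"category_{up}_{down}"] = pair_categories(
                    row[f"{up}_rhythmic"], row[f"{down}_rhythmic"]
                )
        if "translation_rate" in eff and g in eff["translation_rate"]:
            row["te_dependent"] = bool(
                row.get("protein_rhythmic", False)
                and not row.get("mature_rna_rhythmic", False)
                and eff["translation_rate"][g].amplitude > 0
            )
        row["phospho_present"] = bool(truth.phospho_present.get(g, False))
        rows[g] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "gene"
    return df


# ---------------------------------------------------------------------------
# planted-truth builder
# ---------------------------------------------------------------------------


def make_truth(
    pair_counts=((180, 120, 70), (140, 110, 60), (60, 140, 40)),
    n_genes: int = 500,
    baseline: float = 10.0,
    amplitude: float = 3.0,
    noise_sd: float = 1.0,
    te_dependent_fraction: float = 0.45,
    phospho_dependent_fraction: float = 0.625,
    background_phospho_rate: float = 0.3,
    te_cv_conserved: float = 0.05,
    te_cv_disrupted: float = 0.5,
    te_cv_other: float = 0.1,
    n_enhancers: int = 40,
    n_triads: int = 12,
    processing_delay: float = 0.0,
    period: float = 24.0,
    seed: int = 0,
) -> MultiLayerTruth:
    """Plant a multi-layer truth with fixed per-pair category counts.

    ``pair_counts`` gives (conserved, disrupted, enhanced) for the
    transcription->mature RNA, mature RNA->protein and protein->DBP pairs;
    flows must be consistent (rhythmic genes leaving pair i equal those
    entering pair i+1).  Defaults plant conserved fractions of 0.60, 0.56
    and 0.30, a 45% translation-rate-dependent share of protein-specific
    genes, and a 62.5% phosphorylated share of DBP-specific genes --
    matching the regime the pipeline is meant to resolve.  Translation-rate
    variability (CV) is low for genes whose rhythm survives into protein
    and high for genes whose rhythm is lost there.
    """
    (c1, d1, e1), (c2, d2, e2), (c3, d3, e3) = pair_counts
    if c1 + e1 != c2 + d2 or c2 + e2 != c3 + d3:
        raise ValueError("pair_counts flows are inconsistent between adjacent pairs")
    needed = c1 + d1
    if n_genes < needed + max(e1, e2, e3):
        raise ValueError("n_genes too small for the requested planted counts")
    rng = np.random.default_rng(seed)
    genes = [f"gene{i:04d}" for i in range(n_genes)]
    order = list(rng.permutation(genes))

    t_set = order[: c1 + d1]
    nonrhythmic = order[c1 + d1:]
    cons1, disr1 = t_set[:c1], t_set[c1:]
    enh1 = nonrhythmic[:e1]
    r_set = cons1 + enh1
    non_r = [g for g in order if g not in set(r_set)]
    cons2, disr2 = r_set[:c2], r_set[c2:]
    enh2 = [g for g in non_r if g not in set(disr1)][:e2] or non_r[:e2]
    p_set = cons2 + enh2
    non_p = [g for g in order if g not in set(p_set)]
    cons3, disr3 = p_set[:c3], p_set[c3:]
    enh3 = non_p[:e3]
    d_set = cons3 + enh3

    n_te_dep = round(te_dependent_fraction * len(enh2))
    te_dep = set(enh2[:n_te_dep])
    n_phos = round(phospho_dependent_fraction * len(enh3))
    phospho_true = set(enh3[:n_phos])

    def phase() -> float:
        return float(rng.uniform(0.0, 24.0))

    base = dict(baseline=baseline, period=period, noise_sd=noise_sd)
    flat = dict(baseline=baseline, period=period, noise_sd=noise_sd, amplitude=0.0)

    params: dict = {layer: {} for layer in LAYERS}
    source: dict = {layer: {} for layer in LAYERS}

    t_rh, r_rh, p_rh, d_rh = set(t_set), set(r_set), set(p_set), set(d_set)
    for g in genes:
        # transcription
        if g in t_rh:
            params["transcription"][g] = CosinorParams(amplitude=amplitude, phase=phase(), **base)
            source["transcription"][g] = "layer_specific"
        else:
            params["transcription"][g] = CosinorParams(**flat)
            source["transcription"][g] = "none"
        # mature RNA
        if g in r_rh:
            if g in t_rh:  # conserved pair 1: inherit the transcription phase
                params["mature_rna"][g] = CosinorParams(amplitude=amplitude, **base)
                source["mature_rna"][g] = "inherited"
            else:
                params["mature_rna"][g] = CosinorParams(amplitude=amplitude, phase=phase(), **base)
                source["mature_rna"][g] = "layer_specific"
        else:
            params["mature_rna"][g] = CosinorParams(**flat)
            source["mature_rna"][g] = "none"
        # translation rate: rhythmic only when it drives a protein-specific rhythm
        if g in te_dep:
            params["translation_rate"][g] = CosinorParams(
                baseline=1.0, amplitude=0.3, phase=phase(), period=period, noise_sd=0.1
            )
            source["translation_rate"][g] = "layer_specific"
        else:
            cv = (
                te_cv_conserved if g in set(cons2)
                else te_cv_disrupted if g in set(disr2)
                else te_cv_other
            )
            params["translation_rate"][g] = CosinorParams(
                baseline=1.0, amplitude=0.0, period=period, noise_sd=cv
            )
            source["translation_rate"][g] = "none"
        # protein
        if g in p_rh:
            if g in r_rh or g in te_dep:
                params["protein"][g] = CosinorParams(amplitude=amplitude, **base)
                source["protein"][g] = "inherited"
            else:
                params["protein"][g] = CosinorParams(amplitude=amplitude, phase=phase(), **base)
                source["protein"][g] = "layer_specific"
        else:
            params["protein"][g] = CosinorParams(**flat)
            source["protein"][g] = "none"
        # DBP activity
        if g in d_rh:
            if g in p_rh:
                params["dbp"][g] = CosinorParams(amplitude=amplitude, **base)
                source["dbp"][g] = "inherited"
            else:
                params["dbp"][g] = CosinorParams(amplitude=amplitude, phase=phase(), **base)
                source["dbp"][g] = "layer_specific"
        else:
            params["dbp"][g] = CosinorParams(**flat)
            source["dbp"][g] = "none"

    # phosphorylation detection: planted for DBP-specific genes, background rate elsewhere
    phospho_present = {}
    for g in genes:
        if g in set(enh3):
            phospho_present[g] = g in phospho_true
        else:
            phospho_present[g] = bool(rng.uniform() < background_phospho_rate)
    for g in genes:
        if phospho_present[g]:
            params["phospho"][g] = CosinorParams(
                baseline=baseline, amplitude=0.0, period=period, noise_sd=noise_sd
            )
            source["phospho"][g] = "none"

    # enhancers: n_triads fully rhythmic and wired to rhythmic DBPs/genes,
    # plus rhythmic-unlinked and linked-but-arrhythmic decoys
    erna_ids = [f"erna{i:03d}" for i in range(n_enhancers)]
    if n_triads > min(n_enhancers, len(d_set), len(t_set)):
        raise ValueError("n_triads exceeds available rhythmic features")
    dbp_pool = list(rng.permutation(d_set))
    gene_pool = list(rng.permutation(t_set))
    enhancer_gene_pairs, dbp_enhancer_pairs = [], []
    n_decoy = min(5, n_enhancers - n_triads, len(genes) - len(t_set))
    for k, e in enumerate(erna_ids):
        if k < n_triads:
            params["erna"][e] = CosinorParams(amplitude=amplitude, phase=phase(), **base)
            source["erna"][e] = "layer_specific"
            dbp_enhancer_pairs.append((dbp_pool[k], e))
            enhancer_gene_pairs.append((e, gene_pool[k]))
        elif k < n_triads + n_decoy:
            # linked but arrhythmic enhancer: must never yield a triad
            params["erna"][e] = CosinorParams(**flat)
            source["erna"][e] = "none"
            dbp_enhancer_pairs.append((dbp_pool[k % len(dbp_pool)], e))
            enhancer_gene_pairs.append((e, gene_pool[k % len(gene_pool)]))
        elif k % 2 == 0:
            params["erna"][e] = CosinorParams(amplitude=amplitude, phase=phase(), **base)
            source["erna"][e] = "layer_specific"
        else:
            params["erna"][e] = CosinorParams(**flat)
            source["erna"][e] = "none"

    truth = MultiLayerTruth(
        params=params,
        rhythm_source=source,
        phospho_present=phospho_present,
        enhancer_gene_pairs=enhancer_gene_pairs,
        dbp_enhancer_pairs=dbp_enhancer_pairs,
        processing_delay=processing_delay,
    )
    truth.validate()
    return truth


# ---------------------------------------------------------------------------
# toy genome and coverage emission
# ---------------------------------------------------------------------------

TOY_CHROM = "chrT"
TOY_CHROM_LENGTH = 10_000_000

# cycle of body lengths exercising all three window rules
_BODY_LENGTHS = (15_000, 5_000, 1_500, 20_000, 8_000, 3_000)
_GENE_GAP = 4_000


def make_gene_models(gene_ids, seed: int = 0, chrom: str = TOY_CHROM) -> list:
    """Lay genes along the toy chromosome, alternating strands, no overlap."""
    rng = np.random.default_rng(seed)
    genes = []
    cursor = 10_000
    for i, gid in enumerate(gene_ids):
        L = _BODY_LENGTHS[i % len(_BODY_LENGTHS)]
        strand = "+" if i % 2 == 0 else "-"
        start, end = cursor, cursor + L
        if end > TOY_CHROM_LENGTH - 10_000:
            raise ValueError("toy chromosome exhausted; fewer genes or shorter bodies")
        tss, tes = (start, end) if strand == "+" else (end, start)
        genes.append(GeneModel(id=gid, chrom=chrom, strand=strand, tss=tss, tes=tes))
        cursor = end + _GENE_GAP + int(rng.integers(0, 1_000))
    return genes


def make_enhancer_loci(erna_ids, genes, seed: int = 0) -> list:
    """Place enhancer loci mid-gap between genes, clear of every TSS."""
    rng = np.random.default_rng(seed)
    spans = sorted(g.span for g in genes)
    centers = []
    for (s1, e1), (s2, _) in zip(spans, spans[1:]):
        mid = (e1 + s2) // 2
        if s2 - e1 >= 2_400:  # room for the +/-500 bp window plus TSS clearance
            centers.append(mid)
    if len(centers) < len(erna_ids):
        raise ValueError("not enough intergenic gaps for the requested enhancers")
    picks = sorted(rng.choice(len(centers), size=len(erna_ids), replace=False).tolist())
    loci = []
    for e, ci in zip(erna_ids, picks):
        loci.append(
            EnhancerLocus(
                id=e, chrom=genes[0].chrom, strand="+" if ci % 2 == 0 else "-",
                center=int(centers[ci]), fdr=1e-4, fold_change=5.0,
            )
        )
    return loci


@dataclass
class SimulatedCoverage:
    """Per-timepoint stranded coverage plus true library totals."""

    chrom: str
    chrom_length: int
    coverage: dict  # label -> {strand: DataFrame(chrom,start,end,value)}
    totals: dict  # label -> mapped reads

    def write(self, outdir, prefix: str = "cov") -> dict:
        """Write one bedGraph per (timepoint, strand); returns path map."""
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for label, strands in self.coverage.items():
            for strand, df in strands.items():
                tag = "plus" if strand == "+" else "minus"
                path = outdir / f"{prefix}_{label}_{tag}.bedgraph"
                df.to_csv(path, sep="\t", header=False, index=False, float_format="%.10g")
                paths[(label, strand)] = path
        return paths


def generate_coverage(
    features,
    expression: TimeCourseMatrix,
    design: SamplingDesign,
    seed: int = 0,
    reads_per_unit: float = 100.0,
    chrom_length: int = TOY_CHROM_LENGTH,
    windows: dict | None = None,
) -> SimulatedCoverage:
    """Emit stranded per-timepoint coverage implied by an expression matrix.

    Reads are placed uniformly over each feature's quantification window
    (the gene-body window for genes, +/-500 bp for enhancer loci, unless
    explicit ``windows`` are given) at ``round(expression * reads_per_unit)``
    reads; the bedGraph value is reads per bp.  Same-strand features must
    not overlap, and windows must stay on the toy chromosome.
    """
    _ = seed  # placement is deterministic; kept for interface symmetry
    if windows is None:
        windows = {}
        for f in features:
            windows[f.id] = gene_body_window(f) if isinstance(f, GeneModel) else erna_window(f)
    by_strand: dict = {"+": [], "-": []}
    for fid, win in windows.items():
        if win.start < 0 or win.end > chrom_length:
            raise ValueError(f"{fid}: window outside toy chromosome bounds")
        by_strand[win.strand].append((win.start, win.end, fid))
    for strand, items in by_strand.items():
        items.sort()
        for (s1, e1, f1), (s2, _, f2) in zip(items, items[1:]):
            if s2 < e1:
                raise ValueError(f"same-strand overlap between {f1} and {f2}")
    labels = list(expression.data.columns)
    coverage: dict = {}
    totals: dict = {}
    chrom = next(iter(windows.values())).chrom if windows else TOY_CHROM
    for j, label in enumerate(labels):
        strands = {}
        total = 0
        for strand in ("+", "-"):
            rows = []
            for start, end, fid in by_strand[strand]:
                expr = float(expression.data.at[fid, label]) if fid in expression.data.index else 0.0
                count = int(round(max(expr, 0.0) * reads_per_unit))
                total += count
                if count > 0:
                    rows.append((chrom, start, end, count / (end - start)))
            strands[strand] = pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
        coverage[label] = strands
        totals[label] = total
    return SimulatedCoverage(
        chrom=chrom, chrom_length=chrom_length, coverage=coverage, totals=totals
    )
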