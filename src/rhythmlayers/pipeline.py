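"""End-to-end driver: simulate -> quantify -> rhythm -> integrate -> report.

The synthetic pipeline generates a coupled multi-layer bundle, routes the
GRO-seq-like layers (transcription, eRNA) through real coverage files
(bedGraph + GTF + peak BED) and the quantification module, detects rhythms
per layer, classifies rhythm retention between adjacent layers, attributes
layer-specific rhythms to mechanisms, and writes a manifest that makes the
whole run reproducible byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from . import integrate as integ
from . import io as rio
from . import rhythm as rhy
from . import synthdata as syn
from .core import SamplingDesign, TimeCourseMatrix
from .quantify import erna_window, filter_erna_peaks, gene_body_window, quantify_features, translation_rate

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "pca_report", "PcaReport"]

# adj-p thresholds per layer: 0.05 for RNA-scale layers, 0.1 for protein/DBP
DEFAULT_THRESHOLDS = {
    "transcription": 0.05,
    "mature_rna": 0.05,
    "erna": 0.05,
    "translation_rate": 0.05,
    "protein": 0.1,
    "dbp": 0.1,
}


@dataclass
class PipelineConfig:
    """Everything a synthetic end-to-end run depends on."""

    seed: int = 0
    n_genes: int = 500
    pair_counts: tuple = ((180, 120, 70), (140, 110, 60), (60, 140, 40))
    baseline: float = 10.0
    amplitude: float = 3.0
    noise_sd: float = 1.0
    te_dependent_fraction: float = 0.45
    phospho_dependent_fraction: float = 0.625
    n_enhancers: int = 40
    n_triads: int = 12
    n_undetected_proteins: int = 8
    reads_per_unit: float = 100.0
    te_floor: float = 0.1
    thresholds: dict = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))
    period_grid: tuple | None = None
    lag_step: float | None = None
    adjust: str = "permutation"

    def __post_init__(self):
        for layer, thr in self.thresholds.items():
            if not (0.0 < thr < 1.0):
                raise ValueError(f"threshold for {layer} must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        cfg = rio.load_config(path)
        if "pair_counts" in cfg:
            cfg["pair_counts"] = tuple(tuple(x) for x in cfg["pair_counts"])
        if "period_grid" in cfg and cfg["period_grid"] is not None:
            cfg["period_grid"] = tuple(float(p) for p in cfg["period_grid"])
        return cls(**cfg)

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# PCA sanity report
# ---------------------------------------------------------------------------


@dataclass
class PcaReport:
    coords: pd.DataFrame
    score: float
    degenerate: bool
    explained: tuple


def _circular_order_score(coords: np.ndarray, zt: np.ndarray) -> float:
    """Fraction of temporally adjacent samples that are also neighbours in
    the circular order of the 2-D projection (angle around the centroid)."""
    center = coords.mean(axis=0)
    ang = np.arctan2(coords[:, 1] - center[1], coords[:, 0] - center[0])
    angular_order = np.argsort(ang, kind="stable")
    pos = np.empty_like(angular_order)
    pos[angular_order] = np.arange(len(ang))
    n = len(ang)
    time_order = np.argsort(zt, kind="stable")
    hits = 0
    for a, b in zip(time_order, np.roll(time_order, -1)):
        if (pos[a] - pos[b]) % n in (1, n - 1):
            hits += 1
    return hits / n


def pca_report(matrix: TimeCourseMatrix, rhythmic_ids=None) -> PcaReport:
    """PCA of the samples over the rhythmic-feature submatrix.

    Features are standardised (zero mean, unit variance across samples) so
    the shared phase structure dominates; for a genuinely rhythmic dataset
    the samples trace the daily cycle in order around the 2-D projection.
    """
    data = matrix.data if rhythmic_ids is None else matrix.data.loc[list(rhythmic_ids)]
    if data.shape[1] < 3:
        raise ValueError("PCA sanity report needs at least 3 samples")
    X = data.to_numpy(dtype=float)
    X = X[np.isfinite(X).all(axis=1)]
    sd = X.std(axis=1, ddof=0)
    keep = sd > 0
    X = X[keep]
    degenerate = False
    if X.shape[0] < 2:
        degenerate = True
        coords = np.zeros((data.shape[1], 2))
        explained = (0.0, 0.0)
    else:
        Z = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, ddof=0, keepdims=True)
        pca = PCA(n_components=2)
        coords = pca.fit_transform(Z.T)
        explained = tuple(float(v) for v in pca.explained_variance_ratio_)
        if explained[1] < 1e-12 or np.allclose(coords, coords[0]):
            degenerate = True
    score = float("nan") if degenerate else _circular_order_score(coords, matrix.zt)
    df = pd.DataFrame(
        {"sample": data.columns, "zt": matrix.zt, "pc1": coords[:, 0], "pc2": coords[:, 1]}
    )
    return PcaReport(coords=df, score=score, degenerate=degenerate, explained=explained)


# ---------------------------------------------------------------------------
# pipeline stages
# ---------------------------------------------------------------------------


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc

        return wrapper

    return deco


@_stage("simulate")
def _simulate(config: PipelineConfig, design: SamplingDesign, outdir: Path):
    truth = syn.make_truth(
        pair_counts=config.pair_counts,
        n_genes=config.n_genes,
        baseline=config.baseline,
        amplitude=config.amplitude,
        noise_sd=config.noise_sd,
        te_dependent_fraction=config.te_dependent_fraction,
        phospho_dependent_fraction=config.phospho_dependent_fraction,
        n_enhancers=config.n_enhancers,
        n_triads=config.n_triads,
        seed=config.seed,
    )
    bundle = syn.generate_multilayer(truth, design, config.seed)
    genes = syn.make_gene_models(truth.genes, seed=config.seed)
    loci = syn.make_enhancer_loci(truth.erna_ids, genes, seed=config.seed)

    # GRO-seq-like coverage carries both gene-body and enhancer signal
    expr = TimeCourseMatrix(
        pd.concat([bundle.matrices["transcription"].data, bundle.matrices["erna"].data]),
        design.sample_times,
        "au",
    )
    cov = syn.generate_coverage(
        list(genes) + list(loci), expr, design, seed=config.seed,
        reads_per_unit=config.reads_per_unit,
    )
    simdir = outdir / "sim"
    simdir.mkdir(parents=True, exist_ok=True)
    cov.write(simdir, prefix="groseq")
    rio.write_gtf(genes, simdir / "genes.gtf")
    # candidate peak list: true enhancer loci plus decoys failing each rule
    tss0 = genes[0].tss
    decoys = [
        syn.EnhancerLocus("decoy_near_tss", genes[0].chrom, "+", tss0 + 100, 1e-4, 5.0),
        syn.EnhancerLocus("decoy_high_fdr", genes[0].chrom, "+", loci[0].center + 1_500, 0.01, 5.0),
        syn.EnhancerLocus("decoy_low_fold", genes[0].chrom, "-", loci[1].center + 1_500, 1e-4, 2.0),
    ]
    rio.write_peaks(list(loci) + decoys, simdir / "erna_peaks.bed")
    pd.Series(cov.totals).rename("mapped_reads").to_csv(
        simdir / "totals.tsv", sep="\t", header=True, index_label="timepoint"
    )

    rna = bundle.matrices["mature_rna"]
    te = bundle.matrices["translation_rate"]
    ribo = TimeCourseMatrix(
        rna.data.loc[te.data.index] * te.data, design.sample_times, "RPKM"
    )
    rna.to_tsv(simdir / "mature_rna.tsv")
    ribo.to_tsv(simdir / "ribo.tsv")

    # three independent protein datasets; a few genes escape detection in one
    rng = np.random.default_rng(config.seed + 1)
    protein = bundle.matrices["protein"]
    undetected = list(
        rng.choice(protein.feature_ids, size=config.n_undetected_proteins, replace=False)
    )
    for k in (1, 2, 3):
        data = protein.data.copy()
        if k > 1:
            jitter = rng.normal(0, config.noise_sd / 2, data.shape)
            data = (data + jitter).clip(lower=0.0)
        if k == 3:
            data.loc[undetected] = 0.0
        TimeCourseMatrix(data, design.sample_times, "intensity").to_tsv(
            simdir / f"protein_ds{k}.tsv"
        )
    bundle.matrices["dbp"].to_tsv(simdir / "dbp.tsv")
    if "phospho" in bundle.matrices:
        bundle.matrices["phospho"].to_tsv(simdir / "phospho.tsv")
    syn.truth_table(truth).to_csv(simdir / "truth.tsv", sep="\t", float_format="%.10g")
    rio.write_pairs(truth.dbp_enhancer_pairs, simdir / "dbp_enhancer_pairs.tsv")
    rio.write_pairs(truth.enhancer_gene_pairs, simdir / "enhancer_gene_pairs.tsv")
    return bundle, genes, loci


@_stage("quantify")
def _quantify(config: PipelineConfig, design: SamplingDesign, outdir: Path):
    simdir = outdir / "sim"
    qdir = outdir / "quant"
    qdir.mkdir(parents=True, exist_ok=True)
    genes = rio.read_gtf(simdir / "genes.gtf")
    totals = pd.read_csv(simdir / "totals.tsv", sep="\t", index_col=0)["mapped_reads"].to_dict()
    labels = design.sample_labels
    coverage = {
        lab: {
            "+": rio.read_bedgraph(simdir / f"groseq_{lab}_plus.bedgraph"),
            "-": rio.read_bedgraph(simdir / f"groseq_{lab}_minus.bedgraph"),
        }
        for lab in labels
    }
    txn_windows = {g.id: gene_body_window(g) for g in genes}
    txn = quantify_features(coverage, txn_windows, totals, zt=design.sample_times, unit="RPKTM")
    txn.to_tsv(qdir / "transcription.tsv")

    peaks = rio.read_peaks(simdir / "erna_peaks.bed")
    kept = filter_erna_peaks(peaks, [g.tss for g in genes])
    erna_windows = {l.id: erna_window(l) for l in kept}
    erna = quantify_features(coverage, erna_windows, totals, zt=design.sample_times, unit="RPKTM")
    erna.to_tsv(qdir / "erna.tsv")

    rna = rio.read_matrix(simdir / "mature_rna.tsv")
    ribo = rio.read_matrix(simdir / "ribo.tsv")
    te, usable = translation_rate(ribo, rna, floor=config.te_floor)
    te.to_tsv(qdir / "translation_rate.tsv")
    usable.to_csv(qdir / "te_usable.tsv", sep="\t", header=True, index_label="gene")
    return txn, erna, te


@_stage("rhythm")
def _rhythm(config: PipelineConfig, design: SamplingDesign, outdir: Path):
    qdir = outdir / "quant"
    simdir = outdir / "sim"
    rdir = outdir / "rhythm"
    rdir.mkdir(parents=True, exist_ok=True)
    sources = {
        "transcription": qdir / "transcription.tsv",
        "mature_rna": simdir / "mature_rna.tsv",
        "protein": simdir / "protein_ds1.tsv",
        "dbp": simdir / "dbp.tsv",
        "erna": qdir / "erna.tsv",
        "translation_rate": qdir / "translation_rate.tsv",
    }
    results = {}
    refs = None
    for layer, path in sources.items():
        matrix = rio.read_matrix(path)
        if refs is None:
            refs = rhy.reference_waveforms(
                matrix.zt, period_grid=config.period_grid, lag_step=config.lag_step
            )
        res = rhy.jtk_scan(
            matrix,
            refs=refs,
            threshold=config.thresholds[layer],
            adjust=config.adjust,
            perm_seed=config.seed,
        )
        res.to_csv(rdir / f"{layer}.tsv", sep="\t", float_format="%.10g")
        results[layer] = res
    return results


@_stage("integrate")
def _integrate(config: PipelineConfig, outdir: Path, results: dict):
    simdir = outdir / "sim"
    idir = outdir / "integrate"
    idir.mkdir(parents=True, exist_ok=True)
    protein_sets = [rio.read_matrix(simdir / f"protein_ds{k}.tsv") for k in (1, 2, 3)]
    detected = integ.detection_filter(protein_sets)

    calls = {layer: res["rhythmic"].astype(bool) for layer, res in results.items()}
    comparisons = {}
    pair_defs = [
        ("transcription", "mature_rna", None),
        ("mature_rna", "protein", detected),
        ("protein", "dbp", detected),
    ]
    summary: dict = {"pairs": {}}
    for up, down, det in pair_defs:
        comp = integ.classify_pair(calls[up], calls[down], detected_both=det,
                                   up_layer=up, down_layer=down)
        comparisons[(up, down)] = comp
        comp.categories.to_csv(idir / f"categories_{up}_{down}.tsv", sep="\t", header=True)
        summary["pairs"][f"{up}->{down}"] = {
            "counts": comp.counts,
            "conserved_fraction": comp.conserved_fraction,
        }

    te = rio.read_matrix(outdir / "quant" / "translation_rate.tsv")
    rp = comparisons[("mature_rna", "protein")]
    tv = integ.te_variation_compare(te, rp.genes("conserved"), rp.genes("disrupted"))
    summary["te_variation"] = {
        "mean_cv_conserved": tv.mean_conserved,
        "mean_cv_disrupted": tv.mean_disrupted,
        "t": tv.t_statistic,
        "p": tv.p_value,
    }

    att_te = integ.attribute_translation(rp.genes("enhanced"), calls["translation_rate"])
    pd_comp = comparisons[("protein", "dbp")]
    phospho = rio.read_matrix(simdir / "phospho.tsv")
    phospho_detect = {g: True for g in phospho.feature_ids}
    att_ph = integ.attribute_phosphorylation(pd_comp.genes("enhanced"), phospho_detect)
    summary["attribution"] = {
        "te_dependent_fraction": att_te.fraction_dependent,
        "n_protein_specific": len(att_te.analyzed),
        "phospho_dependent_fraction": att_ph.fraction_dependent,
        "n_dbp_specific": len(att_ph.analyzed),
    }

    triads = integ.link_triads(
        calls["dbp"], calls["erna"], calls["transcription"],
        rio.read_pairs(simdir / "dbp_enhancer_pairs.tsv"),
        rio.read_pairs(simdir / "enhancer_gene_pairs.tsv"),
    )
    triads.to_csv(idir / "triads.tsv", sep="\t", index=False)
    summary["n_triads"] = int(len(triads))

    with open(idir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary


@_stage("report")
def _report(config: PipelineConfig, outdir: Path, results: dict):
    repdir = outdir / "report"
    repdir.mkdir(parents=True, exist_ok=True)
    sources = {
        "transcription": outdir / "quant" / "transcription.tsv",
        "mature_rna": outdir / "sim" / "mature_rna.tsv",
        "protein": outdir / "sim" / "protein_ds1.tsv",
        "dbp": outdir / "sim" / "dbp.tsv",
    }
    scores = {}
    for layer, path in sources.items():
        matrix = rio.read_matrix(path)
        res = results[layer]
        rhythmic = list(res.index[res["rhythmic"].astype(bool)])
        rep = pca_report(matrix, rhythmic_ids=rhythmic) if len(rhythmic) >= 2 else None
        if rep is not None:
            rep.coords.to_csv(repdir / f"pca_{layer}.tsv", sep="\t", index=False,
                              float_format="%.10g")
            scores[layer] = {"circular_order_score": rep.score, "degenerate": rep.degenerate}
        # phase/amplitude-ordered heatmap table of the rhythmic features
        ordered = res.loc[rhythmic].sort_values(
            ["lag", "amplitude"], ascending=[True, False], kind="mergesort"
        )
        matrix.data.loc[ordered.index].to_csv(
            repdir / f"heatmap_{layer}.tsv", sep="\t", float_format="%.10g"
        )
    with open(repdir / "pca_scores.json", "w") as fh:
        json.dump(scores, fh, indent=2, sort_keys=True)
    return scores


def _hash_tree(outdir: Path) -> dict:
    hashes = {}
    for path in sorted(outdir.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            hashes[str(path.relative_to(outdir))] = hashlib.sha256(
                path.read_bytes()
            ).hexdigest()
    return hashes


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run the full synthetic pipeline; returns the manifest dictionary.

    Re-running with the same config and seed reproduces every output file
    byte for byte (the manifest records each file's SHA-256).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    design = SamplingDesign()
    logger.info("stage: simulate")
    _simulate(config, design, outdir)
    logger.info("stage: quantify")
    _quantify(config, design, outdir)
    logger.info("stage: rhythm")
    results = _rhythm(config, design, outdir)
    logger.info("stage: integrate")
    summary = _integrate(config, outdir, results)
    logger.info("stage: report")
    scores = _report(config, outdir, results)
    manifest = {
        "config": json.loads(json.dumps(config.to_dict(), default=list)),
        "summary": summary,
        "pca": scores,
        "files": _hash_tree(outdir),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
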