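import numpy as np
import pandas as pd
import pytest

from rhythmlayers.core import SamplingDesign
from rhythmlayers.quantify import gene_body_window, quantify_features, rpktm
from rhythmlayers.rhythm import jtk_scan
from rhythmlayers.synthdata import (
    CosinorParams,
    MultiLayerTruth,
    generate_coverage,
    generate_multilayer,
    generate_timecourse,
    make_gene_models,
    make_truth,
    resolve_effective,
    truth_table,
)
from rhythmlayers.io import BedGraph


class TestCosinorParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"baseline": 0.0},
            {"baseline": 5.0, "amplitude": 6.0},
            {"baseline": 5.0, "period": 12.0},
            {"baseline": 5.0, "noise_sd": -1.0},
            {"baseline": float("nan")},
        ],
    )
    def test_invariants_enforced(self, kwargs):
        with pytest.raises(ValueError):
            CosinorParams(**kwargs)

    def test_phase_normalised_to_one_cycle(self):
        assert CosinorParams(baseline=1.0, phase=25.0).phase == 1.0


class TestGenerateTimecourse:
    def test_flat_noiseless_series_is_exactly_baseline(self, design):
        m = generate_timecourse({"g": CosinorParams(baseline=5.0)}, design, seed=0)
        assert (m.values == 5.0).all()

    def test_same_seed_gives_bitwise_identical_matrices(self, design):
        params = {f"g{i}": CosinorParams(10.0, 2.0, phase=i, noise_sd=1.0) for i in range(5)}
        a = generate_timecourse(params, design, seed=7)
        b = generate_timecourse(params, design, seed=7)
        pd.testing.assert_frame_equal(a.data, b.data)
        c = generate_timecourse(params, design, seed=8)
        assert not a.data.equals(c.data)

    def test_noiseless_cosine_peaks_at_its_phase(self, design):
        m = generate_timecourse(
            {"g": CosinorParams(baseline=10.0, amplitude=2.0, phase=6.0)}, design, seed=0
        )
        assert design.sample_times[np.argmax(m.values[0])] == 6.0

    def test_non_finite_parameter_rejected_with_feature_id(self, design):
        p = CosinorParams(baseline=5.0)
        object.__setattr__(p, "baseline", float("inf"))
        with pytest.raises(ValueError, match="badgene"):
            generate_timecourse({"badgene": p}, design, seed=0)

    def test_empty_params_rejected(self, design):
        with pytest.raises(ValueError):
            generate_timecourse({}, design, seed=0)


def _tiny_truth(n=10, delay=0.0, noise=0.0):
    """All-inherited chain with fixed phases for construction checks."""
    params = {layer: {} for layer in ("transcription", "mature_rna", "protein", "dbp",
                                      "translation_rate")}
    source = {layer: {} for layer in params}
    for i in range(n):
        g = f"g{i}"
        params["transcription"][g] = CosinorParams(10.0, 3.0, phase=2.0 * i % 24, noise_sd=noise)
        source["transcription"][g] = "layer_specific"
        for layer in ("mature_rna", "protein", "dbp"):
            params[layer][g] = CosinorParams(10.0, 3.0, noise_sd=noise)
            source[layer][g] = "inherited"
        params["translation_rate"][g] = CosinorParams(1.0, 0.0, noise_sd=noise)
        source["translation_rate"][g] = "none"
    return MultiLayerTruth(params=params, rhythm_source=source, processing_delay=delay)


class TestGenerateMultilayer:
    def test_inherited_layers_copy_phase_plus_processing_delay(self, design):
        truth = _tiny_truth(n=10, delay=3.0)
        bundle = generate_multilayer(truth, design, seed=0)
        eff = bundle.effective
        for g in truth.genes:
            up = eff["transcription"][g].phase
            assert eff["mature_rna"][g].phase == pytest.approx((up + 3.0) % 24)
            # zero noise: realized peak column matches the shifted phase grid point
            row = bundle.matrices["mature_rna"].data.loc[g].to_numpy()
            peak_zt = design.sample_times[np.argmax(row)]
            expected = (up + 3.0) % 24
            d = min(abs(peak_zt - expected) % 24, 24 - abs(peak_zt - expected) % 24)
            assert d <= 1.5  # nearest grid point

    def test_rhythmic_translation_alone_makes_protein_rhythmic(self, design):
        """RNA flat + rhythmic TE -> rhythmic protein, flat RNA (JTK oracle)."""
        n = 12
        ids = [f"g{i}" for i in range(n)]
        params = {
            "transcription": {g: CosinorParams(10.0) for g in ids},
            "mature_rna": {g: CosinorParams(10.0, noise_sd=0.2) for g in ids},
            "translation_rate": {
                g: CosinorParams(1.0, 0.4, phase=2.0 * i, noise_sd=0.05)
                for i, g in enumerate(ids)
            },
            "protein": {g: CosinorParams(10.0, 3.0, noise_sd=0.2) for g in ids},
        }
        source = {
            "transcription": {g: "none" for g in ids},
            "mature_rna": {g: "none" for g in ids},
            "translation_rate": {g: "layer_specific" for g in ids},
            "protein": {g: "inherited" for g in ids},
        }
        truth = MultiLayerTruth(params=params, rhythm_source=source)
        bundle = generate_multilayer(truth, design, seed=3)
        prot = jtk_scan(bundle.matrices["protein"], threshold=0.1)
        rna = jtk_scan(bundle.matrices["mature_rna"], threshold=0.05)
        assert prot["rhythmic"].mean() >= 0.75  # TE rhythm drives protein
        assert rna["rhythmic"].mean() <= 2 / n  # RNA stays flat (alpha-level flips)

    def test_inherited_without_upstream_rhythm_rejected(self, design):
        params = {
            "transcription": {"g": CosinorParams(10.0)},
            "mature_rna": {"g": CosinorParams(10.0, 3.0)},
        }
        source = {"transcription": {"g": "none"}, "mature_rna": {"g": "inherited"}}
        truth = MultiLayerTruth(params=params, rhythm_source=source)
        with pytest.raises(ValueError, match="inherited"):
            generate_multilayer(truth, design, seed=0)

    def test_dangling_pairing_ids_rejected(self, design):
        truth = _tiny_truth(3)
        truth.enhancer_gene_pairs = [("erna999", "g0")]
        with pytest.raises(ValueError, match="unknown ids"):
            truth.validate()

    def test_empty_pairing_lists_give_valid_bundle(self, design):
        truth = _tiny_truth(3)
        bundle = generate_multilayer(truth, design, seed=0)
        assert truth.enhancer_gene_pairs == [] and truth.dbp_enhancer_pairs == []
        assert set(bundle.matrices) >= {"transcription", "mature_rna", "protein", "dbp"}

    def test_equal_seeds_give_equal_bundles(self, design):
        t = make_truth(seed=5, n_genes=80, pair_counts=((20, 10, 8), (16, 12, 6), (6, 16, 4)),
                       n_enhancers=8, n_triads=3)
        b1 = generate_multilayer(t, design, seed=11)
        b2 = generate_multilayer(t, design, seed=11)
        for layer in b1.matrices:
            pd.testing.assert_frame_equal(b1.matrices[layer].data, b2.matrices[layer].data)


class TestTruthTable:
    def test_round_trip_and_labels_match_flags(self, design, tmp_path):
        truth = make_truth(seed=2, n_genes=80,
                           pair_counts=((20, 10, 8), (16, 12, 6), (6, 16, 4)),
                           n_enhancers=8, n_triads=3)
        table = truth_table(truth)
        path = tmp_path / "truth.tsv"
        table.to_csv(path, sep="\t", float_format="%.10g")
        back = pd.read_csv(path, sep="\t", index_col=0)
        pd.testing.assert_frame_equal(table, back, check_dtype=False)
        eff = resolve_effective(truth)
        for g in truth.genes:
            assert table.loc[g, "transcription_rhythmic"] == (
                eff["transcription"][g].amplitude > 0
            )

    def test_planted_pair_counts_are_exact(self):
        counts = ((20, 10, 8), (16, 12, 6), (6, 16, 4))
        truth = make_truth(seed=0, n_genes=80, pair_counts=counts,
                           n_enhancers=8, n_triads=3)
        table = truth_table(truth)
        pairs = [
            ("category_transcription_mature_rna", counts[0]),
            ("category_mature_rna_protein", counts[1]),
            ("category_protein_dbp", counts[2]),
        ]
        for col, (c, d, e) in pairs:
            vc = table[col].value_counts()
            assert vc.get("conserved", 0) == c
            assert vc.get("disrupted", 0) == d
            assert vc.get("enhanced", 0) == e

    def test_empty_truth_gives_empty_table(self):
        truth = MultiLayerTruth(params={"transcription": {}}, rhythm_source={})
        assert truth_table(truth).empty


class TestGenerateCoverage:
    def _one_gene(self, expr_value, design):
        from rhythmlayers.quantify import GeneModel

        gene = GeneModel(id="g", chrom="chrT", strand="+", tss=100_000, tes=115_000)
        df = pd.DataFrame(
            [[expr_value] * design.n_samples], index=["g"], columns=design.sample_labels
        )
        from rhythmlayers.core import TimeCourseMatrix

        expr = TimeCourseMatrix(df, design.sample_times)
        return gene, expr

    def test_zero_expression_gives_zero_coverage(self, design):
        gene, expr = self._one_gene(0.0, design)
        cov = generate_coverage([gene], expr, design)
        assert all(df.empty for strands in cov.coverage.values() for df in strands.values())
        assert all(t == 0 for t in cov.totals.values())

    def test_hundred_reads_over_ten_kb_window_gives_rpktm_ten(self, design):
        # expression 1.0 at reads_per_unit=100 -> 100 reads over the 10 kb window
        gene, expr = self._one_gene(1.0, design)
        cov = generate_coverage([gene], expr, design, reads_per_unit=100.0)
        win = gene_body_window(gene)
        assert (win.start, win.end) == (102_000, 112_000)
        coverage = {
            lab: {s: BedGraph(df) for s, df in strands.items()}
            for lab, strands in cov.coverage.items()
        }
        totals = {lab: 1e7 for lab in cov.coverage}
        m = quantify_features(coverage, {"g": win}, totals, zt=design.sample_times)
        assert m.values == pytest.approx(10.0)

    def test_minus_strand_gene_covers_only_minus_file(self, design):
        from rhythmlayers.quantify import GeneModel
        from rhythmlayers.core import TimeCourseMatrix

        gene = GeneModel(id="g", chrom="chrT", strand="-", tss=115_000, tes=100_000)
        expr = TimeCourseMatrix(
            pd.DataFrame([[2.0] * design.n_samples], index=["g"],
                         columns=design.sample_labels),
            design.sample_times,
        )
        cov = generate_coverage([gene], expr, design)
        for strands in cov.coverage.values():
            assert strands["+"].empty and not strands["-"].empty

    def test_gene_outside_chromosome_rejected(self, design):
        gene, expr = self._one_gene(1.0, design)
        with pytest.raises(ValueError, match="bounds"):
            generate_coverage([gene], expr, design, chrom_length=110_000)

    def test_same_strand_overlap_rejected(self, design):
        from rhythmlayers.quantify import GeneModel
        from rhythmlayers.core import TimeCourseMatrix

        g1 = GeneModel(id="a", chrom="chrT", strand="+", tss=100_000, tes=115_000)
        g2 = GeneModel(id="b", chrom="chrT", strand="+", tss=105_000, tes=120_000)
        expr = TimeCourseMatrix(
            pd.DataFrame([[1.0] * design.n_samples] * 2, index=["a", "b"],
                         columns=design.sample_labels),
            design.sample_times,
        )
        with pytest.raises(ValueError, match="overlap"):
            generate_coverage([g1, g2], expr, design)


class TestToyGenome:
    def test_gene_models_do_not_overlap_per_strand(self):
        genes = make_gene_models([f"g{i}" for i in range(50)], seed=1)
        for strand in "+-":
            spans = sorted(g.span for g in genes if g.strand == strand)
            assert all(a[1] <= b[0] for a, b in zip(spans, spans[1:]))
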