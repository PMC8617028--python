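"""Insertion counting, window matrix, TF-IDF, LSI, QC, promoters, network."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from tme_atlas.atac_chip import (
    LsiEmbedding,
    WindowMatrix,
    active_promoters,
    atac_cell_qc,
    build_window_matrix,
    correlation_network,
    gene_activity,
    insertions_from_fragments,
    lsi,
    tfidf_transform,
    tss_positions,
)
from tme_atlas.io_formats import FragmentSet, GenomicInterval
from tme_atlas.synthetic_data import CohortDesign, generate_cohort, generate_fragments


def frags_from_rows(rows):
    return FragmentSet(
        pd.DataFrame(rows, columns=["chrom", "start", "end", "barcode", "count"])
    )


class TestInsertions:
    def test_fragment_yields_start_and_end_minus_one(self):
        ins = insertions_from_fragments(
            frags_from_rows([["chr1", 100, 350, "A", 1]])
        )
        assert sorted(ins["pos"]) == [100, 349]

    def test_count_weights_both_sites(self):
        ins = insertions_from_fragments(frags_from_rows([["chr1", 5, 60, "A", 2]]))
        assert (ins["weight"] == 2).all()

    def test_per_cell_totals_twice_fragment_counts(self, rng):
        rows = [
            ["chr1", int(s), int(s) + int(l), f"c{b}", int(c)]
            for s, l, b, c in zip(
                rng.integers(0, 5_000, 50),
                rng.integers(20, 300, 50),
                rng.integers(0, 5, 50),
                rng.integers(1, 4, 50),
            )
        ]
        fs = frags_from_rows(rows)
        ins = insertions_from_fragments(fs)
        per_cell_ins = ins.groupby("barcode")["weight"].sum()
        per_cell_frag = fs.barcode_totals()
        assert (per_cell_ins == 2 * per_cell_frag).all()


class TestWindowMatrix:
    SIZES = {"chr1": 10_000}

    def test_both_insertions_in_first_window(self):
        wm = build_window_matrix(
            frags_from_rows([["chr1", 100, 350, "A", 1]]), self.SIZES
        )
        assert wm.matrix[0, 0] == 2
        assert wm.matrix.sum() == 2

    def test_straddling_fragment_splits_between_windows(self):
        wm = build_window_matrix(
            frags_from_rows([["chr1", 2_400, 2_600, "A", 1]]), self.SIZES
        )
        assert wm.matrix[0, 0] == 1  # insertion at 2400
        assert wm.matrix[0, 1] == 1  # insertion at 2599

    def test_column_sums_match_insertion_oracle(self, rng):
        rows = [
            ["chr1", int(s), int(s) + 50, f"c{i % 3}", 1]
            for i, s in enumerate(rng.integers(0, 9_000, 100))
        ]
        fs = frags_from_rows(rows)
        wm = build_window_matrix(fs, self.SIZES, window_size=2_500)
        ins = insertions_from_fragments(fs)
        oracle = np.zeros(4)
        for pos, w in zip(ins["pos"], ins["weight"]):
            oracle[pos // 2_500] += w
        np.testing.assert_array_equal(
            np.asarray(wm.matrix.sum(axis=0)).ravel(), oracle
        )

    def test_fragment_beyond_chrom_errors(self):
        with pytest.raises(ValueError, match="exceeds"):
            build_window_matrix(
                frags_from_rows([["chr1", 9_990, 10_200, "A", 1]]), self.SIZES
            )

    def test_order_stable_under_shuffling(self, rng):
        rows = [
            ["chr1", int(s), int(s) + 40, "A", 1]
            for s in rng.integers(0, 9_000, 30)
        ]
        wm1 = build_window_matrix(frags_from_rows(rows), self.SIZES)
        wm2 = build_window_matrix(frags_from_rows(rows[::-1]), self.SIZES)
        assert (wm1.matrix != wm2.matrix).nnz == 0


class TestTfidf:
    def test_2x2_worked_example(self):
        # features x cells [[1,1],[1,0]] == cells x windows [[1,1],[1,0]].T
        mat = sp.csr_matrix(np.array([[1, 1], [1, 0]]).T)
        wm = WindowMatrix(
            mat,
            np.array(["c1", "c2"], dtype=object),
            [GenomicInterval("chr1", 0, 2_500), GenomicInterval("chr1", 2_500, 5_000)],
            2_500,
            binarized=True,
        )
        out, _ = tfidf_transform(wm)
        expected_features_by_cells = np.array(
            [[0.5 * np.log(2), 1.0 * np.log(2)], [0.5 * np.log(3), 0.0]]
        )
        np.testing.assert_allclose(
            out.toarray().T, expected_features_by_cells, atol=1e-12
        )

    def test_all_ones_matrix_constant(self):
        mat = sp.csr_matrix(np.ones((5, 4)))
        wm = WindowMatrix(
            mat,
            np.array([f"c{i}" for i in range(5)], dtype=object),
            [GenomicInterval("chr1", i * 100, (i + 1) * 100) for i in range(4)],
            100,
            binarized=True,
        )
        out, _ = tfidf_transform(wm)
        np.testing.assert_allclose(out.toarray(), 0.25 * np.log(2), atol=1e-12)

    def test_matches_dense_formula_on_random_fixture(self, rng):
        X = (rng.random((20, 30)) < 0.3).astype(float)
        X[X.sum(axis=1) == 0, 0] = 1  # no empty cells
        wm = WindowMatrix(
            sp.csr_matrix(X),
            np.array([f"c{i}" for i in range(20)], dtype=object),
            [GenomicInterval("chr1", i * 10, (i + 1) * 10) for i in range(30)],
            10,
            binarized=True,
        )
        out, _ = tfidf_transform(wm)
        tf = X / X.sum(axis=1, keepdims=True)
        idf = np.log(1 + 20 / X.sum(axis=0))
        np.testing.assert_allclose(out.toarray(), tf * idf, atol=1e-10)

    def test_half_presence_idf_value(self):
        X = np.zeros((100, 2))
        X[:50, 0] = 1
        X[:, 1] = 1
        wm = WindowMatrix(
            sp.csr_matrix(X),
            np.array([f"c{i}" for i in range(100)], dtype=object),
            [GenomicInterval("chr1", 0, 10), GenomicInterval("chr1", 10, 20)],
            10,
            binarized=True,
        )
        out, _ = tfidf_transform(wm)
        # cell 0 has both features: tf = 1/2; feature 0 idf = ln(1+100/50)=ln 3
        assert out[0, 0] == pytest.approx(0.5 * np.log(3), abs=1e-12)

    def test_requires_binarized(self):
        wm = WindowMatrix(
            sp.csr_matrix(np.ones((2, 2))),
            np.array(["a", "b"], dtype=object),
            [GenomicInterval("chr1", 0, 10), GenomicInterval("chr1", 10, 20)],
            10,
            binarized=False,
        )
        with pytest.raises(ValueError, match="binarized"):
            tfidf_transform(wm)

    def test_duplicating_a_cell_changes_others_only_via_idf(self, rng):
        X = (rng.random((10, 6)) < 0.5).astype(float)
        X[X.sum(axis=1) == 0, 0] = 1
        def run(mat):
            wm = WindowMatrix(
                sp.csr_matrix(mat),
                np.array([f"c{i}" for i in range(mat.shape[0])], dtype=object),
                [GenomicInterval("chr1", i * 10, (i + 1) * 10) for i in range(6)],
                10,
                binarized=True,
            )
            return tfidf_transform(wm)[0].toarray()
        base = run(X)
        dup = run(np.vstack([X, X[0]]))
        # un-duplicated cells change exactly by the idf ratio per feature
        idf_old = np.log(1 + 10 / X.sum(axis=0))
        idf_new = np.log(1 + 11 / np.vstack([X, X[0]]).sum(axis=0))
        with np.errstate(invalid="ignore"):
            ratio = np.where(base[1:] > 0, dup[1:10] / base[1:], np.nan)
        for j in range(6):
            col = ratio[:, j]
            col = col[~np.isnan(col)]
            if len(col):
                np.testing.assert_allclose(col, idf_new[j] / idf_old[j], rtol=1e-10)


class TestLsi:
    def test_rank2_matrix_has_two_singular_values(self, rng):
        u = rng.random((30, 2))
        v = rng.random((2, 40))
        X = sp.csr_matrix(u @ v)
        emb = lsi(X, [f"c{i}" for i in range(30)], n_components=6, seed=0)
        assert (emb.singular_values[2:] < 1e-8).all()

    def test_reconstruction_matches_dense_svd_oracle(self, rng):
        X = rng.random((20, 30))
        emb = lsi(sp.csr_matrix(X), [f"c{i}" for i in range(20)],
                  n_components=5, drop_first=False, seed=1)
        U, S, Vt = np.linalg.svd(X, full_matrices=False)
        np.testing.assert_allclose(
            np.abs(emb.coordinates.to_numpy()), np.abs(U[:, :5] * S[:5]), atol=1e-8
        )

    def test_two_planted_groups_separate(self):
        design = CohortDesign(seed=41, n_patients=1, n_cells_per_patient=60,
                              proportions={"malignant": 0.5, "Tcell": 0.5})
        _, truth = generate_cohort(design)
        frags = generate_fragments(
            truth, windows_per_type=8, seed=42, fragments_per_cell=600, noise=0.05
        )
        wm = build_window_matrix(frags, {"chr1": 1_000_000, "chr22": 1_000_000})
        tfidf, _ = tfidf_transform(wm.binarize())
        emb = lsi(tfidf, wm.cell_ids, n_components=10, seed=43)
        coords = emb.coordinates
        types = truth.cell_meta.loc[coords.index, "cell_type"]
        a = coords[types == "malignant"].to_numpy()
        b = coords[types == "Tcell"].to_numpy()
        # separation along the between-centroid direction
        d = a.mean(0) - b.mean(0)
        u = d / np.linalg.norm(d)
        pa, pb = a @ u, b @ u
        within = max(pa.std(), pb.std())
        assert pa.mean() - pb.mean() > 5 * within
        assert pa.min() > pb.max()  # linearly separable

    def test_embedding_invariant_to_cell_permutation(self, rng):
        X = rng.random((15, 20))
        ids = [f"c{i}" for i in range(15)]
        emb1 = lsi(sp.csr_matrix(X), ids, n_components=4, seed=3)
        perm = rng.permutation(15)
        emb2 = lsi(sp.csr_matrix(X[perm]), [ids[i] for i in perm],
                   n_components=4, seed=3)
        d1 = np.linalg.norm(
            emb1.coordinates.loc["c0"] - emb1.coordinates.loc["c7"]
        )
        d2 = np.linalg.norm(
            emb2.coordinates.loc["c0"] - emb2.coordinates.loc["c7"]
        )
        assert d1 == pytest.approx(d2, rel=1e-8)

    def test_too_many_components_rejected(self, rng):
        X = sp.csr_matrix(rng.random((5, 6)))
        with pytest.raises(ValueError):
            lsi(X, list("abcde"), n_components=5)


class TestAtacQC:
    def _uniform_frags(self, n, in_peak_n, barcode="A", length=100):
        # in-peak fragments spaced 40 bp inside [0, 50000); rest distal
        rows = []
        for i in range(n):
            start = i * 40 if i < in_peak_n else 100_000 + i * 500
            rows.append(["chr1", start, start + length, barcode, 1])
        return frags_from_rows(rows)

    PEAK = [GenomicInterval("chr1", 0, 50_000)]

    def test_fragment_floor_boundary(self):
        # 999 fragments in peaks -> fail; 1000 -> pass
        for n_in, expect in ((999, False), (1_000, True)):
            frags = self._uniform_frags(n_in, n_in)
            qc = atac_cell_qc(
                frags, self.PEAK, tss=None, disable_rules={"tss_enrichment"}
            )
            assert bool(qc["kept"].iloc[0]) is expect

    def test_low_frip_fails(self):
        frags = self._uniform_frags(12_000, 1_080)  # frip = 0.09
        qc = atac_cell_qc(frags, self.PEAK, tss=None,
                          disable_rules={"tss_enrichment"})
        assert qc["frip"].iloc[0] == pytest.approx(0.09)
        assert not qc["kept"].iloc[0]

    def test_short_fragments_zero_nucleosome_signal(self):
        frags = self._uniform_frags(1_200, 1_200, length=100)
        qc = atac_cell_qc(frags, self.PEAK, tss=None,
                          disable_rules={"tss_enrichment"})
        assert qc["nucleosome_signal"].iloc[0] == 0.0
        assert qc["kept"].iloc[0]

    def test_uniform_coverage_tss_enrichment_near_one(self):
        # one fragment starting at every position: coverage is flat
        rows = [["chr1", s, s + 80, "A", 1] for s in range(0, 12_000)]
        frags = frags_from_rows(rows)
        tss = pd.DataFrame({"chrom": ["chr1"], "pos": [6_000]}, index=["g"])
        qc = atac_cell_qc(frags, self.PEAK, tss=tss)
        assert qc["tss_enrichment"].iloc[0] == pytest.approx(1.0, abs=0.05)
        assert not qc["pass_tss_enrichment"].iloc[0]

    def test_blacklist_ratio(self):
        rows = [["chr1", 10, 110, "A", 1]] * 1 + [
            ["chr1", 5_000 + i, 5_100 + i, "A", 1] for i in range(19)
        ]
        frags = frags_from_rows(rows)
        bl = [GenomicInterval("chr1", 0, 200)]
        qc = atac_cell_qc(frags, self.PEAK, tss=None, blacklist=bl,
                          disable_rules={"tss_enrichment"})
        assert qc["blacklist_ratio"].iloc[0] == pytest.approx(0.05)

    def test_missing_tss_requires_disabled_rule(self):
        frags = self._uniform_frags(10, 10)
        with pytest.raises(ValueError, match="disable"):
            atac_cell_qc(frags, self.PEAK, tss=None)


class TestGeneActivity:
    ANN = pd.DataFrame(
        {
            "chrom": ["chr1", "chr1"],
            "start": [5_000, 5_000],
            "end": [8_000, 8_000],
            "strand": ["+", "-"],
            "is_mito": [False, False],
        },
        index=pd.Index(["plus", "minus"], name="gene_id"),
    )

    def test_strand_aware_regions(self):
        # insertions at 3500 (upstream of + TSS) and 9000 (upstream of - TSS)
        frags = frags_from_rows(
            [["chr1", 3_500, 3_600, "A", 1], ["chr1", 9_000, 9_100, "A", 1]]
        )
        act = gene_activity(frags, self.ANN, upstream=2_000)
        # plus region [3000, 8000): insertions 3500, 3599 in; 9000/9099 out
        assert act.loc["A", "plus"] == 2
        # minus region [5000, 10000): 9000, 9099 in; 3500s out
        assert act.loc["A", "minus"] == 2

    def test_insertion_outside_region_ignored(self):
        frags = frags_from_rows([["chr1", 9_000, 9_100, "A", 1]])
        act = gene_activity(frags, self.ANN, upstream=2_000)
        assert act.loc["A", "plus"] == 0

    def test_no_fragments_means_empty_frame(self):
        act = gene_activity(
            frags_from_rows([["chr2", 0, 50, "A", 1]]), self.ANN
        )
        assert (act.to_numpy() == 0).all()


class TestActivePromoters:
    TSS = pd.DataFrame({"chrom": ["chr1"], "pos": [10_000]}, index=["g"])

    def test_joint_marks_near_tss_active(self):
        k4 = [GenomicInterval("chr1", 9_500, 10_200)]
        k27 = [GenomicInterval("chr1", 9_800, 10_100)]
        assert active_promoters(k4, k27, self.TSS) == ["g"]

    def test_k4_without_overlapping_k27_inactive(self):
        k4 = [GenomicInterval("chr1", 9_500, 10_200)]
        k27 = [GenomicInterval("chr1", 50_000, 50_500)]
        assert active_promoters(k4, k27, self.TSS) == []

    def test_distal_joint_marks_inactive(self):
        k4 = [GenomicInterval("chr1", 15_000, 15_600)]
        k27 = [GenomicInterval("chr1", 15_200, 15_700)]
        assert active_promoters(k4, k27, self.TSS) == []

    def test_monotone_in_max_dist(self):
        k4 = [GenomicInterval("chr1", 11_500, 12_000)]
        k27 = [GenomicInterval("chr1", 11_600, 12_100)]
        near = active_promoters(k4, k27, self.TSS, max_dist=1_000)
        far = active_promoters(k4, k27, self.TSS, max_dist=2_000)
        assert set(near) <= set(far)
        assert far == ["g"]

    def test_tss_positions_strand_aware(self):
        ann = TestGeneActivity.ANN
        tss = tss_positions(ann)
        assert tss.loc["plus", "pos"] == 5_000
        assert tss.loc["minus", "pos"] == 7_999


class TestCorrelationNetwork:
    def test_duplicated_gene_full_weight_edge(self, rng):
        x = rng.random(50)
        act = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.random(50)})
        net = correlation_network(act, threshold=0.15)
        ab = net[(net["gene_a"] == "a") & (net["gene_b"] == "b")]
        assert ab["r"].iloc[0] == pytest.approx(1.0)

    def test_subthreshold_pair_dropped(self, rng):
        n = 2_000
        x = rng.normal(size=n)
        y = 0.10 * x + np.sqrt(1 - 0.01) * rng.normal(size=n)
        act = pd.DataFrame({"a": x, "b": y})
        r = np.corrcoef(x, y)[0, 1]
        net = correlation_network(act, threshold=0.15)
        assert (r < 0.15) == net.empty

    def test_matches_bruteforce_on_five_genes(self, rng):
        act = pd.DataFrame(rng.normal(size=(40, 5)), columns=list("abcde"))
        net = correlation_network(act, threshold=-1.1)  # keep all pairs
        for row in net.itertuples():
            oracle = np.corrcoef(act[row.gene_a], act[row.gene_b])[0, 1]
            assert row.r == pytest.approx(oracle, abs=1e-12)
        assert len(net) == 10

    def test_zero_variance_gene_excluded(self, rng):
        act = pd.DataFrame({"flat": np.ones(30), "a": rng.random(30), "b": rng.random(30)})
        with pytest.warns(UserWarning, match="flat"):
            net = correlation_network(act)
        assert "flat" not in set(net["gene_a"]) | set(net["gene_b"])
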