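import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import treedecon as td
from treedecon.reference import CPM_SCALE


class TestNormalizeCpm:
    def test_single_column_scales_to_a_million(self):
        m = pd.DataFrame({"s1": [2.0, 3.0, 5.0]}, index=["a", "b", "c"])
        out = td.normalize_cpm(m)
        np.testing.assert_allclose(out["s1"], [2e5, 3e5, 5e5])
        assert out["s1"].sum() == pytest.approx(1e6)

    def test_column_already_normalized_is_unchanged(self):
        m = pd.DataFrame({"s1": [4e5, 6e5]}, index=["a", "b"])
        np.testing.assert_allclose(td.normalize_cpm(m), m)

    def test_matches_per_element_oracle(self):
        rng = np.random.default_rng(3)
        m = pd.DataFrame(
            rng.integers(1, 50, size=(3, 2)).astype(float),
            index=["a", "b", "c"],
            columns=["s1", "s2"],
        )
        out = td.normalize_cpm(m)
        for j in m.columns:  # independent per-element computation
            total = sum(m.loc[g, j] for g in m.index)
            for g in m.index:
                assert out.loc[g, j] == pytest.approx(m.loc[g, j] / total * 1e6)

    def test_zero_column_names_sample(self):
        m = pd.DataFrame({"good": [1.0, 2.0], "empty": [0.0, 0.0]}, index=["a", "b"])
        with pytest.raises(ValueError, match="empty"):
            td.normalize_cpm(m)

    @settings(max_examples=25, deadline=None)
    @given(
        arrays(
            np.float64,
            (4, 3),
            elements=st.floats(0.0, 1e4, allow_nan=False),
        ).filter(lambda a: (a.sum(axis=0) > 0).all())
    )
    def test_idempotent(self, values):
        m = pd.DataFrame(values, index=list("abcd"), columns=list("xyz"))
        once = td.normalize_cpm(m)
        twice = td.normalize_cpm(once)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-9)


class TestClusterProfiles:
    def test_identical_cells_give_cpm_profile(self):
        ref = td.SingleCellReference(
            counts=np.array([[10, 0], [10, 0], [5, 5], [5, 5]], dtype=float),
            gene_ids=np.array(["g0", "g1"], dtype=object),
            cell_ids=np.array([f"c{i}" for i in range(4)], dtype=object),
            clusters=np.array(["A", "A", "B", "B"], dtype=object),
            subjects=np.array(["s", "s", "s", "s"], dtype=object),
        )
        profiles, _, single = td.cluster_profiles(ref)
        np.testing.assert_allclose(profiles.loc["A"], [1e6, 0.0])
        assert single == ["A", "B"]  # only one subject

    def test_two_subject_symmetry(self):
        # one cluster, 2 subjects with opposite pure profiles, equal cell counts
        ref = td.SingleCellReference(
            counts=np.array([[10, 0], [10, 0], [0, 10], [0, 10]], dtype=float),
            gene_ids=np.array(["g0", "g1"], dtype=object),
            cell_ids=np.array([f"c{i}" for i in range(4)], dtype=object),
            clusters=np.array(["A"] * 4, dtype=object),
            subjects=np.array(["s1", "s1", "s2", "s2"], dtype=object),
        )
        profiles, subject_profiles, _ = td.cluster_profiles(ref)
        np.testing.assert_allclose(profiles.loc["A"], [5e5, 5e5])
        np.testing.assert_allclose(subject_profiles.loc[("s1", "A")], [1e6, 0.0])

    def test_matches_groupby_oracle(self, small_sim):
        ref, _ = small_sim
        profiles, subject_profiles, _ = td.cluster_profiles(ref)
        cpm = ref.cpm()
        # brute force: loop over clusters, average cell CPM rows
        for cluster in ref.cluster_labels:
            mask = ref.clusters == cluster
            np.testing.assert_allclose(profiles.loc[cluster].values, cpm[mask].mean(axis=0))
        for subject in ref.subject_labels:
            for cluster in ref.cluster_labels:
                mask = (ref.clusters == cluster) & (ref.subjects == subject)
                if mask.any():
                    np.testing.assert_allclose(
                        subject_profiles.loc[(subject, cluster)].values,
                        cpm[mask].mean(axis=0),
                    )

    def test_invariant_to_cell_permutation(self, tiny_ref):
        profiles, _, _ = td.cluster_profiles(tiny_ref)
        rng = np.random.default_rng(0)
        perm = rng.permutation(tiny_ref.n_cells)
        shuffled = td.SingleCellReference(
            counts=tiny_ref.counts_dense()[perm],
            gene_ids=tiny_ref.gene_ids,
            cell_ids=tiny_ref.cell_ids[perm],
            clusters=tiny_ref.clusters[perm],
            subjects=tiny_ref.subjects[perm],
        )
        profiles2, _, _ = td.cluster_profiles(shuffled)
        pd.testing.assert_frame_equal(profiles, profiles2)


class TestGeneWeights:
    def test_constant_gene_gets_weight_one(self):
        ref = td.SingleCellReference(
            counts=np.full((8, 2), 10.0),
            gene_ids=np.array(["g0", "g1"], dtype=object),
            cell_ids=np.array([f"c{i}" for i in range(8)], dtype=object),
            clusters=np.array(["A"] * 4 + ["B"] * 4, dtype=object),
            subjects=np.array(["s1", "s2"] * 4, dtype=object),
        )
        w = td.gene_weights(ref)
        np.testing.assert_allclose(w, 1.0)

    def test_in_unit_interval(self, small_sim):
        ref, _ = small_sim
        w = td.gene_weights(ref)
        assert ((w > 0) & (w <= 1)).all()

    def test_mean_preserving_spread_never_raises_weight(self, tiny_ref):
        # spread g3 counts within each (cluster, subject) pair while a
        # compensating change in g4 keeps every cell total constant:
        # all means are unchanged, the cell-level CV of g3 strictly grows
        w = td.gene_weights(tiny_ref)
        counts = tiny_ref.counts_dense().copy()
        gi3 = list(tiny_ref.gene_ids).index("g3")
        gi4 = list(tiny_ref.gene_ids).index("g4")
        for i in range(0, tiny_ref.n_cells, 2):  # cells i, i+1 share labels
            counts[i, gi3] += 3
            counts[i, gi4] -= 3
            counts[i + 1, gi3] -= 3
            counts[i + 1, gi4] += 3
        spread = td.SingleCellReference(
            counts=counts, gene_ids=tiny_ref.gene_ids, cell_ids=tiny_ref.cell_ids,
            clusters=tiny_ref.clusters, subjects=tiny_ref.subjects,
        )
        w2 = td.gene_weights(spread)
        assert w2["g3"] < w["g3"]
        assert w2["g4"] < w["g4"]

    def test_larger_subject_variation_means_smaller_weight(self):
        # gA varies between subjects, gB is constant; the filler gene keeps
        # every cell total at 100 so CPM stays proportional to counts
        rows, clusters, subjects = [], [], []
        for cluster in ("A", "B"):
            for subject, a_level in (("s1", 10.0), ("s2", 30.0)):
                for _ in range(3):
                    rows.append([a_level, 20.0, 100.0 - a_level - 20.0])
                    clusters.append(cluster)
                    subjects.append(subject)
        ref = td.SingleCellReference(
            counts=np.array(rows),
            gene_ids=np.array(["gA", "gB", "filler"], dtype=object),
            cell_ids=np.array([f"c{i}" for i in range(len(rows))], dtype=object),
            clusters=np.array(clusters, dtype=object),
            subjects=np.array(subjects, dtype=object),
        )
        w = td.gene_weights(ref)
        assert w["gA"] < w["gB"]
        assert w["gB"] == pytest.approx(1.0)

    def test_matches_hand_computed_cvs(self, tiny_ref):
        w = td.gene_weights(tiny_ref)
        cpm = tiny_ref.cpm()
        for gi, gene in enumerate(tiny_ref.gene_ids):
            cell_cv2, subj_cv2 = [], []
            for cluster in tiny_ref.cluster_labels:
                mask = tiny_ref.clusters == cluster
                vals = cpm[mask, gi]
                if vals.mean() > 0:
                    cell_cv2.append(np.var(vals, ddof=1) / vals.mean() ** 2)
                subj_means = []
                for subject in tiny_ref.subject_labels:
                    smask = mask & (tiny_ref.subjects == subject)
                    if smask.any():
                        subj_means.append(cpm[smask, gi].mean())
                if len(subj_means) >= 2 and np.mean(subj_means) > 0:
                    subj_cv2.append(np.var(subj_means, ddof=1) / np.mean(subj_means) ** 2)
            expected = 1.0 / (
                1.0
                + (np.mean(subj_cv2) if subj_cv2 else 0.0)
                + (np.mean(cell_cv2) if cell_cv2 else 0.0)
            )
            assert w[gene] == pytest.approx(expected, rel=1e-9)


class TestSignature:
    def test_exclusive_markers_give_diagonal_dominance(self, tiny_ref):
        markers = {"A": [("g0", 5.0)], "B": [("g1", 5.0)], "C": [("g2", 5.0)]}
        sig = td.build_signature(tiny_ref, markers)
        B = sig.values
        for gene, cluster in zip(["g0", "g1", "g2"], ["A", "B", "C"]):
            assert B.loc[gene, cluster] == B.loc[gene].max()
            assert B.loc[gene, cluster] > 0

    def test_duplicate_marker_appears_once(self, tiny_ref):
        markers = {"A": [("g0", 5.0), ("g3", 1.0)], "B": [("g3", 2.0), ("g1", 5.0)]}
        sig = td.build_signature(tiny_ref, markers)
        assert sig.gene_ids.count("g3") == 1

    def test_row_count_is_union_of_planted(self, small_sim, small_markers, small_signature):
        expected = set()
        for genes in small_markers.per_cluster.values():
            expected |= {g for g, _ in genes}
        assert set(small_signature.gene_ids) == expected

    def test_missing_marker_raises(self, tiny_ref):
        with pytest.raises(KeyError, match="nope"):
            td.build_signature(tiny_ref, {"A": [("nope", 1.0)]})


class TestGroupSignature:
    def test_singleton_tree_reproduces_cluster_signature(self, tiny_ref):
        markers = {"A": [("g0", 5.0)], "B": [("g1", 5.0)], "C": [("g2", 5.0)]}
        sig = td.build_signature(tiny_ref, markers)
        tree = td.ClusterTree.singleton(["A", "B", "C"])
        gsig = td.group_signature(sig, tiny_ref, tree)
        np.testing.assert_allclose(
            gsig.values[["A", "B", "C"]].values, sig.values[["A", "B", "C"]].values
        )

    def test_equal_count_group_is_mean_of_members(self, tiny_ref):
        markers = {"A": [("g0", 5.0)], "B": [("g1", 5.0)], "C": [("g2", 5.0)]}
        sig = td.build_signature(tiny_ref, markers)
        tree = td.ClusterTree(groups={"AB": ["A", "B"], "C": ["C"]})
        gsig = td.group_signature(sig, tiny_ref, tree)
        expected = (sig.values["A"] + sig.values["B"]) / 2
        np.testing.assert_allclose(gsig.values["AB"], expected, rtol=1e-9)

    def test_matches_pooled_mean_oracle(self, small_sim, small_signature):
        ref, _ = small_sim
        labels = ref.cluster_labels
        tree = td.ClusterTree(
            groups={"g1": labels[:2], "g2": labels[2:3], "g3": labels[3:]}
        )
        gsig = td.group_signature(small_signature, ref, tree)
        cpm = ref.cpm()
        gene_pos = {g: i for i, g in enumerate(ref.gene_ids)}
        cols = [gene_pos[g] for g in small_signature.gene_ids]
        for name, members in tree.groups.items():
            mask = np.isin(ref.clusters, members)
            np.testing.assert_allclose(
                gsig.values[name].values, cpm[np.flatnonzero(mask)][:, cols].mean(axis=0)
            )

    def test_unknown_tree_label_raises(self, tiny_ref):
        markers = {"A": [("g0", 5.0)], "B": [("g1", 5.0)], "C": [("g2", 5.0)]}
        sig = td.build_signature(tiny_ref, markers)
        tree = td.ClusterTree(groups={"bad": ["A", "B", "Z"]})
        with pytest.raises(ValueError, match="Z"):
            td.group_signature(sig, tiny_ref, tree)


def test_crc_epithelial_tree_groups():
    tree = td.crc_epithelial_tree()
    assert tree.groups["tumor_CMS"] == ["CMS1", "CMS2", "CMS3", "CMS4"]
    assert len(tree.cluster_labels) == 9
    tree.validate_against(tree.cluster_labels)
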