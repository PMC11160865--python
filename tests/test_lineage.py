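import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cardiofusion import genotyping as gt
from cardiofusion import lineage as lin
from cardiofusion import sim as simmod
from cardiofusion import SimConfig


def _pipeline_to_assignments(bundle, **clade_kwargs):
    g = gt.genotype_matrix(bundle.counts)
    filtered, _ = gt.filter_panel(g)
    profiles = lin.binarize(filtered)
    z = lin.upgma_cluster(lin.cosine_similarity_matrix(profiles))
    clades = lin.define_clades(z, profiles, **clade_kwargs)
    ploidy = bundle.cells.set_index("cell_id")["ploidy_class"]
    return clades, profiles, lin.assign_cells(clades, profiles, ploidy)


class TestBinarize:
    def test_call_status_mapping(self):
        g = pd.DataFrame(
            {
                "cell_id": ["a", "a", "a"],
                "site_id": ["s1", "s2", "s3"],
                "call": ["CALLED", "ABSENT", "NO_DATA"],
            }
        )
        profiles = lin.binarize(g)
        assert list(profiles.loc["a"]) == [1, 0, 0]

    def test_all_called_row(self):
        g = pd.DataFrame(
            {"cell_id": ["a"] * 3, "site_id": ["s1", "s2", "s3"], "call": ["CALLED"] * 3}
        )
        assert lin.binarize(g).loc["a"].tolist() == [1, 1, 1]


class TestCosineSimilarity:
    def test_identity(self):
        assert lin.cosine_similarity([1, 1, 0], [1, 1, 0]) == pytest.approx(1.0)

    def test_orthogonal_supports(self):
        assert lin.cosine_similarity([1, 0, 0], [0, 1, 1]) == 0.0

    def test_hand_evaluation(self):
        assert lin.cosine_similarity([1, 1, 0], [1, 0, 1]) == pytest.approx(0.5)

    def test_zero_norm_convention(self):
        assert lin.cosine_similarity([0, 0], [1, 1]) == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            lin.cosine_similarity([1, 0], [1, 0, 1])

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(
            st.lists(st.integers(0, 1), min_size=5, max_size=5),
            min_size=2,
            max_size=8,
        )
    )
    def test_matrix_symmetric_and_bounded(self, rows):
        s = lin.cosine_similarity_matrix(np.array(rows))
        assert np.allclose(s, s.T)
        assert np.all((s >= 0) & (s <= 1))


def _brute_force_average_linkage(d):
    """O(n^3) UPGMA reference: merge the closest pair, average by sizes."""
    n = d.shape[0]
    d = d.astype(float).copy()
    active = {i: (1, i) for i in range(n)}  # id -> (size, node)
    dist = {(i, j): d[i, j] for i in range(n) for j in range(i + 1, n)}
    merges = []
    next_node = n
    while len(active) > 1:
        (i, j), h = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        si, ni = active[i]
        sj, nj = active[j]
        merges.append(h)
        for k in list(active):
            if k in (i, j):
                continue
            a = dist[tuple(sorted((i, k)))]
            b = dist[tuple(sorted((j, k)))]
            dist[tuple(sorted((i, k)))] = (si * a + sj * b) / (si + sj)
        active.pop(j)
        active[i] = (si + sj, next_node)
        dist = {
            k: v for k, v in dist.items() if j not in k
        }
        next_node += 1
    return np.array(merges)


class TestUpgma:
    def test_three_cell_hand_trace(self):
        # d(A,B)=0.1, d(A,C)=d(B,C)=0.8: merge {A,B} at 0.1, then C at 0.8
        s = 1.0 - np.array([[0, 0.1, 0.8], [0.1, 0, 0.8], [0.8, 0.8, 0]])
        z = lin.upgma_cluster(s)
        assert set(z[0, :2].astype(int)) == {0, 1}
        assert z[0, 2] == pytest.approx(0.1)
        assert z[1, 2] == pytest.approx(0.8)

    def test_identical_profiles_merge_at_zero(self):
        x = np.ones((4, 3))
        z = lin.upgma_cluster(lin.cosine_similarity_matrix(x))
        assert np.allclose(z[:, 2], 0.0)

    def test_single_cell_rejected(self):
        with pytest.raises(ValueError):
            lin.upgma_cluster(np.ones((1, 1)))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_merge_heights_match_brute_force_reference(self, seed):
        # tiny symmetric jitter removes exact ties, whose breaking order is
        # implementation-defined
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 2, size=(20, 12))
        s = lin.cosine_similarity_matrix(x)
        jit = rng.uniform(0, 1e-9, s.shape)
        s = s - (jit + jit.T)
        np.fill_diagonal(s, 1.0)
        z = lin.upgma_cluster(s)
        ref = _brute_force_average_linkage(1.0 - s)
        assert np.allclose(np.sort(z[:, 2]), np.sort(ref), atol=1e-12)

    def test_heights_monotone_nondecreasing(self, rng):
        x = rng.integers(0, 2, size=(30, 15))
        z = lin.upgma_cluster(lin.cosine_similarity_matrix(x))
        assert np.all(np.diff(z[:, 2]) >= -1e-12)

    def test_permutation_invariant_heights(self, rng):
        x = rng.integers(0, 2, size=(15, 10)).astype(float)
        x += rng.normal(0, 1e-6, x.shape)  # break exact ties
        z1 = lin.upgma_cluster(lin.cosine_similarity_matrix(x))
        perm = rng.permutation(15)
        z2 = lin.upgma_cluster(lin.cosine_similarity_matrix(x[perm]))
        assert np.allclose(np.sort(z1[:, 2]), np.sort(z2[:, 2]), atol=1e-9)


class TestNewick:
    def test_round_trip_leaf_set_and_heights(self, rng):
        import dendropy

        x = rng.integers(0, 2, size=(8, 6))
        z = lin.upgma_cluster(lin.cosine_similarity_matrix(x))
        labels = [f"cell{i}" for i in range(8)]
        nwk = lin.linkage_to_newick(z, labels)
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        assert {t.label for t in tree.taxon_namespace} == set(labels)
        # ultrametric: every root-to-leaf path length equals the root height
        depths = [leaf.distance_from_root() for leaf in tree.leaf_node_iter()]
        assert np.allclose(depths, z[-1, 2], atol=1e-5)


class TestDefineCladesAndAssignment:
    def test_zero_dropout_recovers_simulated_clades_exactly(self, clean_bundle):
        clades, profiles, assignments = _pipeline_to_assignments(clean_bundle)
        truth_defs = {
            frozenset(v) for v in clean_bundle.lineage.clade_defs.values()
        }
        found_defs = {frozenset(v) for v in clades.clades.values()}
        assert found_defs == truth_defs

    def test_zero_dropout_assignments_match_origins(self, clean_bundle):
        clades, profiles, assignments = _pipeline_to_assignments(clean_bundle)
        # map found clade ids to true clade indices through defining sites
        site_to_true = {
            s: c for c, sites in clean_bundle.lineage.clade_defs.items() for s in sites
        }
        clade_to_true = {
            cid: site_to_true[next(iter(sites))] for cid, sites in clades.clades.items()
        }
        merged = assignments.merge(clean_bundle.cells, on=["cell_id", "ploidy_class"])
        for _, row in merged[~merged["is_doublet"]].iterrows():
            found = {
                clade_to_true[c] for c in row["clades"].split(",") if c
            }
            true = {int(v) for v in str(row["origin_clades"]).split(",")}
            assert found == true

    def test_no_false_multiclade_among_unfused(self, clean_bundle):
        _, _, assignments = _pipeline_to_assignments(clean_bundle)
        merged = assignments.merge(clean_bundle.cells, on=["cell_id", "ploidy_class"])
        unfused = merged[~merged["is_fused"] & ~merged["is_doublet"]]
        assert (unfused["n_clades"] <= 1).all()

    def test_identical_cells_give_single_clade(self):
        profiles = pd.DataFrame(
            np.ones((6, 4), dtype=np.int8),
            index=[f"c{i}" for i in range(6)],
            columns=[f"s{i}" for i in range(4)],
        )
        z = lin.upgma_cluster(lin.cosine_similarity_matrix(profiles))
        clades = lin.define_clades(z, profiles)
        assert len(clades.clades) == 1

    def test_defining_sites_disjoint_across_clades(self, dropout_bundle):
        clades, _, _ = _pipeline_to_assignments(dropout_bundle)
        seen = set()
        for sites in clades.clades.values():
            assert not (sites & seen)
            seen |= sites

    def test_no_defining_site_in_foreign_single_clade_cell(self, dropout_bundle):
        """Clade-specific exclusivity: no defining sSNV is carried by a cell
        assigned solely to a different clade (holds by construction)."""
        clades, profiles, assignments = _pipeline_to_assignments(dropout_bundle)
        owner = clades.defining_site_to_clade()
        single = assignments[assignments["status"] == lin.SINGLE_CLADE]
        x = profiles.loc[single["cell_id"]]
        for site, cid in owner.items():
            carriers = set(x.index[x[site] > 0])
            foreign = single[single["cell_id"].isin(carriers) & (single["clades"] != cid)]
            assert foreign.empty

    def test_dropout_recovery_across_seeds(self):
        """9 nested clades, 1-5 sSNVs per branch, AD+LD=0.3, 400 cells:
        the reconstruction recovers most clades with faithful memberships
        and never invents multi-clade cells in fusion-free cohorts."""
        recovered, correct = [], []
        for seed in (1, 2, 3, 4, 5):
            cfg = SimConfig(
                seed=seed,
                n_cells_by_ploidy={"tetraploid": 400},
                fusion_fraction_by_ploidy={"tetraploid": 0.0},
                doublet_rate=0.0,
                allelic_dropout=0.2,
                locus_dropout=0.1,
            )
            bundle = simmod.simulate_dataset(cfg)
            clades, _, assignments = _pipeline_to_assignments(bundle)
            merged = assignments.merge(bundle.cells, on=["cell_id", "ploidy_class"])
            single = merged[merged["n_clades"] == 1]
            mapping = {}
            for cid in clades.clades:
                members = single.loc[single["clades"] == cid, "origin_clades"]
                if len(members):
                    mapping[cid] = members.mode()[0]
            recovered.append(len(set(mapping.values())))
            ok = single.apply(
                lambda r: mapping.get(r["clades"]) == r["origin_clades"], axis=1
            )
            correct.append(ok.mean())
            assert (merged["n_clades"] <= 1).all()  # no fusion -> no multi-clade
        assert np.median(recovered) >= 8
        assert np.median(correct) >= 0.85

    def test_target_clades_override_caps_count(self, clean_bundle):
        g = gt.genotype_matrix(clean_bundle.counts)
        filtered, _ = gt.filter_panel(g)
        profiles = lin.binarize(filtered)
        z = lin.upgma_cluster(lin.cosine_similarity_matrix(profiles))
        clades = lin.define_clades(z, profiles, target_clades=2)
        assert len(clades.clades) <= 2


class TestAssignCells:
    def _toy(self):
        clades = lin.CladeSet(
            clades={"cladeA": {"s1"}, "cladeB": {"s2"}},
            members={"cladeA": set(), "cladeB": set()},
        )
        profiles = pd.DataFrame(
            [[1, 0, 1], [1, 1, 0], [0, 0, 1]],
            index=["a", "ab", "none"],
            columns=["s1", "s2", "s3"],
        )
        return clades, profiles

    def test_single_multi_and_uncladed(self):
        clades, profiles = self._toy()
        a = lin.assign_cells(clades, profiles).set_index("cell_id")
        assert a.loc["a", "status"] == lin.SINGLE_CLADE
        assert a.loc["ab", "status"] == lin.MULTI_CLADE
        assert a.loc["ab", "n_clades"] == 2
        assert a.loc["none", "status"] == lin.UNCLADED


class TestDetectFusion:
    def test_observed_fraction(self):
        rows = (
            [{"cell_id": f"t{i}", "ploidy_class": "tetraploid",
              "clades": "cladeA", "n_clades": 1, "status": "SINGLE_CLADE"}
             for i in range(130)]
            + [{"cell_id": f"m{i}", "ploidy_class": "tetraploid",
                "clades": "cladeA,cladeB", "n_clades": 2, "status": "MULTI_CLADE"}
               for i in range(8)]
        )
        summary = lin.detect_fusion(pd.DataFrame(rows)).set_index("ploidy_class")
        assert summary.loc["tetraploid", "observed_multiclade_fraction"] == pytest.approx(
            8 / 138
        )

    def test_no_multiclade_gives_zero(self):
        df = pd.DataFrame(
            [{"cell_id": "a", "ploidy_class": "diploid", "clades": "cladeA",
              "n_clades": 1, "status": "SINGLE_CLADE"}]
        )
        s = lin.detect_fusion(df).set_index("ploidy_class")
        assert s.loc["diploid", "observed_multiclade_fraction"] == 0.0

    def test_diploid_multiclade_flagged_as_presumptive_doublets(self):
        df = pd.DataFrame(
            [
                {"cell_id": "a", "ploidy_class": "diploid", "clades": "cladeA,cladeB",
                 "n_clades": 2, "status": "MULTI_CLADE"},
                {"cell_id": "b", "ploidy_class": "higher", "clades": "cladeA,cladeB",
                 "n_clades": 2, "status": "MULTI_CLADE"},
            ]
        )
        s = lin.detect_fusion(df).set_index("ploidy_class")
        assert s.loc["diploid", "presumptive_doublets"] == 1
        assert s.loc["higher", "presumptive_doublets"] == 0
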