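import numpy as np
import pandas as pd
import pytest

from drafts.cross_species import (
    cut_two_clusters,
    detect_depletion,
    hierarchical_cluster,
    pairwise_correlation,
    pca,
    profile_matrix,
    species_selective,
)


def profile(rng, n=200, samples=("a", "b", "c")):
    m = pd.DataFrame(
        rng.normal(size=(n, len(samples))),
        index=[f"C{i}" for i in range(n)],
        columns=pd.Index(samples, name="sample"),
    )
    return m


class TestPairwiseCorrelation:
    def test_duplicated_column_gives_unit_correlation(self, rng):
        m = profile(rng)
        m["b"] = m["a"]
        r = pairwise_correlation(m)
        assert r.loc["a", "b"] == pytest.approx(1.0)
        assert np.allclose(r, r.T)
        assert np.allclose(np.diag(r), 1.0)

    def test_negated_column(self, rng):
        m = profile(rng, samples=("a", "b"))
        m["b"] = -m["a"]
        assert pairwise_correlation(m).loc["a", "b"] == pytest.approx(-1.0)

    def test_shared_variance_sets_r(self, rng):
        # two species share 50% of activity variance -> r ~= sqrt(0.5)
        n = 2000
        shared = rng.normal(size=n)
        m = pd.DataFrame(
            {
                "a": np.sqrt(0.5) * shared + np.sqrt(0.5) * rng.normal(size=n),
                "b": np.sqrt(0.5) * shared + np.sqrt(0.5) * rng.normal(size=n),
            }
        )
        m.columns.name = "sample"
        r = pairwise_correlation(m).loc["a", "b"]
        assert r == pytest.approx(np.sqrt(0.5) ** 2, abs=0.05)

    def test_constant_column_errors(self, rng):
        m = profile(rng)
        m["b"] = 1.0
        with pytest.raises(ValueError, match="b"):
            pairwise_correlation(m)

    def test_psd(self, rng):
        r = pairwise_correlation(profile(rng, samples=list("abcdef")))
        eigs = np.linalg.eigvalsh(r.to_numpy())
        assert eigs.min() > -1e-8


class TestPca:
    def test_identical_samples_project_together(self, rng):
        m = profile(rng, samples=("a", "b", "c"))
        m["b"] = m["a"]
        scores, _ = pca(m)
        np.testing.assert_allclose(scores.loc["a"], scores.loc["b"], atol=1e-9)

    def test_explained_variance_sums_to_one(self, rng):
        m = profile(rng, n=50, samples=list("abcde"))
        _, evf = pca(m, n_components=5)
        assert evf.sum() == pytest.approx(1.0)

    def test_scores_preserve_pairwise_distances(self, rng):
        m = profile(rng, n=40, samples=list("abcde"))
        scores, _ = pca(m, n_components=5)
        X = m.T.to_numpy()
        Xc = X - X.mean(axis=0)
        for i in range(5):
            for j in range(i + 1, 5):
                d_true = np.linalg.norm(Xc[i] - Xc[j])
                d_pca = np.linalg.norm(scores.iloc[i] - scores.iloc[j])
                assert d_pca == pytest.approx(d_true, rel=1e-9)

    def test_too_many_components_errors(self, rng):
        with pytest.raises(ValueError):
            pca(profile(rng, samples=("a", "b")), n_components=5)

    def test_deterministic_signs(self, rng):
        m = profile(rng, samples=list("abcd"))
        s1, _ = pca(m)
        s2, _ = pca(m.copy())
        pd.testing.assert_frame_equal(s1, s2)


class TestHierarchical:
    def test_identical_pair_joins_first(self, rng):
        m = profile(rng, samples=("a", "b", "c"))
        m["b"] = m["a"] + rng.normal(0, 1e-6, size=len(m))
        m["c"] = -m["a"]
        nwk = hierarchical_cluster(m, axis="samples")
        # the identical pair forms the innermost clade
        inner = nwk[nwk.rindex("(") :]
        assert "a" in inner and "b" in inner and "c" not in inner

    def test_average_linkage_matches_brute_force_on_three_leaves(self, rng):
        m = profile(rng, n=100, samples=("a", "b", "c"))
        corr = m.corr()
        d = 1 - corr
        # brute-force average linkage: closest pair joins, then the rest
        pairs = [("a", "b"), ("a", "c"), ("b", "c")]
        first = min(pairs, key=lambda p: d.loc[p[0], p[1]])
        nwk = hierarchical_cluster(m, axis="samples")
        inner = nwk[nwk.rindex("(") : nwk.index(")", nwk.rindex("("))]
        assert set(first) == {x.split(":")[0] for x in inner.strip("(").split(",")}

    def test_planted_two_block_structure_recovered(self, rng):
        blockA = rng.normal(size=5)
        blockB = rng.normal(size=5)
        rows = []
        for i in range(40):
            base = blockA if i < 20 else blockB
            rows.append(base + rng.normal(0, 0.1, size=5))
        m = pd.DataFrame(rows, index=[f"C{i}" for i in range(40)])
        m.columns.name = "sample"
        labels = cut_two_clusters(m, axis="constructs")
        groups = [set(labels.index[labels == g]) for g in (1, 2)]
        expected = [{f"C{i}" for i in range(20)}, {f"C{i}" for i in range(20, 40)}]
        assert groups in (expected, expected[::-1])  # Rand index 1.0


def make_activity(tx_raw: dict, samples) -> pd.DataFrame:
    idx = sorted(tx_raw)
    cols = {}
    for si, s in enumerate(samples):
        cols[(s, "tx_raw")] = pd.Series({c: tx_raw[c][si] for c in idx})
        cols[(s, "pass_filter")] = pd.Series({c: True for c in idx})
    df = pd.DataFrame(cols)
    df.columns = pd.MultiIndex.from_tuples(df.columns, names=["sample", "field"])
    return df


class TestSpeciesSelective:
    def test_twenty_fold_is_selective(self):
        acts = make_activity({"A": (100.0, 5.0)}, ("s1", "s2"))
        sel = species_selective(acts)
        assert sel == {"s1": ["A"], "s2": []}

    def test_exactly_ten_fold_is_not_selective(self):
        acts = make_activity({"A": (100.0, 10.0)}, ("s1", "s2"))
        sel = species_selective(acts)
        assert sel == {"s1": [], "s2": []}

    def test_simulated_selective_set_recovered_exactly(self, rng):
        tx = {}
        planted = {"s1": set(), "s2": set()}
        for i in range(100):
            cid = f"C{i:03d}"
            base = float(rng.uniform(1, 10))
            if i % 10 == 0:
                tx[cid] = (base * 20, base)
                planted["s1"].add(cid)
            elif i % 10 == 5:
                tx[cid] = (base, base * 15)
                planted["s2"].add(cid)
            else:
                tx[cid] = (base, base * float(rng.uniform(0.5, 2)))
        sel = species_selective(make_activity(tx, ("s1", "s2")))
        assert set(sel["s1"]) == planted["s1"]
        assert set(sel["s2"]) == planted["s2"]


class TestDepletion:
    def test_identical_pools_nothing_depleted(self):
        counts = pd.Series([100] * 20, index=[f"C{i}" for i in range(20)])
        seqs = {f"C{i}": "ACGT" * 20 for i in range(20)}
        rep = detect_depletion(counts, counts, seqs)
        assert rep.depleted_ids == []
        assert "skipped" in rep.note

    def test_bh_on_tied_pvalues_is_identity(self):
        from scipy.stats import false_discovery_control

        q = false_discovery_control(np.full(50, 0.01), method="bh")
        np.testing.assert_allclose(q, 0.01)

    def test_planted_ccngg_depletion_recovered(self):
        from drafts import synthetic_data as sd

        lib, _ = sd.generate_library(300, motif_plant_frac=0.0, seed=51)
        din, dout, hit = sd.simulate_depletion_counts(
            lib, depth_in=150_000, depth_out=150_000, seed=52
        )
        rep = detect_depletion(din, dout, lib)
        recovered = len(set(rep.depleted_ids) & set(hit)) / len(hit)
        assert recovered >= 0.95
        assert rep.enriched_kmers.iloc[0]["kmer"] == "CCNGG"
        dep = rep.per_construct[rep.per_construct["depleted"]]
        assert (dep["log2_fc"] <= np.log2(0.5)).all()

    def test_null_false_positive_rate(self):
        from drafts import synthetic_data as sd

        fprs = []
        for s in range(30):
            lib, _ = sd.generate_library(
                100, reg_len=80, motif_plant_frac=0.0, seed=500 + s
            )
            din, dout, _ = sd.simulate_depletion_counts(
                lib, factor=1.0, depth_in=40_000, depth_out=40_000, seed=600 + s
            )
            rep = detect_depletion(din, dout, lib)
            fprs.append(len(rep.depleted_ids) / len(lib))
        assert np.mean(fprs) <= 0.05


class TestProfileAndHybrids:
    def test_profile_matrix_requires_universal_activity(self, sim_small):
        from drafts import quantify

        t = quantify.tabulate_counts(sim_small["reads"], sim_small["lib"])
        acts = quantify.compute_activity(t)
        m = profile_matrix(acts)
        assert not m.isna().any().any()
        passing = acts[("sample1", "pass_filter")] & acts[("sample1", "tx_z")].notna()
        assert set(m.index) == set(acts.index[passing])

    def test_hybrid_profiles_track_mixing_weight(self, rng):
        # hybrid = weighted average of two species' log activities
        n = 500
        a = rng.normal(size=n)
        b = 0.3 * a + np.sqrt(1 - 0.09) * rng.normal(size=n)
        rs = []
        for w in (0.0, 0.25, 0.5, 0.75, 1.0):
            hybrid = w * a + (1 - w) * b
            rs.append(np.corrcoef(hybrid, a)[0, 1])
        assert all(x < y for x, y in zip(rs, rs[1:]))
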