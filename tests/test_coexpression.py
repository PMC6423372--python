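"""Mutual-rank networks, module detection and metamodule collapse."""
import itertools

import numpy as np
import pandas as pd
import pytest

from polyploidkit import coexpression as cx
from polyploidkit.errors import ValidationError
from polyploidkit.model import ExpressionMatrix, Library


def _matrix(counts: np.ndarray, n_libs=None, gene_ids=None):
    counts = np.asarray(counts)
    n_genes, n_libs = counts.shape
    gene_ids = gene_ids or [f"g{i:03d}" for i in range(n_genes)]
    libs = [Library(library_id=f"L{j:02d}") for j in range(n_libs)]
    return ExpressionMatrix(
        counts=pd.DataFrame(counts, index=gene_ids,
                            columns=[l.library_id for l in libs]),
        gene_length_bp=pd.Series(1000, index=gene_ids),
        libraries=libs)


class TestFilterLowExpression:
    def test_all_zero_gene_removed(self):
        counts = np.vstack([np.zeros(35, dtype=int), np.full(35, 50)])
        kept = cx.filter_low_expression(_matrix(counts))
        assert kept == ["g001"]

    def test_rule_boundary_30_vs_29(self):
        base = np.full(35, 50)
        gene_30_low = base.copy(); gene_30_low[:30] = 4
        gene_29_low = base.copy(); gene_29_low[:29] = 4
        kept = cx.filter_low_expression(_matrix(np.vstack([gene_30_low, gene_29_low])))
        assert kept == ["g001"]  # 30 low conditions removed, 29 kept

    def test_too_few_libraries_keeps_all_with_warning(self):
        counts = np.zeros((2, 5), dtype=int)
        with pytest.warns(UserWarning, match="min_conditions"):
            kept = cx.filter_low_expression(_matrix(counts))
        assert len(kept) == 2


class TestTransformCounts:
    def test_log2_with_unit_size_factors(self):
        # identical libraries -> size factors 1; count 7 -> log2(8) = 3
        counts = np.array([[7, 7], [100, 100], [10, 10]])
        out = cx.transform_counts(_matrix(counts))
        assert out.iloc[0, 0] == pytest.approx(3.0)
        assert out.iloc[0, 1] == pytest.approx(3.0)

    def test_zero_count_maps_to_zero(self):
        counts = np.array([[0, 0], [100, 100], [10, 10]])
        out = cx.transform_counts(_matrix(counts))
        assert out.iloc[0, 0] == 0.0

    def test_depth_doubling_absorbed_by_size_factor(self):
        counts = np.array([[10, 20], [100, 200], [50, 100]])
        sf = cx.size_factors(_matrix(counts).counts)
        assert sf["L01"] / sf["L00"] == pytest.approx(2.0)
        out = cx.transform_counts(_matrix(counts))
        np.testing.assert_allclose(out["L00"], out["L01"], rtol=1e-12)

    def test_all_zero_library_rejected(self):
        counts = np.array([[1, 0], [2, 0]])
        with pytest.raises(ValidationError):
            cx.transform_counts(_matrix(counts))


class TestPcc:
    def test_self_correlation_and_anticorrelation(self):
        x = np.arange(10.0)
        df = pd.DataFrame([x, -x, x * 2], index=["a", "b", "c"])
        r = cx.pcc_matrix(df)
        assert r.loc["a", "a"] == pytest.approx(1.0)
        assert r.loc["a", "b"] == pytest.approx(-1.0)
        assert r.loc["a", "c"] == pytest.approx(1.0)

    def test_hand_computed_correlation(self):
        df = pd.DataFrame([[1.0, 2.0, 4.0], [1.0, 3.0, 5.0], [5.0, 1.0, 2.0]],
                          index=["a", "b", "c"])
        r = cx.pcc_matrix(df)
        expected = np.corrcoef(df.to_numpy())
        np.testing.assert_allclose(r.to_numpy(), expected, atol=1e-12)

    def test_zero_variance_gene_dropped(self):
        df = pd.DataFrame([[1.0, 2.0, 3.0], [5.0, 5.0, 5.0]], index=["a", "b"])
        with pytest.warns(UserWarning, match="zero-variance"):
            r = cx.pcc_matrix(df)
        assert list(r.index) == ["a"]


def _oracle_mutual_rank(pcc: pd.DataFrame) -> pd.DataFrame:
    """Brute-force double ranking: explicit per-row sorted rank tables with
    averaged ties."""
    genes = list(pcc.index)
    rank = pd.DataFrame(np.nan, index=genes, columns=genes)
    for i in genes:
        partners = [j for j in genes if j != i]
        vals = sorted({pcc.loc[i, j] for j in partners}, reverse=True)
        pos = 1
        val_rank = {}
        for v in vals:
            n = sum(1 for j in partners if pcc.loc[i, j] == v)
            val_rank[v] = pos + (n - 1) / 2  # average of occupied positions
            pos += n
        for j in partners:
            rank.loc[i, j] = val_rank[pcc.loc[i, j]]
    mr = pd.DataFrame(np.nan, index=genes, columns=genes)
    for i, j in itertools.permutations(genes, 2):
        mr.loc[i, j] = np.sqrt(rank.loc[i, j] * rank.loc[j, i])
    return mr


class TestMutualRank:
    def test_three_gene_rank_table(self):
        pcc = pd.DataFrame([[1.0, 0.9, 0.5], [0.9, 1.0, 0.7], [0.5, 0.7, 1.0]],
                           index=list("abc"), columns=list("abc"))
        mr = cx.mutual_rank(pcc)
        assert mr.loc["a", "b"] == pytest.approx(1.0)  # reciprocal best
        assert mr.loc["a", "c"] == pytest.approx(2.0)
        assert mr.loc["b", "c"] == pytest.approx(np.sqrt(2))

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_double_rank_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 9))
        x = rng.normal(size=(n, 12))
        pcc = pd.DataFrame(np.corrcoef(x),
                           index=[f"g{i}" for i in range(n)],
                           columns=[f"g{i}" for i in range(n)])
        got = cx.mutual_rank(pcc)
        expected = _oracle_mutual_rank(pcc)
        np.testing.assert_allclose(got.to_numpy(), expected.to_numpy(),
                                   atol=1e-12, equal_nan=True)

    def test_symmetry_and_floor(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(6, 10))
        pcc = pd.DataFrame(np.corrcoef(x))
        mr = cx.mutual_rank(pcc).to_numpy()
        np.testing.assert_allclose(mr, mr.T, equal_nan=True)
        assert np.nanmin(mr) >= 1.0


class TestBuildNetworks:
    def _mats(self):
        genes = list("abcd")
        pcc = pd.DataFrame(0.9, index=genes, columns=genes)
        mr = pd.DataFrame([[np.nan, 1.0, 6.0, 2.0],
                           [1.0, np.nan, 40.0, 3.0],
                           [6.0, 40.0, np.nan, 9.0],
                           [2.0, 3.0, 9.0, np.nan]], index=genes, columns=genes)
        return pcc, mr

    def test_decay_values(self):
        pcc, mr = self._mats()
        nets = cx.build_networks(pcc, mr, xs=(5, 10))
        e5 = nets[5].set_index(["gene_a", "gene_b"])
        assert e5.loc[("a", "b"), "weight"] == pytest.approx(1.0)  # MR=1
        assert e5.loc[("a", "c"), "weight"] == pytest.approx(np.exp(-1.0))  # MR=6, x=5
        e10 = nets[10].set_index(["gene_a", "gene_b"])
        assert e10.loc[("a", "d"), "weight"] == pytest.approx(np.exp(-0.1))

    def test_pcc_filter(self):
        pcc, mr = self._mats()
        pcc.loc["a", "b"] = pcc.loc["b", "a"] = 0.5  # below 0.6
        nets = cx.build_networks(pcc, mr, xs=(5,))
        assert ("a", "b") not in set(zip(nets[5]["gene_a"], nets[5]["gene_b"]))

    def test_edge_sets_nested_in_x(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(15, 10))
        x[5:] += x[:1] * 2  # induce correlation
        pcc = pd.DataFrame(np.corrcoef(x))
        pcc.index = pcc.columns = [f"g{i:02d}" for i in range(15)]
        mr = cx.mutual_rank(pcc)
        nets = cx.build_networks(pcc, mr)
        edge_sets = {xv: set(zip(df["gene_a"], df["gene_b"]))
                     for xv, df in nets.items()}
        for lo, hi in itertools.pairwise(sorted(edge_sets)):
            assert edge_sets[lo] <= edge_sets[hi]


def _clique_edges(cliques, weight=1.0, x=5):
    rows = []
    for nodes in cliques:
        for u, v in itertools.combinations(nodes, 2):
            rows.append({"gene_a": u, "gene_b": v, "pcc": 1.0, "mr": 1.0,
                         "weight": weight, "x": x})
    return pd.DataFrame(rows)


class TestDetectModules:
    def test_two_disjoint_cliques(self):
        edges = _clique_edges([list("abcde"), list("fghij")])
        mods = cx.detect_modules(edges)
        assert sorted(sorted(m.genes) for m in mods) == \
            [list("abcde"), list("fghij")]
        for m in mods:
            # w_in = 10, boundary 0, penalty 2*5 -> cohesiveness 0.5
            assert m.quality == pytest.approx(0.5)
            assert m.p_value <= 0.1

    def test_single_edge_cohesiveness_boundary(self):
        # one weight-1 edge: f = 1/(1+0+4) = 0.2, exactly at the inclusive
        # quality threshold; retention then hinges on the p-value, and an
        # isolated pair cannot beat the exact rank-sum floor of 1/6
        edges = _clique_edges([list("ab")])
        assert cx.detect_modules(edges) == []
        relaxed = cx.detect_modules(edges, p_max=0.2)
        assert len(relaxed) == 1
        assert relaxed[0].quality == pytest.approx(0.2)
        assert relaxed[0].p_value == pytest.approx(1 / 6, abs=1e-9)

    def test_planted_partition_recovery(self):
        rng = np.random.default_rng(42)
        rows = []
        for u in range(40):
            for v in range(u + 1, 40):
                p = 0.9 if (u < 20) == (v < 20) else 0.05
                if rng.random() < p:
                    rows.append({"gene_a": f"g{u:02d}", "gene_b": f"g{v:02d}",
                                 "pcc": 1.0, "mr": 1.0, "weight": 1.0, "x": 5})
        mods = cx.detect_modules(pd.DataFrame(rows))
        blocks = [set(f"g{u:02d}" for u in range(20)),
                  set(f"g{u:02d}" for u in range(20, 40))]
        for block in blocks:
            jac = max(len(block & set(m.genes)) / len(block | set(m.genes))
                      for m in mods)
            assert jac >= 0.9

    def test_empty_network(self):
        assert cx.detect_modules(pd.DataFrame(
            columns=["gene_a", "gene_b", "pcc", "mr", "weight", "x"])) == []

    def test_null_gaussian_expression_yields_no_modules(self):
        """On unstructured i.i.d. Gaussian expression, the full pipeline
        retains no modules in >=90% of seeds."""
        no_module_seeds = 0
        n_seeds = 50
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            expr = pd.DataFrame(rng.normal(size=(100, 35)),
                                index=[f"g{i:03d}" for i in range(100)])
            pcc = cx.pcc_matrix(expr)
            mr = cx.mutual_rank(pcc)
            nets = cx.build_networks(pcc, mr)
            n_mods = sum(len(cx.detect_modules(e, x=x)) for x, e in nets.items())
            no_module_seeds += (n_mods == 0)
        assert no_module_seeds >= 0.9 * n_seeds


class TestMetamodules:
    def _mod(self, mid, x, genes, q=0.5, p=0.01):
        return cx.Module(module_id=mid, x=x, genes=frozenset(genes),
                         quality=q, p_value=p)

    def test_high_overlap_collapses(self):
        m1 = self._mod("m1", 5, "abc")
        m2 = self._mod("m2", 10, "abcd")  # Jaccard 0.75
        mms = cx.collapse_metamodules([m1, m2])
        assert len(mms) == 1
        assert mms[0].genes == frozenset("abcd")

    def test_disjoint_modules_stay_separate(self):
        mms = cx.collapse_metamodules([self._mod("m1", 5, "abc"),
                                       self._mod("m2", 10, "xyz")])
        assert len(mms) == 2

    def test_gene_sets_disjoint_and_complete(self):
        rng = np.random.default_rng(1)
        genes = [f"g{i:02d}" for i in range(30)]
        modules = []
        for k in range(12):
            size = int(rng.integers(3, 9))
            members = rng.choice(genes, size=size, replace=False)
            modules.append(self._mod(f"m{k}", 5, members))
        mms = cx.collapse_metamodules(modules)
        assigned = [g for mm in mms for g in mm.genes]
        assert len(assigned) == len(set(assigned))  # disjoint
        assert set(assigned) == {g for m in modules for g in m.genes}  # complete

    def test_shared_gene_goes_to_most_frequent_component(self):
        # 'z' appears twice in the first component, once in the second
        mods = [self._mod("m1", 5, ["a", "b", "z"]),
                self._mod("m2", 10, ["a", "b", "z"]),
                self._mod("m3", 5, ["x", "y", "z"])]
        mms = cx.collapse_metamodules(mods)
        holder = next(mm for mm in mms if "a" in mm.genes)
        assert "z" in holder.genes
        other = next(mm for mm in mms if "x" in mm.genes)
        assert "z" not in other.genes


class TestAnnotateMetamodules:
    def _mm(self, genes):
        return cx.Metamodule(metamodule_id="MM0001", genes=frozenset(genes),
                             module_ids=["m1"])

    def _fpkm(self):
        return pd.DataFrame({"F1": [10.0, 10.0], "F2": [10.0, 10.0],
                             "V1": [2.0, 2.0], "V2": [2.0, 2.0]},
                            index=["a", "b"])

    def test_fruit_elevated_strict_inequality(self):
        mm = self._mm("ab")
        cx.annotate_metamodules([mm], self._fpkm(), ["F1", "F2"])
        assert mm.fruit_elevated is True
        flat = self._fpkm() * 0 + 5.0
        mm2 = self._mm("ab")
        cx.annotate_metamodules([mm2], flat, ["F1", "F2"])
        assert mm2.fruit_elevated is False  # equal means -> not elevated

    def test_sm_domain_flags(self):
        mm = self._mm("ab")
        domain_map = pd.DataFrame({"gene_id": ["a", "b"],
                                   "domain_id": ["PF00001", "PF00067"]})
        cx.annotate_metamodules([mm], self._fpkm(), ["F1", "F2"],
                                domain_map=domain_map,
                                sm_domains=["PF00067"])
        assert mm.sm_domain_hit is True
        assert mm.sm_domains == frozenset({"PF00067"})

    def test_no_domain_map_leaves_flag_none(self):
        mm = self._mm("ab")
        cx.annotate_metamodules([mm], self._fpkm(), ["F1", "F2"])
        assert mm.sm_domain_hit is None

    def test_packaged_sm_domain_list_loads(self):
        domains = cx.sm_domain_list()
        assert "PF00067" in domains
        assert all(d.startswith("PF") for d in domains)
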