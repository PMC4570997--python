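import itertools
import math

import dendropy
import networkx as nx
import numpy as np
import pytest
from dendropy.calculate import popgenstat

from cladedelim.popgen import (
    amova,
    collapse_haplotypes,
    diversity,
    diversity_table,
    fu_li_dstar,
    msn,
    msn_edgelist,
    pairwise_difference_matrix,
    tajimas_d,
)
from cladedelim.simulate import SimScenario, simulate_clade_dataset, simulate_coalescent, evolve_k80
from cladedelim.seqio import Alignment, SequenceRecord

from conftest import make_alignment

_DEC = np.array(list("ACGT"))


def coalescent_alignment(n, theta_locus, L, rng, prefix="t"):
    """Neutral sample of n sequences at per-locus theta (per-site theta/L)."""
    tree = simulate_coalescent(n, theta_locus / L, rng, prefix=prefix)
    tips = evolve_k80(tree, L, 4.0, rng)
    return make_alignment(
        ["".join(_DEC[tips[f"{prefix}{i}"]]) for i in range(n)],
        ids=[f"{prefix}{i}" for i in range(n)],
    )


class TestCollapseHaplotypes:
    def test_identical_sequences_one_haplotype(self):
        tab = collapse_haplotypes(make_alignment(["ACGT"] * 5))
        assert tab.n_haplotypes == 1 and tab.counts == [5]

    def test_counts_ordered_and_named(self):
        tab = collapse_haplotypes(make_alignment(["AAAA", "AAAT", "AAAA", "AAAA", "AAAT", "TTTT"]))
        assert tab.names == ["H1", "H2", "H3"]
        assert tab.counts == [3, 2, 1]
        assert tab.n_sequences == 6

    def test_gap_columns_removed_before_collapsing(self):
        # the two sequences differ only at a column carrying a gap: one haplotype
        tab = collapse_haplotypes(make_alignment(["ACG-", "ACGT"]))
        assert tab.n_haplotypes == 1
        assert len(tab.haplotypes[0]) == 3

    def test_country_composition(self):
        aln = make_alignment(
            ["AAAA", "AAAA", "TTTT"], country=["Egypt", "Pakistan", "Egypt"]
        )
        tab = collapse_haplotypes(aln)
        assert tab.group_counts.loc["H1", "Egypt"] == 1
        assert tab.group_counts.loc["H1", "Pakistan"] == 1
        assert tab.group_counts.loc["H2", "Egypt"] == 1

    def test_all_columns_removed_is_fatal(self):
        with pytest.raises(ValueError, match="every column"):
            collapse_haplotypes(make_alignment(["N-", "AC"]))


class TestDiversity:
    def test_haplotype_diversity_closed_form(self):
        # multiplicities {2,1,1}: Hd = (4/3)(1 - 0.375) = 0.8333
        st = diversity(make_alignment(["AAAA", "AAAA", "AAAT", "AATT"]))
        assert st.Hd == pytest.approx(4 / 3 * (1 - 0.375), abs=1e-12)
        assert st.h == 3

    def test_k_matches_brute_force_over_pairs(self, rng):
        for _ in range(10):
            n = int(rng.integers(4, 20))
            seqs = ["".join(rng.choice(list("ACGT"), size=30)) for _ in range(n)]
            st = diversity(make_alignment(seqs))
            brute = np.mean([
                sum(a != b for a, b in zip(x, y))
                for x, y in itertools.combinations(seqs, 2)
            ])
            assert st.k == pytest.approx(brute, abs=1e-9)
            assert st.pi == pytest.approx(brute / 30, abs=1e-9)

    def test_monomorphic_alignment(self):
        st = diversity(make_alignment(["ACGT" * 3] * 6))
        assert st.S == 0 and st.k == 0
        assert math.isnan(st.tajima_D) and math.isnan(st.fu_li_Dstar)
        assert st.Hd == 0.0

    def test_tajimas_d_matches_dendropy(self, rng):
        for rep in range(5):
            aln = coalescent_alignment(12, 5.0, 800, rng)
            st = diversity(aln)
            fasta = "".join(f">{r.id}\n{r.sequence}\n" for r in aln)
            chars = dendropy.DnaCharacterMatrix.get(data=fasta, schema="fasta")
            assert st.S == popgenstat.num_segregating_sites(chars)
            assert st.k == pytest.approx(
                popgenstat.average_number_of_pairwise_differences(chars), abs=1e-9
            )
            if st.S > 0:
                assert st.tajima_D == pytest.approx(popgenstat.tajimas_d(chars), abs=1e-9)

    def test_tajima_centered_under_neutrality(self, rng):
        # E[D] under neutrality is slightly negative (~ -0.07 at n=20);
        # 500 replicates keep the Monte Carlo error well inside the band
        vals = []
        for _ in range(500):
            aln = coalescent_alignment(20, 5.0, 2000, rng)
            d = diversity(aln).tajima_D
            if not math.isnan(d):
                vals.append(d)
        assert abs(np.mean(vals)) < 0.15

    def test_fu_li_d_requires_outgroup(self):
        aln = make_alignment(["AAAA", "AAAT", "AATT", "TTTT"])
        st = diversity(aln)
        assert math.isnan(st.fu_li_D)
        st_og = diversity(
            make_alignment(["AAAA", "AAAT", "AATT", "TTTT", "AAAA"], ids=list("abcdo")),
            outgroup="o",
        )
        assert not math.isnan(st_og.fu_li_D)
        assert st_og.n == 4  # outgroup excluded from the indices

    def test_fu_li_dstar_sign_tracks_singleton_excess(self, rng):
        # a star-like sample (every mutation a singleton) drives D* negative
        base = "A" * 40
        seqs = [base] * 6
        star = []
        for i, s in enumerate(seqs):
            mutated = list(s)
            mutated[i] = "T"  # each sequence gets a private singleton
            star.append("".join(mutated))
        st = diversity(make_alignment(star))
        assert st.fu_li_Dstar < 0
        # shared (internal-branch) variation at the same S is less negative
        shared = [("T" * 20 + "A" * 20) if i < 3 else base for i in range(6)]
        st2 = diversity(make_alignment(shared))
        assert st2.fu_li_Dstar > st.fu_li_Dstar

    def test_diversity_table_rows(self, default_dataset):
        table = diversity_table(default_dataset.alignment, default_dataset.truth)
        assert "all" in table.index
        assert set("ABCDE") <= set(table.index)
        assert (table["n"].drop("all").sum()) == len(default_dataset.alignment)


class TestTajimaFormula:
    def test_undefined_cases(self):
        assert math.isnan(tajimas_d(3, 5, 1.0))  # n < 4
        assert math.isnan(tajimas_d(10, 0, 0.0))  # S = 0

    def test_sign_behaviour(self):
        # k below S/a1 -> negative; above -> positive
        a1 = sum(1 / i for i in range(1, 10))
        assert tajimas_d(10, 10, 10 / a1 - 1) < 0
        assert tajimas_d(10, 10, 10 / a1 + 1) > 0


class TestAmova:
    def fixated(self):
        recs = []
        for g, base in [("G1", "AAAAAAAAAA"), ("G2", "TTTTTAAAAA")]:
            for i in range(4):
                recs.append(SequenceRecord(f"{g}_{i}", base, country=g, clade_label=g))
        aln = Alignment(recs)
        groups = {r.id: r.clade_label for r in recs}
        pops = {r.id: r.country for r in recs}
        return aln, groups, pops

    def test_complete_fixation(self):
        aln, groups, pops = self.fixated()
        res = amova(aln, groups, pops, n_permutations=0)
        assert res.phi_CT == pytest.approx(1.0)
        assert res.phi_ST == pytest.approx(1.0)
        assert res.percent["a"] == pytest.approx(100.0)

    def test_percentages_sum_to_100(self, default_dataset):
        aln = default_dataset.alignment
        groups = {r.id: r.clade_label for r in aln}
        pops = {r.id: r.country for r in aln}
        res = amova(aln, groups, pops, n_permutations=0)
        total = sum(v for v in res.percent.values() if v == v)
        assert total == pytest.approx(100.0, abs=0.01)

    def test_flat_hierarchy_collapses_phi(self, default_dataset):
        # every population its own group: phi_SC undefined, phi_CT == phi_ST
        aln = default_dataset.alignment
        pops = {r.id: r.country for r in aln}
        res = amova(aln, pops, pops, n_permutations=0)
        assert math.isnan(res.phi_SC)
        assert res.phi_CT == pytest.approx(res.phi_ST, abs=1e-12)

    def test_structured_data_significant(self, default_dataset):
        aln = default_dataset.alignment
        groups = {r.id: r.clade_label for r in aln}
        pops = {r.id: r.country for r in aln}
        res = amova(aln, groups, pops, n_permutations=99, seed=7)
        assert res.phi_ST > 0.9
        assert res.p_values["phi_ST"] <= 0.05

    def test_accepts_precomputed_matrix(self):
        aln, groups, pops = self.fixated()
        d = pairwise_difference_matrix(aln)
        res = amova((d, aln.ids), groups, pops, n_permutations=0)
        assert res.phi_ST == pytest.approx(1.0)

    def test_unlabelled_ids_rejected(self):
        aln, groups, pops = self.fixated()
        del groups["G1_0"]
        with pytest.raises(ValueError, match="without group"):
            amova(aln, groups, pops)

    def test_null_pvalues_approximately_uniform(self, rng):
        # panmictic data with arbitrary labels: phi_CT p-values ~ U(0,1)
        from scipy.stats import kstest

        pvals = []
        for _ in range(200):
            aln = coalescent_alignment(24, 8.0, 500, rng)
            ids = aln.ids
            pops = {sid: f"p{i % 8}" for i, sid in enumerate(ids)}
            groups = {sid: f"g{int(pops[sid][1:]) % 4}" for sid in ids}
            res = amova(aln, groups, pops, n_permutations=99,
                        seed=int(rng.integers(2**31)))
            pvals.append(res.p_values["phi_CT"])
        assert kstest(pvals, "uniform").pvalue > 0.01


class TestMsn:
    def test_two_haplotypes_single_edge(self):
        tab = collapse_haplotypes(make_alignment(["AAAA", "TTTA"]))
        g = msn(tab)
        assert list(g.edges(data="steps")) == [("H1", "H2", 3)]

    def test_equidistant_triple_gives_triangle(self):
        # three haplotypes mutually one step apart: all edges tie for the MST
        tab = collapse_haplotypes(make_alignment(["AAAA", "ATAA", "AGAA"]))
        g = msn(tab)
        assert g.number_of_edges() == 3

    def test_star_clade_topology(self):
        # dominant haplotype plus singletons each one step away
        seqs = ["AAAAAAAA"] * 5 + ["TAAAAAAA", "ATAAAAAA", "AATAAAAA"]
        g = msn(collapse_haplotypes(make_alignment(seqs)))
        degrees = dict(g.degree())
        assert degrees["H1"] == 3
        assert all(degrees[h] == 1 for h in ("H2", "H3", "H4"))

    def test_contains_mst_and_connected(self, default_dataset):
        tab = collapse_haplotypes(default_dataset.alignment)
        g = msn(tab)
        assert nx.is_connected(g)
        # oracle: an MST over the complete haplotype graph has the same
        # total weight as an MST restricted to the network's edges
        enc = np.array([[ord(c) for c in h] for h in tab.haplotypes])
        full = nx.Graph()
        for i in range(len(enc)):
            for j in range(i + 1, len(enc)):
                full.add_edge(tab.names[i], tab.names[j],
                              weight=int((enc[i] != enc[j]).sum()))
        w_full = sum(d["weight"] for *_, d in
                     nx.minimum_spanning_tree(full).edges(data=True))
        sub = nx.Graph((u, v, {"weight": d["steps"]}) for u, v, d in g.edges(data=True))
        w_sub = sum(d["weight"] for *_, d in
                    nx.minimum_spanning_tree(sub).edges(data=True))
        assert w_sub == w_full

    def test_epsilon_relaxation_adds_edges(self):
        seqs = ["AAAAAAAA", "TTAAAAAA", "TTTTAAAA"]
        tab = collapse_haplotypes(make_alignment(seqs))
        g0 = msn(tab, epsilon=0)
        g2 = msn(tab, epsilon=2)
        assert g2.number_of_edges() >= g0.number_of_edges()

    def test_edgelist_export(self, tmp_path):
        tab = collapse_haplotypes(make_alignment(["AAAA", "TTTA"]))
        df = msn_edgelist(msn(tab))
        assert list(df.columns) == ["h1", "h2", "steps"]
        assert len(df) == 1

    def test_single_haplotype_no_edges(self):
        g = msn(collapse_haplotypes(make_alignment(["ACGT", "ACGT"])))
        assert g.number_of_nodes() == 1 and g.number_of_edges() == 0
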