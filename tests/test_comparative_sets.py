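import numpy as np
import pandas as pd
import pytest
import biotite.sequence.align as balign

from amfsecretome import (
    Comparison,
    ComparisonDesign,
    classify_patterns,
    collapse_isoforms,
    cross_species_groups,
    host_specificity_ratio,
    local_align,
    round_half_up,
    venn_counts,
)
from amfsecretome.catalog_merge import ProteinRecord
from amfsecretome.secretome_filter import SecretomeEntry, SignalPrediction

from _oracles import sw_score_affine

AA = "ACDEFGHIKLMNPQRSTVWY"
_B62 = balign.SubstitutionMatrix.std_protein_matrix()


def blosum62(a, b):
    return int(_B62.get_score(a, b))


def entry(pid, mature):
    rec = ProteinRecord(pid, "sp", "M" * 19 + mature, "merged")
    return SecretomeEntry(rec, mature, SignalPrediction(True, 19))


def random_seq(rng, n, alphabet=AA):
    return "".join(rng.choice(list(alphabet), size=n))


class TestLocalAlign:
    def test_self_alignment_scores_diagonal_sum(self):
        rng = np.random.default_rng(0)
        seq = random_seq(rng, 50)
        hit = local_align(seq, seq)
        assert hit.identity == 1.0
        assert hit.score == sum(blosum62(c, c) for c in seq)
        assert hit.e_value < 1e-5

    def test_all_negative_substitutions_give_empty_alignment(self):
        hit = local_align("AAAA", "WWWW")
        assert hit.score == 0 and hit.aln_length == 0

    @pytest.mark.parametrize("trial", range(100))
    def test_score_equals_exhaustive_dp_oracle(self, trial):
        rng = np.random.default_rng(1000 + trial)
        a = random_seq(rng, int(rng.integers(1, 21)))
        b = random_seq(rng, int(rng.integers(1, 21)))
        hit = local_align(a, b)
        assert hit.score == sw_score_affine(a, b, blosum62)

    def test_symmetric_in_sequence_order(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            a, b = random_seq(rng, 30), random_seq(rng, 25)
            assert local_align(a, b).score == local_align(b, a).score

    def test_bit_score_and_evalue_conversion(self):
        hit = local_align("MKTWYENNACDEF" * 3, "MKTWYENNACDEF" * 3)
        lam, k = 0.267, 0.041
        expected_bits = (lam * hit.score - np.log(k)) / np.log(2)
        assert hit.bit_score == pytest.approx(expected_bits)
        m = n = 39
        assert hit.e_value == pytest.approx(m * n * 2 ** (-expected_bits))


def toy_calls(up_map, labels):
    """Build per-comparison call tables from {gene: set(up labels)}."""
    calls = {}
    for lab in labels:
        calls[lab] = pd.DataFrame(
            {
                "gene_id": list(up_map),
                "call": ["up" if lab in s else "ns" for s in up_map.values()],
            }
        )
    return calls


DESIGN = ComparisonDesign(
    "reference",
    [Comparison(c, c) for c in ("Mt", "Bd", "Lc", "ERM", "GR24")],
    host_labels=frozenset({"Mt", "Bd", "Lc"}),
    erm_labels=frozenset({"ERM"}),
    signal_labels=frozenset({"GR24"}),
)


class TestClassifyPatterns:
    def test_host_centric_categories(self):
        up = {
            "g1": {"Mt", "Bd", "Lc"},
            "g2": {"Mt"},
            "g3": {"Mt", "Bd"},
            "g4": {"ERM"},
            "g5": {"GR24"},
            "g6": set(),
            "g7": {"Mt", "Bd", "Lc", "ERM"},
        }
        cls = {c.gene_id: c for c in classify_patterns(toy_calls(up, [c.label for c in DESIGN.comparisons]), DESIGN)}
        assert cls["g1"].category == "common_all_hosts"
        assert cls["g2"].category == "host_specific:Mt"
        assert cls["g3"].category == "shared_subset:Bd+Mt"
        assert cls["g4"].category == "erm_up"
        assert cls["g5"].category == "signal_up"
        assert cls["g6"].category == "none"
        assert cls["g7"].category == "common_all_hosts"  # hosts take priority
        assert cls["g7"].up_in == frozenset({"Mt", "Bd", "Lc", "ERM"})  # raw set kept

    def test_missing_comparison_rejected(self):
        calls = toy_calls({"g1": {"Mt"}}, ["Mt"])
        with pytest.raises(ValueError, match="missing comparisons"):
            classify_patterns(calls, DESIGN)


class TestVennCounts:
    def test_toy_regions(self):
        up = {"g1": {"Mt"}, "g2": {"Mt", "Bd"}, "g3": {"Mt", "Bd"}}
        cls = classify_patterns(toy_calls(up, [c.label for c in DESIGN.comparisons]), DESIGN)
        regions = venn_counts(cls, {"Mt", "Bd", "Lc"})
        assert regions[frozenset({"Mt"})] == 1
        assert regions[frozenset({"Mt", "Bd"})] == 2
        assert sum(regions.values()) == 3

    def test_empty_input_all_zero(self):
        regions = venn_counts([], {"Mt", "Bd"})
        assert set(regions.values()) == {0}

    def test_regions_partition_the_up_pool(self, calls1, default_config):
        from amfsecretome import default_design

        design = default_design(default_config, 1)
        cls = classify_patterns(calls1, design)
        regions = venn_counts(cls, design.host_labels)
        pool = sum(1 for c in cls if c.up_in & design.host_labels)
        assert sum(regions.values()) == pool


class TestHostSpecificity:
    def test_published_worked_example(self):
        # region counts printed for the two-host comparison: 69 + 81 single,
        # 53 shared -> 150 of 203 host-specific -> 74%
        regions = {
            frozenset({"Mt"}): 69,
            frozenset({"Bd"}): 81,
            frozenset({"Mt", "Bd"}): 53,
        }
        ratio = host_specificity_ratio(regions, {"Mt", "Bd"})
        assert ratio == pytest.approx(100 * 150 / 203)
        assert round_half_up(ratio) == 74

    def test_all_common_is_zero(self):
        assert host_specificity_ratio({frozenset({"Mt", "Bd"}): 10}, {"Mt", "Bd"}) == 0.0

    def test_all_single_host_is_hundred(self):
        regions = {frozenset({"Mt"}): 4, frozenset({"Bd"}): 6}
        assert host_specificity_ratio(regions, {"Mt", "Bd"}) == 100.0

    def test_empty_pool_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            host_specificity_ratio({}, {"Mt"})

    @pytest.mark.parametrize("x,expected", [(73.89, 74), (0.5, 1), (2.44, 2), (-1.5, -2)])
    def test_round_half_up(self, x, expected):
        assert round_half_up(x) == expected


class TestCrossSpeciesGroups:
    def test_single_linkage_joins_paralogs(self):
        rng = np.random.default_rng(3)
        core = random_seq(rng, 60)
        a1, a2 = entry("A1", core), entry("A2", core[:50] + random_seq(rng, 10))
        b1 = entry("B1", core)
        b2 = entry("B2", random_seq(rng, 60))
        groups = cross_species_groups([a1, a2], [b1, b2])
        assert len(groups) == 1
        assert groups[0].members == ["A1", "A2", "B1"]

    def test_disjoint_pairs_stay_separate(self):
        rng = np.random.default_rng(4)
        s1, s2 = random_seq(rng, 60), random_seq(rng, 60)
        groups = cross_species_groups(
            [entry("A1", s1), entry("A2", s2)],
            [entry("B1", s1), entry("B2", s2)],
        )
        assert [g.members for g in groups] == [["A1", "B1"], ["A2", "B2"]]

    def test_groups_need_both_species(self):
        rng = np.random.default_rng(5)
        groups = cross_species_groups(
            [entry("A1", random_seq(rng, 60))],
            [entry("B1", random_seq(rng, 60))],
        )
        assert groups == []

    def test_order_invariance_and_monotone_merging(self):
        rng = np.random.default_rng(6)
        core = random_seq(rng, 60)
        ents_a = [entry("A1", core), entry("A2", random_seq(rng, 60))]
        ents_b = [entry("B1", core), entry("B2", random_seq(rng, 60))]
        ref = cross_species_groups(ents_a, ents_b)
        alt = cross_species_groups(ents_a[::-1], ents_b[::-1])
        assert [g.members for g in ref] == [g.members for g in alt]
        # relaxing the threshold can only merge, never split
        loose = cross_species_groups(ents_a, ents_b, e_threshold=1e-1)
        for g in ref:
            assert any(set(g.members) <= set(h.members) for h in loose)

    def test_planted_homolog_families_recovered(self, study, secretome, secretome2):
        feats = study.truth.features
        fam = {
            e.id: feats.loc[e.id, "family_id"]
            for e in secretome + secretome2
            if feats.loc[e.id, "family_id"] != ""
        }
        sub1 = [e for e in secretome if e.id in fam]
        sub2 = [e for e in secretome2 if e.id in fam]
        assert len(sub1) >= 15 and len(sub2) >= 15
        groups = cross_species_groups(sub1, sub2)
        gm = [set(g.members) for g in groups]
        planted: dict[str, set] = {}
        for pid, f in fam.items():
            planted.setdefault(f, set()).add(pid)
        recovered = sum(1 for mem in planted.values() if any(mem <= g for g in gm))
        assert recovered / len(planted) >= 0.9


class TestCollapseIsoforms:
    def base(self, rng, n=300):
        return random_seq(rng, n, alphabet="ACGT")

    def mutate(self, rng, seq, n_mut):
        out = list(seq)
        for i in rng.choice(len(seq), size=n_mut, replace=False):
            out[i] = str(rng.choice([c for c in "ACGT" if c != out[i]]))
        return "".join(out)

    def test_near_identical_pair_collapses_to_longer(self):
        rng = np.random.default_rng(7)
        a = self.base(rng)
        b = self.mutate(rng, a, 3) + "ACGTACGT"  # 99% identical, longer
        reps, mapping = collapse_isoforms({"t1": a, "t2": b})
        assert reps == ["t2"]
        assert mapping == {"t1": "t2", "t2": "t2"}

    def test_diverged_pair_kept_separate(self):
        rng = np.random.default_rng(8)
        a = self.base(rng)
        b = self.mutate(rng, a, 15)  # 95% identity, below the >97% bar
        reps, _ = collapse_isoforms({"t1": a, "t2": b})
        assert reps == ["t1", "t2"]

    def test_single_linkage_chain(self):
        rng = np.random.default_rng(9)
        a = self.base(rng)
        b = self.mutate(rng, a, 3)
        c = self.mutate(rng, b, 3)
        reps, mapping = collapse_isoforms({"t1": a, "t2": b, "t3": c})
        assert len(reps) == 1
        assert len(set(mapping.values())) == 1
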