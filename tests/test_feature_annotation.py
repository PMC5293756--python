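import numpy as np
import pytest
from scipy import stats

from amfsecretome import (
    DEFAULT_MOTIF_CATALOG,
    classify_rcp_kex2,
    classify_scr,
    cluster_tribes,
    compile_motif,
    detect_nls,
    find_tandem_repeats,
    motif_enrichment,
    pfam_enrichment,
    scan_motif_catalog,
)
from amfsecretome.feature_annotation import MotifPatternError, positional_summary
from amfsecretome.secretome_filter import SecretomeEntry, SignalPrediction
from amfsecretome.catalog_merge import ProteinRecord

from _oracles import (
    brute_motif_positions,
    brute_tandem_arrays,
    connected_components,
    hypergeom_upper_tail,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


def entry(pid, mature):
    rec = ProteinRecord(pid, "sp", "M" * 19 + mature, "merged")
    return SecretomeEntry(rec, mature, SignalPrediction(True, 19))


def random_seq(rng, n):
    return "".join(rng.choice(list(AA), size=n))


class TestScr:
    @pytest.mark.parametrize(
        "length,cys,expected",
        [
            (150, 5, True),   # 3.33% of 150
            (200, 10, False),  # length bound is strict
            (199, 6, True),    # 6/199 = 3.02%
            (100, 3, True),    # exactly 3.00%
            (100, 2, False),   # 2% < 3%
            (66, 2, True),     # 2/66 = 3.03%, minimum count inclusive
            (67, 2, False),    # 2/67 = 2.99%
            (40, 1, False),    # below the 2-cysteine floor
        ],
    )
    def test_threshold_exactness(self, length, cys, expected):
        seq = "C" * cys + "A" * (length - cys)
        res = classify_scr(seq)
        assert res.is_scr is expected
        assert res.length == length and res.cys_count == cys

    def test_applied_to_mature_sequence(self):
        # cysteines in the signal peptide do not count
        e = entry("p", "A" * 100)
        e.protein.aa_sequence = "C" * 19 + "A" * 100
        assert classify_scr(e).cys_count == 0


class TestNls:
    def test_basic_residue_window_found(self):
        # six of seven residues basic
        hits = detect_nls("AAAAAKKKRKVKAAAAA")
        assert len(hits) == 1

    def test_five_of_seven_basic_is_below_threshold(self):
        assert detect_nls("AAAAAPKKKRKVAAAAA") == []

    def test_polyalanine_has_no_hits(self):
        assert detect_nls("A" * 50) == []

    def test_override_table_wins(self):
        e = entry("p1", "PKKKRKV" + "A" * 20)
        assert detect_nls(e, {"p1": False}) == []
        assert detect_nls(entry("p2", "A" * 30), {"p2": True}) == [1]

    def test_planted_nls_recovered_on_synthetic_secretome(self, study, secretome):
        feats = study.truth.features
        planted = [e for e in secretome if feats.loc[e.id, "has_nls"]]
        assert len(planted) >= 10
        found = sum(bool(detect_nls(e)) for e in planted)
        assert found / len(planted) >= 0.95


class TestTandemRepeats:
    def test_exact_array_called_with_unit_and_copies(self):
        calls = find_tandem_repeats("MA" + "QWERTYD" * 5 + "LL")
        assert len(calls) == 1
        r = calls[0]
        assert (r.unit_length, r.copy_number) == (7, 5)
        assert r.mean_unit_identity == pytest.approx(1.0)
        assert r.span == (3, 37)
        assert r.unit_consensus == "QWERTYD"

    def test_homopolymer_not_called(self):
        assert find_tandem_repeats("A" * 10) == []
        assert find_tandem_repeats("W" * 40 + "A" * 12 + "W" * 5) == []

    def test_degenerate_array_detected_and_shuffled_control_clean(self):
        rng = np.random.default_rng(0)
        unit = "KWERTYDS"
        units = []
        for _ in range(5):
            u = list(unit)
            for i in range(len(u)):
                if rng.random() < 0.1:  # ~20% divergence between adjacent copies
                    u[i] = str(rng.choice(list(AA)))
            units.append("".join(u))
        seq = "MA" + "".join(units) + "LL"
        calls = find_tandem_repeats(seq)
        assert any(r.copy_number >= 3 and r.mean_unit_identity < 1.0 for r in calls)
        shuffled = "".join(rng.permutation(list(seq)))
        assert bool(find_tandem_repeats(shuffled)) == bool(brute_tandem_arrays(shuffled))

    @pytest.mark.parametrize("trial", range(8))
    def test_presence_matches_exhaustive_oracle_on_short_sequences(self, trial):
        rng = np.random.default_rng(100 + trial)
        if trial % 2 == 0:
            seq = random_seq(rng, int(rng.integers(20, 61)))
        else:  # half the trials contain a genuine planted array
            unit = random_seq(rng, int(rng.integers(3, 8)))
            seq = random_seq(rng, 5) + unit * int(rng.integers(3, 6)) + random_seq(rng, 5)
        impl = find_tandem_repeats(seq)
        oracle = brute_tandem_arrays(seq)
        assert bool(impl) == bool(oracle)


class TestKex2:
    @pytest.mark.parametrize(
        "unit,expected",
        [
            ("KRLLSWQT", "cleavable_rcp"),   # KR matches [KR]R
            ("KKLLSWQT", "non_cleavable_rcp"),  # second residue must be R
            ("RRSAMWQT", "cleavable_rcp"),   # RR matches [KR]R
        ],
    )
    def test_conserved_kex2_site_classification(self, unit, expected):
        seq = "MA" + unit * 4 + "LL"
        assert classify_rcp_kex2(seq) == expected

    def test_no_repeats_is_not_rcp(self):
        rng = np.random.default_rng(0)
        assert classify_rcp_kex2(random_seq(rng, 60)) == "not_rcp"

    def test_site_must_be_conserved_across_units(self):
        # [KR]R in a single unit only: repeats exist but are not cleavable
        units = ["KRAASWQT"] + ["AAAASWQT"] * 3
        seq = "MA" + "".join(units) + "LL"
        calls = find_tandem_repeats(seq, min_identity=0.7)
        if calls:
            assert classify_rcp_kex2(seq, calls) == "non_cleavable_rcp"


class TestMotifScan:
    def test_literal_and_degenerate_hits(self):
        hits = {h.motif_id: h for h in scan_motif_catalog("AAARSIDELDAAA")}
        assert "RSIDELD" in hits and hits["RSIDELD"].position == 4
        hits = {h.motif_id: h for h in scan_motif_catalog("AAARALGAAA")}
        assert "RxLx" in hits  # RALG instantiates RxLx

    def test_overlapping_occurrences_counted(self):
        hits = {h.motif_id: h for h in scan_motif_catalog("RALRALRA", {"RxLx": "RxLx"})}
        assert hits["RxLx"].count == 2

    def test_malformed_pattern_is_named(self):
        with pytest.raises(MotifPatternError, match="R\\[XY"):
            compile_motif("R[XY")
        with pytest.raises(MotifPatternError):
            compile_motif("rxlr")

    @pytest.mark.parametrize("pattern", sorted(DEFAULT_MOTIF_CATALOG.values()))
    def test_scanner_equals_bruteforce_oracle(self, pattern):
        rng = np.random.default_rng(hash(pattern) % 2**31)
        rx = compile_motif(pattern)
        for _ in range(20):
            seq = random_seq(rng, 200)
            impl = [m.start() + 1 for m in rx.finditer(seq)]
            assert impl == brute_motif_positions(seq, pattern)

    def test_every_hit_rematches_at_recorded_position(self, secretome):
        for e in secretome[:80]:
            for h in scan_motif_catalog(e.mature_sequence):
                rx = compile_motif(h.pattern)
                m = rx.match(e.mature_sequence, h.position - 1)
                assert m is not None


class TestEnrichment:
    def test_equal_rates_are_not_enriched(self):
        rows = motif_enrichment({"m": 10}, 100, {"m": 100}, 1000)
        assert rows[0].odds_ratio == pytest.approx(1.0)
        assert rows[0].p > 0.3

    def test_p_equals_direct_hypergeometric_summation(self):
        rows = motif_enrichment({"m": 30}, 100, {"m": 10}, 1000)
        expected = hypergeom_upper_tail(30, 1100, 40, 100)
        assert rows[0].p == pytest.approx(expected, rel=1e-9)

    def test_planted_enriched_motifs_flagged(self, study, secretome):
        feats = study.truth.features
        sp1 = feats[feats["species"] == 1]
        bg_ids = [i for i in sp1.index if not sp1.loc[i, "is_secreted"]]
        cat = {**study.catalog_a, **study.catalog_b}
        fg_counts: dict[str, int] = {}
        bg_counts: dict[str, int] = {}
        for e in secretome:
            for h in scan_motif_catalog(e.mature_sequence):
                fg_counts[h.motif_id] = fg_counts.get(h.motif_id, 0) + 1
        for i in bg_ids:
            if i not in cat:
                continue
            for h in scan_motif_catalog(cat[i].aa_sequence):
                bg_counts[h.motif_id] = bg_counts.get(h.motif_id, 0) + 1
        rows = {r.feature_id: r for r in motif_enrichment(fg_counts, len(secretome), bg_counts, len(bg_ids))}
        planted = sorted(set(feats.loc[feats["motif_id"] != "", "motif_id"]))
        assert planted
        for m in planted:
            assert rows[m].q <= 0.05, m

    def test_zero_size_sets_rejected(self):
        with pytest.raises(ValueError):
            motif_enrichment({"m": 1}, 0, {"m": 1}, 10)

    def test_p_values_uniform_under_label_permutation(self):
        # permuting secretome labels over a fixed pool makes the test a null
        rng = np.random.default_rng(42)
        n_pool, n_fg, carriers = 2000, 1000, 600
        labels = np.array([1] * carriers + [0] * (n_pool - carriers))
        ps = []
        for _ in range(1000):
            perm = rng.permutation(labels)
            k_fg = int(perm[:n_fg].sum())
            k_bg = carriers - k_fg
            ps.append(float(stats.hypergeom.sf(k_fg - 1, n_pool, carriers, n_fg)))
        ps = np.sort(ps)
        grid = (np.arange(len(ps)) + 1) / len(ps)
        # discrete p-values stochastically dominate uniform; KS-style distance
        ks = np.max(np.abs(ps - grid))
        assert ks < 0.1

    def test_positional_summary_quartiles(self):
        s = positional_summary([1, 2, 3, 4, 5])
        assert (s["q1"], s["median"], s["q3"]) == (2, 3, 4)
        assert positional_summary([])["n"] == 0


class TestTribes:
    def test_identical_sequences_form_one_tribe(self):
        seq = "MKTWYENNACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQRSTVWY"
        entries = [entry(f"p{i}", seq) for i in range(3)]
        tribes = cluster_tribes(entries)
        assert len(set(tribes.values())) == 1
        assert set(tribes.values()) != {"unique"}

    def test_unrelated_sequences_stay_singletons(self):
        rng = np.random.default_rng(1)
        entries = [entry("a", random_seq(rng, 80)), entry("b", random_seq(rng, 80))]
        assert set(cluster_tribes(entries).values()) == {"unique"}

    def test_components_equal_graph_oracle(self):
        from amfsecretome import local_align

        rng = np.random.default_rng(9)
        base = random_seq(rng, 60)
        seqs = {
            "a1": base, "a2": base[:50] + random_seq(rng, 10),
            "b1": random_seq(rng, 60), "b2": random_seq(rng, 60),
            "c1": base[::-1],
        }
        entries = [entry(k, v) for k, v in sorted(seqs.items())]
        tribes = cluster_tribes(entries, prefilter=False)
        edges = []
        for i, a in enumerate(sorted(seqs)):
            for b in sorted(seqs)[i + 1:]:
                hit = local_align(seqs[a], seqs[b], query_id=a, subject_id=b)
                if hit.identity >= 0.30 and hit.aln_length >= 0.5 * max(len(seqs[a]), len(seqs[b])):
                    edges.append((a, b))
        oracle = {frozenset(c) for c in connected_components(sorted(seqs), edges)}
        impl: dict[str, set] = {}
        for pid, t in tribes.items():
            impl.setdefault(t if t != "unique" else pid, set()).add(pid)
        assert {frozenset(v) for v in impl.values()} == oracle

    def test_partition_and_order_invariance(self):
        rng = np.random.default_rng(3)
        base = random_seq(rng, 70)
        entries = [entry(f"p{i}", base if i < 4 else random_seq(rng, 70)) for i in range(8)]
        ref = cluster_tribes(entries)
        assert set(ref) == {e.id for e in entries}
        shuffled = [entries[i] for i in rng.permutation(len(entries))]
        assert cluster_tribes(shuffled) == ref


class TestPfamEnrichment:
    def test_ubiquitous_domain_has_p_one(self):
        sec = {f"s{i}": ["PF001"] for i in range(5)}
        rep = {**sec, **{f"r{i}": ["PF001"] for i in range(20)}}
        rows = pfam_enrichment(sec, rep)
        assert rows[0].p == pytest.approx(1.0)

    def test_toy_table_matches_direct_summation(self):
        sec = {f"s{i}": (["PF7"] if i < 5 else []) for i in range(10)}
        rep = dict(sec)
        for i in range(90):
            rep[f"r{i}"] = ["PF7"] if i < 5 else []
        rows = {r.feature_id: r for r in pfam_enrichment(sec, rep)}
        expected = hypergeom_upper_tail(5, 100, 10, 10)
        assert rows["PF7"].p == pytest.approx(expected, rel=1e-9)

    def test_domain_absent_from_secretome_never_enriched(self):
        sec = {"s1": []}
        rep = {"s1": [], "r1": ["PF9"], "r2": ["PF9"]}
        rows = {r.feature_id: r for r in pfam_enrichment(sec, rep)}
        assert rows["PF9"].p == pytest.approx(1.0)

    def test_secretome_must_be_subset(self):
        with pytest.raises(ValueError, match="absent from repertoire"):
            pfam_enrichment({"ghost": []}, {"r1": []})
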