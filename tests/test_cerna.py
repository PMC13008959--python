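import numpy as np
import pytest

from circscape.cerna import (
    DEFAULT_PROFILES,
    TargetSite,
    build_network,
    consensus_filter,
    hub_rank,
    scan_all,
    scan_targets,
    score_site,
    sponge_consistency,
)
from circscape.genome import reverse_complement

MIR = "ACGTACGTACGTACGTACGTA"  # 21 nt


def perfect_window(mirna=MIR):
    return reverse_complement(mirna)


class TestScoreSite:
    def test_perfect_site_has_zero_penalty(self):
        penalty, _ = score_site(MIR, perfect_window())
        assert penalty == 0.0

    def test_single_wobble_outside_seed(self):
        # miRNA position 21 (3' end) pairs the first window base; a G:U
        # wobble there costs 0.5 (outside the 2-13 seed)
        mir = MIR[:-1] + "G"  # miRNA base G at position 21
        win = list(reverse_complement(mir))
        win[0] = "T"  # target U pairs miRNA G: wobble
        penalty, _ = score_site(mir, "".join(win))
        assert penalty == 0.5

    def test_mismatch_in_seed_is_doubled(self):
        # miRNA position 5 lies in the seed; its window column is L-5
        win = list(perfect_window())
        col = len(MIR) - 5
        cur = win[col]
        win[col] = {"A": "C", "C": "A", "G": "T", "T": "G"}[cur]
        # ensure the substitute is a mismatch, not a wobble partner
        penalty, _ = score_site(MIR, "".join(win))
        assert penalty == 2.0

    def test_window_length_constraint(self):
        with pytest.raises(ValueError):
            score_site(MIR, "ACGT")


class TestScanTargets:
    def test_planted_site_found_at_recorded_offset(self):
        rng = np.random.default_rng(0)
        bases = np.array(list("ACGT"))
        target = "".join(rng.choice(bases, 200))
        target = target[:90] + perfect_window() + target[90 + 21 :]
        sites = scan_targets("m", MIR, "t", target, cutoff=0.0)
        assert [s.position for s in sites] == [90]
        assert sites[0].penalty == 0.0

    def test_equals_exhaustive_window_scoring(self):
        """Sliding-window scan must agree with per-window score_site on
        every window of a random 500-nt target."""
        rng = np.random.default_rng(4)
        bases = np.array(list("ACGT"))
        mir = "".join(rng.choice(bases, 21))
        target = "".join(rng.choice(bases, 500))
        # plant one decent (1-mismatch) site so something passes
        w = list(reverse_complement(mir))
        w[0] = {"A": "C", "C": "A", "G": "T", "T": "G"}[w[0]]
        target = target[:250] + "".join(w) + target[250 + 21 :]
        cutoff = 6.0
        sites = scan_targets("m", mir, "t", target, cutoff=cutoff)
        oracle = {
            i: score_site(mir, target[i : i + 21])[0]
            for i in range(len(target) - 20)
        }
        # every reported site matches its exhaustive penalty and passes
        for s in sites:
            assert s.penalty == oracle[s.position] <= cutoff
        # greedy non-overlap: any unreported passing window overlaps a
        # reported site with smaller-or-equal penalty
        reported = {(s.position, s.position + 21): s.penalty for s in sites}
        for i, p in oracle.items():
            if p <= cutoff and not any(
                a <= i < b or a < i + 21 <= b for (a, b) in reported
            ):
                assert any(
                    pen <= p and a < i + 21 and i < b
                    for (a, b), pen in reported.items()
                )

    def test_overlapping_sites_keep_best(self):
        target = "A" * 30 + perfect_window() + "A" * 30
        sites = scan_targets("m", MIR, "t", target, cutoff=8.0)
        positions = [s.position for s in sites]
        assert len(positions) == len(set(positions))
        for a, b in zip(sites, sites[1:]):
            assert b.position >= a.position + 21 or a.position >= b.position + 21

    def test_circular_junction_site_recovered(self):
        site = perfect_window()
        # split the site across the circle junction
        target = site[10:] + "C" * 80 + site[:10]
        assert scan_targets("m", MIR, "t", target, cutoff=0.0) == []
        sites = scan_targets("m", MIR, "t", target, cutoff=0.0, circular=True)
        assert len(sites) == 1
        assert sites[0].position == len(target) - 10


class TestConsensus:
    def test_profiles_are_nested(self):
        rng = np.random.default_rng(8)
        bases = np.array(list("ACGT"))
        mirnas = {"m1": "".join(rng.choice(bases, 21))}
        targets = {
            f"t{i}": "".join(rng.choice(bases, 300)) for i in range(10)
        }
        targets["t0"] = (
            targets["t0"][:100]
            + reverse_complement(mirnas["m1"])
            + targets["t0"][121:]
        )
        per_profile = scan_all(mirnas, targets, "mRNA")
        keys = {
            name: {(s.mirna_id, s.target_id, s.position) for s in sites}
            for name, sites in per_profile.items()
        }
        assert keys["strict"] <= keys["medium"] <= keys["lenient"]

    def test_consensus_is_profile_intersection(self):
        s = lambda pen: TargetSite("m", "t", "mRNA", 0, pen)
        per_profile = {
            "strict": [s(0.0)],
            "medium": [s(0.0), TargetSite("m", "u", "mRNA", 5, 2.0)],
            "lenient": [s(0.0), TargetSite("m", "u", "mRNA", 5, 2.0)],
        }
        kept = consensus_filter(per_profile)
        assert [(x.mirna_id, x.target_id) for x in kept] == [("m", "t")]

    def test_single_profile_degenerates_to_itself(self):
        sites = [TargetSite("m", "t", "mRNA", 0, 1.0)]
        kept = consensus_filter({"only": sites})
        assert [(x.mirna_id, x.target_id) for x in kept] == [("m", "t")]

    def test_empty_profile_set_rejected(self):
        with pytest.raises(ValueError):
            consensus_filter({})


def small_network():
    circ_sites = [
        TargetSite("miR1", f"circ{i}", "circRNA", 0, 0.0) for i in range(3)
    ]
    mrna_sites = [
        TargetSite("miR1", f"gene{i}", "mRNA", 0, 0.0) for i in range(5)
    ]
    de = {f"circ{i}": {"state": "up", "log2fc": 2.0} for i in range(3)}
    de.update({f"gene{i}": {"state": "down", "log2fc": -2.0} for i in range(5)})
    return build_network(circ_sites, mrna_sites, de, "cold")


class TestNetwork:
    def test_tripartite_star(self):
        g = small_network()
        assert g.number_of_edges() == 8
        kinds = {d["kind"] for _, d in g.nodes(data=True)}
        assert kinds == {"miRNA", "circRNA", "mRNA"}

    def test_empty_interactions_give_empty_graph(self):
        g = build_network([], [], {}, "cold")
        assert g.number_of_nodes() == 0

    def test_kind_mismatch_rejected(self):
        bad = [TargetSite("miR1", "x", "mRNA", 0, 0.0)]
        with pytest.raises(ValueError):
            build_network(bad, [], {}, "cold")

    def test_hub_rank_orders_and_breaks_ties(self):
        sites_x = [TargetSite("miRX", f"c{i}", "circRNA", 0, 0.0) for i in range(7)]
        sites_y = [TargetSite("miRY", f"c{i}", "circRNA", 0, 0.0) for i in range(3)]
        sites_a = [TargetSite("miRA", f"d{i}", "circRNA", 0, 0.0) for i in range(3)]
        g = build_network(sites_x + sites_y + sites_a, [], {}, "cold")
        ranks = hub_rank(g, k=10)["by_circ_targets"]
        assert ranks[0] == ("miRX", 7)
        assert ranks[1] == ("miRA", 3)  # tie with miRY broken by id
        assert len(ranks) == 3  # k larger than miRNA count: full ranking

    def test_sponge_signature(self):
        g = small_network()
        res = sponge_consistency(g, "miR1")
        assert (res["fraction_circ_up"], res["fraction_mrna_down"]) == (1.0, 1.0)

    def test_sponge_mixed_fixture(self):
        circ_sites = [
            TargetSite("m", f"c{i}", "circRNA", 0, 0.0) for i in range(4)
        ]
        mrna_sites = [
            TargetSite("m", f"g{i}", "mRNA", 0, 0.0) for i in range(5)
        ]
        de = {f"c{i}": {"state": "up" if i < 3 else "ns"} for i in range(4)}
        de.update({f"g{i}": {"state": "down" if i < 2 else "ns"} for i in range(5)})
        g = build_network(circ_sites, mrna_sites, de, "cold")
        res = sponge_consistency(g, "m")
        assert res["fraction_circ_up"] == pytest.approx(0.75)
        assert res["fraction_mrna_down"] == pytest.approx(0.4)

    def test_sponge_zero_denominator_flagged(self):
        g = build_network(
            [TargetSite("m", "c0", "circRNA", 0, 0.0)], [], {}, "cold"
        )
        res = sponge_consistency(g, "m")
        assert res["zero_denominator"]

    def test_absent_mirna_rejected(self):
        with pytest.raises(KeyError):
            sponge_consistency(small_network(), "nope")


class TestPlantedSites:
    def test_all_planted_sites_recovered_by_all_profiles(self, bundle):
        from circscape import annotate
        from circscape.filtering import CircRNA

        truth = bundle.truth
        mirnas = truth.mirna_seqs
        circ_seqs = {}
        for rec in truth.planted_circs:
            if rec["circ_type"] == "intronic":
                continue
            circ = CircRNA(
                rec["circ_id"], rec["contig"], rec["acceptor"], rec["donor"],
                rec["strand"],
            )
            cls = annotate.classify_type(circ, bundle.annotation)
            circ_seqs[rec["circ_id"]] = annotate.circ_sequence(
                cls, circ, bundle.annotation, bundle.genome
            )
        per_profile = scan_all(mirnas, circ_seqs, "circRNA", circular=True)
        planted = {
            (s["mirna_id"], s["target_id"], s["position"])
            for s in truth.planted_sites
            if s["target_kind"] == "circRNA"
        }
        for name, sites in per_profile.items():
            found = {(s.mirna_id, s.target_id, s.position) for s in sites}
            assert planted <= found, name

    def test_shuffled_mirnas_hit_far_fewer_targets(self, bundle):
        from circscape import annotate
        from circscape.filtering import CircRNA

        truth = bundle.truth
        rng = np.random.default_rng(0)
        shuffled = {
            mid: "".join(rng.permutation(list(seq)))
            for mid, seq in truth.mirna_seqs.items()
        }
        circ_seqs = {}
        for rec in truth.planted_circs:
            if rec["circ_type"] == "intronic":
                continue
            circ = CircRNA(
                rec["circ_id"], rec["contig"], rec["acceptor"], rec["donor"],
                rec["strand"],
            )
            cls = annotate.classify_type(circ, bundle.annotation)
            circ_seqs[rec["circ_id"]] = annotate.circ_sequence(
                cls, circ, bundle.annotation, bundle.genome
            )
        real = consensus_filter(
            scan_all(truth.mirna_seqs, circ_seqs, "circRNA", circular=True)
        )
        fake = consensus_filter(
            scan_all(shuffled, circ_seqs, "circRNA", circular=True)
        )
        assert len(real) >= 10 * max(1, len(fake))
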