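import numpy as np
import pandas as pd
import pytest

from circscape import filtering
from circscape.coupling import pearson
from circscape.synth import (
    ConfigError,
    GeneratorConfig,
    generate_bundle,
    generate_reference,
    simulate_bsj_candidates,
    simulate_expression,
)


class TestDeterminism:
    def test_same_seed_same_outputs(self):
        b1 = generate_bundle(GeneratorConfig(seed=9))
        b2 = generate_bundle(GeneratorConfig(seed=9))
        assert b1.genome.contigs == b2.genome.contigs
        pd.testing.assert_frame_equal(b1.candidates, b2.candidates)
        pd.testing.assert_frame_equal(b1.circ_counts, b2.circ_counts)
        assert b1.truth.mirna_seqs == b2.truth.mirna_seqs

    def test_different_seed_differs(self):
        b1 = generate_bundle(GeneratorConfig(seed=9))
        b2 = generate_bundle(GeneratorConfig(seed=10))
        assert b1.genome.contigs != b2.genome.contigs


class TestReference:
    def test_gene_count(self, bundle):
        nuclear = [g for g in bundle.annotation.genes if g.gene_id != "psbA_like"]
        assert len(nuclear) == 360
        assert len(bundle.truth.host_genes) == 60

    def test_host_introns_longer_than_nonhost(self, bundle):
        def mean_intron(genes):
            lens = [
                len(i)
                for g in genes
                for i in g.transcripts[0].introns
            ]
            return np.mean(lens)

        hosts = [bundle.annotation.gene(g) for g in bundle.truth.host_genes]
        nonhosts = [
            g
            for g in bundle.annotation.genes
            if g.gene_id.startswith("gN")
        ]
        assert mean_intron(hosts) > mean_intron(nonhosts)

    def test_host_exons_and_isoforms_exceed_nonhost(self, bundle):
        hosts = [bundle.annotation.gene(g) for g in bundle.truth.host_genes]
        nonhosts = [g for g in bundle.annotation.genes if g.gene_id.startswith("gN")]
        assert np.mean([g.n_exons_max for g in hosts]) > np.mean(
            [g.n_exons_max for g in nonhosts]
        )
        assert np.mean([g.n_isoforms for g in hosts]) > np.mean(
            [g.n_isoforms for g in nonhosts]
        )

    def test_impossible_config_rejected(self):
        with pytest.raises(ConfigError):
            GeneratorConfig(n_genes=10)  # fewer genes than planted circs


class TestCandidates:
    def test_true_scores_above_rnaser_threshold(self, bundle):
        truth_ids = {c["circ_id"] for c in bundle.truth.planted_circs}
        df = bundle.candidates
        true_rn = df[(df["bsj_id"].isin(truth_ids)) & (df["library"] == "rnaser")]
        assert (true_rn["score"] > 0.1).all()

    def test_artifact_scores_below_thresholds(self, bundle):
        art_ids = {
            a["bsj_id"] for a in bundle.truth.artifacts if not a["ultralong"]
        }
        df = bundle.candidates[bundle.candidates["bsj_id"].isin(art_ids)]
        rn = df[df["library"] == "rnaser"]
        ct = df[df["library"] == "control"]
        assert (rn["score"] <= 0.1).all()
        assert (ct["score"] <= 0.9).all()

    def test_fully_intergenic_artifacts(self):
        cfg = GeneratorConfig(seed=4, artifact_intergenic_fraction=1.0)
        genome, annotation, truth = generate_reference(cfg)
        for art in truth.artifacts:
            if art["ultralong"]:
                continue
            hosts = annotation.genes_containing(
                art["contig"], art["acceptor"], art["donor"]
            )
            assert not hosts

    def test_every_candidate_has_truth_id(self, bundle):
        known = (
            {c["circ_id"] for c in bundle.truth.planted_circs}
            | {a["bsj_id"] for a in bundle.truth.artifacts}
        )
        assert set(bundle.candidates["bsj_id"]) <= known

    def test_ultralong_spans_exceed_cutoff(self, bundle):
        ul = [a for a in bundle.truth.artifacts if a["ultralong"]]
        assert ul and all(a["donor"] - a["acceptor"] > 100_000 for a in ul)

    def test_candidate_table_parses_with_pipeline_reader(self, bundle, tmp_path):
        path = tmp_path / "cand.tsv"
        bundle.candidates.to_csv(path, sep="\t", index=False)
        df = filtering.read_candidates(path)
        assert len(df) == len(bundle.candidates)


class TestExpression:
    def test_perfect_correlation_without_noise(self):
        cfg = GeneratorConfig(
            seed=3, poisson_noise=False, expression_rho=1.0, plant_de=False
        )
        _, _, truth = generate_reference(cfg)
        circ, gene = simulate_expression(truth, cfg)
        for rec in truth.planted_circs[:5]:
            r = pearson(circ.loc[rec["circ_id"]], gene.loc[rec["host_gene"]])
            assert r == pytest.approx(1.0, abs=1e-9)

    def test_rho_recovered_by_direct_correlation(self):
        cfg = GeneratorConfig(seed=7, n_expr_replicates=100, expression_rho=0.8,
                              plant_de=False)
        _, _, truth = generate_reference(cfg)
        circ, gene = simulate_expression(truth, cfg)
        rs = [
            pearson(circ.loc[c["circ_id"]], gene.loc[c["host_gene"]])
            for c in truth.planted_circs
        ]
        assert abs(np.median(rs) - 0.8) <= 0.05

    def test_zero_rho_gives_small_correlations(self):
        cfg = GeneratorConfig(seed=7, n_expr_replicates=100, expression_rho=0.0,
                              plant_de=False)
        _, _, truth = generate_reference(cfg)
        circ, gene = simulate_expression(truth, cfg)
        rs = [
            abs(pearson(circ.loc[c["circ_id"]], gene.loc[c["host_gene"]]))
            for c in truth.planted_circs
        ]
        assert np.mean(rs) <= 0.1

    def test_too_few_samples_rejected(self):
        cfg = GeneratorConfig(seed=1)
        _, _, truth = generate_reference(cfg)
        cfg.n_expr_replicates = 0
        with pytest.raises(ConfigError):
            simulate_expression(truth, cfg)


class TestOrthologsAndSites:
    def test_planted_category_mix(self, bundle):
        cats = [c["category"] for c in bundle.truth.conservation]
        assert cats.count("Accordant") == 5
        assert cats.count("Half-accordant") == 5
        assert cats.count("Unaccordant") == 5

    def test_accordant_sites_identical(self, bundle):
        by_id = {c["circ_id"]: c for c in bundle.truth.species_b_circs}
        for rec in bundle.truth.conservation:
            if rec["category"] != "Accordant":
                continue
            b = by_id[rec["circ_b"]]
            seq = bundle.truth.species_b_genes[rec["gene_b"]]
            assert 0 <= b["acceptor"] < b["donor"] <= len(seq)

    def test_sites_are_exact_reverse_complements(self, bundle):
        # spot-check against the species-agnostic mRNA targets
        from circscape.genome import reverse_complement

        for s in bundle.truth.planted_sites:
            if s["target_kind"] != "mRNA":
                continue
            tx = bundle.annotation.gene(s["target_id"]).transcripts[0]
            seq = tx.spliced_sequence(bundle.genome)
            site = reverse_complement(bundle.truth.mirna_seqs[s["mirna_id"]])
            assert seq[s["position"] : s["position"] + len(site)] == site


class TestChloroplast:
    def test_clustered_bsjs_inside_terminal_window(self, bundle):
        cfg = bundle.config
        gene = bundle.annotation.gene(bundle.truth.psba_gene)
        win = int(round(len(gene.interval) * cfg.terminal_window_fraction))
        wstart = gene.interval.end - win
        for rec in bundle.truth.chloro_clustered:
            assert wstart <= rec["acceptor"] < rec["donor"] <= gene.interval.end
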