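"""Generator contracts: determinism, planted structure, truth consistency."""

import numpy as np
import pandas as pd
import pytest

from aqnet import synthetic as syn
from aqnet.promoters import expected_hit_rate, extract_promoters, scan


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs,msg", [
        (dict(module_size=50, n_genes=50), "module_size"),
        (dict(p_fg=0.2, p_bg=0.5), "p_bg"),
        (dict(n_conditions=0), "positive"),
        (dict(frip_values=(0.5, 1.2)), "frip_values"),
        (dict(gc_content=0.0), "gc_content"),
        (dict(motif_list={"m": "A" * 3000}), "longer than the promoter"),
        (dict(motif_list={"m": "ACXT"}), "illegal IUPAC"),
    ])
    def test_invariant_violations_rejected(self, kwargs, msg):
        with pytest.raises(ValueError, match=msg):
            syn.SyntheticConfig(**kwargs)

    def test_module_includes_guide(self, small_config):
        assert small_config.guide in small_config.module_members
        assert len(small_config.module_members) == small_config.module_size


class TestDeterminism:
    def test_same_seed_gives_identical_outputs(self, small_config):
        a = syn.generate_all(small_config)
        b = syn.generate_all(small_config)
        assert a.expression.to_csv() == b.expression.to_csv()
        assert a.genome == b.genome
        assert a.de_table.to_csv() == b.de_table.to_csv()
        assert a.orthology.to_csv() == b.orthology.to_csv()
        for sa, sb in zip(a.peak_sets, b.peak_sets):
            assert sa.peaks.to_csv() == sb.peaks.to_csv()
        assert a.truth.to_dict() == b.truth.to_dict()

    def test_different_seed_changes_outputs(self, small_config):
        import dataclasses

        other = dataclasses.replace(small_config, seed=small_config.seed + 1)
        assert (syn.gen_expression(small_config)[0].to_csv()
                != syn.gen_expression(other)[0].to_csv())

    def test_components_regenerate_independently(self, small_config):
        # promoters are untouched by regenerating the expression component
        g1, t1, _ = syn.gen_promoters(small_config, set())
        syn.gen_expression(small_config)
        g2, t2, _ = syn.gen_promoters(small_config, set())
        assert g1 == g2 and t1.equals(t2)


class TestExpressionStructure:
    def test_zero_loading_makes_module_independent_of_guide(self, small_config):
        import dataclasses

        cfg = dataclasses.replace(small_config, module_correlation=0.0,
                                  n_conditions=200)
        matrix, smap, truth = syn.gen_expression(cfg)
        log = np.log2(matrix.to_numpy() + 1)
        members = [g for g in truth.module_members if g != cfg.guide]
        gi = cfg.gene_ids.index(cfg.guide)
        idx = [cfg.gene_ids.index(g) for g in members]
        cors = np.corrcoef(log)[gi, idx]
        assert np.abs(cors).mean() < 0.15

    def test_module_correlation_exceeds_background(self):
        cfg = syn.SyntheticConfig(seed=4, n_genes=200, n_conditions=60,
                                  module_size=30, module_correlation=0.95)
        matrix, _, truth = syn.gen_expression(cfg)
        log = np.log2(matrix.to_numpy() + 1)
        corr = np.corrcoef(log)
        midx = [cfg.gene_ids.index(g) for g in truth.module_members]
        inside = corr[np.ix_(midx, midx)]
        within = inside[np.triu_indices_from(inside, k=1)].mean()
        bidx = [i for i in range(cfg.n_genes) if i not in set(midx)]
        outside = corr[np.ix_(midx, bidx)].mean()
        assert within > 0.7 > outside

    def test_replicate_columns_map_onto_conditions(self, small_config):
        matrix, smap, _ = syn.gen_expression(small_config)
        assert list(matrix.columns) == list(smap["sample_id"])
        counts = smap.groupby("condition_id").size()
        assert (counts == small_config.n_replicates_per_condition).all()
        assert (matrix.to_numpy() >= 0).all()


class TestPromoterPlanting:
    def test_forced_planting_covers_every_foreground_gene(self):
        cfg = syn.SyntheticConfig(seed=9, n_genes=40, module_size=5,
                                  targets_per_set=10, p_fg=1.0, p_bg=0.0)
        fg = set(cfg.gene_ids[:20])
        _, _, truth = syn.gen_promoters(cfg, fg)
        planted = {(s["gene"], s["motif"]) for s in truth.planted_motif_sites}
        assert planted == {(g, m) for g in sorted(fg) for m in cfg.motif_list}

    def test_sites_lie_within_promoter_bounds(self, small_config):
        _, _, truth = syn.gen_promoters(small_config,
                                        set(small_config.module_members))
        for site in truth.planted_motif_sites:
            assert 1 <= site["offset"]
            assert site["offset"] + len(site["instance"]) - 1 <= \
                small_config.promoter_length

    def test_minus_strand_site_is_reverse_complemented_in_genome(self):
        from Bio.Seq import Seq

        cfg = syn.SyntheticConfig(seed=9, n_genes=10, module_size=4,
                                  targets_per_set=5, p_fg=1.0, p_bg=0.0)
        genome, tss, truth = syn.gen_promoters(cfg, set(cfg.gene_ids))
        minus = tss[tss["strand"] == "-"].iloc[0]
        site = next(s for s in truth.planted_motif_sites
                    if s["gene"] == minus["gene_id"])
        contig = genome[minus["seq_id"]]
        L, o, m = cfg.promoter_length, site["offset"], len(site["instance"])
        start = int(minus["tss"]) + L - o - m + 1  # 0-based genomic start
        assert contig[start: start + m] == str(
            Seq(site["instance"]).reverse_complement())
        # and promoter extraction recovers the sense-strand instance
        pset = extract_promoters(genome, tss, length=L)
        assert pset[minus["gene_id"]][o - 1: o - 1 + m] == site["instance"]

    def test_chance_hits_match_analytic_rate(self):
        cfg = syn.SyntheticConfig(seed=21, n_genes=400, p_fg=0.0, p_bg=0.0,
                                  promoter_length=500, gc_content=0.4,
                                  motif_list={"AKATTCY": "AKATTCY"})
        genome, tss, truth = syn.gen_promoters(cfg, set())
        assert truth.planted_motif_sites == []
        pset = extract_promoters(genome, tss, length=500)
        hits = scan(pset, cfg.motif_list).hits
        positions = 400 * (500 - 7 + 1)
        rate = expected_hit_rate("AKATTCY", 0.4)
        expect = positions * rate
        assert abs(len(hits) - expect) < 4 * np.sqrt(expect)

    def test_foreground_outside_universe_rejected(self, small_config):
        with pytest.raises(ValueError, match="outside the generated universe"):
            syn.gen_promoters(small_config, {"nope"})


class TestPeaksDeAndOrthology:
    def test_no_planted_targets_yields_no_calls(self):
        from aqnet.dapseq import assign_targets

        cfg = syn.SyntheticConfig(seed=5, n_genes=40, targets_per_set=1,
                                  peaks_per_set=20)
        _, tss, _ = syn.gen_promoters(cfg, set())
        sets, truth = syn.gen_peaks(cfg, tss)
        background_only = sets[0].peaks[
            ~sets[0].peaks["peak_id"].isin(
                [f"{sets[0].set_id}_p0001"])].reset_index(drop=True)
        import dataclasses

        stripped = dataclasses.replace(sets[0], peaks=background_only)
        assert len(assign_targets(stripped, tss, window=cfg.promoter_length)) == 0

    def test_de_truth_matches_table_signs(self, small_config):
        table, truth = syn.gen_de_table(small_config)
        assert ((table["fdr"] > 0) & (table["fdr"] <= 1)).all()
        by_gene = table.set_index("gene_id")
        for rec in truth.true_de:
            fc = by_gene.loc[rec["gene"], "log2fc"]
            assert (fc > 0) == (rec["direction"] == "up")
            assert by_gene.loc[rec["gene"], "fdr"] < 0.05

    def test_orthology_partial_one_to_one_covering_module(self, small_config):
        table = syn.gen_orthology(small_config)
        assert table["gene_species_1"].is_unique
        assert table["gene_species_2"].is_unique
        assert set(small_config.module_members) <= set(table["gene_species_1"])
        assert len(table) <= small_config.n_orthologs

    def test_simulate_presence_requires_subset(self):
        with pytest.raises(ValueError, match="subset"):
            syn.simulate_presence(1, ["m"], ["a"], ["b"], 0.5, 0.1)


class TestSequenceFixtures:
    def test_gen_orf_is_valid_and_deterministic(self):
        orf = syn.gen_orf(3, 300)
        assert orf == syn.gen_orf(3, 300)
        assert orf.startswith("ATG") and orf[-3:] in {"TAA", "TAG", "TGA"}
        internal = [orf[i:i + 3] for i in range(3, len(orf) - 3, 3)]
        assert not set(internal) & {"TAA", "TAG", "TGA"}

    def test_gen_protein_pair_differs_at_requested_positions(self):
        a, b = syn.gen_protein_pair(7, length=50, n_diffs=4)
        assert len(a) == len(b) == 50
        assert sum(x != y for x, y in zip(a, b)) == 4
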