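import numpy as np
import pytest

from foldspec.intervals import Interval, interval_gene_set, rank_and_partition
from foldspec.io_formats import read_deg_table, write_deg_table
from foldspec.motifs import scan_presence
from foldspec.synthetic import (
    MotifPlant,
    PlantedTerm,
    SyntheticConfig,
    gen_annotation,
    gen_deg_table,
    gen_promoters,
    genome_gene_ids,
)


class TestGenDegTable:
    def test_reference_scale_counts_and_clip(self):
        cfg = SyntheticConfig(n_up=789, n_down=659, seed=1)
        recs, truth = gen_deg_table(cfg)
        ups = [r for r in recs if r.direction == "up"]
        downs = [r for r in recs if r.direction == "down"]
        assert (len(ups), len(downs)) == (789, 659)
        assert all(1.5 <= r.fold_change <= 88.0 for r in ups)
        assert all(1.4 <= r.fold_change <= 143.0 for r in downs)
        assert set(truth.quantile_of["up"].values()) == set(range(1, 7))

    def test_same_seed_byte_identical_tables(self, tmp_path):
        for name in ("a.tsv", "b.tsv"):
            recs, _ = gen_deg_table(SyntheticConfig(seed=7))
            write_deg_table(recs, tmp_path / name)
        assert (tmp_path / "a.tsv").read_bytes() == (tmp_path / "b.tsv").read_bytes()

    def test_generated_table_passes_reader(self, tmp_path):
        recs, _ = gen_deg_table(SyntheticConfig(n_up=50, n_down=40, seed=3))
        write_deg_table(recs, tmp_path / "deg.tsv")
        assert read_deg_table(tmp_path / "deg.tsv") == recs

    def test_degenerate_range_rejected(self):
        with pytest.raises(ValueError, match="range"):
            SyntheticConfig(fc_range_up=(5.0, 5.0))

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError):
            gen_deg_table(SyntheticConfig(n_up=4, q=6))


class TestGenAnnotation:
    def test_reference_planting_reconstructs_96_12_split(self):
        """size 108, pi = 96/108, target (1,2) on 789 UGs -> 96 in, 12 out."""
        plant = PlantedTerm("T:PLANT", 108, "up", (1, 2), 96 / 108)
        cfg = SyntheticConfig(n_up=789, n_down=659, planted_terms=[plant], seed=5)
        degs, _ = gen_deg_table(cfg)
        ann, _ = gen_annotation(cfg, degs, genome_size=3000)
        part = rank_and_partition([g for g in degs if g.direction == "up"], 6)
        inside = interval_gene_set(part, Interval(1, 2))
        members = ann.genes_for("T:PLANT")
        assert len(members) == 108
        assert len(members & inside) == 96
        assert len(members - inside) == 12
        assert members <= part.genes()

    def test_null_concentration_is_admissible_but_flat(self):
        # pi equal to the interval's background share is allowed (no depletion)
        plant = PlantedTerm("T:NULL", 60, "up", (1, 2), 2 / 6)
        cfg = SyntheticConfig(n_up=600, n_down=200, planted_terms=[plant], seed=2)
        degs, _ = gen_deg_table(cfg)
        ann, _ = gen_annotation(cfg, degs, genome_size=2000)
        assert len(ann.genes_for("T:NULL")) == 60

    def test_depleting_concentration_rejected(self):
        with pytest.raises(ValueError, match="depletion"):
            SyntheticConfig(planted_terms=[PlantedTerm("T", 50, "up", (1, 2), 0.2)])

    def test_capacity_exceeded_rejected(self):
        plant = PlantedTerm("T", 500, "up", (1, 1), 0.9)
        cfg = SyntheticConfig(n_up=600, n_down=200, planted_terms=[plant], seed=2)
        degs, _ = gen_deg_table(cfg)
        with pytest.raises(ValueError, match="capacity"):
            gen_annotation(cfg, degs, genome_size=2000)

    def test_background_terms_and_determinism(self):
        cfg = SyntheticConfig(n_up=100, n_down=100, n_background_terms=20, seed=9)
        degs, _ = gen_deg_table(cfg)
        a1, _ = gen_annotation(cfg, degs, genome_size=500)
        a2, _ = gen_annotation(cfg, degs, genome_size=500)
        assert len(a1) == 20
        assert a1.terms == a2.terms


class TestGenPromoters:
    def test_full_presence_when_insertion_certain(self):
        plant = MotifPlant("TTAGGG", "up", (1, 1), 1.0, 0.0)
        cfg = SyntheticConfig(n_up=60, n_down=60, motif_plants=[plant],
                              promoter_length=100, seed=4)
        degs, _ = gen_deg_table(cfg)
        genes = genome_gene_ids(200, degs)
        proms, _ = gen_promoters(cfg, degs, genes)
        part = rank_and_partition([g for g in degs if g.direction == "up"], 6)
        targets = interval_gene_set(part, Interval(1, 1))
        pres = scan_presence(proms)
        for g in targets:
            assert "CCCTAA" in pres.hexamers_in(g)

    def test_background_presence_matches_closed_form(self):
        """Empirical presence of a hexamer in i.i.d. promoters matches
        1 - (1 - 2/4^6)^(L-5) within Monte-Carlo error."""
        cfg = SyntheticConfig(n_up=6, n_down=6, promoter_length=300, seed=8)
        degs, _ = gen_deg_table(cfg)
        genes = genome_gene_ids(2000, degs)
        proms, _ = gen_promoters(cfg, degs, genes)
        pres = scan_presence(proms)
        expected = 1 - (1 - 2 * 4.0 ** -6) ** (300 - 5)
        for hexamer in ("TTAGGG", "ACGTCA", "AAACCC"):
            rate = float(pres.presence_of(hexamer).mean())
            assert rate == pytest.approx(expected, abs=4 * np.sqrt(expected * (1 - expected) / 2000))

    def test_determinism_under_seed(self):
        cfg = SyntheticConfig(n_up=20, n_down=20, promoter_length=80, seed=12)
        degs, _ = gen_deg_table(cfg)
        genes = genome_gene_ids(60, degs)
        p1, _ = gen_promoters(cfg, degs, genes)
        p2, _ = gen_promoters(cfg, degs, genes)
        assert p1.sequences == p2.sequences

    def test_too_short_promoters_rejected(self):
        cfg = SyntheticConfig(n_up=20, n_down=20, promoter_length=4, seed=1)
        degs, _ = gen_deg_table(cfg)
        with pytest.raises(ValueError):
            gen_promoters(cfg, degs, genome_gene_ids(40, degs))


class TestRecoveryMonotonicity:
    def test_recovery_rate_non_decreasing_in_concentration(self):
        from foldspec.pipeline import planted_term_trial

        rates = []
        for pi in (0.4, 0.5, 0.9):
            hits = [planted_term_trial(200 + i, pi=pi).recovered for i in range(8)]
            rates.append(sum(hits))
        assert rates[0] <= rates[1] <= rates[2]
        assert rates[2] >= 7  # strong planting nearly always recovered
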