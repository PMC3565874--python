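"""Synthetic-data generator: determinism, structural guarantees, truth
labels."""

import numpy as np
import pytest

from retrointron.kaks import GENETIC_CODE
from retrointron.simulate import (
    GenerationError,
    InjectionError,
    SimulationConfig,
    generate_parent_gene,
    inject_intron_gain,
    retropose,
    simulate_dataset,
    write_dataset,
)


@pytest.fixture()
def rng():
    return np.random.default_rng(23)


class TestParentGenes:
    def test_structure_and_boundaries(self, rng):
        cfg = SimulationConfig(exon_count=(4, 4))
        info = generate_parent_gene(cfg, rng)
        assert len(info["exons_rel"]) == 4
        seq = info["seq"]
        for (s1, e1), (s2, e2) in zip(info["exons_rel"], info["exons_rel"][1:]):
            intron = seq[e1:s2]
            assert intron[:2] == "GT" and intron[-2:] == "AG"

    def test_cds_translates_without_internal_stops(self, rng):
        info = generate_parent_gene(SimulationConfig(), rng)
        cds = info["cds"]
        assert len(cds) % 3 == 0
        aas = [GENETIC_CODE[cds[i:i + 3]] for i in range(0, len(cds) - 3, 3)]
        assert "*" not in aas
        assert GENETIC_CODE[cds[-3:]] == "*"

    def test_same_seed_same_gene(self):
        a = generate_parent_gene(SimulationConfig(), np.random.default_rng(5))
        b = generate_parent_gene(SimulationConfig(), np.random.default_rng(5))
        assert a["seq"] == b["seq"]
        assert a["exons_rel"] == b["exons_rel"]

    def test_degenerate_length_distribution_rejected(self, rng):
        with pytest.raises(ValueError):
            generate_parent_gene(SimulationConfig(exon_len=(0, 0)), rng)
        with pytest.raises(ValueError):
            generate_parent_gene(SimulationConfig(exon_len=(50, 10)), rng)


class TestRetroposition:
    def test_zero_divergence_identity_case(self):
        """With zero rates the retrocopy equals spliced mRNA + poly(A)."""
        cfg = SimulationConfig(sub_rate=0.0, indel_rate=0.0)
        ds = simulate_dataset(cfg, seed=3)
        row = ds.truth.query("mechanism == 'none' and ~is_decoy").iloc[0]
        from retrointron.core import revcomp
        locus = ds.genome_records[row.chrom][row.start:row.end]
        if row.strand == "-":
            locus = revcomp(locus)
        parent_cds = None
        # reconstruct the parent CDS from the annotation and chr1
        parent = ds.parents[row.parent_id]
        tid = parent.transcript_ids[0]
        parent_cds = "".join(
            ds.genome_records["chr1"][iv.start:iv.end]
            for iv in parent.cds[tid])
        assert locus == parent_cds + "A" * cfg.polya_len

    def test_polya_tail_is_pure_a(self, rng):
        cfg = SimulationConfig(polya_len=20)
        retro = retropose("ATGGCTAAA", cfg, rng)
        assert retro.endswith("A" * 20)

    def test_intron_count_matches_parent(self):
        ds = simulate_dataset(SimulationConfig(), seed=3)
        for _, row in ds.truth.query("~is_decoy").iterrows():
            parent = ds.parents[row.parent_id]
            assert parent.n_introns(parent.transcript_ids[0]) >= 4


class TestInjection:
    def test_cryptic_leaves_sequence_untouched(self, rng):
        cfg = SimulationConfig()
        base = generate_parent_gene(cfg, rng)["cds"]
        res = inject_intron_gain(base, "intronization_cryptic", cfg, rng)
        assert res["seq"] == base
        a, b = res["intron"]
        assert base[a:a + 2] == "GT" and base[b - 2:b] == "AG"

    def test_substitution_edits_at_most_two_bases(self, rng):
        cfg = SimulationConfig(compensating_indel_prob=0.0)
        base = generate_parent_gene(cfg, rng)["cds"]
        res = inject_intron_gain(base, "intronization_substitution", cfg, rng)
        assert 1 <= len(res["edits"]) <= 2
        a, b = res["intron"]
        seq = res["seq"]
        assert seq[a:a + 2] == "GT" and seq[b - 2:b] == "AG"
        # at least one boundary base differs from the parent
        donor_diff = sum(x != y for x, y in zip(base[a:a + 2], seq[a:a + 2]))
        acc_diff = sum(x != y for x, y in zip(base[b - 2:b], seq[b - 2:b]))
        assert donor_diff + acc_diff >= 1

    def test_insertion_adds_new_sequence(self, rng):
        cfg = SimulationConfig()
        base = generate_parent_gene(cfg, rng)["cds"]
        res = inject_intron_gain(base, "insertion", cfg, rng)
        a, b = res["intron"]
        assert len(res["seq"]) == len(base) + (b - a)
        assert (b - a) % 3 == 0

    def test_cryptic_without_candidate_pair_errors(self, rng):
        cfg = SimulationConfig()
        with pytest.raises(InjectionError):
            inject_intron_gain("A" * 2000, "intronization_cryptic", cfg, rng)

    def test_unknown_mechanism_rejected(self, rng):
        with pytest.raises(ValueError):
            inject_intron_gain("A" * 2000, "teleportation",
                               SimulationConfig(), rng)


class TestDatasetDeterminism:
    def test_identical_outputs_for_same_seed(self, tmp_path):
        ds1 = simulate_dataset(SimulationConfig(), seed=17)
        ds2 = simulate_dataset(SimulationConfig(), seed=17)
        assert ds1.genome_records == ds2.genome_records
        assert ds1.truth.equals(ds2.truth)
        p1 = write_dataset(ds1, tmp_path / "a")
        p2 = write_dataset(ds2, tmp_path / "b")
        for key in ("genome", "annotation", "truth", "transcripts"):
            assert open(p1[key]).read() == open(p2[key]).read()

    def test_different_seeds_differ(self):
        ds1 = simulate_dataset(SimulationConfig(), seed=17)
        ds2 = simulate_dataset(SimulationConfig(), seed=18)
        assert ds1.genome_records != ds2.genome_records


class TestTruthConsistency:
    def test_intron_coordinates_inside_locus(self, fixture_data):
        truth = fixture_data.dataset.truth
        for _, row in truth.query("intron_start >= 0").iterrows():
            assert row.start < row.intron_start < row.intron_end < row.end

    def test_mechanism_counts_match_config(self, fixture_data):
        truth = fixture_data.dataset.truth
        cfg = fixture_data.dataset.config
        events = truth[(truth.mechanism != "none") & (~truth.is_decoy)]
        assert len(events) == cfg.n_gain_events
        assert len(truth[~truth.is_decoy]) == cfg.n_retrocopies
        assert truth.is_decoy.sum() == cfg.n_decoys

    def test_annotated_boundaries_are_splice_valid(self, fixture_data):
        """Every annotated gained intron reads GT..AG on its transcript
        strand, including reverse-orientation events."""
        from retrointron.core import GenomicInterval
        data = fixture_data
        for _, row in data.dataset.truth.query("intron_start >= 0").iterrows():
            gene = data.genes[row.retro_id]
            iv = GenomicInterval(row.chrom, int(row.intron_start),
                                 int(row.intron_end), gene.strand)
            seq = data.genome.fetch(iv)
            assert seq[:2] == "GT" and seq[-2:] == "AG", row.retro_id
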