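"""Simulator contracts: determinism, composition, TA targeting, hotspots,
read structure, and serialization round-trips."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import primsite as p
from primsite.synthetic_data import (
    CapacityError,
    ConfigurationError,
    Gene,
    JunctionError,
    PlacementError,
    find_ta_positions,
    splice_integration,
    write_gff3,
    read_gff3,
)

from oracles import naive_ta_scan


# ---------------------------------------------------------------------------
# Genome generation


def test_genome_deterministic_and_alphabet():
    cfg = p.SimulationConfig(seed=1, n_chromosomes=1, chromosome_lengths=10_000)
    g1 = p.generate_genome(cfg)
    g2 = p.generate_genome(cfg)
    assert g1.chromosomes == g2.chromosomes
    assert set(g1.chromosomes["chr1"]) <= set("ACGT")


def test_genome_gc_zero_is_at_only():
    cfg = p.SimulationConfig(seed=2, n_chromosomes=1, chromosome_lengths=10_000,
                             gc_fraction=0.0)
    g = p.generate_genome(cfg)
    assert set(g.chromosomes["chr1"]) <= {"A", "T"}


def test_genome_gc_fraction_binomial_bound():
    # at 2 Mb the binomial SD of the GC fraction is ~0.00035, so +-0.01 is
    # a >20-sigma envelope
    cfg = p.SimulationConfig(seed=3, n_chromosomes=1, chromosome_lengths=2_000_000,
                             gc_fraction=0.42)
    seq = p.generate_genome(cfg).chromosomes["chr1"]
    gc = (seq.count("G") + seq.count("C")) / len(seq)
    assert abs(gc - 0.42) < 0.01


def test_genome_rejects_zero_length():
    cfg = p.SimulationConfig(seed=1, n_chromosomes=1, chromosome_lengths=0)
    with pytest.raises(ConfigurationError):
        p.generate_genome(cfg)


def test_every_chromosome_contains_ta(small_genome):
    for seq in small_genome.chromosomes.values():
        assert "TA" in seq


def test_ta_scan_matches_naive_oracle():
    cfg = p.SimulationConfig(seed=4, n_chromosomes=1, chromosome_lengths=100_000)
    seq = p.generate_genome(cfg).chromosomes["chr1"]
    assert find_ta_positions(seq).tolist() == naive_ta_scan(seq)


# ---------------------------------------------------------------------------
# Gene model


def test_gene_model_empty():
    cfg = p.SimulationConfig(seed=5, n_chromosomes=1, chromosome_lengths=10_000,
                             n_genes=0)
    g = p.generate_genome(cfg)
    model = p.generate_gene_model(g, cfg)
    assert len(model.genes) == 0


def test_two_cds_gene_has_one_intron_equal_to_gap():
    gene = Gene("g1", "chr1", "+", 100, 1000,
                cds=[(100, 300), (600, 1000)])
    assert gene.introns() == [(300, 600)]


def test_gene_model_gff3_roundtrip_and_determinism(tmp_path, small_genome,
                                                   small_config):
    model = p.generate_gene_model(small_genome, small_config)
    f1, f2 = tmp_path / "a.gff3", tmp_path / "b.gff3"
    write_gff3(f1, model, small_genome, seed=small_config.seed)
    write_gff3(f2, p.generate_gene_model(small_genome, small_config),
               small_genome, seed=small_config.seed)
    assert f1.read_bytes() == f2.read_bytes()
    back = read_gff3(f1)
    assert len(back.genes) == len(model.genes)
    for a, b in zip(back.genes, model.genes):
        assert (a.gene_id, a.chromosome, a.strand, a.start, a.end) == (
            b.gene_id, b.chromosome, b.strand, b.start, b.end)
        assert a.cds == b.cds and a.utr5 == b.utr5 and a.utr3 == b.utr3


def test_gene_placement_error_when_density_too_high():
    cfg = p.SimulationConfig(seed=6, n_chromosomes=1, chromosome_lengths=10_000,
                             n_genes=50)
    g = p.generate_genome(cfg)
    with pytest.raises(PlacementError, match="density"):
        p.generate_gene_model(g, cfg)


def test_nonoverlapping_by_default(small_genome, small_config):
    model = p.generate_gene_model(small_genome, small_config)
    for chrom, genes in model.by_chromosome().items():
        spans = sorted((g.start, g.end) for g in genes)
        for (s0, e0), (s1, e1) in zip(spans, spans[1:]):
            assert e0 <= s1


# ---------------------------------------------------------------------------
# Integration events


def test_simulate_integrations_n_zero(small_genome):
    assert p.simulate_integrations(small_genome, 0, seed=1) == []


def test_all_events_sit_on_ta(small_genome):
    for seed in range(3):
        for ev in p.simulate_integrations(small_genome, 50, seed=seed):
            seq = small_genome.chromosomes[ev.chromosome]
            assert seq[ev.position : ev.position + 2] == "TA"


def test_events_deduplicated(small_genome):
    evs = p.simulate_integrations(small_genome, 200, seed=7)
    keys = {(e.chromosome, e.position) for e in evs}
    assert len(keys) == 200


def test_capacity_error(small_genome):
    n_ta = sum(len(find_ta_positions(s)) for s in small_genome.chromosomes.values())
    with pytest.raises(CapacityError):
        p.simulate_integrations(small_genome, n_ta + 1, seed=1)


def test_hotspot_occupancy_beats_null_99th_percentile(small_genome):
    """A 50x-weighted window's occupancy exceeds the 99th percentile of the
    null occupancy distribution estimated by a 10,000-draw Monte-Carlo
    oracle at matched TA share."""
    width = 2_000
    hot = (("chr1", 10 * width, 11 * width), 50.0)
    evs = p.simulate_integrations(small_genome, 300, [hot], seed=8)
    (hc, hs, he), _ = hot
    occupancy = sum(1 for e in evs if e.chromosome == hc and hs <= e.position < he)

    # null oracle: multinomial over windows proportional to TA counts
    rng = np.random.default_rng(0)
    ta_share = []
    for name, seq in small_genome.chromosomes.items():
        pos = find_ta_positions(seq)
        for s in range(0, len(seq), width):
            ta_share.append(np.sum((pos >= s) & (pos < s + width)))
    ta_share = np.array(ta_share, dtype=float)
    probs = ta_share / ta_share.sum()
    hot_idx = 10  # chr1 windows come first, in order
    draws = rng.multinomial(300, probs, size=10_000)[:, hot_idx]
    assert occupancy > np.percentile(draws, 99)


def test_null_window_counts_consistent_with_ta_multinomial(small_genome):
    """With no hotspots, aggregated per-window counts pass a chi-square
    goodness-of-fit against TA-proportional expectation in >= 9/10 seeds."""
    width = 10_000
    ta_share = []
    for name, seq in small_genome.chromosomes.items():
        pos = find_ta_positions(seq)
        for s in range(0, len(seq), width):
            ta_share.append(np.sum((pos >= s) & (pos < s + width)))
    probs = np.array(ta_share, dtype=float)
    probs /= probs.sum()
    passed = 0
    for seed in range(10):
        evs = p.simulate_integrations(small_genome, 400, seed=100 + seed)
        counts = np.zeros(len(probs))
        offsets = {}
        i = 0
        for name, seq in small_genome.chromosomes.items():
            offsets[name] = (i, width)
            i += -(-len(seq) // width)
        for e in evs:
            base, w = offsets[e.chromosome]
            counts[base + e.position // w] += 1
        _, pval = stats.chisquare(counts, 400 * probs)
        if pval > 0.01:
            passed += 1
    assert passed >= 9


# ---------------------------------------------------------------------------
# Integrated sequence construction


def test_splice_convention_example():
    out = splice_integration("ACGTACGT", 3, "GGGG", "", "CCCC")
    assert out == "ACGTA" + "GGGG" + "CCCC" + "TACGT"
    assert len(out) == 18


def test_splice_rejects_non_ta():
    with pytest.raises(JunctionError):
        splice_integration("ACGTACGT", 0, "GGGG", "", "CCCC")


def test_construct_length_and_ta_duplication(small_genome, transposon):
    ev = p.simulate_integrations(small_genome, 1, seed=9)[0]
    out = p.construct_integrated_sequence(small_genome, ev, transposon)
    chrom = small_genome.chromosomes[ev.chromosome]
    assert len(out) == len(chrom) + transposon.total_length() + 2
    # TA at both junctions
    i = ev.position
    assert out[i : i + 2] == "TA"
    j = i + 2 + transposon.total_length()
    assert out[j : j + 2] == "TA"


# ---------------------------------------------------------------------------
# Junction reads


def test_reads_are_exact_substrings_when_error_free(small_genome, transposon,
                                                    small_config):
    evs = p.simulate_integrations(small_genome, 10, seed=10)
    reads = p.generate_junction_reads(small_genome, evs, transposon, small_config)
    constructs = {
        e.event_id: p.construct_integrated_sequence(small_genome, e, transposon)
        for e in evs
    }
    from primsite.io import revcomp
    for r in reads:
        eid = r.name.split("|")[0]
        c = constructs[eid]
        assert r.sequence in c or revcomp(r.sequence) in c


def test_read_count(small_genome, transposon):
    cfg = p.SimulationConfig(seed=11, n_chromosomes=2, chromosome_lengths=100_000,
                             reads_per_event=3)
    evs = p.simulate_integrations(small_genome, 10, seed=11)
    reads = p.generate_junction_reads(small_genome, evs, transposon, cfg)
    assert len(reads) == 60  # 10 events x 2 sides x 3 reads


def test_substitution_rate_binomial_bound(small_genome, transposon):
    cfg = p.SimulationConfig(seed=12, n_chromosomes=2, chromosome_lengths=100_000,
                             substitution_error_rate=0.01, reads_per_event=8,
                             read_length=100)
    evs = p.simulate_integrations(small_genome, 80, seed=12)
    noisy = p.generate_junction_reads(small_genome, evs, transposon, cfg)
    clean_cfg = p.SimulationConfig(seed=12, n_chromosomes=2,
                                   chromosome_lengths=100_000,
                                   reads_per_event=8, read_length=100)
    clean = p.generate_junction_reads(small_genome, evs, transposon, clean_cfg)
    mism = total = 0
    for a, b in zip(noisy, clean):
        assert len(a.sequence) == len(b.sequence)
        mism += sum(x != y for x, y in zip(a.sequence, b.sequence))
        total += len(a.sequence)
    assert total > 100_000
    assert abs(mism / total - 0.01) < 0.003


def test_fastq_deterministic(tmp_path, small_genome, transposon, small_config):
    from primsite.io import write_fastq
    evs = p.simulate_integrations(small_genome, 10, seed=13)
    f1, f2 = tmp_path / "a.fq", tmp_path / "b.fq"
    write_fastq(f1, p.generate_junction_reads(small_genome, evs, transposon,
                                              small_config), seed=13)
    write_fastq(f2, p.generate_junction_reads(small_genome, evs, transposon,
                                              small_config), seed=13)
    assert f1.read_bytes() == f2.read_bytes()


# ---------------------------------------------------------------------------
# Random TA fragments


def test_random_fragments_contain_ta(small_genome):
    frags = p.generate_random_ta_fragments(small_genome, 50, 60, seed=14)
    assert len(frags) == 50
    assert all("TA" in f.sequence for f in frags)


def test_random_fragments_n_zero(small_genome):
    assert p.generate_random_ta_fragments(small_genome, 0, 60, seed=1) == []


def test_random_fragment_starts_proportional_to_chromosome_length():
    """Across 10 seeds, pooled mapped fragment counts per chromosome follow
    chromosome lengths within chi-square tolerance."""
    cfg = p.SimulationConfig(seed=15, n_chromosomes=3,
                             chromosome_lengths=(50_000, 100_000, 150_000))
    g = p.generate_genome(cfg)
    from primsite.junction_calling import map_random_fragments
    counts = {name: 0 for name in g.names}
    for seed in range(10):
        frags = p.generate_random_ta_fragments(g, 60, 60, seed=seed)
        mapped = map_random_fragments(frags, g)
        for chrom, n in mapped.groupby("chromosome")["support_reads"].sum().items():
            counts[chrom] += int(n)
    observed = np.array([counts[n] for n in g.names], dtype=float)
    lengths = np.array([len(g.chromosomes[n]) for n in g.names], dtype=float)
    expected = observed.sum() * lengths / lengths.sum()
    _, pval = stats.chisquare(observed, expected)
    assert pval > 0.001
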