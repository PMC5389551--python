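"""Synthetic community generator: determinism, truth tables, error rates."""

import numpy as np
import pytest

from seedtax.kmers import revcomp
from seedtax.simulate import GenusGroup, SimConfig, simulate_genomes, simulate_reads


def small_cfg(**kw):
    defaults = dict(rng_seed=5, genome_length=5000, n_fragments=50,
                    genus_groups=[GenusGroup(1)] * 3, insert_mean=400,
                    insert_sd=20, sub_rate=0.0, indel_rate=0.0)
    defaults.update(kw)
    return SimConfig(**defaults)


def test_same_seed_reproduces_byte_identical_output():
    cfg = small_cfg()
    refs1, _ = simulate_genomes(cfg)
    refs2, _ = simulate_genomes(cfg)
    assert [(r.id, r.sequence) for r in refs1] == [(r.id, r.sequence) for r in refs2]
    pairs1, truth1 = simulate_reads(refs1, cfg)
    pairs2, truth2 = simulate_reads(refs2, cfg)
    assert [(p[0].sequence, p[1].sequence) for p in pairs1] == [
        (p[0].sequence, p[1].sequence) for p in pairs2
    ]
    assert truth1.equals(truth2)


def test_genus_members_share_the_conserved_block():
    cfg = small_cfg(genus_groups=[GenusGroup(3, 0.8), GenusGroup(2, 0.5)],
                    genome_length=2000)
    refs, tree = simulate_genomes(cfg)
    assert len(refs) == 5
    g1 = [r.sequence for r in refs if r.id.startswith("g1")]
    # an identical 1600-base block at a shared offset
    matches = np.array([[a == b for a, b in zip(g1[0], g1[1])]])
    assert sum(a == b for a, b in zip(g1[0], g1[1])) >= 1600
    assert sum(a == b for a, b in zip(g1[0], g1[2])) >= 1600
    # taxonomy: species under genus under root
    assert tree.path_to_root(refs[0].taxid) == [11, 10, 1]


def test_zero_conserved_fraction_gives_independent_genomes():
    cfg = small_cfg(genus_groups=[GenusGroup(2, 0.0)], genome_length=4000)
    refs, _ = simulate_genomes(cfg)
    agree = sum(a == b for a, b in zip(refs[0].sequence, refs[1].sequence))
    assert agree < 0.30 * 4000  # ~25% by chance


def test_error_free_reads_are_exact_substrings():
    cfg = small_cfg()
    refs, _ = simulate_genomes(cfg)
    pairs, truth = simulate_reads(refs, cfg)
    by_id = {r.id: r.sequence for r in refs}
    for (r1, r2), row in zip(pairs, truth.itertuples()):
        g = by_id[row.genome_id]
        assert g[row.genome_position : row.genome_position + len(r1.sequence)] == r1.sequence
        assert revcomp(r2.sequence) in g


def test_truth_table_is_complete_and_unique():
    cfg = small_cfg(n_fragments=200)
    refs, _ = simulate_genomes(cfg)
    pairs, truth = simulate_reads(refs, cfg)
    assert len(truth) == 200
    assert truth["fragment_id"].is_unique
    assert {p[0].id for p in pairs} == set(truth["fragment_id"])


def test_single_abundance_cites_one_genome():
    cfg = small_cfg(genus_groups=[GenusGroup(1)] * 3, abundances=[1.0, 0.0, 0.0])
    refs, _ = simulate_genomes(cfg)
    _, truth = simulate_reads(refs, cfg)
    assert set(truth["genome_id"]) == {refs[0].id}


def test_insert_sizes_match_the_configured_distribution():
    cfg = small_cfg(n_fragments=2000, genome_length=20000, insert_mean=400, insert_sd=30)
    refs, _ = simulate_genomes(cfg)
    pairs, truth = simulate_reads(refs, cfg)
    by_id = {r.id: r.sequence for r in refs}
    inserts = []
    for (r1, r2), row in zip(pairs, truth.itertuples()):
        g = by_id[row.genome_id]
        end = g.index(revcomp(r2.sequence), row.genome_position) + len(r2.sequence)
        inserts.append(end - row.genome_position)
    inserts = np.array(inserts)
    assert abs(inserts.mean() - 400) < 3 * 30 / np.sqrt(len(inserts)) + 1
    assert abs(inserts.std() - 30) < 5


def test_substitution_rate_is_calibrated():
    """Observed mismatch fraction within 3 binomial SDs of the target."""
    cfg = small_cfg(n_fragments=10_000, genome_length=20000, sub_rate=0.01)
    refs, _ = simulate_genomes(cfg)
    pairs, truth = simulate_reads(refs, cfg)
    by_id = {r.id: r.sequence for r in refs}
    mism = total = 0
    for (r1, _), row in zip(pairs, truth.itertuples()):
        ref = by_id[row.genome_id][row.genome_position : row.genome_position + 150]
        mism += sum(a != b for a, b in zip(r1.sequence, ref))
        total += 150
    p = 0.01
    sd = np.sqrt(p * (1 - p) / total)
    assert abs(mism / total - p) < 3 * sd


def test_chimeric_fragments_have_large_inserts():
    cfg = small_cfg(n_fragments=500, genome_length=20000, chimera_rate=0.2)
    refs, _ = simulate_genomes(cfg)
    pairs, truth = simulate_reads(refs, cfg)
    by_id = {r.id: r.sequence for r in refs}
    for (r1, r2), row in zip(pairs, truth.itertuples()):
        if row.chimeric:
            g = by_id[row.genome_id]
            end = g.index(revcomp(r2.sequence), row.genome_position) + len(r2.sequence)
            assert end - row.genome_position >= cfg.chimera_min_insert


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        GenusGroup(2, 1.0)
    with pytest.raises(ValueError):
        SimConfig(genus_groups=[GenusGroup(2)], abundances=[0.7, 0.7]).genome_abundances()
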