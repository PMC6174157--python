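"""Cohort generator: determinism, planted structure, count model, round-trips."""

import dataclasses

import numpy as np
import pytest

from mirtfnet.errors import ConfigError, GenerationError
from mirtfnet.io import read_counts, read_fasta, read_gmt, read_tf_list
from mirtfnet.seq import reverse_complement
from mirtfnet.synthetic import (
    SimulationConfig,
    generate_cohort,
    generate_mirnome,
    generate_transcriptome,
    plant_target_sites,
    read_truth,
    simulate_counts,
    write_cohort,
)

from conftest import TINY_PARAMS


def small_config(**overrides):
    seed = overrides.pop("rng_seed", 7)
    params = dict(TINY_PARAMS)
    params.update(overrides)
    return SimulationConfig(rng_seed=seed, **params)


def test_transcriptome_is_deterministic_and_sized():
    cfg = SimulationConfig(n_genes=100, n_tfs=10, rng_seed=7)
    g1 = generate_transcriptome(cfg)
    g2 = generate_transcriptome(cfg)
    assert len(g1) == 100
    assert [g.utr_seq for g in g1] == [g.utr_seq for g in g2]
    assert sum(g.is_tf for g in g1) == 10


def test_transcriptome_zero_tfs():
    cfg = SimulationConfig(n_genes=50, n_tfs=0, hub_site_mirnas=0, rng_seed=1)
    assert sum(g.is_tf for g in generate_transcriptome(cfg)) == 0


def test_utr_lengths_within_range():
    cfg = SimulationConfig(n_genes=400, utr_length_range=(200, 2000), rng_seed=3)
    lengths = [len(g.utr_seq) for g in generate_transcriptome(cfg)]
    assert min(lengths) >= 200 and max(lengths) <= 2000


def test_invalid_config_names_offending_field():
    with pytest.raises(ConfigError, match="n_pairs"):
        generate_transcriptome(SimulationConfig(n_pairs=1))
    with pytest.raises(ConfigError, match="n_tfs"):
        generate_transcriptome(SimulationConfig(n_genes=10, n_tfs=20))
    with pytest.raises(ConfigError, match="hub_site_mirnas"):
        SimulationConfig(planted_up_mirnas=5, hub_site_mirnas=10).validate()


def test_mirnome_lengths_and_distinct_planted_seeds():
    cfg = SimulationConfig(n_mirnas=120, planted_up_mirnas=60, hub_site_mirnas=0, rng_seed=5)
    mirnas = generate_mirnome(cfg)
    assert len(mirnas) == 120
    assert all(19 <= len(m.mature_seq) <= 23 for m in mirnas)
    planted_seeds = [m.seed for m in mirnas[:60]]
    assert len(set(planted_seeds)) == 60
    again = generate_mirnome(cfg)
    assert [m.mature_seq for m in again] == [m.mature_seq for m in mirnas]


def test_planted_sites_written_as_8mers(tiny_cohort):
    truth = tiny_cohort["truth"]
    utrs = {g.gene_id: g.utr_seq for g in tiny_cohort["genes"]}
    by_id = {m.id: m for m in tiny_cohort["mirnas"]}
    intervals: dict[str, list] = {}
    for mirna_id, entries in truth.target_map.items():
        site = reverse_complement(by_id[mirna_id].mature_seq[1:8]) + "A"
        for gene_id, pos in entries:
            assert utrs[gene_id][pos : pos + 8] == site
            intervals.setdefault(gene_id, []).append((pos, pos + 8))
    # no planted site overlaps another
    for gene_id, spans in intervals.items():
        spans.sort()
        for (a1, b1), (a2, b2) in zip(spans, spans[1:]):
            assert b1 <= a2


def test_hub_carries_exactly_the_requested_sites(tiny_cohort):
    truth = tiny_cohort["truth"]
    cfg = tiny_cohort["config"]
    hub_targeting = {
        m for m, entries in truth.target_map.items()
        if any(g == truth.hub_gene_id for g, _ in entries)
    }
    assert len(hub_targeting) == cfg.hub_site_mirnas
    hub_gene = next(g for g in tiny_cohort["genes"] if g.gene_id == truth.hub_gene_id)
    assert hub_gene.is_tf


def test_hub_zero_sites_leaves_hub_untouched():
    cfg = small_config(hub_site_mirnas=0, targets_per_mirna=0)
    genes = generate_transcriptome(cfg)
    mirnas = generate_mirnome(cfg)
    planted, truth = plant_target_sites(genes, mirnas, cfg)
    assert truth.target_map == {m.id: [] for m in mirnas[: cfg.planted_up_mirnas]}
    assert {g.gene_id: g.utr_seq for g in planted} == {
        g.gene_id: g.utr_seq for g in genes
    }


def test_hub_utr_too_short_raises_generation_error():
    cfg = small_config(utr_length_range=(30, 40), hub_site_mirnas=10)
    genes = generate_transcriptome(cfg)
    mirnas = generate_mirnome(cfg)
    with pytest.raises(GenerationError, match="host"):
        plant_target_sites(genes, mirnas, cfg)


def test_counts_deterministic_and_column_sums_in_range(tiny_cohort):
    cfg = tiny_cohort["config"]
    lo, hi = cfg.library_size_range
    for cm in (tiny_cohort["mrna"], tiny_cohort["mirna"]):
        sums = cm.library_sizes.to_numpy()
        assert (sums >= lo * 0.8).all() and (sums <= hi * 1.2).all()
    genes, mirnas = tiny_cohort["genes"], tiny_cohort["mirnas"]
    again_mrna, again_mirna = simulate_counts(
        genes, mirnas, dataclasses.replace(tiny_cohort["truth"]), cfg
    )
    assert (again_mrna.counts == tiny_cohort["mrna"].counts).all().all()
    assert (again_mirna.counts == tiny_cohort["mirna"].counts).all().all()


def test_planted_fold_change_recovered_in_low_dispersion_limit():
    """Near the Poisson limit with matched libraries, the empirical tumor/normal
    ratio of planted up-miRNAs recovers the planted fold change within 5%."""
    ratios = []
    for seed in (1, 2, 3):
        cfg = SimulationConfig(
            rng_seed=seed,
            n_genes=50,
            n_tfs=5,
            n_mirnas=200,
            planted_up_mirnas=5,
            planted_down_mirnas=0,
            hub_site_mirnas=3,
            targets_per_mirna=2,
            target_pool_genes=10,
            nb_dispersion=1e-4,
            background_de_fraction=0.0,
            library_size_range=(500_000, 500_000),
        )
        genes, mirnas, _, mirna_cm, truth = generate_cohort(cfg)
        for m in sorted(truth.up_mirna_ids):
            row = mirna_cm.counts.loc[m]
            for pair in mirna_cm.pair_ids:
                t, n = mirna_cm.pair_samples(pair)
                ratios.append(row[t] / row[n])
    assert np.mean(ratios) == pytest.approx(4.0, rel=0.05)


def test_global_null_construction_centers_log_ratios_at_zero():
    cfg = SimulationConfig(
        rng_seed=11,
        n_genes=400,
        n_tfs=10,
        n_mirnas=20,
        planted_up_mirnas=2,
        planted_down_mirnas=0,
        hub_site_mirnas=1,
        targets_per_mirna=1,
        target_pool_genes=4,
        planted_mirna_fc=1.0,
        target_suppression_fc=1.0,
        background_de_fraction=0.0,
        library_size_range=(300_000, 300_000),
    )
    genes, mirnas, mrna_cm, _, truth = generate_cohort(cfg)
    logr = []
    for pair in mrna_cm.pair_ids:
        t, n = mrna_cm.pair_samples(pair)
        logr.append(np.log((mrna_cm.counts[t] + 0.5) / (mrna_cm.counts[n] + 0.5)))
    assert abs(np.mean(np.concatenate(logr))) < 0.05


def test_write_cohort_round_trips(tmp_path, tiny_cohort):
    files = write_cohort(
        tiny_cohort["genes"],
        tiny_cohort["mirnas"],
        tiny_cohort["mrna"],
        tiny_cohort["mirna"],
        tiny_cohort["truth"],
        tmp_path,
    )
    utrs = read_fasta(files["utr_fasta"])
    assert len(utrs) == tiny_cohort["config"].n_genes
    assert utrs == {g.gene_id: g.utr_seq for g in tiny_cohort["genes"]}
    cm = read_counts(files["mrna_counts"], lengths_path=files["mrna_lengths"])
    assert (cm.counts == tiny_cohort["mrna"].counts).all().all()
    assert (cm.samples == tiny_cohort["mrna"].samples.loc[cm.samples.index]).all().all()
    cm2 = read_counts(files["mirna_counts"])
    assert (cm2.counts == tiny_cohort["mirna"].counts).all().all()
    truth = read_truth(files["truth"])
    assert truth.target_map == tiny_cohort["truth"].target_map
    assert truth.up_mirna_ids == tiny_cohort["truth"].up_mirna_ids
    tf_ids = read_tf_list(files["tf_list"])
    assert tf_ids == {g.gene_id for g in tiny_cohort["genes"] if g.is_tf}
    gmt = read_gmt(files["go_map"])
    assert all(len(genes) > 0 for _, genes in gmt.values())
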