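import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

from wgdkit import ks as ksmod
from wgdkit.simulate import (Branch, ConfigError, ExpressionConfig, HistoryConfig,
                             WgdEvent, evolve_codons, five_genome_config,
                             homology_for, pair_config, random_cds,
                             realize_sequences, simulate_dataset,
                             simulate_expression, simulate_gene_orders)


def test_no_events_no_loss_identity():
    """Without events or loss every genome equals the ancestor and homology
    between two genomes is a perfect 1:1 matching."""
    cfg = pair_config([], seed=1, n_chromosomes=2, genes_per_chromosome=50)
    ds = simulate_gene_orders(cfg)
    assert len(ds.annotations["O"]) == len(ds.annotations["W"]) == 100
    hom = homology_for(ds, "O", "W")
    assert len(hom) == 100
    assert set(hom.pairs["event"]) == {"speciation"}
    # same ancestral order on both sides
    o = ds.truth.copies("O").sort_values(["chromosome", "order_index"])
    w = ds.truth.copies("W").sort_values(["chromosome", "order_index"])
    assert list(o["anc_id"]) == list(w["anc_id"])


def test_nested_tetraploidies_without_loss_give_four_copies(double_wgd_clean):
    counts = double_wgd_clean.truth.copies("W").groupby("anc_id").size()
    assert (counts == 4).all()


def test_determinism_same_seed():
    cfg1 = pair_config([WgdEvent("E", 30.0, 2, retained_fraction=0.7)],
                       seed=9, n_chromosomes=2, genes_per_chromosome=80)
    cfg2 = pair_config([WgdEvent("E", 30.0, 2, retained_fraction=0.7)],
                       seed=9, n_chromosomes=2, genes_per_chromosome=80)
    d1 = simulate_dataset(cfg1, sequences=True)
    d2 = simulate_dataset(cfg2, sequences=True)
    pd.testing.assert_frame_equal(d1.truth.genes, d2.truth.genes)
    assert d1.cds == d2.cds


def test_orders_independent_of_sequence_realization():
    """Gene orders are identical whether or not sequences are generated."""
    cfg = pair_config([WgdEvent("E", 30.0, 2, retained_fraction=0.8)],
                      seed=4, n_chromosomes=2, genes_per_chromosome=60)
    a = simulate_dataset(cfg, sequences=False)
    b = simulate_dataset(cfg, sequences=True)
    pd.testing.assert_frame_equal(a.truth.genes, b.truth.genes)
    cds = realize_sequences(a)
    assert cds == b.cds


def test_conservation_of_gene_counts():
    """Retained + deleted genes equal the pre-loss copy number."""
    cfg = pair_config([WgdEvent("E", 30.0, 2, retained_fraction=0.7, p_loss=0.3)],
                      seed=5, n_chromosomes=2, genes_per_chromosome=200)
    ds = simulate_gene_orders(cfg)
    n_pre = 2 * 400
    deleted = ds.truth.run_lengths.query("genome == 'W'")["deleted"].sum()
    assert len(ds.annotations["W"]) + deleted == n_pre


def test_deletion_run_mean_matches_geometric_parameter():
    """Law of large numbers: mean requested run length -> 1/p within 10%."""
    cfg = pair_config([WgdEvent("E", 30.0, 2, retained_fraction=0.65, p_loss=0.3)],
                      seed=6, n_chromosomes=4, genes_per_chromosome=2500)
    ds = simulate_gene_orders(cfg)
    req = ds.truth.run_lengths["requested"].to_numpy()
    assert len(req) >= 2000
    assert abs(req.mean() - 1 / 0.3) / (1 / 0.3) < 0.10


def test_keep_one_copy_infeasible_raises():
    cfg = pair_config([WgdEvent("E", 30.0, 2, retained_fraction=0.3)],
                      seed=7, n_chromosomes=1, genes_per_chromosome=50)
    with pytest.raises(ConfigError):
        simulate_gene_orders(cfg)


def test_clock_uniform_rates_give_expected_ks_peaks():
    """With all rates 1 the expected duplicate Ks is 2 * r_ref * age."""
    cfg = pair_config([WgdEvent("E", 30.0, 2)], seed=8,
                      n_chromosomes=1, genes_per_chromosome=30)
    ds = simulate_gene_orders(cfg)
    peak = ds.truth.true_peaks.query("genome == 'W' and event == 'E'")
    assert peak["expected_ks"].iloc[0] == pytest.approx(2 * cfg.r_ref * 30.0)


def test_zero_branch_length_keeps_sequence():
    rng = np.random.default_rng(0)
    seq = random_cds(100, rng)
    out = evolve_codons(seq, 0.0, 0.2, rng)
    assert np.array_equal(seq, out)


def test_sequence_divergence_consistency_small():
    """Pairs evolved to target Ks=0.3 recover it in the Nei-Gojobori mean."""
    rng = np.random.default_rng(12)
    est = []
    for _ in range(60):
        anc = random_cds(300, rng)
        a = evolve_codons(anc, 0.15, 0.2, rng)
        b = evolve_codons(anc, 0.15, 0.2, rng)
        est.append(ksmod.nei_gojobori(a, b).Ks)
    assert np.mean(est) == pytest.approx(0.3, rel=0.06)


def test_expression_delta_one_is_balanced(double_wgd_clean):
    ds = double_wgd_clean
    ds.config.expression = replace(ds.config.expression, genome="W",
                                   sigma_copy=0.0, delta=1.0)
    m = simulate_expression(ds)
    truth = ds.truth.expression_truth
    dom = truth["dominant_genes"]
    vals = np.log2(m.condition_means() + 1.0)
    genes = ds.truth.copies("W")
    by_anc = {}
    for g, anc, path in zip(genes["gene_id"], genes["anc_id"], genes["path"]):
        by_anc.setdefault((anc, path.rsplit("|", 1)[0]), []).append(g)
    ratios = []
    for (_anc, _pre), pair in by_anc.items():
        if len(pair) == 2:
            hi = [g for g in pair if g in dom]
            lo = [g for g in pair if g not in dom]
            if len(hi) == 1 and len(lo) == 1:
                ratios.append(vals.loc[hi[0]].mean() - vals.loc[lo[0]].mean())
    assert abs(np.mean(ratios)) < 0.05


def test_expression_delta_two_low_noise_ratio_one(double_wgd_clean):
    ds = double_wgd_clean
    ds.config.expression = replace(ds.config.expression, genome="W", delta=2.0,
                                   sigma_copy=0.0, sigma_replicate=1e-6)
    m = simulate_expression(ds)
    truth = ds.truth.expression_truth
    genes = ds.truth.copies("W")
    dom = truth["dominant_genes"]
    means = m.condition_means()
    by_key = {}
    for g, anc, path in zip(genes["gene_id"], genes["anc_id"], genes["path"]):
        by_key.setdefault((anc, path.rsplit("|", 1)[0]), []).append(g)
    checked = 0
    for pair in by_key.values():
        hi = [g for g in pair if g in dom]
        lo = [g for g in pair if g not in dom]
        if len(hi) == 1 and len(lo) == 1:
            ratio = np.log2(means.loc[hi[0]].to_numpy() / means.loc[lo[0]].to_numpy())
            assert np.allclose(ratio, 1.0, atol=1e-3)
            checked += 1
    assert checked > 100


def test_expression_planted_zero_rows(double_wgd_clean):
    ds = double_wgd_clean
    ds.config.expression = replace(ds.config.expression, genome="W", zero_fraction=0.1)
    m = simulate_expression(ds)
    silent_anc = ds.truth.expression_truth["silent_anc"]
    genes = ds.truth.copies("W")
    zero_rows = set(m.values.index[(m.values == 0).all(axis=1)])
    expected = {g for g, anc in zip(genes["gene_id"], genes["anc_id"]) if anc in silent_anc}
    assert zero_rows == expected


def test_invalid_configs_rejected():
    with pytest.raises(ConfigError):
        WgdEvent("bad", 10.0, multiplicity=4)
    with pytest.raises(ConfigError):
        WgdEvent("bad", 10.0, retained_fraction=0.0)
    cfg = pair_config([], seed=0)
    cfg.expression = replace(cfg.expression, delta=-1.0)
    with pytest.raises(ConfigError):
        cfg.validate()


def test_five_genome_truth_peaks_reflect_branch_rates():
    cfg = five_genome_config(seed=1, n_chromosomes=1, genes_per_chromosome=20)
    ds = simulate_gene_orders(cfg)
    peaks = ds.truth.true_peaks.set_index(["genome", "event"])["expected_ks"]
    # V is the clock reference: ECH at 2 * r_ref * 130
    assert peaks.loc[("V", "ECH")] == pytest.approx(2 * cfg.r_ref * 130.0)
    # the fast carrot-like lineage shows an older apparent ECH than V
    assert peaks.loc[("D", "ECH")] > peaks.loc[("V", "ECH")]
    # nested events are ordered alpha < beta < ECH within each lineage
    for g in ("D", "X"):
        assert peaks.loc[(g, "A-alpha")] < peaks.loc[(g, "A-beta")] < peaks.loc[(g, "ECH")]
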