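import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

from wgdkit import event_table as etab
from wgdkit import fractionation as frac
from wgdkit.pipeline import event_table_analysis
from wgdkit.simulate import WgdEvent, pair_config, simulate_dataset
from tests.conftest import toy_annotation


def _table_from_pattern(pattern, coverage=None):
    """Build a one-column event table from a presence pattern."""
    n = len(pattern)
    ref = toy_annotation("R", [(f"r{i}", "c1", 100 * i + 1, 100 * i + 50)
                               for i in range(n)])
    core = {"T": [{f"r{i}": f"t{i}" for i, p in enumerate(pattern) if p}]}
    schema = etab.TableSchema("R", 1, [etab.GenomeSpec("T", 1, etab.hierarchy(0))])
    cov = {"T": {0: coverage if coverage is not None else [("c1", 0, n - 1)]}}
    return etab.EventTable(schema=schema, reference_genes=ref.genes[
        ["gene_id", "chromosome", "order_index"]], core=core, paralogs=[],
        coverage=cov)


def test_run_extraction_patterns():
    runs = frac.extract_runs(_table_from_pattern([1, 1, 0, 0, 0, 1]), "T")
    assert runs.lengths == [3]
    runs = frac.extract_runs(_table_from_pattern([1, 1, 1, 1]), "T")
    assert runs.lengths == [] and runs.truncated == []
    runs = frac.extract_runs(_table_from_pattern([1, 0, 0, 1, 0, 0, 0, 0, 0, 1]), "T")
    assert runs.lengths == [2, 5]


def test_boundary_truncated_runs_flagged():
    runs = frac.extract_runs(_table_from_pattern([0, 0, 1, 1, 0]), "T")
    assert runs.lengths == []
    assert sorted(runs.truncated) == [1, 2]


def test_runs_outside_coverage_ignored():
    # coverage only spans genes 0..3: the trailing missing genes do not count
    runs = frac.extract_runs(
        _table_from_pattern([1, 0, 0, 1, 0, 0], coverage=[("c1", 0, 3)]), "T")
    assert runs.lengths == [2]


def test_geometric_mle_is_reciprocal_mean():
    fit = frac.fit_geometric([2, 2, 2], min_runs=1)
    assert fit.p_hat == pytest.approx(0.5)
    assert fit.model_fraction_lt10 == pytest.approx(1 - 0.5**9)


def test_geometric_model_fraction_closed_form():
    rng = np.random.default_rng(0)
    fit = frac.fit_geometric(rng.geometric(0.3, 500).tolist())
    assert fit.model_fraction_lt10 == pytest.approx(1 - (1 - fit.p_hat) ** 9)


def test_geometric_recovery_from_simulated_runs():
    rng = np.random.default_rng(1)
    fit = frac.fit_geometric(rng.geometric(0.3, 2000).tolist())
    assert 0.27 <= fit.p_hat <= 0.33
    assert fit.chi2_pvalue > 1e-4  # data generated from the fitted family


def test_insufficient_runs_error():
    with pytest.raises(frac.InsufficientRunsError):
        frac.fit_geometric([2, 3, 4])


def test_run_conservation_against_truth():
    """Extracted missing positions + retained genes = covered positions."""
    cfg = pair_config([WgdEvent("E", 40.0, 2, retained_fraction=0.8, p_loss=0.3)],
                      seed=33, n_chromosomes=2, genes_per_chromosome=400)
    ds = simulate_dataset(cfg)
    schema = etab.TableSchema("O", 1, [etab.GenomeSpec("W", 2, etab.hierarchy(("E", 0, 1)))])
    table = event_table_analysis(ds, reference="O", schema=schema)
    runs = frac.extract_runs(table, "W")
    presence = table.row_presence("W")
    covered = missing = 0
    ref = table.reference_genes
    for s in range(2):
        for chrom, sub in ref.groupby("chromosome", sort=False):
            ivs = frac._merge_intervals([(lo, hi) for c, lo, hi in table.coverage["W"][s]
                                         if c == chrom])
            for lo, hi in ivs:
                sel = sub[(sub["order_index"] >= lo) & (sub["order_index"] <= hi)]
                covered += len(sel)
                missing += int((~presence[sel.index, s]).sum())
    assert sum(runs.lengths) + sum(runs.truncated) == missing
    assert missing <= covered


def test_retention_profile_hand_instance():
    table = _table_from_pattern([1, 0, 0, 1, 1, 0, 1, 1, 1, 1])
    prof = frac.retention_profile(table, "T", window=5, step=5)["profile"]
    assert list(prof["retention"]) == [pytest.approx(0.6), pytest.approx(0.8)]


def test_retention_profile_window_too_large():
    table = _table_from_pattern([1, 1, 1])
    with pytest.raises(ValueError):
        frac.retention_profile(table, "T", window=10)


def test_planted_biased_loss_detected_by_sign_test():
    """One subgenome losing far more genes yields a significant sign test."""
    rng = np.random.default_rng(2)
    n = 2000
    ref = toy_annotation("R", [(f"r{i}", "c1", 100 * i + 1, 100 * i + 50)
                               for i in range(n)])
    keep_a = rng.random(n) > 0.10
    keep_b = rng.random(n) > 0.35
    core = {"T": [{f"r{i}": f"a{i}" for i in range(n) if keep_a[i]},
                  {f"r{i}": f"b{i}" for i in range(n) if keep_b[i]}]}
    schema = etab.TableSchema("R", 1, [etab.GenomeSpec("T", 2, etab.hierarchy(("E", 0, 1)))])
    table = etab.EventTable(schema=schema, reference_genes=ref.genes[
        ["gene_id", "chromosome", "order_index"]], core=core, paralogs=[],
        coverage={"T": {0: [("c1", 0, n - 1)], 1: [("c1", 0, n - 1)]}})
    res = frac.retention_profile(table, "T")
    tests = res["tests"]
    assert len(tests) == 1
    assert tests["p_value"].iloc[0] < 0.01
    assert tests["n_a_higher"].iloc[0] > tests["n_b_higher"].iloc[0]
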