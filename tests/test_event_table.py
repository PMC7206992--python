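import numpy as np
import pandas as pd
import pytest

from wgdkit import event_table as etab
from wgdkit.collinearity import AnchorPair, ColinearBlock
from wgdkit.pipeline import event_table_analysis
from tests.conftest import toy_annotation


def test_paper_schema_has_39_columns():
    """Triplicated reference plus multiplicities 1, 3, 4, 4 -> 39 columns."""
    schema = etab.paper_schema()
    assert schema.total_columns == 39


@pytest.mark.parametrize("m_ref,mults,expected", [
    (1, [2], 3),
    (1, [4], 5),
    (3, [1, 3, 4, 4], 39),
    (2, [1, 1], 6),
])
def test_column_count_formula(m_ref, mults, expected):
    specs = []
    for i, m in enumerate(mults):
        if m == 1:
            h = etab.hierarchy(0)
        elif m == 2:
            h = etab.hierarchy(("E", 0, 1))
        elif m == 3:
            h = etab.hierarchy(("E", 0, 1, 2))
        else:
            h = etab.hierarchy(("E1", ("E2", 0, 1), ("E2", 2, 3)))
        specs.append(etab.GenomeSpec(f"g{i}", m, h))
    schema = etab.TableSchema("R", m_ref, specs)
    assert schema.total_columns == expected


def _hand_table():
    """5 reference genes; one target region covering genes 0-2."""
    ref = toy_annotation("R", [(f"r{i}", "c1", 100 * i + 1, 100 * i + 50)
                               for i in range(5)])
    anchors = [AnchorPair(f"r{i}", f"t{i}", i, i, 10.0) for i in range(3)]
    blk = ColinearBlock("R", "T", "c1", "tc1", anchors, "same", 30.0)
    schema = etab.TableSchema("R", 1, [etab.GenomeSpec("T", 2, etab.hierarchy(("E", 0, 1)))])
    table = etab.build_event_table(schema, ref, {"T": [blk]})
    return table


def test_hand_built_table_fill():
    table = _hand_table()
    col0 = table.core["T"][0]
    assert col0 == {"r0": "t0", "r1": "t1", "r2": "t2"}
    assert table.core["T"][1] == {}
    frame = table.to_frame()
    assert frame.shape[1] == 3
    assert frame.loc["r3", "R|T.0"] is None or pd.isna(frame.loc["r3", "R|T.0"])


def test_table_tsv_uses_dot_for_missing(tmp_path):
    table = _hand_table()
    p = tmp_path / "table.tsv"
    etab.table_to_tsv(table, p)
    lines = p.read_text().splitlines()
    assert any("\t." in l for l in lines[1:])


def test_zero_loss_table_has_no_missing_cells(double_wgd_clean, double_wgd_schema):
    table = event_table_analysis(double_wgd_clean, reference="O",
                                 schema=double_wgd_schema)
    presence = table.row_presence("W")
    assert presence.all()
    assert table.n_columns == 5


def test_retention_percentages_sum_to_100(clade_small):
    schema = etab.paper_schema()
    table = event_table_analysis(clade_small, reference="V", schema=schema)
    assert table.n_columns == 39
    stats = etab.retention_stats(table)
    sums = stats.groupby("genome")["percent"].sum()
    assert np.allclose(sums, 100.0, atol=1e-9)


def test_overflow_layers_raises():
    ref = toy_annotation("R", [(f"r{i}", "c1", 100 * i + 1, 100 * i + 50)
                               for i in range(10)])
    blocks = []
    for k in range(3):  # three mutually overlapping regions, multiplicity 2
        anchors = [AnchorPair(f"r{i}", f"t{k}_{i}", i, i, 1.0) for i in range(8)]
        blocks.append(ColinearBlock("R", "T", "c1", f"tc{k}", anchors, "same", 8.0))
    schema = etab.TableSchema("R", 1, [etab.GenomeSpec("T", 2, etab.hierarchy(("E", 0, 1)))])
    with pytest.raises(etab.OverflowLayerError, match="c1"):
        etab.build_event_table(schema, ref, {"T": blocks})


def test_dollo_loss_epoch_rules():
    """Presence patterns map to the documented epochs."""
    ref = toy_annotation("R", [("r0", "c1", 1, 50)])
    schema = etab.TableSchema("R", 1, [etab.GenomeSpec(
        "T", 4, etab.hierarchy(("A-beta", ("A-alpha", 0, 1), ("A-alpha", 2, 3))))])

    def classify(pattern):
        core = {"T": [dict() if not p else {"r0": f"t{s}"}
                      for s, p in enumerate(pattern)]}
        table = etab.EventTable(schema=schema, reference_genes=ref.genes[
            ["gene_id", "chromosome", "order_index"]], core=core, paralogs=[],
            coverage={"T": {s: [("c1", 0, 0)] for s in range(4)}})
        return etab.classify_loss_epochs(table, "T")["events"]

    assert classify([True, True, True, True]) == {}
    assert classify([True, False, True, True]) == {"after_A-alpha": 1}
    assert classify([False, False, True, False]) == {
        "between_A-beta_and_A-alpha": 1, "after_A-alpha": 1}
    assert classify([False, False, False, False]) == {"before_A-beta": 1}


def test_zero_loss_simulation_reports_zero_loss_events(double_wgd_clean, double_wgd_schema):
    table = event_table_analysis(double_wgd_clean, reference="O",
                                 schema=double_wgd_schema)
    loss = etab.classify_loss_epochs(table, "W")
    assert loss["events"] == {}


def test_homology_circles_deterministic(tmp_path, double_wgd_clean, double_wgd_schema):
    table = event_table_analysis(double_wgd_clean, reference="O",
                                 schema=double_wgd_schema)
    p1, p2 = tmp_path / "c1.svg", tmp_path / "c2.svg"
    etab.render_homology_circles(table, p1)
    etab.render_homology_circles(table, p2)
    assert p1.read_bytes() == p2.read_bytes()
    assert b"circles" in p1.read_bytes()
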