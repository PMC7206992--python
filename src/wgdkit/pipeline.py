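"""End-to-end analysis flows and the declarative pipeline driver.

The building blocks here (colinearity -> Ks -> peaks -> correction ->
dating -> tables -> fractionation -> expression) are plain functions over
the library types, used both by the command-line interface and directly in
scripts; :func:`run_pipeline` executes them in dependency order on a
simulated dataset and writes TSVs, figures and a manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd
import yaml

from . import collinearity as col
from . import event_table as etab
from . import expression as expr
from . import fractionation as frac
from . import io_formats as io
from . import ks as ksmod
from . import peaks as pk
from . import rates
from .simulate import (SimulatedDataset, five_genome_config,
                       homology_for, simulate_dataset, simulate_expression)

logger = logging.getLogger("wgdkit")


# ---------------------------------------------------------------------------
# analysis building blocks
# ---------------------------------------------------------------------------

def blocks_and_ks(dataset: SimulatedDataset, genome_a: str,
                  genome_b: Optional[str] = None, gap_limit: int = col.GAP_LIMIT,
                  min_anchors: int = col.MIN_ANCHORS,
                  max_family_size: int = col.MAX_FAMILY_SIZE,
                  with_ks: bool = True) -> tuple[list, Optional[pd.DataFrame]]:
    """Homology -> family filter -> chained blocks (-> anchor Ks) for one
    genome pair of a simulated dataset."""
    hom = homology_for(dataset, genome_a, genome_b)
    hom = col.filter_families(hom, max_family_size)
    ann_a = dataset.annotations[genome_a]
    ann_b = None if genome_b in (None, genome_a) else dataset.annotations[genome_b]
    blocks = col.chain_blocks(hom, ann_a, ann_b, gap_limit, min_anchors)
    etab.label_blocks_from_homology(blocks, hom)
    ks_df = None
    if with_ks:
        if dataset.cds is None:
            raise ValueError("dataset has no sequences; run realize_sequences first")
        cds = dict(dataset.cds[genome_a])
        if genome_b not in (None, genome_a):
            cds.update(dataset.cds[genome_b])
        pairs = [(a.gene_a, a.gene_b) for b in blocks for a in b.anchors]
        ks_df = ksmod.ks_table(cds, pairs)
        ksmod.block_ks_median(blocks, ks_df)
    return blocks, ks_df


@dataclass
class DatingResult:
    assignments: dict          # lineage -> {event: component} (uncorrected)
    lambdas: dict              # lineage -> final multiplicative correction
    corrected: dict            # lineage -> {event: component} (corrected)
    dates: rates.CalibratedDates
    samples: dict              # lineage -> Ks array used


def dating_analysis(dataset: SimulatedDataset, reference: str = "V",
                    lineages: Sequence[str] = ("X", "D"),
                    events: Mapping[str, Sequence[str]] = None,
                    shared_event: str = "ECH", later_event: str = "A-alpha",
                    anchor_event: str = "ECH", anchor_age: float = 130.0,
                    bandwidth: float = pk.DEFAULT_BANDWIDTH,
                    window: tuple = pk.DEFAULT_WINDOW) -> DatingResult:
    """Full shared-event rate correction and dating on self-Ks samples.

    For each lineage the self (paralog) Ks sample is decomposed into the
    expected event peaks; each lineage is aligned to the reference on the
    shared oldest event; the faster of the first two lineages is re-aligned
    on the later shared event with the slower as reference; corrected peaks
    are dated through the anchored event age.
    """
    if events is None:
        events = {reference: ["ECH"],
                  **{l: ["A-alpha", "A-beta", "ECH"] for l in lineages}}
    samples = {}
    assignments = {}
    for genome in [reference, *lineages]:
        _blocks, ks_df = blocks_and_ks(dataset, genome)
        ok = ks_df[ks_df["status"] == "ok"]["Ks"].to_numpy()
        samples[genome] = ok
        curve = pk.kde_density(ok, bandwidth=bandwidth, window=window)
        expected = events[genome]
        if len(expected) == 1:
            # a single skewed peak may need a minor tail component; the
            # principal component represents the event
            fit = pk.fit_mixture(curve)
            assignments[genome] = {expected[0]: fit.principal}
        else:
            fit = pk.fit_mixture(curve, n_components=len(expected))
            assignments[genome] = pk.assign_events(fit, expected)

    lambdas = {reference: 1.0}
    corrected = {reference: rates.corrected_assignment(assignments[reference], 1.0)}
    for lin in lineages:
        rf = rates.estimate_rate_factor(assignments[lin], assignments[reference],
                                        shared_event, lineage=lin, reference=reference)
        lambdas[lin] = rf.value
        corrected[lin] = rates.corrected_assignment(assignments[lin], rf.value)

    if len(lineages) >= 2 and later_event is not None:
        a, b = lineages[0], lineages[1]
        # the slower lineage (larger lambda) becomes the second-stage reference
        slow, fast = (a, b) if lambdas[a] >= lambdas[b] else (b, a)
        lam = rates.recorrect_pair(corrected[slow], corrected[fast], later_event,
                                   lambdas[fast], lineage_fast=fast)
        lambdas[fast] = lam
        corrected[fast] = rates.corrected_assignment(assignments[fast], lam)

    dating_lineage = lineages[0] if lineages else reference
    dates = rates.date_events(corrected[dating_lineage], anchor_event=anchor_event,
                              anchor_age=anchor_age)
    return DatingResult(assignments=assignments, lambdas=lambdas,
                        corrected=corrected, dates=dates, samples=samples)


def event_table_analysis(dataset: SimulatedDataset, reference: str = "V",
                         schema: Optional[etab.TableSchema] = None,
                         pair_ks: Optional[Mapping] = None,
                         gap_limit: int = col.GAP_LIMIT,
                         min_anchors: int = col.MIN_ANCHORS) -> etab.EventTable:
    """Build the reference-anchored event table from chained blocks.

    Blocks are labelled with their divergence event from the homology table
    (simulated data ships exact labels; on real data
    :func:`wgdkit.event_table.label_blocks_by_ks` fills the same field);
    ortholog layers are grouped into sibling pairs via ``pair_ks`` when the
    schema nests two events.
    """
    if schema is None:
        schema = etab.paper_schema()
    blocks_by_genome = {}
    for spec in schema.genomes:
        blocks, _ = blocks_and_ks(dataset, reference, spec.genome, gap_limit,
                                  min_anchors, with_ks=False)
        blocks_by_genome[spec.genome] = blocks
    ref_self = []
    if schema.m_ref > 1:
        ref_self, _ = blocks_and_ks(dataset, reference, None, gap_limit,
                                    min_anchors, with_ks=False)
    if pair_ks is None:
        pair_ks = truth_pair_ages(dataset, [g.genome for g in schema.genomes])
    return etab.build_event_table(schema, dataset.annotations[reference],
                                  blocks_by_genome, ref_self,
                                  reference_paralog_label=None, pair_ks=pair_ks)


def truth_pair_ages(dataset: SimulatedDataset, genomes: Sequence[str]) -> dict:
    """Within-genome gene-pair divergence ages from simulator homology,
    usable as the layer-pairing divergence measure when no sequences exist."""
    out: dict = {}
    for g in set(genomes):
        hom = homology_for(dataset, g)
        for q, s, age in zip(hom.pairs["query"], hom.pairs["subject"], hom.pairs["age"]):
            out[(q, s)] = age
    return out


# ---------------------------------------------------------------------------
# pipeline configuration
# ---------------------------------------------------------------------------

DEFAULTS = {
    "seed": 0,
    "outdir": "wgdkit_run",
    "simulate": {"leaves": ["V", "C", "L", "D", "X"], "n_chromosomes": 4,
                 "genes_per_chromosome": 800, "sequences": True},
    "collinearity": {"gap_limit": 50, "min_anchors": 5, "max_family_size": 30,
                     "proximal_window": 10},
    "peaks": {"bandwidth": 0.05, "r2_threshold": 0.95, "window": [0.0, 3.0]},
    "dating": {"reference": "V", "lineages": ["X", "D"], "shared_event": "ECH",
               "later_event": "A-alpha", "anchor_event": "ECH", "anchor_age": 130.0},
    "fractionation": {"window": 30, "step": 5},
    "expression": {"genome": "X", "fold_threshold": 2.0},
    "stages": ["simulate", "collinearity", "ks", "peaks", "table",
               "fractionate", "expression"],
}


class ConfigValidationError(ValueError):
    def __init__(self, errors: Sequence[str]):
        super().__init__("; ".join(errors))
        self.errors = list(errors)


def validate_config(path_or_mapping) -> dict:
    """Load and normalize a pipeline config; all problems reported at once,
    unknown keys warn instead of failing."""
    if isinstance(path_or_mapping, (str, Path)):
        with open(path_or_mapping) as fh:
            raw = yaml.safe_load(fh) or {}
    else:
        raw = dict(path_or_mapping or {})
    cfg = json.loads(json.dumps(DEFAULTS))  # deep copy
    errors: list[str] = []
    for key, value in raw.items():
        if key not in cfg:
            logger.warning("unknown config key %r ignored", key)
            continue
        if isinstance(cfg[key], dict):
            if not isinstance(value, dict):
                errors.append(f"{key}: expected a mapping")
                continue
            for k2, v2 in value.items():
                if k2 not in cfg[key]:
                    logger.warning("unknown config key %s.%s ignored", key, k2)
                    continue
                cfg[key][k2] = v2
        else:
            cfg[key] = value
    if cfg["peaks"]["bandwidth"] <= 0:
        errors.append("peaks.bandwidth: must be positive")
    if not 0 < cfg["peaks"]["r2_threshold"] <= 1:
        errors.append("peaks.r2_threshold: must be in (0, 1]")
    if cfg["collinearity"]["gap_limit"] < 0:
        errors.append("collinearity.gap_limit: must be >= 0")
    if cfg["expression"]["fold_threshold"] <= 1:
        errors.append("expression.fold_threshold: must exceed 1")
    if errors:
        raise ConfigValidationError(errors)
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: Mapping) -> dict:
    """Execute the configured stages on a simulated dataset; returns the
    manifest (also written to ``<outdir>/manifest.json``)."""
    cfg = validate_config(config)
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"parameters": cfg, "seed": cfg["seed"], "stages": {}}
    t_all = time.time()

    sim = cfg["simulate"]
    hist = five_genome_config(seed=cfg["seed"], leaves=tuple(sim["leaves"]),
                              n_chromosomes=sim["n_chromosomes"],
                              genes_per_chromosome=sim["genes_per_chromosome"])
    t0 = time.time()
    dataset = simulate_dataset(hist, sequences=sim["sequences"])
    manifest["stages"]["simulate"] = {
        "seconds": round(time.time() - t0, 2),
        "genomes": {g: len(a) for g, a in dataset.annotations.items()},
    }
    ref = cfg["dating"]["reference"]
    lineages = [l for l in cfg["dating"]["lineages"] if l in dataset.annotations]

    summary_tables: dict[str, pd.DataFrame] = {}

    if "ks" in cfg["stages"] and sim["sequences"]:
        t0 = time.time()
        dres = dating_analysis(
            dataset, reference=ref, lineages=lineages,
            shared_event=cfg["dating"]["shared_event"],
            later_event=cfg["dating"]["later_event"],
            anchor_event=cfg["dating"]["anchor_event"],
            anchor_age=cfg["dating"]["anchor_age"],
            bandwidth=cfg["peaks"]["bandwidth"],
            window=tuple(cfg["peaks"]["window"]))
        summary_tables["dates"] = dres.dates.table
        peak_rows = []
        for lin, assignment in dres.corrected.items():
            for ev, c in assignment.items():
                peak_rows.append({"lineage": lin, "event": ev, "mu_corrected": c.mean,
                                  "sd_corrected": c.sd, "lambda": dres.lambdas[lin]})
        summary_tables["corrected_peaks"] = pd.DataFrame(peak_rows)
        manifest["stages"]["dating"] = {
            "seconds": round(time.time() - t0, 2),
            "lambdas": {k: round(v, 4) for k, v in dres.lambdas.items()},
            "dates": {row["event"]: round(row["date"], 2)
                      for _i, row in dres.dates.table.iterrows()},
        }

    if "table" in cfg["stages"]:
        t0 = time.time()
        schema = etab.paper_schema()
        schema.genomes = [g for g in schema.genomes if g.genome in dataset.annotations]
        table = event_table_analysis(dataset, reference=ref, schema=schema,
                                     gap_limit=cfg["collinearity"]["gap_limit"],
                                     min_anchors=cfg["collinearity"]["min_anchors"])
        etab.table_to_tsv(table, outdir / "event_table.tsv")
        summary_tables["retention"] = etab.retention_stats(table)
        loss = {g.genome: etab.classify_loss_epochs(table, g.genome)
                for g in schema.genomes}
        summary_tables["loss_epochs"] = pd.DataFrame(
            [{"genome": g, "epoch": e, "events": n,
              "missing_cells": loss[g]["missing_cells"].get(e, 0)}
             for g in loss for e, n in sorted(loss[g]["events"].items())])
        manifest["stages"]["table"] = {"seconds": round(time.time() - t0, 2),
                                       "columns": table.n_columns}

        if "fractionate" in cfg["stages"]:
            t0 = time.time()
            frac_rows = []
            for g in schema.genomes:
                runs = frac.extract_runs(table, g.genome)
                row = {"genome": g.genome, "n_runs": len(runs.lengths)}
                if len(runs.lengths) >= 30:
                    fit = frac.fit_geometric(runs)
                    row.update({"p_hat": fit.p_hat, "se": fit.se,
                                "fraction_lt10": fit.observed_fraction_lt10,
                                "model_fraction_lt10": fit.model_fraction_lt10})
                frac_rows.append(row)
            summary_tables["fractionation"] = pd.DataFrame(frac_rows)
            manifest["stages"]["fractionate"] = {"seconds": round(time.time() - t0, 2)}

        if "expression" in cfg["stages"] and cfg["expression"]["genome"] in dataset.annotations:
            t0 = time.time()
            matrix = simulate_expression(dataset)
            pd_res = expr.pair_divergence(table, matrix, cfg["expression"]["genome"],
                                          cfg["expression"]["fold_threshold"])
            summary_tables["expression_divergence"] = pd_res["per_event"]
            summary_tables["dominance"] = expr.dominance_test(pd_res["pairs"])
            try:
                summary_tables["one_vs_two_copy"] = expr.one_vs_two_copy_test(
                    table, matrix, cfg["expression"]["genome"])
            except expr.InsufficientDataError as exc:
                logger.warning("one-vs-two-copy test skipped: %s", exc)
            manifest["stages"]["expression"] = {"seconds": round(time.time() - t0, 2)}

    paths = io.write_tables(summary_tables, outdir)
    manifest["outputs"] = {p.name: _sha256(p) for p in sorted(paths)}
    manifest["total_seconds"] = round(time.time() - t_all, 2)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
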