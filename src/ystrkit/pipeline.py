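"""End-to-end orchestration of a Y-STR population study.

``run_pipeline`` drives the study workflow over one configuration:
ingest (read a haplotype table or simulate one) -> DYS389II.I recoding ->
duplicated-allele filtering -> forensic summaries (optionally against a kit
subset) -> population distances (Rst matrix, AMOVA with permutation test)
-> MDS -> hierarchical clustering -> haplogroup prediction -> median-joining
network -> machine-readable report.

Every number in the report is produced by exactly one module operation; the
report stores full precision and rounds only at render time.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from ystrkit import __version__, forensic, io, mj_network, popdist
from ystrkit.coalsim import SimConfig, simulate_dataset
from ystrkit.datamodel import HaplotypeTable
from ystrkit.haplogroup import batch_predict, load_frequency_table, microvariant_crosstab
from ystrkit.panels import get_panel

logger = logging.getLogger(__name__)

DEFAULT_STEPS = ("filter", "stats")
KNOWN_STEPS = ("recode_dys389", "filter", "stats", "distance", "mds", "cluster",
               "predict", "network")


@dataclass
class PipelineConfig:
    """Declarative configuration of one pipeline run."""

    input: str | None = None  # haplotype table path; mutually exclusive with simulate
    simulate: dict | None = None  # SimConfig fields
    panel: str = "powerplex_y23"
    steps: tuple[str, ...] = DEFAULT_STEPS
    seed: int | None = None
    outdir: str = "."
    params: dict[str, Any] = field(default_factory=dict)  # per-step parameters

    def __post_init__(self) -> None:
        if (self.input is None) == (self.simulate is None):
            raise ValueError("configure exactly one of 'input' or 'simulate'")
        unknown = set(self.steps) - set(KNOWN_STEPS)
        if unknown:
            raise ValueError(f"unknown steps: {sorted(unknown)}")
        stochastic = {"distance"} & set(self.steps)
        perms = self.params.get("distance", {}).get("permutations", 0)
        if (self.simulate is not None or (stochastic and perms)) and self.seed is None:
            raise ValueError("a seed is mandatory when any stochastic step is enabled")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(
            input=raw.get("input"),
            simulate=raw.get("simulate"),
            panel=raw.get("panel", "powerplex_y23"),
            steps=tuple(raw.get("steps", DEFAULT_STEPS)),
            seed=raw.get("seed"),
            outdir=raw.get("outdir", "."),
            params=raw.get("params", {}),
        )


def _ingest(config: PipelineConfig) -> HaplotypeTable:
    if config.input is not None:
        path = Path(config.input)
        if not path.exists():
            raise FileNotFoundError(f"input table not found: {path}")
        meta_cols = tuple(config.params.get("io", {}).get("metadata_cols", ()))
        panel = None if config.panel == "auto" else get_panel(config.panel)
        return io.read_haplotype_table(path, panel, metadata_cols=meta_cols)
    sim = dict(config.simulate or {})
    sim.setdefault("seed", config.seed)
    table, _truth = simulate_dataset(SimConfig.from_dict(sim))
    return table


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured steps in dependency order; returns the report.

    Mandatory-step failures (ingest) raise; optional-step failures are
    recorded as warnings in the report and the run continues.
    """
    report: dict[str, Any] = {
        "version": __version__,
        "config": {
            "input": config.input,
            "simulate": config.simulate,
            "panel": config.panel,
            "steps": list(config.steps),
            "seed": config.seed,
            "params": config.params,
        },
        "warnings": [],
        "steps": {},
    }
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table = _ingest(config)
    report["n_input_rows"] = len(table)

    def run_step(name: str, fn) -> None:
        if name not in config.steps:
            return
        t0 = time.perf_counter()
        try:
            report["steps"][name] = fn()
            logger.info("step %s: %.3fs", name, time.perf_counter() - t0)
        except Exception as exc:  # optional steps degrade to warnings
            report["warnings"].append(f"step {name} failed: {exc}")
            logger.warning("step %s failed: %s", name, exc)

    if "recode_dys389" in config.steps:
        table = io.recode_dys389(table)
        report["steps"]["recode_dys389"] = {"done": True}

    if "filter" in config.steps:
        table, filt = io.filter_duplicated_alleles(table)
        report["steps"]["filter"] = {
            "n_input": filt.n_input,
            "n_removed_duplicated": filt.n_removed_duplicated,
            "n_retained": filt.n_retained,
            "removed_ids": list(filt.removed_ids),
        }

    def stats_step():
        p = config.params.get("stats", {})
        out: dict[str, Any] = {"full": forensic.haplotype_summary(table).as_dict()}
        locus_div = forensic.locus_diversity_table(table)
        out["per_locus"] = {
            d.locus: {"GD": d.GD, "PIC": d.PIC, "MP": d.MP_locus, "n_alleles": d.n_alleles}
            for d in locus_div
        }
        subset = p.get("subset")
        if subset:
            loci = get_panel(config.panel).yfiler17_subset if subset == "yfiler17" else tuple(subset)
            _full, reduced = forensic.kit_comparison(table, loci)
            out["subset"] = {"loci": list(loci), **reduced.as_dict()}
        return out

    run_step("stats", stats_step)

    def distance_step():
        p = config.params.get("distance", {})
        metric = p.get("metric", "sum_squared_steps")
        dm = popdist.rst_matrix(table, metric=metric)
        dm.to_csv(outdir / "rst_matrix.csv")
        pim = popdist.pi_matrices(table, metric=metric)
        res = popdist.amova_rst(
            table,
            metric=metric,
            permutations=int(p.get("permutations", 0)),
            seed=config.seed,
        )
        return {
            "rst_matrix_csv": str(outdir / "rst_matrix.csv"),
            "labels": list(dm.labels),
            "rst_matrix": dm.values.tolist(),
            "pi_within": pim.PiX.tolist(),
            "pi_between": pim.PiXY.tolist(),
            "pi_corrected": pim.corrected.tolist(),
            "amova": {
                "sigma_among": res.sigma_among,
                "sigma_within": res.sigma_within,
                "rst": res.rst,
                "p_value": res.p_value,
            },
        }

    run_step("distance", distance_step)

    def mds_step():
        dist = report["steps"].get("distance")
        if dist is None:
            raise RuntimeError("mds requires the distance step")
        dm = popdist.DistanceMatrix(tuple(dist["labels"]), np.asarray(dist["rst_matrix"]))
        res = popdist.classical_mds(dm, dims=int(config.params.get("mds", {}).get("dims", 2)))
        coords = {lab: res.coordinates[i].tolist() for i, lab in enumerate(res.labels)}
        return {"coordinates": coords, "eigenvalues": res.eigenvalues.tolist(),
                "positive_mass_captured": res.positive_mass_captured}

    run_step("mds", mds_step)

    def cluster_step():
        dist = report["steps"].get("distance")
        if dist is None:
            raise RuntimeError("cluster requires the distance step")
        p = config.params.get("cluster", {})
        dm = popdist.DistanceMatrix(tuple(dist["labels"]), np.asarray(dist["rst_matrix"]))
        res = popdist.hierarchical_clusters(
            dm, linkage=p.get("linkage", "upgma"), k=int(p.get("k", 2))
        )
        (outdir / "dendrogram.nwk").write_text(res.to_newick() + "\n")
        return {"assignments": res.assignments, "newick": str(outdir / "dendrogram.nwk")}

    run_step("cluster", cluster_step)

    def predict_step():
        p = config.params.get("predict", {})
        if "frequency_table" not in p:
            raise RuntimeError("predict step needs params.predict.frequency_table")
        ft = load_frequency_table(p["frequency_table"], p.get("priors", "uniform"))
        thresholds = (float(p.get("min_prob", 85.0)), float(p.get("min_fitness", 15.0)))
        preds, tally = batch_predict(table, ft, thresholds)
        preds.to_csv(outdir / "predictions.csv", index=False)
        out = {
            "predictions_csv": str(outdir / "predictions.csv"),
            "tally": tally.to_dict(orient="records"),
        }
        locus = p.get("microvariant_locus")
        if locus:
            ct = microvariant_crosstab(table, locus, preds["Haplogroup"].tolist())
            out["microvariant_crosstab"] = ct.to_dict(orient="records")
        return out

    run_step("predict", predict_step)

    def network_step():
        p = config.params.get("network", {})
        reduced = mj_network.prepare_network_input(table, p.get("annotate_col"))
        net = mj_network.median_joining(reduced, epsilon=int(p.get("epsilon", 0)))
        mj_network.export_network(net, outdir / "network.graphml", "graphml")
        return {
            "graphml": str(outdir / "network.graphml"),
            "n_nodes": net.graph.number_of_nodes(),
            "n_median_vectors": net.n_medians,
            "n_edges": net.graph.number_of_edges(),
            "total_weight": net.total_weight(),
            "n_excluded_rows": len(reduced.excluded_ids),
        }

    run_step("network", network_step)

    (outdir / "report.json").write_text(json.dumps(report, indent=2, default=str))
    (outdir / "report.txt").write_text(render_report(report))
    return report


def render_report(report: dict) -> str:
    """Human-readable rendering (rounding applied only here)."""
    lines = [f"ystrkit {report['version']} pipeline report", ""]
    if report["warnings"]:
        lines.append("WARNINGS:")
        lines.extend(f"  - {w}" for w in report["warnings"])
        lines.append("")
    for step, body in report["steps"].items():
        lines.append(f"[{step}]")
        if step == "filter":
            lines.append(
                f"  {body['n_input']} rows in, {body['n_removed_duplicated']} duplicated-allele "
                f"haplotypes removed, {body['n_retained']} retained"
            )
        elif step == "stats":
            s = body["full"]
            lines.append(
                f"  n={s['n']}  distinct={s['h_distinct']}  HD={s['HD']:.6f}  "
                f"MP={s['MP']:.6f}  DC={s['DC_percent']:.1f}%"
            )
            if "subset" in body:
                r = body["subset"]
                lines.append(
                    f"  subset({len(r['loci'])} loci): distinct={r['h_distinct']}  "
                    f"HD={r['HD']:.6f}  DC={r['DC_percent']:.1f}%"
                )
        elif step == "distance":
            a = body["amova"]
            p = "" if a["p_value"] is None else f"  p={a['p_value']:.4f}"
            lines.append(f"  Rst={a['rst']:.5f}{p}")
        elif step == "predict":
            for row in body["tally"][:12]:
                lines.append(
                    f"  {row['Haplogroup']:>12}: {row['Count']:4d}  ({row['Percent']:.1f}%)"
                )
        elif step == "network":
            lines.append(
                f"  {body['n_nodes']} nodes ({body['n_median_vectors']} median vectors), "
                f"{body['n_edges']} edges, total weight {body['total_weight']}"
            )
        else:
            lines.append(f"  {body}")
        lines.append("")
    return "\n".join(lines)
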