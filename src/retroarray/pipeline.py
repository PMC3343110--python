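"""End-to-end orchestration: simulate / annotate / preprocess / DE /
population stats / contig assembly wired into one reproducible run.

A run is described by a YAML config (see ``retroarray/data/toy_scenario.yaml``
for the bundled example).  Stages execute in dependency order as pure
functions over files; a JSON run manifest recording the config hash, input
checksums, parameters, seed and per-stage outputs is written on success and
on failure.  Re-running a completed pipeline with unchanged config and
inputs is a no-op unless forced.

Exit statuses: 0 success, 2 missing input, 3 parameter validation failure,
1 any other stage failure.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import tempfile
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import pandas as pd
import yaml

from . import __version__, io as raio
from .annotate import Genome, align_probe, annotate_platform, annotation_summary
from .contigs import (
    assemble_contigs,
    cluster_recurrent_deletions,
    detect_deletions,
    find_ltr_flanked,
    match_probes_to_contigs,
    probe_class_counts,
)
from .diffexp import run_de, summarize_by_element
from .model import Parameters, percent
from .popstats import GroupSpec, compare_probe_populations, ma_table, population_tests_table
from .preprocess import (
    filter_absent_illumina,
    preprocess_affymetrix,
    preprocess_illumina,
    quantile_normalize,
)
from . import simulate as sim

logger = logging.getLogger("retroarray")

STATUS_OK = 0
STATUS_FAILED = 1
STATUS_MISSING_INPUT = 2
STATUS_BAD_PARAMS = 3


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_hash(config: dict) -> str:
    canonical = yaml.safe_dump(config, sort_keys=True).encode()
    return hashlib.sha256(canonical).hexdigest()


def _atomic_write_text(path: Path, text: str) -> None:
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=path.name)
    with os.fdopen(fd, "w") as fh:
        fh.write(text)
    os.replace(tmp, path)


class RunManifest:
    """Record of one pipeline run; serialised as JSON next to the outputs."""

    def __init__(self, config: dict, seed: int):
        self.data = {
            "version": __version__,
            "config_hash": _config_hash(config),
            "seed": seed,
            "parameters": {},
            "inputs": {},
            "outputs": {},
            "status": "running",
            "failed_stage": None,
        }

    def record_input(self, name: str, path: Path) -> None:
        self.data["inputs"][name] = {"path": str(path), "sha256": _sha256(path)}

    def record_output(self, stage: str, name: str, path: Path) -> None:
        self.data["outputs"].setdefault(stage, {})[name] = str(path)

    def write(self, path: Path) -> None:
        _atomic_write_text(path, json.dumps(self.data, indent=2, sort_keys=True) + "\n")


def _load_config(config_path) -> dict:
    with open(config_path) as fh:
        return yaml.safe_load(fh) or {}


def run_full(config_path, outdir=None, seed: Optional[int] = None, force: bool = False) -> int:
    """Execute every configured stage; returns the exit status.

    The manifest is written to ``<outdir>/manifest.json`` whether the run
    succeeds or fails.
    """
    try:
        config = _load_config(config_path)
    except FileNotFoundError:
        logger.error("config file not found: %s", config_path)
        return STATUS_MISSING_INPUT
    outdir = Path(outdir or config.get("outdir", "retroarray_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    if seed is not None:
        config["seed"] = int(seed)
    config.setdefault("seed", 0)

    manifest_path = outdir / "manifest.json"
    manifest = RunManifest(config, config["seed"])
    try:
        params = Parameters(**(config.get("parameters") or {}))
        manifest.data["parameters"] = dict(params.__dict__)
    except (TypeError, ValueError) as exc:
        logger.error("parameter validation failed: %s", exc)
        manifest.data["status"] = "failed"
        manifest.data["failed_stage"] = "parameters"
        manifest.write(manifest_path)
        return STATUS_BAD_PARAMS

    if not force and manifest_path.exists():
        try:
            previous = json.loads(manifest_path.read_text())
        except json.JSONDecodeError:
            previous = {}
        if (
            previous.get("status") == "success"
            and previous.get("config_hash") == manifest.data["config_hash"]
        ):
            logger.info("outputs up to date; skipping (use force to re-run)")
            return STATUS_OK

    stage = "resolve-inputs"
    try:
        # ------------------------------------------------------------------
        stage = "simulate"
        if "simulate" in config:
            block = config["simulate"]
            if block in (None, "default", {}):
                sim_config = sim.default_config(seed=config["seed"])
            else:
                block = dict(block)
                block.setdefault("seed", config["seed"])
                sim_config = sim.config_from_dict(block)
            dataset = sim.simulate_all(sim_config)
            simdir = outdir / "sim"
            paths = sim.write_dataset(dataset, simdir)
            for name, p in paths.items():
                manifest.record_output("simulate", name, p)
            inputs = {k: str(v) for k, v in paths.items()}
        else:
            inputs = dict(config.get("inputs") or {})

        for key in ("genome", "rmsk", "probes", "expression"):
            if key not in inputs or not Path(inputs[key]).exists():
                logger.error("missing input: %s", key)
                manifest.data["status"] = "failed"
                manifest.data["failed_stage"] = "resolve-inputs"
                manifest.write(manifest_path)
                return STATUS_MISSING_INPUT
            manifest.record_input(key, Path(inputs[key]))

        # ------------------------------------------------------------------
        stage = "annotate"
        platform = config.get("platform", "generic")
        chemistry = config.get("chemistry", "probe_complementary_to_transcript")
        genome = Genome(raio.read_fasta(inputs["genome"]))
        repeats = raio.read_rmsk_table(inputs["rmsk"], config.get("rmsk_dialect", "ucsc"))
        probes = raio.read_probe_table(inputs["probes"], platform)
        annotations = annotate_platform(probes, genome, repeats, params, chemistry)
        annot_path = outdir / "annot.tsv"
        raio.write_probe_annotation_table(
            annotations, annot_path, {p.probe_id: p.sequence for p in probes}
        )
        totals, per_class = annotation_summary(annotations)
        summary_path = outdir / "annot_summary.tsv"
        per_class.to_csv(summary_path, sep="\t", index=False)
        manifest.record_output("annotate", "annotations", annot_path)
        manifest.record_output("annotate", "summary", summary_path)

        # ------------------------------------------------------------------
        stage = "preprocess"
        route = config.get("preprocess", "log2_quantile")
        scale = "log2" if route == "log2_quantile" else "raw"
        matrix = raio.read_expression_table(
            inputs["expression"], scale=scale,
            detection_path=inputs.get("detection"),
            design_path=inputs.get("design"),
        )
        if route == "illumina":
            matrix = preprocess_illumina(matrix, params.log2_offset, params.detection_alpha)
        elif route == "affymetrix":
            matrix = preprocess_affymetrix(matrix)
        elif route == "log2_quantile":
            matrix = quantile_normalize(matrix)
            if matrix.detection is not None:
                matrix = filter_absent_illumina(matrix, params.detection_alpha)
        elif route != "none":
            raise ValueError(f"unknown preprocess route {route!r}")
        norm_path = outdir / "norm.tsv"
        raio.write_expression_table(matrix, norm_path)
        manifest.record_output("preprocess", "normalized", norm_path)

        # ------------------------------------------------------------------
        stage = "de"
        contrast = config.get("contrast") or {"case": "case", "control": "control"}
        prior, results = run_de(matrix, contrast["case"], contrast["control"], params)
        de_path = outdir / "de.tsv"
        results.to_csv(de_path, sep="\t", index_label="probe_id")
        table, de_totals = summarize_by_element(results, annotations)
        elements_path = outdir / "elements.tsv"
        table.to_csv(elements_path, sep="\t", index=False)
        totals_path = outdir / "de_totals.json"
        _atomic_write_text(totals_path, json.dumps(de_totals, indent=2) + "\n")
        manifest.record_output("de", "results", de_path)
        manifest.record_output("de", "element_summary", elements_path)
        manifest.record_output("de", "totals", totals_path)

        # ------------------------------------------------------------------
        stage = "population-stats"
        ma_path = outdir / "ma.tsv"
        ma_table(results).to_csv(ma_path, sep="\t")
        specs = [GroupSpec(**g) for g in config.get("groups", [])]
        tests = compare_probe_populations(results, annotations, specs)
        pop_path = outdir / "poptests.tsv"
        population_tests_table(tests).to_csv(pop_path, sep="\t", index=False)
        manifest.record_output("population-stats", "ma", ma_path)
        manifest.record_output("population-stats", "tests", pop_path)

        # ------------------------------------------------------------------
        stage = "assemble-contigs"
        contig_cfg = config.get("contigs")
        if contig_cfg:
            element = contig_cfg["element"]
            hits = [r for r in repeats if r.element == element]
            if not hits:
                raise ValueError(f"no repeat hits for element {element!r}")
            cons_length = hits[0].cons_length
            contigs = assemble_contigs(hits, cons_length, params)
            ltr_name = contig_cfg.get("ltr")
            if ltr_name:
                ltr_hits = [r for r in repeats if r.element == ltr_name]
                contigs = find_ltr_flanked(contigs, ltr_hits, params)
            deletions = [d for c in contigs for d in detect_deletions(c, params)]
            clusters = cluster_recurrent_deletions(deletions, len(contigs), params)
            up = set(results.index[results["call"] == "up"])
            unaffected = set(results.index[results["call"] == "unchanged"])
            placements = {
                p.probe_id: align_probe(p, genome, params.max_mismatches)
                for p in probes
                if p.probe_id in up or p.probe_id in unaffected
            }
            classes = match_probes_to_contigs(placements, contigs, up, unaffected)
            bed_path = outdir / "contigs.bed"
            with open(bed_path, "w") as fh:
                for c in contigs:
                    fh.write(
                        f"{c.chrom}\t{c.span_start}\t{c.span_end}\t{c.contig_id}"
                        f"\t{c.coverage_fraction:.4f}\t{c.strand}\n"
                    )
            cov_path = outdir / "coverage.tsv"
            pd.DataFrame(
                [
                    {
                        "contig_id": c.contig_id,
                        "n_segments": len(c.segments),
                        "coverage_fraction": c.coverage_fraction,
                        "full_length": c.coverage_fraction > params.full_length_fraction,
                        "ltr_flanked": c.ltr_flanked,
                        "covered": ";".join(f"{s}-{e}" for s, e in c.covered),
                    }
                    for c in contigs
                ]
            ).to_csv(cov_path, sep="\t", index=False)
            del_path = outdir / "deletions.tsv"
            pd.DataFrame(
                [
                    {
                        "contig_id": d.contig_id, "cons_start": d.cons_start,
                        "cons_end": d.cons_end, "terminal": d.terminal,
                    }
                    for d in deletions
                ]
            ).to_csv(del_path, sep="\t", index=False)
            clusters_path = outdir / "deletion_clusters.tsv"
            pd.DataFrame(
                [
                    {
                        "cons_start": cl.cons_start, "cons_end": cl.cons_end,
                        "n_contigs": cl.n_contigs, "fraction": cl.fraction,
                        "contig_ids": ";".join(cl.contig_ids),
                    }
                    for cl in clusters
                ]
            ).to_csv(clusters_path, sep="\t", index=False)
            classes_path = outdir / "contig_probe_classes.tsv"
            pd.DataFrame(
                [{"contig_id": c.contig_id, "probe_class": c.probe_class} for c in classes]
            ).to_csv(classes_path, sep="\t", index=False)
            for name, p in (
                ("bed", bed_path), ("coverage", cov_path), ("deletions", del_path),
                ("clusters", clusters_path), ("probe_classes", classes_path),
            ):
                manifest.record_output("assemble-contigs", name, p)

        # ------------------------------------------------------------------
        stage = "report"
        report = repeat_report({config.get("contrast_name", "contrast"): results}, annotations)
        report_path = outdir / "report.txt"
        _atomic_write_text(report_path, report)
        manifest.record_output("report", "report", report_path)

    except Exception as exc:  # record the failed stage, then report failure
        logger.exception("stage %s failed: %s", stage, exc)
        manifest.data["status"] = "failed"
        manifest.data["failed_stage"] = stage
        manifest.write(manifest_path)
        if isinstance(exc, FileNotFoundError):
            return STATUS_MISSING_INPUT
        return STATUS_FAILED

    manifest.data["status"] = "success"
    manifest.write(manifest_path)
    return STATUS_OK


def repeat_report(results_by_contrast: Dict[str, pd.DataFrame], annotations) -> str:
    """Human-readable per-element up/down summary across contrasts.

    An element is marked with an arrow when at least two of its expressed
    sense probes are called in that direction, a bracketed arrow when exactly
    one probe is, and '-' otherwise.  A trailing block reports the
    changed/expressed repeat probe fractions per contrast.
    """
    if not results_by_contrast:
        raise ValueError("no contrasts supplied")
    tables = {}
    totals = {}
    for name, results in results_by_contrast.items():
        tables[name], totals[name] = summarize_by_element(results, annotations)
    elements: List[Tuple[str, str, str]] = []
    seen = set()
    for table in tables.values():
        for _, row in table.iterrows():
            key = (row["class"], row["family"], row["element"])
            if key not in seen:
                seen.add(key)
                elements.append(key)
    elements.sort()
    contrasts = list(results_by_contrast)
    lines = ["element\tfamily\tclass\t" + "\t".join(contrasts)]
    for cls, family, element in elements:
        marks = []
        for name in contrasts:
            table = tables[name]
            row = table[table["element"] == element]
            if row.empty:
                marks.append("-")
                continue
            n_up = int(row["n_up"].iloc[0])
            n_down = int(row["n_down"].iloc[0])
            if n_up >= 2 and n_up > n_down:
                marks.append("up")
            elif n_down >= 2 and n_down > n_up:
                marks.append("down")
            elif n_up == 1 and n_down == 0:
                marks.append("(up)")
            elif n_down == 1 and n_up == 0:
                marks.append("(down)")
            else:
                marks.append("-")
        lines.append(f"{element}\t{family}\t{cls}\t" + "\t".join(marks))
    lines.append("")
    for name in contrasts:
        t = totals[name]
        lines.append(
            f"# {name}: {t['n_changed_repeat_probes']} "
            f"({t['pct_changed_repeat_probes']}%) of the "
            f"{t['n_expressed_repeat_probes']} expressed repeat probes changed"
        )
    return "\n".join(lines) + "\n"
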