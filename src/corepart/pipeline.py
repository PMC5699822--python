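"""End-to-end orchestration of the pipeline stages from one structured
configuration, with a deterministic manifest of produced artifacts."""

from __future__ import annotations

import difflib
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from . import alignments as al
from . import capture as cap
from . import simulate as sim
from . import treedist, treeqc
from .likelihood import nj_guide_tree
from .partition import CoreSpec, build_charsets, write_charset_definitions
from .scheme import greedy_scheme_search, exhaustive_scheme_search, write_scheme_report

logger = logging.getLogger(__name__)

STAGES = ("clean", "charsets", "model_select", "treeqc", "treedist", "capture")

_DEFAULTS: dict[str, Any] = {
    "seed": 0,
    "output_dir": "corepart_out",
    "log_level": "INFO",
    "loci_dir": None,
    "trees_dir": None,
    "specimen_table": None,
    "simulate_preset": None,          # e.g. "weevil-like"
    "n_taxa": 8,
    "n_loci": 6,
    "stages": list(STAGES),
    "core_length": 160,
    "n_flank_bins": 5,
    "min_completeness": 0.70,
    "criterion": "aicc",
    "search": "greedy",
    "drop_quantile": 0.10,
    "saturation_multiplier": 1.5,
    "burnin": 0.25,
    "asdsf_min_freq": 0.10,
    "sequencing_year": None,
    "posterior_samples": 20,
    "posterior_perturbation": 0.1,
}


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    values: dict[str, Any]

    def __getattr__(self, key: str) -> Any:
        try:
            return self.values[key]
        except KeyError as exc:
            raise AttributeError(key) from exc


def validate_config(cfg: str | Path | Mapping[str, Any]) -> PipelineConfig:
    """Load, default and validate a pipeline configuration.

    Unknown keys are rejected with a closest-match suggestion; parameter
    ranges are checked before any stage runs.
    """
    if isinstance(cfg, (str, Path)):
        raw = yaml.safe_load(Path(cfg).read_text())
        if not isinstance(raw, dict):
            raise ConfigError("config file must hold a key/value mapping")
    else:
        raw = dict(cfg)
    values = dict(_DEFAULTS)
    for key, value in raw.items():
        if key not in _DEFAULTS:
            hint = difflib.get_close_matches(key, _DEFAULTS, n=1)
            suffix = f" (did you mean {hint[0]!r}?)" if hint else ""
            raise ConfigError(f"unknown config key {key!r}{suffix}")
        values[key] = value

    if not (0 <= values["burnin"] < 1):
        raise ConfigError("burnin must be in [0, 1)")
    if not (0 <= values["drop_quantile"] <= 1):
        raise ConfigError("drop_quantile must be in [0, 1]")
    if not (0 < values["min_completeness"] <= 1):
        raise ConfigError("min_completeness must be in (0, 1]")
    if values["core_length"] < 1 or values["n_flank_bins"] < 1:
        raise ConfigError("core_length and n_flank_bins must be >= 1")
    if values["search"] not in ("greedy", "exhaustive"):
        raise ConfigError("search must be greedy or exhaustive")
    if values["criterion"] != "aicc":
        raise ConfigError("only the aicc criterion is supported")
    unknown_stages = set(values["stages"]) - set(STAGES)
    if unknown_stages:
        raise ConfigError(f"unknown stages: {sorted(unknown_stages)}")

    simulating = values["simulate_preset"] is not None
    if not simulating and values["loci_dir"] is None and set(values["stages"]) & {
        "clean", "charsets", "model_select"
    }:
        raise ConfigError("loci_dir (or a simulate preset) is required")
    if not simulating and "treedist" in values["stages"] and values["trees_dir"] is None:
        raise ConfigError("treedist stage enabled but no trees_dir given")
    if not simulating and "capture" in values["stages"] and values["specimen_table"] is None:
        raise ConfigError("capture stage enabled but no specimen_table given")
    for key in ("loci_dir", "trees_dir", "specimen_table"):
        if values[key] is not None and not Path(values[key]).exists():
            raise ConfigError(f"{key} does not exist: {values[key]}")
    return PipelineConfig(values)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the enabled stages in order and write a manifest.

    Identical configuration and seed give identical output checksums; a
    stage failure aborts with the stage name, leaving a partial manifest
    on disk.
    """
    out_dir = Path(cfg.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, str(cfg.log_level).upper(), logging.INFO))
    logger.info("effective config: %s", json.dumps(cfg.values, default=str, sort_keys=True))
    manifest: dict = {"config": cfg.values, "stages": {}, "checksums": {}}
    manifest_path = out_dir / "manifest.json"

    def record(stage: str, *paths: Path) -> None:
        manifest["stages"][stage] = [str(p) for p in paths]
        for p in paths:
            manifest["checksums"][p.name] = _sha256(p)
        manifest_path.write_text(json.dumps(manifest, indent=1, default=str, sort_keys=True))

    core_spec = CoreSpec(cfg.core_length, cfg.n_flank_bins)
    try:
        loci, samples_by_locus = _ingest_or_simulate(cfg, out_dir, record)
        stages = cfg.stages
        if "clean" in stages:
            loci = [al.drop_empty_columns(a) for a in loci]
            taxa = sorted({t for a in loci for t in a.taxa})
            loci = al.filter_by_completeness(
                loci, al.MatrixFilterConfig(taxa, cfg.min_completeness)
            )
            if not loci:
                raise RuntimeError("no locus passed the completeness filter")
            summaries, agg = al.summarize_loci(loci, taxa)
            path = out_dir / "locus_summary.tsv"
            with open(path, "w") as fh:
                fh.write("locus_id\tlength\tn_taxa\tpis\tcompleteness\n")
                for s in summaries:
                    fh.write(
                        f"{s.locus_id}\t{s.length}\t{s.n_taxa}\t{s.pis}\t{s.completeness:.6g}\n"
                    )
                fh.write(
                    f"# mean_length={agg.mean_length:.6g} mean_pis={agg.mean_pis:.6g} "
                    f"slope={agg.slope:.6g} r2={agg.r_squared:.6g}\n"
                )
            record("clean", path)
        charsets_by_locus = {a.locus_id: build_charsets(a, core_spec) for a in loci}
        if "charsets" in stages:
            path = out_dir / "charsets.nex"
            write_charset_definitions(charsets_by_locus, path)
            record("charsets", path)
        if "model_select" in stages:
            search = greedy_scheme_search if cfg.search == "greedy" else exhaustive_scheme_search
            schemes = {}
            for a in loci:
                tree = nj_guide_tree(a)
                schemes[a.locus_id] = search(charsets_by_locus[a.locus_id], a, tree)
            path = out_dir / "scheme_report.tsv"
            write_scheme_report(schemes, path)
            record("model_select", path)
        mccts: dict[str, Any] = {}
        if "treeqc" in stages:
            paths = _run_treeqc(cfg, loci, samples_by_locus, out_dir, mccts)
            record("treeqc", *paths)
        if "treedist" in stages:
            trees = dict(mccts)
            if not trees and cfg.trees_dir:
                for p in sorted(Path(cfg.trees_dir).glob("*.nwk")) + sorted(
                    Path(cfg.trees_dir).glob("*.tre")
                ):
                    trees[p.stem] = treeqc.read_tree(p)
            if len(trees) >= 2:
                tables = treedist.pairwise_distance_table(trees)
                path = out_dir / "tree_distances.tsv"
                treedist.write_distance_tables(tables, path)
                record("treedist", path)
        if "capture" in stages:
            if cfg.specimen_table:
                records = cap.read_specimen_table(cfg.specimen_table, cfg.sequencing_year)
            else:
                records = sim.simulate_capture_table(
                    {
                        "weevils": sim.CaptureStudyModel(2.0, -0.03, 0.8, 610),
                        "bees": sim.CaptureStudyModel(1.5, -0.03, 0.8, 900),
                        "jays": sim.CaptureStudyModel(2.5, -0.03, 0.8, 4500),
                    },
                    n_per_study=15,
                    seed=int(cfg.seed) + 1,
                )
            path = out_dir / "capture_report.tsv"
            cap.write_capture_report(records, path)
            record("capture", path)
    except Exception as exc:
        manifest["failed_stage"] = getattr(exc, "stage", "unknown")
        manifest_path.write_text(json.dumps(manifest, indent=1, default=str, sort_keys=True))
        raise
    return manifest


def _ingest_or_simulate(cfg: PipelineConfig, out_dir: Path, record) -> tuple[list, dict]:
    samples_by_locus: dict[str, list[treeqc.TreeSample]] = {}
    if cfg.simulate_preset is not None:
        sim_cfg = sim.SimConfig(
            seed=int(cfg.seed),
            n_taxa=int(cfg.n_taxa),
            n_loci=int(cfg.n_loci),
            core_length=cfg.core_length,
            n_flank_bins=cfg.n_flank_bins,
        )
        tree = sim.simulate_tree(sim_cfg.n_taxa, sim_cfg.seed, sim_cfg.tree_height)
        loci = []
        loci_dir = out_dir / "sim_loci"
        loci_dir.mkdir(parents=True, exist_ok=True)
        truths = {}
        for i in range(sim_cfg.n_loci):
            aln, truth = sim.simulate_locus(
                tree, sim_cfg, seed=sim_cfg.seed * 10_000 + i, locus_id=f"uce-{i + 1}"
            )
            loci.append(aln)
            truths[aln.locus_id] = truth
            with open(loci_dir / f"{aln.locus_id}.fasta", "w") as fh:
                for t, s in zip(aln.taxa, aln.seqs):
                    fh.write(f">{t}\n{s}\n")
            samples_by_locus[aln.locus_id] = [
                sim.simulate_posterior_sample(
                    tree, int(cfg.posterior_samples), float(cfg.posterior_perturbation),
                    seed=sim_cfg.seed * 10_000 + 1000 * (run + 1) + i,
                )
                for run in range(2)
            ]
        truth_path = out_dir / "sim_truth.json"
        sim.write_truth(truths, truth_path)
        record("simulate", truth_path)
        return loci, samples_by_locus
    loci = al.read_locus_alignments(cfg.loci_dir)
    if not loci:
        raise RuntimeError(f"no loci found in {cfg.loci_dir}")
    return loci, samples_by_locus


def _run_treeqc(cfg, loci, samples_by_locus, out_dir: Path, mccts: dict) -> list[Path]:
    records = []
    for a in loci:
        rec = treeqc.LocusQCRecord(a.locus_id)
        try:
            tree = nj_guide_tree(a)
            p = treeqc.p_distance_matrix(a)
            patristic = treeqc.patristic_matrix(tree, a.taxa)
            rec.sat_slope, rec.sat_intercept, rec.sat_r2 = treeqc.saturation_regression(
                p, patristic
            )
        except ValueError as exc:
            logger.warning("saturation stats failed for %s: %s", a.locus_id, exc)
        samples = samples_by_locus.get(a.locus_id)
        if samples:
            post = [treeqc.apply_burnin(
                treeqc.TreeSample(s.trees, burnin_fraction=float(cfg.burnin))
            ) for s in samples]
            combined = treeqc.TreeSample(
                [t for s in post for t in s.trees], burnin_fraction=0.0
            )
            mcct_tree = treeqc.mcct(combined)
            mccts[a.locus_id] = mcct_tree
            try:
                rec.mean_support = treeqc.mean_support(mcct_tree)
            except ValueError:
                pass
        records.append(rec)
    paths = []
    if len(records) >= 2 and all(np.isfinite(r.mean_support) for r in records):
        treeqc.filter_low_support_loci(records, float(cfg.drop_quantile))
    slopes_ok = sum(np.isfinite(r.sat_slope) for r in records)
    if slopes_ok >= 4:
        treeqc.flag_saturated_loci(
            [r for r in records if np.isfinite(r.sat_slope)],
            multiplier=float(cfg.saturation_multiplier),
        )
    qc_path = out_dir / "locus_qc.tsv"
    treeqc.write_qc_report(records, qc_path)
    paths.append(qc_path)
    kept_path = out_dir / "kept_loci.txt"
    kept_path.write_text(
        "".join(f"{r.locus_id}\n" for r in records if r.kept)
    )
    paths.append(kept_path)
    if samples_by_locus:
        asdsf_path = out_dir / "asdsf.tsv"
        with open(asdsf_path, "w") as fh:
            fh.write("locus_id\tasdsf\n")
            for locus_id in sorted(samples_by_locus):
                post = [treeqc.apply_burnin(
                    treeqc.TreeSample(s.trees, burnin_fraction=float(cfg.burnin))
                ) for s in samples_by_locus[locus_id]]
                try:
                    value = treeqc.asdsf(
                        treeqc.split_frequencies(post), float(cfg.asdsf_min_freq)
                    )
                    fh.write(f"{locus_id}\t{value:.6g}\n")
                except ValueError as exc:
                    fh.write(f"{locus_id}\tNA\n")
        paths.append(asdsf_path)
    return paths
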