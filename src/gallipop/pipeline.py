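"""End-to-end pipeline: config validation, stage orchestration, reports.

A YAML run config names the input VCF and sample sheet (or a simulation
scenario), toggles stages and sets per-stage parameters.  Stages execute in
the analysis order QC -> diversity -> FST -> LD decay -> ROH -> islands ->
Ne -> ESR -> PCA/NJ, writing one TSV (or newick/BED) per product, stamped
with the package version, a config hash, and the per-stage seeds derived
from the global seed by a stable labelled hash.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .diversity import diversity_table, fst_matrix
from .esr import ESRConfig, MCMCSchedule, esr_summary, esr_table, pseudo_replicate_esr
from .genotypes import GenotypeMatrix, QCConfig, apply_qc, read_sample_sheet, read_vcf
from .ld import ld_decay_curve
from .ne import contemporary_ne, historical_ne, ld_pairs_for_ne
from .roh import (ROHParams, detect_roh_all, f_roh, islands_to_bed,
                  l_auto_from_matrix, roh_islands, segments_to_frame,
                  snp_roh_incidence)
from .simulate import SimConfig, simulate
from .structure import nj_tree, pca_table, population_distance_matrix

_STAGES = ("qc", "diversity", "fst", "ld", "roh", "ne", "esr", "structure")


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed: labelled SHA-256 of the global seed, below 2^31."""
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


def _log(stage: str, level: str, message: str) -> None:
    print(f"[{stage}] {level}: {message}", file=sys.stderr)


@dataclass
class RunConfig:
    output_dir: str
    vcf: str | None = None
    sample_sheet: str | None = None
    simulate: dict | None = None
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(_STAGES))
    qc: dict = field(default_factory=dict)
    ld: dict = field(default_factory=dict)
    roh: dict = field(default_factory=dict)
    ne: dict = field(default_factory=dict)
    esr: dict = field(default_factory=dict)
    structure: dict = field(default_factory=dict)

    def config_hash(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(asdict(self), sort_keys=True).encode()).hexdigest()[:16]


def validate_config(path) -> RunConfig:
    """Parse and range-check a YAML run config; unknown keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    errors: list[str] = []
    known = set(RunConfig.__dataclass_fields__)
    for key in raw:
        if key not in known:
            errors.append(f"unknown key: {key!r}")
    if "output_dir" not in raw:
        errors.append("missing required key: output_dir")
    for key in ("vcf", "sample_sheet"):
        if raw.get(key) and not Path(raw[key]).exists():
            errors.append(f"{key} path does not exist: {raw[key]}")
    if not raw.get("vcf") and not raw.get("simulate"):
        errors.append("either 'vcf' or 'simulate' must be given")
    stages = raw.get("stages", list(_STAGES))
    for s in stages:
        if s not in _STAGES:
            errors.append(f"unknown stage: {s!r}")
    qc = raw.get("qc", {})
    try:
        QCConfig(**{k: v for k, v in qc.items() if k != "per_population"})
    except (TypeError, ValueError) as exc:
        errors.append(f"qc: {exc}")
    try:
        ROHParams(**raw.get("roh", {}))
    except (TypeError, ValueError) as exc:
        errors.append(f"roh: {exc}")
    if errors:
        raise ValueError("invalid config:\n  " + "\n  ".join(errors))
    return RunConfig(**{k: raw[k] for k in raw})


def _load_matrix(config: RunConfig) -> tuple[GenotypeMatrix, np.ndarray | None]:
    if config.simulate is not None:
        sim_cfg = SimConfig(**{**config.simulate,
                               "seed": config.simulate.get(
                                   "seed", stage_seed(config.seed, "simulate"))})
        matrix, truth = simulate(sim_cfg)
        return matrix, truth.ancestral_freqs
    sheet = read_sample_sheet(config.sample_sheet) if config.sample_sheet else None
    return read_vcf(config.vcf, sample_sheet=sheet), None


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute the enabled stages; returns the paths of every written output."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    stamp = {"version": __version__, "config_hash": config.config_hash(),
             "seed": config.seed,
             "stage_seeds": {s: stage_seed(config.seed, s) for s in _STAGES}}

    def write(name: str, df: pd.DataFrame) -> None:
        path = outdir / name
        df.to_csv(path, sep="\t", index=False, float_format="%.10g")
        outputs[name] = path

    matrix, ancestral = _load_matrix(config)
    _log("load", "info", f"{matrix.n_samples} samples x {matrix.n_variants} variants")

    stage = "load"
    try:
        if "qc" in config.stages:
            stage = "qc"
            qc_kwargs = dict(config.qc)
            per_pop = qc_kwargs.pop("per_population", False)
            filtered, report = apply_qc(matrix, QCConfig(**qc_kwargs),
                                        per_population=per_pop)
            kept = {v.id for v in filtered.variants}
            if ancestral is not None:
                ancestral = ancestral[[v.id in kept for v in matrix.variants]]
            _log("qc", "info", f"retained {report.n_retained}/{report.n_input}")
            write("qc_report.tsv", report.to_frame())
            matrix = filtered
        if "diversity" in config.stages:
            stage = "diversity"
            write("diversity.tsv", diversity_table(matrix))
        if "fst" in config.stages:
            stage = "fst"
            if len(matrix.populations) > 1:
                fm = fst_matrix(matrix)
                write("fst_pairs.tsv", fm.to_long_frame())
                fm.to_square_frame().to_csv(outdir / "fst_matrix.tsv", sep="\t")
                outputs["fst_matrix.tsv"] = outdir / "fst_matrix.tsv"
            else:
                _log("fst", "warning", "single population; FST skipped")
        if "ld" in config.stages:
            stage = "ld"
            frames = []
            for pop in matrix.populations:
                curve = ld_decay_curve(matrix, pop,
                                       seed=stage_seed(config.seed, f"ld:{pop}"),
                                       **config.ld)
                frames.append(curve.to_frame())
            write("ld_decay.tsv", pd.concat(frames, ignore_index=True))
        seg_by_sample = None
        if "roh" in config.stages:
            stage = "roh"
            params = ROHParams(**config.roh)
            seg_by_sample = detect_roh_all(matrix, params)
            write("roh_segments.tsv", segments_to_frame(seg_by_sample, matrix))
            l_auto = l_auto_from_matrix(matrix)
            rows, island_frames, bed_frames = [], [], []
            for pop in matrix.populations:
                idx = matrix.pop_indices(pop)
                frohs = [f_roh(seg_by_sample[matrix.sample_ids[i]], l_auto)
                         for i in idx]
                nsegs = [len(seg_by_sample[matrix.sample_ids[i]]) for i in idx]
                kbs = [sum(s.length_kb for s in seg_by_sample[matrix.sample_ids[i]])
                       for i in idx]
                rows.append({"population": pop, "nseg_mean": np.mean(nsegs),
                             "kb_mean": np.mean(kbs),
                             "f_roh_mean": np.mean(frohs),
                             "f_roh_sd": np.std(frohs, ddof=1) if len(frohs) > 1 else 0.0,
                             "l_auto_kb": l_auto})
                inc = snp_roh_incidence(seg_by_sample, matrix, pop)
                if inc["incidence"].gt(0).any() and len(inc) >= 100:
                    islands = roh_islands(inc, group=pop)
                    island_frames += [{"group": pop, "chrom": i.chrom,
                                       "start_bp": i.start_bp, "end_bp": i.end_bp,
                                       "n_snps": i.n_snps,
                                       "peak_incidence": i.peak_incidence}
                                      for i in islands]
                    if islands:
                        bed_frames.append(islands_to_bed(islands))
                inc.insert(0, "population", pop)
            write("roh_summary.tsv", pd.DataFrame(rows))
            write("roh_islands.tsv", pd.DataFrame(
                island_frames, columns=["group", "chrom", "start_bp", "end_bp",
                                        "n_snps", "peak_incidence"]))
            if bed_frames:
                bed = pd.concat(bed_frames, ignore_index=True)
                bed.to_csv(outdir / "roh_islands.bed", sep="\t", index=False,
                           header=False)
                outputs["roh_islands.bed"] = outdir / "roh_islands.bed"
        if "ne" in config.stages:
            stage = "ne"
            ne_cfg = dict(config.ne)
            n_sub = ne_cfg.pop("n_subsample", 40)
            traj_frames, point_rows = [], []
            for pop in matrix.populations:
                seed = stage_seed(config.seed, f"ne:{pop}")
                r2, dist, n_used = ld_pairs_for_ne(matrix, pop, n_subsample=n_sub,
                                                   seed=seed)
                traj = historical_ne(r2, dist, n_individuals=n_used,
                                     population=pop, **ne_cfg)
                traj_frames.append(traj.to_frame())
                pt = contemporary_ne(matrix, pop, n_subsample=n_sub, seed=seed)
                point_rows.append(vars(pt))
            write("ne_trajectory.tsv", pd.concat(traj_frames, ignore_index=True))
            write("ne_contemporary.tsv", pd.DataFrame(point_rows))
        if "esr" in config.stages:
            stage = "esr"
            if not matrix.sex_linked_mask.any():
                _log("esr", "warning", "no sex-linked SNPs; ESR skipped")
            else:
                esr_kwargs = dict(config.esr)
                mcmc = esr_kwargs.pop("mcmc", None)
                esr_cfg = ESRConfig(seed=stage_seed(config.seed, "esr"),
                                    **esr_kwargs)
                if mcmc:
                    esr_cfg.mcmc = MCMCSchedule(**mcmc)
                estimates = pseudo_replicate_esr(matrix, config=esr_cfg,
                                                 ancestral_freqs=ancestral)
                write("esr_replicates.tsv", esr_table(estimates))
                write("esr_summary.tsv", esr_summary(estimates))
        if "structure" in config.stages:
            stage = "structure"
            n_comp = config.structure.get("n_components", 2)
            pca = pca_table(matrix, n_components=n_comp)
            varprop = pca.attrs["variance_proportions"]
            write("pca.tsv", pca)
            (outdir / "pca_variance.tsv").write_text(
                "component\tproportion\n" + "".join(
                    f"PC{k + 1}\t{v:.10g}\n" for k, v in enumerate(varprop)))
            outputs["pca_variance.tsv"] = outdir / "pca_variance.tsv"
            level = config.structure.get("tree_level", "population")
            if level == "population" and len(matrix.populations) >= 3:
                dm = population_distance_matrix(matrix)
            elif matrix.n_samples >= 3:
                from .structure import allele_sharing_distance
                dm = allele_sharing_distance(matrix)
            else:
                dm = None
            if dm is not None:
                tree = nj_tree(dm)
                (outdir / "nj_tree.nwk").write_text(tree.to_newick() + "\n")
                outputs["nj_tree.nwk"] = outdir / "nj_tree.nwk"
            else:
                _log("structure", "warning", "too few taxa for a tree")
    except Exception as exc:
        _log(stage, "error", str(exc))
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    (outdir / "run_manifest.json").write_text(json.dumps(stamp, indent=2) + "\n")
    outputs["run_manifest.json"] = outdir / "run_manifest.json"
    return outputs
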