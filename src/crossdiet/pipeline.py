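"""End-to-end orchestration: simulate -> summarize -> diversity -> models.

A run is fully described by a flat :class:`RunConfig` (serialisable to
YAML and persisted next to the outputs), so a config plus the package
version determines every number in the report. Warnings use a fixed
``WARN`` prefix so they are machine-greppable in the log.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import composition as comp
from . import dirichlet, diversity, io, mixedlm, simulate

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Flat configuration of a full pipeline run."""

    out_dir: str = "crossdiet_run"
    seed: int = 7

    # stage toggles
    do_simulate: bool = True
    do_summarize: bool = True
    do_diversity: bool = True
    do_dirichlet: bool = True
    do_lmm: bool = True

    # inputs when not simulating
    feature_table: str | None = None
    mapping_file: str | None = None

    # simulation
    dogs_per_group: int = 25
    exclusions: tuple[int, int] = (2, 4)
    k_families: int = 20
    phi: float = 50.0
    sigma_u: float = 0.5
    depth_range: tuple[int, int] = simulate.DEFAULT_DEPTH_RANGE

    # composition
    rank: str = "phylum"
    group_by: str = "Diet"
    top_k: int = 20
    epsilon: float = 1e-6

    # diversity
    rarefaction_depth: int = diversity.DEFAULT_RAREFACTION_DEPTH
    shannon_base: float = 2.0
    permanova_terms: str = "Diet,Group"
    permutations: int = 999
    strata: str | None = None

    # dirichlet model
    chains: int = 4
    iterations: int = 10_000
    level: float = 0.89

    # mixed model
    lmm_fixed: str = "Diet,Group,Diet:Group"
    lmm_subject: str = "DogID"


def validate_config(config: RunConfig | dict) -> RunConfig:
    """Type/range checks with an aggregated, human-readable error list."""
    if isinstance(config, dict):
        known = {f.name for f in dataclasses.fields(RunConfig)}
        unknown = sorted(set(config) - known)
        if unknown:
            raise ValueError(f"unknown config keys: {unknown}")
        config = RunConfig(**config)
    problems: list[str] = []
    if not (0.0 < config.level < 1.0):
        problems.append(f"level must be in (0, 1), got {config.level}")
    k = max(config.k_families + 1, 2)
    if not (0.0 < config.epsilon < 1.0 / k):
        problems.append(f"epsilon must be in (0, 1/{k}), got {config.epsilon}")
    if config.rarefaction_depth < 1:
        problems.append("rarefaction_depth must be >= 1")
    if config.do_dirichlet and config.chains < 2:
        problems.append("chains must be >= 2 when the Dirichlet stage is on "
                        "(split R-hat needs multiple chains)")
    if config.iterations < 4:
        problems.append("iterations must be >= 4")
    if config.top_k < 1:
        problems.append("top_k must be >= 1")
    if config.permutations < 99:
        problems.append("permutations must be >= 99")
    if config.rank not in ("phylum", "family", "genus"):
        problems.append(f"rank must be phylum|family|genus, got {config.rank!r}")
    if not config.do_simulate and not (config.feature_table and config.mapping_file):
        problems.append("feature_table and mapping_file required when not simulating")
    lo, hi = config.depth_range
    if lo < 1 or hi < lo:
        problems.append(f"invalid depth_range {config.depth_range}")
    if problems:
        raise ValueError("invalid configuration:\n  - " + "\n  - ".join(problems))
    return config


def load_config(path: str | Path) -> RunConfig:
    with open(path) as handle:
        raw = yaml.safe_load(handle) or {}
    for key in ("exclusions", "depth_range"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    return validate_config(raw)


def save_config(config: RunConfig, path: str | Path) -> None:
    data = dataclasses.asdict(config)
    for key in ("exclusions", "depth_range"):
        data[key] = list(data[key])
    with open(path, "w") as handle:
        yaml.safe_dump(data, handle, sort_keys=True)


def _setup_logging(out_dir: Path) -> None:
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
    root = logging.getLogger("crossdiet")
    root.setLevel(logging.INFO)
    handler = logging.FileHandler(out_dir / "run.log")
    handler.setFormatter(fmt)
    root.addHandler(handler)
    if not any(isinstance(h, logging.StreamHandler)
               and not isinstance(h, logging.FileHandler) for h in root.handlers):
        console = logging.StreamHandler()
        console.setFormatter(fmt)
        root.addHandler(console)


def run_pipeline(config: RunConfig | dict) -> dict[str, Path]:
    """Execute the enabled stages in dependency order; return output paths.

    Stage failure raises with the failing stage named; outputs written by
    earlier stages are retained.
    """
    config = validate_config(config)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    _setup_logging(out_dir)
    save_config(config, out_dir / "run_config.yaml")
    logger.info("master seed: %d", config.seed)
    outputs: dict[str, Path] = {"config": out_dir / "run_config.yaml"}
    report: list[str] = [f"crossdiet run @ {time.strftime('%Y-%m-%d %H:%M:%S')}",
                         f"master seed: {config.seed}", ""]
    stage = "simulate"
    try:
        counts, meta = _stage_data(config, out_dir, outputs, report)
        if config.do_summarize:
            stage = "summarize"
            model_comp = _stage_summarize(config, counts, meta, out_dir, outputs, report)
        else:
            model_comp = None
        if config.do_diversity:
            stage = "diversity"
            _stage_diversity(config, counts, meta, out_dir, outputs, report)
        if config.do_dirichlet:
            stage = "dirichlet"
            if model_comp is None:
                model_comp = _model_composition(config, counts)
            _stage_dirichlet(config, model_comp, meta, out_dir, outputs, report)
        if config.do_lmm:
            stage = "lmm"
            _stage_lmm(config, counts, meta, out_dir, outputs, report)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    report_path = out_dir / "report.txt"
    report_path.write_text("\n".join(report) + "\n")
    outputs["report"] = report_path
    logger.info("report written to %s", report_path)
    return outputs


def _stage_data(config, out_dir, outputs, report):
    if config.do_simulate:
        design = simulate.TrialDesign(config.dogs_per_group, tuple(config.exclusions))
        truth = simulate.default_ground_truth(
            categories=config.k_families, design=design, phi=config.phi,
            sigma_u=config.sigma_u, depth_range=tuple(config.depth_range),
            seed=config.seed)
        ds = simulate.simulate_dataset(design, truth, seed=config.seed)
        paths = simulate.write_dataset(ds.counts, ds.metadata, truth,
                                       out_dir / "dataset")
        outputs.update(paths)
        report.append(f"simulated dataset: {len(ds.metadata)} samples, "
                      f"{len(truth.categories)} categories, phi={truth.phi}")
        return ds.counts, ds.metadata
    counts = io.read_feature_table(config.feature_table)
    meta = io.read_mapping_file(config.mapping_file)
    report.append(f"loaded dataset: {len(meta)} samples")
    return counts, meta


def _model_composition(config, counts):
    agg = comp.aggregate_taxa(counts, config.rank)
    rel = comp.relative_abundance(agg)
    top = comp.top_k_with_other(rel, config.top_k)
    return comp.adjust_zeros(top, config.epsilon)


def _stage_summarize(config, counts, meta, out_dir, outputs, report):
    agg = comp.aggregate_taxa(counts, config.rank)
    rel = comp.relative_abundance(agg)
    summary = comp.summarize_group(rel, meta, config.group_by)
    path = out_dir / f"summary_{config.rank}_by_{config.group_by}.tsv"
    summary.to_csv(path, sep="\t", index=False, float_format="%.6g")
    outputs["summary"] = path
    report.append(f"median/range summary ({config.rank} by {config.group_by}):")
    report.append(summary.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
    report.append("")
    return _model_composition(config, counts)


def _stage_diversity(config, counts, meta, out_dir, outputs, report):
    rare = diversity.rarefy(counts, config.rarefaction_depth, seed=config.seed)
    sh = diversity.shannon(rare, base=config.shannon_base)
    sh_path = out_dir / "shannon.tsv"
    sh.to_frame().to_csv(sh_path, sep="\t", float_format="%.10g")
    outputs["shannon"] = sh_path
    dm = diversity.bray_curtis_matrix(rare)
    dm_path = out_dir / "bray_curtis.tsv"
    io.write_distance_matrix(dm, dm_path)
    outputs["distance_matrix"] = dm_path
    ord_res = diversity.pcoa(dm, n_axes=2)
    ord_path = out_dir / "pcoa.tsv"
    ord_res.coordinates.to_csv(ord_path, sep="\t", float_format="%.10g")
    outputs["pcoa"] = ord_path
    perm = diversity.permanova(dm, meta, config.permanova_terms,
                               n_permutations=config.permutations,
                               seed=config.seed, strata=config.strata)
    perm_path = out_dir / "permanova.tsv"
    perm.table.to_csv(perm_path, sep="\t", index=False, float_format="%.6g")
    outputs["permanova"] = perm_path
    shift = diversity.distance_to_baseline(dm, meta)
    shift_path = out_dir / "distance_to_baseline.tsv"
    shift.to_csv(shift_path, sep="\t", index=False, float_format="%.10g")
    outputs["distance_to_baseline"] = shift_path
    report.append(f"PERMANOVA ({config.permanova_terms}, "
                  f"{config.permutations} permutations):")
    report.append(perm.table.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
    report.append("PCoA variance explained: " + ", ".join(
        f"{a}={p:.1%}" for a, p in ord_res.proportion_explained.items()))
    report.append("")


def _stage_dirichlet(config, model_comp, meta, out_dir, outputs, report):
    data = dirichlet.build_design(meta, model_comp)
    spec = dirichlet.ModelSpec(chains=config.chains, iterations=config.iterations,
                               seed=config.seed)
    draws = dirichlet.fit_mcmc(data, spec)
    draws_path = out_dir / "posterior_draws.csv"
    core = ([f"beta[{c},{k}]" for c in draws.cells for k in draws.categories[1:]]
            + [f"sd_u[{k}]" for k in draws.categories[1:]] + ["phi"])
    draws.to_long_frame(core).to_csv(draws_path, index=False, float_format="%.8g")
    outputs["posterior_draws"] = draws_path
    rh = dirichlet.rhat_summary(draws, core)
    rh_path = out_dir / "rhat.tsv"
    rh.to_frame().to_csv(rh_path, sep="\t", float_format="%.4f")
    outputs["rhat"] = rh_path
    fitted = dirichlet.fitted_intervals(draws, level=config.level)
    predicted = dirichlet.predicted_intervals(draws, level=config.level,
                                              seed=config.seed)
    intervals = pd.concat([fitted, predicted], ignore_index=True)
    int_path = out_dir / "intervals.tsv"
    intervals.to_csv(int_path, sep="\t", index=False, float_format="%.6g")
    outputs["intervals"] = int_path
    report.append(f"Dirichlet model: {len(draws.cells)} cells x "
                  f"{len(draws.categories)} categories, "
                  f"{draws.n_chains} chains x {draws.n_draws} kept draws")
    report.append(f"R-hat extremes: min={rh.min():.3f}, max={rh.max():.3f}")
    report.append(f"{int(config.level * 100)}% interval table: {int_path.name}")
    report.append("")


def _stage_lmm(config, counts, meta, out_dir, outputs, report):
    rare = diversity.rarefy(counts, config.rarefaction_depth, seed=config.seed)
    sh = diversity.shannon(rare, base=config.shannon_base)
    sub_meta = meta.loc[[s for s in sh.index if s in meta.index]]
    sh = sh.loc[sub_meta.index]
    fit = mixedlm.fit_reml(sh, sub_meta, config.lmm_fixed, config.lmm_subject)
    fit_path = out_dir / "lmm_fit.tsv"
    fit.summary().to_csv(fit_path, sep="\t", float_format="%.6g")
    outputs["lmm_fit"] = fit_path
    marg, cond = mixedlm.r2_nakagawa(fit)
    r2_path = out_dir / "lmm_r2.tsv"
    pd.DataFrame([{"marginal_r2": marg, "conditional_r2": cond}]).to_csv(
        r2_path, sep="\t", index=False, float_format="%.6g")
    outputs["lmm_r2"] = r2_path
    emm = mixedlm.marginal_means(fit, "Diet")
    emm_path = out_dir / "lmm_marginal_means_diet.tsv"
    emm.to_csv(emm_path, sep="\t", index=False, float_format="%.6g")
    outputs["lmm_marginal_means"] = emm_path
    report.append("Shannon mixed model:")
    report.append(f"  sigma2_subject={fit.sigma2_subject:.4f}, "
                  f"sigma2_residual={fit.sigma2_residual:.4f}")
    report.append(f"  marginal R2={marg:.3f}, conditional R2={cond:.3f}")
    report.append("  marginal means (Diet):")
    report.append(emm.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
    report.append("")
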