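"""Pipeline orchestration: config parsing, stage dispatch, run manifests.

A run is described by a flat YAML config with one section per requested
stage.  Stages execute in dependency order (simulate → quantify/fit →
profile), each writing its artifacts under the output directory; a
``manifest.json`` records the config hash, seeds, package version and
every artifact produced, so identical configs reproduce identical runs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

import episwitch
from episwitch._util import config_hash
from episwitch import io as eio
from episwitch.assays import compare_rates_yates, crash_apparent_loss_rate, pedigree_rate
from episwitch.kinetics import (
    DEFAULT_GENERATION_TIME_HR,
    PER_GENERATION,
    TwoStateRates,
    equilibrium_check,
    fit_rates,
    to_per_generation,
)
from episwitch.mnase import occupancy_pipeline, call_peaks
from episwitch.segregation import SegregationModel, predicted_rate_table
from episwitch.simulate import (
    LineageSimConfig,
    MNaseSimConfig,
    RelaxationSimConfig,
    simulate_crash_population,
    simulate_mnase_fragments,
    simulate_pedigree,
    simulate_relaxation,
)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger(__name__)

#: Execution order; requested stages run in this sequence.
STAGE_ORDER = (
    "predict_loss",
    "simulate_crash",
    "simulate_relaxation",
    "simulate_pedigree",
    "simulate_mnase",
    "quantify_crash",
    "fit_kinetics",
    "pedigree_rates",
    "mnase_profile",
)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending input."""


@dataclass
class PipelineConfig:
    """Validated pipeline configuration.

    ``stages`` maps stage name → stage options (dict).  Unknown stage
    names or top-level keys are rejected.
    """

    outdir: Path
    seed: int = 0
    generation_time_hr: float = DEFAULT_GENERATION_TIME_HR
    stages: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        if not isinstance(self.seed, int):
            raise ValueError(f"seed must be an integer, got {self.seed!r}")
        unknown = set(self.stages) - set(STAGE_ORDER)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}; known: {list(STAGE_ORDER)}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known_top = {"outdir", "seed", "generation_time_hr", "stages"}
        unknown = set(raw) - known_top
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}; known: {sorted(known_top)}")
        if "outdir" not in raw:
            raise ValueError("config must set outdir")
        return cls(
            outdir=Path(raw["outdir"]),
            seed=int(raw.get("seed", 0)),
            generation_time_hr=float(raw.get("generation_time_hr", DEFAULT_GENERATION_TIME_HR)),
            stages=raw.get("stages", {}) or {},
        )

    def hash(self) -> str:
        return config_hash(
            {
                "seed": self.seed,
                "generation_time_hr": self.generation_time_hr,
                "stages": self.stages,
            }
        )


def _check_inputs(cfg: PipelineConfig) -> None:
    for stage, opts in cfg.stages.items():
        path = (opts or {}).get("input")
        if path is not None and not Path(path).exists():
            raise PipelineError(f"stage {stage!r}: input path {path} does not exist")


def _stage_predict_loss(cfg, opts, outdir, artifacts):
    n_max = int(opts.get("n_max", 14))
    n_min = int(opts.get("n_min", 7))
    m = int(opts.get("min_parental", 1))
    p = float(opts.get("p_strand", 0.5))
    models = [SegregationModel(n, m, p) for n in range(n_max, n_min - 1, -1)]
    table = predicted_rate_table(models)
    out = outdir / "predicted_loss_rates.tsv"
    table.to_csv(out, sep="\t", index=False)
    artifacts.append(out)


def _stage_simulate_crash(cfg, opts, outdir, artifacts):
    sim = LineageSimConfig(seed=int(opts.get("seed", cfg.seed)), **{
        k: v for k, v in opts.items() if k not in ("seed",)
    })
    pop = simulate_crash_population(sim)
    out = outdir / "crash_events.csv"
    eio.write_flow_events(pop, out, provenance={"config_hash": config_hash(sim), "seed": sim.seed})
    artifacts.append(out)


def _stage_simulate_relaxation(cfg, opts, outdir, artifacts):
    genotypes = opts.get("genotypes")
    if not genotypes:
        raise PipelineError("stage 'simulate_relaxation': needs a genotypes mapping "
                            "{name: {k_on_per_gen, k_off_per_gen, initial_state}}")
    courses = []
    for i, (name, g) in enumerate(sorted(genotypes.items())):
        rates = TwoStateRates(
            float(g["k_on_per_gen"]), float(g["k_off_per_gen"]),
            PER_GENERATION, cfg.generation_time_hr,
        )
        sim = RelaxationSimConfig(
            rates=rates,
            generation_time_hr=cfg.generation_time_hr,
            initial_state=g.get("initial_state", "sorted_silenced"),
            genotype=name,
            n_cells_sampled=int(opts.get("n_cells_sampled", 500)),
            seed=int(opts.get("seed", cfg.seed)) + i,
        )
        courses.extend(simulate_relaxation(sim))
    out = outdir / "relaxation_timecourses.tsv"
    eio.write_timecourses(courses, out, provenance={"seed": cfg.seed})
    artifacts.append(out)


def _stage_simulate_pedigree(cfg, opts, outdir, artifacts):
    rates = TwoStateRates(
        float(opts.get("k_on_per_gen", 0.003)),
        float(opts.get("k_off_per_gen", 0.11)),
        PER_GENERATION, cfg.generation_time_hr,
    )
    loss, est = simulate_pedigree(
        rates,
        int(opts.get("n_divisions", 1000)),
        int(opts.get("seed", cfg.seed)),
        n_divisions_establishment=opts.get("n_divisions_establishment"),
    )
    out = outdir / "pedigree_counts.tsv"
    eio.write_pedigree([loss, est], out, provenance={"seed": cfg.seed})
    artifacts.append(out)


def _stage_simulate_mnase(cfg, opts, outdir, artifacts):
    region = tuple(opts.get("region", ("chrIII", 292000, 295000)))
    region = (str(region[0]), int(region[1]), int(region[2]))
    dyads = tuple(int(d) for d in opts.get("dyads", ()))
    if not dyads:
        raise PipelineError("stage 'simulate_mnase': needs a dyads list")
    sim = MNaseSimConfig(
        region=region, dyads=dyads,
        coverage=int(opts.get("coverage", 50)),
        seed=int(opts.get("seed", cfg.seed)),
    )
    frags = simulate_mnase_fragments(sim)
    out = outdir / "mnase_fragments.bed"
    eio.write_bed3(frags, out, provenance={"config_hash": config_hash(sim), "seed": sim.seed})
    artifacts.append(out)


def _stage_quantify_crash(cfg, opts, outdir, artifacts):
    path = opts.get("input", outdir / "crash_events.csv")
    pop = eio.read_flow_events(path)
    res = crash_apparent_loss_rate(pop)
    out = outdir / "crash_rates.json"
    out.write_text(json.dumps({
        "apparent_loss_rate": res.rate,
        "n_rfp_gfp": res.n_rfp_gfp,
        "n_rfp_only": res.n_rfp_only,
        "n_gfp_only": res.n_gfp_only,
    }, indent=2) + "\n")
    artifacts.append(out)


def _stage_fit_kinetics(cfg, opts, outdir, artifacts):
    path = opts.get("input", outdir / "relaxation_timecourses.tsv")
    courses = eio.read_timecourses(path)
    by_geno = {}
    for tc in courses:
        by_geno.setdefault(tc.genotype, []).append(tc)
    fits = []
    equil_rows = []
    method = opts.get("method", "pooled")
    for geno in sorted(by_geno):
        fit = fit_rates(by_geno[geno], method=method)
        fits.append(fit)
        per_gen = to_per_generation(fit.rates)
        eq = per_gen.equilibrium_expressed
        chk = equilibrium_check(per_gen, 100 * (1 - eq), 100 * eq)
        equil_rows.append({
            "genotype": geno,
            "pct_silenced": 100 * (1 - eq),
            "pct_expressed": 100 * eq,
            "e_over_s": chk.e_over_s,
            "kon_over_koff": chk.kon_over_koff,
        })
    out = outdir / "fits.json"
    eio.write_fit_results(fits, out, provenance={"seed": cfg.seed, "config_hash": cfg.hash()})
    artifacts.append(out)
    eq_out = outdir / "equilibrium_check.json"
    eq_out.write_text(json.dumps(equil_rows, indent=2) + "\n")
    artifacts.append(eq_out)


def _stage_pedigree_rates(cfg, opts, outdir, artifacts):
    path = opts.get("input", outdir / "pedigree_counts.tsv")
    counts = eio.read_pedigree(path)
    rows = []
    for c in counts:
        rate, (lo, hi) = pedigree_rate(c)
        rows.append({
            "genotype": c.genotype, "direction": c.direction,
            "n_divisions": c.n_divisions, "n_events": c.n_events,
            "rate": rate, "ci95_low": lo, "ci95_high": hi,
        })
    comparisons = []
    for i in range(len(counts)):
        for j in range(i + 1, len(counts)):
            if counts[i].direction == counts[j].direction:
                chi2, p = compare_rates_yates(counts[i], counts[j])
                comparisons.append({
                    "a": counts[i].genotype, "b": counts[j].genotype,
                    "direction": counts[i].direction, "chi2": chi2, "p": p,
                })
    out = outdir / "pedigree_rates.json"
    out.write_text(json.dumps({"rates": rows, "yates_comparisons": comparisons}, indent=2) + "\n")
    artifacts.append(out)


def _stage_mnase_profile(cfg, opts, outdir, artifacts):
    path = opts.get("input", outdir / "mnase_fragments.bed")
    region = tuple(opts.get("region", ("chrIII", 292000, 295000)))
    region = (str(region[0]), int(region[1]), int(region[2]))
    frags = eio.read_bed3(path, region=region)
    profile = occupancy_pipeline(
        frags,
        min_len=int(opts.get("min_len", 140)),
        max_len=int(opts.get("max_len", 180)),
        window=int(opts.get("window", 25)),
    )
    raw_out = outdir / "occupancy_raw.bedgraph"
    sm_out = outdir / "occupancy_smoothed.bedgraph"
    eio.write_bedgraph(profile, raw_out, which="raw")
    eio.write_bedgraph(profile, sm_out, which="smoothed")
    peaks = call_peaks(profile)
    pk_out = outdir / "peaks.json"
    pk_out.write_text(json.dumps({"chrom": profile.chrom, "peaks": [int(p) for p in peaks]}, indent=2) + "\n")
    artifacts.extend([raw_out, sm_out, pk_out])


_STAGE_FUNCS = {
    "predict_loss": _stage_predict_loss,
    "simulate_crash": _stage_simulate_crash,
    "simulate_relaxation": _stage_simulate_relaxation,
    "simulate_pedigree": _stage_simulate_pedigree,
    "simulate_mnase": _stage_simulate_mnase,
    "quantify_crash": _stage_quantify_crash,
    "fit_kinetics": _stage_fit_kinetics,
    "pedigree_rates": _stage_pedigree_rates,
    "mnase_profile": _stage_mnase_profile,
}


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the requested stages in dependency order.

    Returns (and writes) a manifest describing inputs, config hash,
    package version, seeds, and produced artifacts.  Any stage failure
    aborts the run with a :class:`PipelineError` naming the stage.
    """
    _check_inputs(cfg)  # fail before any stage runs
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []
    for stage in STAGE_ORDER:
        if stage not in cfg.stages:
            continue
        opts = cfg.stages[stage] or {}
        log.info("stage %s: starting", stage)
        try:
            _STAGE_FUNCS[stage](cfg, opts, cfg.outdir, artifacts)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
        log.info("stage %s: done", stage)
    manifest = {
        "config_hash": cfg.hash(),
        "seed": cfg.seed,
        "generation_time_hr": cfg.generation_time_hr,
        "version": episwitch.__version__,
        "stages_run": [s for s in STAGE_ORDER if s in cfg.stages],
        "artifacts": [str(a) for a in artifacts],
    }
    (cfg.outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
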