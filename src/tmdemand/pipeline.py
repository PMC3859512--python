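"""End-to-end orchestration: simulate -> exclusions -> fit -> select ->
project -> report, driven by a single YAML config with reproducibility
metadata (seed and config hash in every output header)."""
from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import gee, growth, projection, selection, synthetic_data

log = logging.getLogger("tmdemand")


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs.

    Either ``simulate`` holds generator settings, or ``paths`` points at
    existing panel / LMS / population CSVs.
    """

    outdir: str = "tmdemand-out"
    seed: int = 0
    simulate: dict = field(default_factory=dict)
    paths: dict = field(default_factory=dict)
    grid: str = "default"  # default | default+interactions | final-only
    parsimony_delta: float = 0.01
    horizon: tuple[int, int] = (2010, 2024)
    incidence_window: tuple[int, int] | None = None
    scenarios: dict = field(default_factory=lambda: {
        "baseline": 0.0, "mort-40": 0.4, "mort-80": 0.8,
    })

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.horizon = tuple(cfg.horizon)
        if cfg.incidence_window is not None:
            cfg.incidence_window = tuple(cfg.incidence_window)
        return cfg

    def canonical(self) -> str:
        # outdir is excluded: where outputs land is not part of the analysis
        payload = {k: getattr(self, k) for k in self.__dataclass_fields__
                   if k != "outdir"}
        return json.dumps(payload, sort_keys=True, default=str)

    def hash(self) -> str:
        return hashlib.sha256(self.canonical().encode()).hexdigest()[:12]


def demo_config(outdir: str, seed: int = 0) -> PipelineConfig:
    """The bundled synthetic scenario, calibrated to the published cohort
    scale (381 patients, mean demand ~38.7 units/yr, ~7M population)."""
    return PipelineConfig(
        outdir=outdir,
        seed=seed,
        simulate={"n_patients": 381, "years": [2005, 2009]},
    )


def _header(cfg: PipelineConfig) -> list[str]:
    return [f"tmdemand run seed={cfg.seed} config_hash={cfg.hash()}"]


def _write_csv(df: pd.DataFrame, path: Path, cfg: PipelineConfig) -> None:
    with open(path, "w") as fh:
        for line in _header(cfg):
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)


def load_inputs(cfg: PipelineConfig):
    """Return (panel, lms, population), simulating them if configured."""
    if cfg.simulate:
        sim = dict(cfg.simulate)
        sim.setdefault("seed", cfg.seed)
        if "years" in sim:
            sim["years"] = tuple(sim["years"])
        gen = synthetic_data.GeneratorConfig(**sim)
        lms = synthetic_data.generate_lms_reference()
        cohort = synthetic_data.generate_cohort(gen, lms)
        pop_years = range(gen.years[0], cfg.horizon[1] + 1)
        pop = synthetic_data.generate_population_projection(
            pop_years, gen.population_base, gen.population_growth,
            gen.population_cv,
        )
        return cohort.panel, lms, pop
    for key in ("panel", "lms", "population"):
        p = cfg.paths.get(key)
        if not p or not Path(p).exists():
            raise FileNotFoundError(
                f"pipeline input {key!r} not found at {p!r}; set paths.{key} "
                "or configure the simulate block"
            )
    panel = pd.read_csv(cfg.paths["panel"], comment="#")
    lms = growth.LMSReference.read_csv(cfg.paths["lms"])
    pop = projection.PopulationProjection.read_csv(cfg.paths["population"])
    return panel, lms, pop


def build_grid(cfg: PipelineConfig) -> list[gee.ModelVariant]:
    if cfg.grid == "default":
        return gee.default_grid()
    if cfg.grid == "default+interactions":
        return gee.default_grid() + gee.interaction_grid()
    if cfg.grid == "final-only":
        return [gee.ModelVariant(("age2", "weight2"), "independent")]
    raise ValueError(f"unknown grid {cfg.grid!r}")


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage, writing scores.csv, fit.json, table2.csv,
    forecast.csv and run.log into ``cfg.outdir``. Returns the in-memory
    stage results. Rerunning with the same config is bit-identical."""
    t0 = time.time()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(outdir / "run.log", mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)
    log.setLevel(logging.INFO)
    try:
        return _run_pipeline(cfg, outdir, t0)
    except Exception as exc:
        log.error("pipeline failed: %s", exc)
        raise
    finally:
        log.removeHandler(fh)
        fh.close()


def _run_pipeline(cfg: PipelineConfig, outdir: Path, t0: float) -> dict:
    log.info("config hash %s, seed %d", cfg.hash(), cfg.seed)

    panel_raw, lms, pop = load_inputs(cfg)
    log.info("input panel: %d rows, %d patients",
             len(panel_raw), panel_raw["patient_id"].nunique())
    if cfg.simulate:
        _write_csv(panel_raw, outdir / "panel.csv", cfg)
        lms.to_csv(outdir / "lms.csv", header_lines=_header(cfg))
        pop.to_csv(outdir / "population.csv", header_lines=_header(cfg))

    # --- exclusions and weight backfill [stage: exclusions]
    panel, excl = gee.apply_exclusions(panel_raw)
    panel, no_weight = growth.backfill_weights(panel, lms)
    excl.missing_weight_patients = sorted(
        set(excl.missing_weight_patients) | set(no_weight)
    )
    log.info("exclusions: %s", excl.summary())

    # --- model selection [stage: selection]
    grid = build_grid(cfg)
    scores = selection.run_variant_grid(panel, grid)
    final_variant = selection.select_final(scores, cfg.parsimony_delta)
    log.info("selected variant: %s", final_variant.name)
    _write_csv(selection.scores_table(scores), outdir / "scores.csv", cfg)

    # --- final fit [stage: fit]
    fit = gee.fit_model(panel, final_variant)
    log.info("fit: %d patients, %d rows, Pearson scale %.3f",
             fit.n_patients, fit.n_obs, fit.scale)
    fit.to_json(outdir / "fit.json")
    table2 = gee.relative_demand_table(fit)
    _write_csv(table2, outdir / "table2.csv", cfg)
    for term in ("age", "weight"):
        if f"{term}2" in fit.params.index:
            log.info("peak %s: %.1f", term, gee.peak_covariate(fit, term))

    # --- demographic rates [stage: rates]
    base_year = int(panel["year"].max())
    window = cfg.incidence_window or (int(panel_raw["year"].min()) + 1, base_year)
    incidence = projection.estimate_incidence(panel_raw, pop, window)
    mortality = projection.estimate_mortality(panel_raw)
    log.info("incidence %.3f/100k (%d cases), adult mortality %.2f%%",
             incidence.overall_per_100k, incidence.n_cases, 100 * mortality)

    # --- forecast scenarios [stage: projection]
    roster = projection.baseline_roster(panel, base_year, lms)
    gcovs = projection.group_covariates(panel, lms)
    horizon = list(range(cfg.horizon[0], cfg.horizon[1] + 1))
    fc = projection.run_scenarios(
        fit, roster, lms, incidence, pop, gcovs, mortality,
        horizon, base_year, reductions=cfg.scenarios,
    )
    _write_csv(fc, outdir / "forecast.csv", cfg)
    for name in cfg.scenarios:
        sub = fc[fc["scenario"] == name]
        pct, ann = projection.growth_summary(
            pd.concat([
                pd.DataFrame({
                    "year": [base_year],
                    "total_units": [
                        float(panel.loc[panel["year"] == base_year, "units"].sum())
                    ],
                }),
                sub[["year", "total_units"]],
            ]),
            base_year, horizon[-1],
        )
        log.info("scenario %s: %+.1f%% over %d years (%.2f%%/yr), 2024 total %.0f",
                 name, pct, horizon[-1] - base_year, ann,
                 sub["total_units"].iloc[-1])

    log.info("pipeline finished in %.1f s", time.time() - t0)
    return {
        "panel": panel,
        "exclusions": excl,
        "scores": scores,
        "variant": final_variant,
        "fit": fit,
        "incidence": incidence,
        "mortality": mortality,
        "forecast": fc,
        "base_year": base_year,
    }


def write_report(forecast: pd.DataFrame, outdir, plot: bool = True) -> Path:
    """Write a plain-text scenario summary (and a simple trajectory plot)
    from a forecast table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    lines = ["Projected annual blood demand (units)", ""]
    for name, sub in forecast.groupby("scenario"):
        first, last = sub.iloc[0], sub.iloc[-1]
        lines.append(
            f"{name}: {first['total_units']:.0f} ({first['year']:.0f}) -> "
            f"{last['total_units']:.0f} ({last['year']:.0f}) "
            f"[95% PI {last['pi_lo']:.0f}, {last['pi_hi']:.0f}], "
            f"new-case share {100 * last['newcase_units'] / last['total_units']:.1f}%"
        )
    path = outdir / "report.txt"
    path.write_text("\n".join(lines) + "\n")
    if plot:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(7, 4.5))
        for name, sub in forecast.groupby("scenario"):
            ax.plot(sub["year"], sub["total_units"], label=name)
            if name == "baseline":
                ax.fill_between(sub["year"], sub["pi_lo"], sub["pi_hi"], alpha=0.2)
        ax.set_xlabel("year")
        ax.set_ylabel("blood demand (units)")
        ax.legend()
        fig.tight_layout()
        fig.savefig(outdir / "forecast.png", dpi=120)
        plt.close(fig)
    return path
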