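"""End-to-end orchestration: batch detection, strain summaries, report.

``run_pipeline`` takes a configuration mapping (usually loaded from YAML),
processes every animal through the detection stages, and writes a report
directory of CSV tables plus a JSON summary that validates against the
shipped schema.  All randomness flows from the single top-level seed
recorded in the report, so identical config + seed reproduces byte-identical
outputs.
"""

from __future__ import annotations

import itertools
import json
from importlib import metadata
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import pydantic
import yaml

from . import core_io, quiescence, survival, synthetic
from .core_io import Trace, get_preset, logger

__all__ = ["run_pipeline", "load_config", "ReportSummary"]


# ---------------------------------------------------------------------------
# Report schema (validated with pydantic; a JSON-schema copy ships alongside)
# ---------------------------------------------------------------------------

class StrainSummary(pydantic.BaseModel):
    strain: str
    n_animals: int
    mean_sleep_fraction: float
    sem_sleep_fraction: float
    mean_ris_baseline: float
    mean_rim_inactivity_fraction: float


class Comparison(pydantic.BaseModel):
    strain_a: str
    strain_b: str
    quantity: str
    t: float
    df: float
    p_raw: float
    p_adj: float
    significant: bool


class RegressionSummary(pydantic.BaseModel):
    x_quantity: str
    y_quantity: str
    intercept: float
    slope: float
    r_squared: float
    n_points: int


class SurvivalComparisonRow(pydantic.BaseModel):
    strain: str
    day_tested: int
    alive: int
    dead: int
    p_raw: float
    p_adj: float
    significant: bool
    t50_fit: float | None = None
    k_fit: float | None = None
    A_fit: float | None = None
    converged: bool | None = None


class ReportSummary(pydantic.BaseModel):
    """Schema of the report's summary.json."""

    seed: int
    preset: dict
    version: str
    n_animals_processed: int
    n_animals_failed: int
    strains: list[StrainSummary]
    comparisons: list[Comparison]
    regression: RegressionSummary | None = None
    survival: list[SurvivalComparisonRow] | None = None
    survival_reference_day: float | None = None


def report_json_schema() -> dict:
    """The JSON schema the shipped ``report_schema.json`` file contains."""
    return ReportSummary.model_json_schema()


def _package_version() -> str:
    try:
        return metadata.version("wormq")
    except metadata.PackageNotFoundError:
        return "unknown"


# ---------------------------------------------------------------------------
# Config
# ---------------------------------------------------------------------------

def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("pipeline config must be a mapping")
    return cfg


def _collect_traces(cfg: Mapping, seed: int) -> list[Trace]:
    if "traces" in cfg:
        spec = cfg["traces"]
        path = Path(spec["path"])
        if not path.exists():
            raise FileNotFoundError(f"trace table {path} does not exist")
        traces = core_io.read_trace_table(path, dt=float(spec["dt"]),
                                          unit_scale=float(spec.get("unit_scale", 1.0)))
        if not traces:
            raise ValueError(f"trace table {path} contains no animals")
        return traces
    if "simulate" in cfg:
        sim = cfg["simulate"]
        panel = synthetic.strain_panel()
        strains = sim.get("strains", ["wildtype"])
        n = int(sim.get("n_animals", 10))
        duration = float(sim.get("hours", 12)) * 3600.0
        dt = float(sim.get("dt", 10.0))
        noise_sd = float(sim.get("noise_sd", 0.05))
        root = np.random.SeedSequence(seed)
        traces = []
        for strain, child in zip(strains, root.spawn(len(strains))):
            if strain not in panel:
                raise ValueError(f"unknown strain {strain!r}; available: {sorted(panel)}")
            for i, sub in enumerate(child.spawn(n)):
                animal_seed = int(sub.generate_state(1)[0] % (2 ** 31))
                trace, _ = synthetic.simulate_recording(
                    panel[strain], duration=duration, dt=dt, noise_sd=noise_sd,
                    seed=animal_seed, animal_id=f"{strain}_{i:03d}")
                traces.append(trace)
        return traces
    raise ValueError("config must contain a 'traces' or a 'simulate' block")


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: Mapping | str | Path, out_dir: str | Path,
                 seed: int = 0) -> ReportSummary:
    """Run the configured analyses and write the report bundle.

    Writes ``bouts.tsv`` (all animals), ``strain_summary.csv``,
    ``comparisons.csv`` (pairwise Welch tests on sleep fraction,
    BH-corrected within the family), an inactivity-vs-quiescence regression,
    optionally ``survival_comparisons.csv``, and ``summary.json``.  Animals
    whose detection fails are logged, excluded and counted in the summary.
    """
    cfg = load_config(config) if isinstance(config, (str, Path)) else dict(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", seed))

    preset_name = cfg.get("preset", "calcium_20x")
    presets = core_io.load_presets(cfg.get("preset_config"))
    params = get_preset(preset_name, presets)

    traces = _collect_traces(cfg, seed)

    bouts_path = out / "bouts.tsv"
    if bouts_path.exists():
        bouts_path.unlink()
    rows = []
    n_failed = 0
    for trace in traces:
        try:
            sleep = quiescence.detect_sleep(trace, params)
            core_io.write_bouts(sleep, bouts_path, append=True)
            frac = quiescence.fraction_in_bouts(sleep)
            activity, act_valid = _ris_activity(trace)
            baseline = float(np.median(activity[act_valid])) if act_valid.any() else np.nan
            rim_frac = np.nan
            if trace.rim is not None:
                rim_bouts = quiescence.detect_rim_inactivity(trace.rim, trace.dt,
                                                             valid=trace.valid,
                                                             animal_id=trace.animal_id)
                core_io.write_bouts(rim_bouts, bouts_path, append=True)
                rim_frac = quiescence.fraction_in_bouts(rim_bouts)
            rows.append(dict(animal_id=trace.animal_id, strain=trace.strain,
                             sleep_fraction=frac, ris_baseline=baseline,
                             rim_inactivity_fraction=rim_frac))
        except Exception as exc:  # noqa: BLE001 - one bad animal must not kill the batch
            n_failed += 1
            logger.warning("animal %s failed and was excluded: %s", trace.animal_id, exc)
    if not rows:
        raise ValueError("no animal could be processed")
    per_animal = pd.DataFrame(rows)
    per_animal.to_csv(out / "per_animal.csv", index=False)

    # --- strain summaries ---
    strains = []
    for strain, grp in per_animal.groupby("strain", sort=True):
        f = grp["sleep_fraction"].to_numpy()
        strains.append(StrainSummary(
            strain=strain, n_animals=len(grp),
            mean_sleep_fraction=float(f.mean()),
            sem_sleep_fraction=float(f.std(ddof=1) / np.sqrt(len(f))) if len(f) > 1 else float("nan"),
            mean_ris_baseline=float(grp["ris_baseline"].mean()),
            mean_rim_inactivity_fraction=float(grp["rim_inactivity_fraction"].mean()),
        ))
    pd.DataFrame([s.model_dump() for s in strains]).to_csv(out / "strain_summary.csv", index=False)

    # --- pairwise Welch comparisons of sleep fraction, BH within the family ---
    comparisons: list[Comparison] = []
    names = sorted(per_animal["strain"].unique())
    pairs = list(itertools.combinations(names, 2))
    if pairs and all((per_animal["strain"] == s).sum() >= 2 for s in names):
        raw = []
        for a, b in pairs:
            t, df, p = survival.welch_test(
                per_animal.loc[per_animal["strain"] == a, "sleep_fraction"],
                per_animal.loc[per_animal["strain"] == b, "sleep_fraction"])
            raw.append((a, b, t, df, p))
        adj, rej = survival.bh_fdr([r[4] for r in raw], q=float(cfg.get("q", 0.05)))
        for (a, b, t, df, p), pa, sig in zip(raw, adj, rej):
            comparisons.append(Comparison(strain_a=a, strain_b=b,
                                          quantity="sleep_fraction", t=t, df=df,
                                          p_raw=p, p_adj=float(pa), significant=bool(sig)))
        pd.DataFrame([c.model_dump() for c in comparisons]).to_csv(
            out / "comparisons.csv", index=False)

    # --- RIM-inactivity vs quiescence regression across animals ---
    regression = None
    reg_df = per_animal.dropna(subset=["rim_inactivity_fraction"])
    if len(reg_df) >= 2 and reg_df["sleep_fraction"].nunique() > 1:
        fit = survival.linear_fit(reg_df["sleep_fraction"], reg_df["rim_inactivity_fraction"])
        regression = RegressionSummary(
            x_quantity="sleep_fraction", y_quantity="rim_inactivity_fraction",
            intercept=fit.intercept, slope=fit.slope, r_squared=fit.r_squared,
            n_points=len(reg_df))

    # --- optional survival arm ---
    surv_rows = None
    ref_day = None
    if "survival" in cfg:
        scfg = cfg["survival"]
        table = core_io.read_survival_table(scfg["table"])
        endpoint = scfg.get("endpoint", "survival")
        res = survival.compare_survival_at_reference(
            table, scfg["reference"], float(scfg.get("fraction", 0.5)),
            q=float(scfg.get("q", 0.05)), endpoint=endpoint)
        ref_day = float(res.attrs["reference_day"])
        surv_rows = []
        for r in res.itertuples():
            row = SurvivalComparisonRow(strain=r.strain, day_tested=int(r.day_tested),
                                        alive=int(r.alive), dead=int(r.dead),
                                        p_raw=float(r.p_raw), p_adj=float(r.p_adj),
                                        significant=bool(r.significant))
            try:
                fit = survival.fit_logistic3(table, r.strain, endpoint=endpoint)
                row.t50_fit, row.k_fit, row.A_fit = fit.t50, fit.k, fit.A
                row.converged = fit.converged
            except ValueError:
                pass
            surv_rows.append(row)
        pd.DataFrame([r.model_dump() for r in surv_rows]).to_csv(
            out / "survival_comparisons.csv", index=False)

    summary = ReportSummary(
        seed=seed,
        preset=dict(name=params.name, smooth_window=params.smooth_window,
                    threshold=params.threshold, min_duration=params.min_duration,
                    direction=params.direction),
        version=_package_version(),
        n_animals_processed=len(rows), n_animals_failed=n_failed,
        strains=strains, comparisons=comparisons, regression=regression,
        survival=surv_rows, survival_reference_day=ref_day)
    (out / "summary.json").write_text(summary.model_dump_json(indent=2) + "\n")
    _write_text_summary(summary, out / "summary.txt")
    return summary


def _ris_activity(trace: Trace) -> tuple[np.ndarray, np.ndarray]:
    """GCaMP/mKate2 ratio if both channels exist, else raw GCaMP."""
    from .signal_extraction import ratiometric_activity
    if trace.gcamp is not None and trace.mkate2 is not None:
        return ratiometric_activity(trace.gcamp, trace.mkate2, valid=trace.valid)
    if trace.gcamp is not None:
        ok = trace.valid & np.isfinite(trace.gcamp)
        return trace.gcamp, ok
    return np.full(trace.n_frames, np.nan), np.zeros(trace.n_frames, dtype=bool)


def _write_text_summary(summary: ReportSummary, path: Path) -> None:
    lines = [f"wormq report (seed={summary.seed}, preset={summary.preset['name']})",
             f"animals processed: {summary.n_animals_processed}"
             f" (failed: {summary.n_animals_failed})", ""]
    for s in summary.strains:
        lines.append(f"  {s.strain:15s} n={s.n_animals:3d}"
                     f" sleep_fraction={s.mean_sleep_fraction:.4f}"
                     f" (sem {s.sem_sleep_fraction:.4f})"
                     f" RIS_baseline={s.mean_ris_baseline:.4f}")
    if summary.regression is not None:
        r = summary.regression
        lines += ["", f"regression {r.y_quantity} = {r.intercept:.4f}"
                      f" + {r.slope:.4f} * {r.x_quantity} (R^2={r.r_squared:.3f},"
                      f" n={r.n_points})"]
    if summary.survival is not None:
        lines += ["", f"survival comparisons at reference day {summary.survival_reference_day:g}:"]
        for r in summary.survival:
            star = "*" if r.significant else " "
            lines.append(f"  {r.strain:15s} day {r.day_tested:3d}"
                         f" alive/dead {r.alive}/{r.dead}"
                         f" p_adj={r.p_adj:.4g} {star}")
    path.write_text("\n".join(lines) + "\n")


def validate_report(path: str | Path) -> ReportSummary:
    """Parse and validate a summary.json against the report schema."""
    return ReportSummary.model_validate_json(Path(path).read_text())
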