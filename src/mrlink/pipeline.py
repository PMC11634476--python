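"""Configuration-driven orchestration of the full analysis.

Each ``run_*`` function takes a configuration dictionary (usually loaded
from YAML), executes the corresponding stage chain, writes its outputs under
``out_dir`` and returns a JSON-serializable run report with per-stage record
counts, all estimates, the software version, the seed and a config echo.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import pandas as pd

from . import __version__
from .sumstats import SumstatsTable, read_sumstats, write_sumstats, harmonize_pair
from .instruments import (LDMatrix, SelectionConfig, select_by_pvalue, clump,
                          f_statistics, filter_weak)
from .estimators import MREstimate
from .model import MRModel, results_table
from .presso import PressoConfig
from .mediation import ScreenConfig, two_step_mediation, screen_mediators, mediation_effect
from .simulate import SimConfig, simulate_chain, plant_outliers

log = logging.getLogger("mrlink")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, err: Exception):
        super().__init__(f"stage {stage!r} failed: {err}")
        self.stage = stage


def load_config(path) -> dict:
    import yaml
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config file must contain a mapping")
    return cfg


def _read_trait(spec: dict, default_label: str) -> SumstatsTable:
    return read_sumstats(spec["path"], column_map=spec.get("columns"),
                         trait_label=spec.get("label", default_label))


def _selection_config(cfg: dict) -> SelectionConfig:
    return SelectionConfig(**cfg.get("selection", {}))


def _estimate_to_dict(est: MREstimate | None):
    return est.to_dict() if est is not None else None


def _write_report(report: dict, out_dir: Path) -> Path:
    path = out_dir / "report.json"
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return path


def _base_report(cfg: dict, seed: int) -> dict:
    return {"version": __version__, "seed": seed, "config": cfg,
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S")}


def select_instruments(table: SumstatsTable, ld: LDMatrix | None,
                       sel: SelectionConfig, counts: dict) -> SumstatsTable:
    """p-value threshold -> LD clumping -> F filter, recording stage counts."""
    counts["n_read"] = len(table)
    t0 = time.monotonic()
    selected = select_by_pvalue(table, sel.p_threshold)
    counts["n_selected"] = len(selected)
    if ld is not None:
        selected = clump(selected, ld, r2_max=sel.r2_max, window_kb=sel.window_kb)
    counts["n_clumped"] = len(selected)
    strong = filter_weak(selected, f_min=sel.f_min)
    counts["n_strong"] = len(strong)
    counts["mean_F"] = f_statistics(strong, f_min=sel.f_min).mean_f
    log.info("instrument selection: %s in %.2fs", counts, time.monotonic() - t0)
    return strong


def run_simulate(cfg: dict, out_dir, seed: int | None = None) -> dict:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sim_kwargs = dict(cfg.get("simulate", {}))
    if seed is not None:
        sim_kwargs["seed"] = seed
    plant = sim_kwargs.pop("outliers", None)
    sim = SimConfig(**sim_kwargs)
    try:
        exposure, mediator, outcome, ld, truth = simulate_chain(sim)
        if plant:
            outcome, truth = plant_outliers(outcome, truth, int(plant["k"]),
                                            float(plant["offset_in_se"]),
                                            seed=sim.seed + 1)
    except ValueError as err:
        raise StageError("simulate", err) from err

    write_sumstats(exposure, out_dir / "exposure.tsv")
    write_sumstats(mediator, out_dir / "mediator.tsv")
    write_sumstats(outcome, out_dir / "outcome.tsv")
    ld.save(out_dir / "ld_matrix.tsv", out_dir / "ld_positions.tsv")
    truth.to_frame().to_csv(out_dir / "truth.tsv", sep="\t", index=False,
                            float_format="%.17g")

    report = _base_report(cfg, sim.seed)
    report["files"] = {k: str(out_dir / f"{k}.tsv")
                       for k in ("exposure", "mediator", "outcome", "truth")}
    report["truth"] = {"alpha": truth.alpha, "theta": truth.theta,
                       "delta": truth.delta, "total_effect": truth.total_effect,
                       "mediation_proportion": truth.mediation_proportion,
                       "outlier_ids": truth.outlier_ids}
    _write_report(report, out_dir)
    return report


def run_mr(cfg: dict, out_dir, seed: int | None = None) -> dict:
    """select -> clump -> F-filter -> harmonize -> IVW/Egger/Q/LOO/MR-PRESSO."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = seed if seed is not None else int(cfg.get("seed", 0))
    counts: dict = {}

    try:
        exposure = _read_trait(cfg["exposure"], "exposure")
        outcome = _read_trait(cfg["outcome"], "outcome")
    except (KeyError, ValueError, OSError) as err:
        raise StageError("read", err) from err
    ld = None
    if "ld" in cfg:
        try:
            ld = LDMatrix.load(cfg["ld"]["matrix"], cfg["ld"]["positions"])
        except (KeyError, ValueError, OSError) as err:
            raise StageError("ld", err) from err

    sel = _selection_config(cfg)
    try:
        instruments = select_instruments(exposure, ld, sel, counts)
    except ValueError as err:
        raise StageError("instruments", err) from err

    try:
        h = harmonize_pair(instruments, outcome, **cfg.get("harmonize", {}))
    except ValueError as err:
        raise StageError("harmonize", err) from err
    counts["n_harmonized"] = h.n_snp

    model = MRModel(h)
    try:
        results = model.fit_all()
    except ValueError as err:
        raise StageError("estimate", err) from err
    table = results_table(results)
    table.to_csv(out_dir / "mr_results.tsv", sep="\t", index=False, na_rep="NA",
                 float_format="%.8g")

    loo_rows = []
    if h.n_snp >= 3:
        for vid, est in model.leave_one_out():
            loo_rows.append({"excluded": vid, **est.to_dict()})
        pd.DataFrame(loo_rows).to_csv(out_dir / "leave_one_out.tsv", sep="\t",
                                      index=False, float_format="%.8g")

    presso_result = None
    if h.n_snp >= 4:
        pcfg = PressoConfig(seed=seed, **cfg.get("presso", {}))
        try:
            presso_result = model.run_presso(pcfg)
        except ValueError as err:
            raise StageError("presso", err) from err
        (out_dir / "presso.json").write_text(presso_result.to_json())

    report = _base_report(cfg, seed)
    report["counts"] = counts
    report["estimates"] = [r.to_row() for r in results]
    report["presso"] = presso_result.to_dict() if presso_result else None
    _write_report(report, out_dir)
    return report


def _read_prefit(path) -> dict[str, MREstimate]:
    """Pre-fitted stage estimates: TSV with columns role, beta, se where role
    is exposure_mediator, mediator_outcome or total."""
    df = pd.read_csv(path, sep=None, engine="python")
    need = {"role", "beta", "se"}
    if not need <= set(df.columns):
        raise ValueError("pre-fitted estimates file needs columns role, beta, se")
    out = {}
    for row in df.itertuples():
        out[str(row.role)] = MREstimate.from_beta_se("prefit", float(row.beta),
                                                     float(row.se), 0)
    missing = {"exposure_mediator", "mediator_outcome", "total"} - set(out)
    if missing:
        raise ValueError(f"pre-fitted estimates missing roles: {sorted(missing)}")
    return out


def run_mediate(cfg: dict, out_dir, seed: int | None = None) -> dict:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = seed if seed is not None else int(cfg.get("seed", 0))
    denominator_mode = cfg.get("denominator_mode", "fixed")
    report = _base_report(cfg, seed)

    if "prefit" in cfg:
        try:
            est = _read_prefit(cfg["prefit"])
            res = mediation_effect(est["exposure_mediator"],
                                   est["mediator_outcome"], est["total"],
                                   denominator_mode=denominator_mode)
        except (ValueError, OSError) as err:
            raise StageError("prefit", err) from err
    else:
        try:
            exposure = _read_trait(cfg["exposure"], "exposure")
            mediator = _read_trait(cfg["mediator"], "mediator")
            outcome = _read_trait(cfg["outcome"], "outcome")
        except (KeyError, ValueError, OSError) as err:
            raise StageError("read", err) from err
        ld = None
        if "ld" in cfg:
            ld = LDMatrix.load(cfg["ld"]["matrix"], cfg["ld"]["positions"])
        sel = _selection_config(cfg)
        counts_x: dict = {}
        counts_m: dict = {}
        try:
            exp_instr = select_instruments(exposure, ld, sel, counts_x)
            med_instr = select_instruments(mediator, ld, sel, counts_m)
            res = two_step_mediation(
                exposure, mediator, outcome, exp_instr, med_instr,
                mode=cfg.get("estimator", "random"),
                denominator_mode=denominator_mode, **cfg.get("harmonize", {}))
        except ValueError as err:
            raise StageError("mediate", err) from err
        report["counts"] = {"exposure": counts_x, "mediator": counts_m}

    report["mediation"] = res.to_dict()
    report["mediation"]["proportion_pct"] = res.proportion_pct
    (out_dir / "mediation.json").write_text(json.dumps(report["mediation"],
                                                       indent=2))
    _write_report(report, out_dir)
    return report


def run_screen(cfg: dict, out_dir, seed: int | None = None) -> dict:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = seed if seed is not None else int(cfg.get("seed", 0))
    try:
        exposure = _read_trait(cfg["exposure"], "exposure")
        outcome = _read_trait(cfg["outcome"], "outcome")
        mediator_specs = cfg["mediators"]
        if not mediator_specs:
            raise ValueError("empty candidate list")
    except (KeyError, ValueError, OSError) as err:
        raise StageError("read", err) from err

    ld = None
    if "ld" in cfg:
        ld = LDMatrix.load(cfg["ld"]["matrix"], cfg["ld"]["positions"])
    sel = _selection_config(cfg)
    counts: dict = {}
    try:
        exp_instr = select_instruments(exposure, ld, sel, counts)
    except ValueError as err:
        raise StageError("instruments", err) from err

    candidates = []
    for spec in mediator_specs:
        label = spec.get("label", spec["path"])
        table = _read_trait(spec, label)
        instr = select_by_pvalue(table, sel.p_threshold)
        candidates.append((label, table, instr))

    scfg = ScreenConfig(**cfg.get("screen", {}))
    try:
        screen = screen_mediators(exposure, outcome, candidates, exp_instr,
                                  cfg=scfg, **cfg.get("harmonize", {}))
    except ValueError as err:
        raise StageError("screen", err) from err

    screen.to_tsv(out_dir / "screen.tsv")
    screen.volcano_frame().to_csv(out_dir / "volcano.tsv", sep="\t", index=False,
                                  float_format="%.8g")
    report = _base_report(cfg, seed)
    report["counts"] = counts
    report["beta_total"] = screen.beta_total.to_dict()
    report["n_candidates"] = len(candidates)
    report["n_positive"] = screen.n_positive
    report["n_negative"] = screen.n_negative
    report["qualifiers"] = screen.qualifiers
    report["mediation"] = {k: v.to_dict() for k, v in screen.results.items()}
    _write_report(report, out_dir)
    return report
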