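"""End-to-end workflow: design -> fit -> rank -> report.

`run_pipeline` packages the screening workflow into one call driven by a
flat YAML-compatible config so a sample can go from design table to ranked
combinations and regimen lookups in a single command.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import io as qio
from .errors import ValidationError
from .panel import build_oacd, validate_design
from .pharmacodynamics import response_surface_map
from .ranking import locate_regimen, rank_combinations, top_combinations
from .surface import fit_surface
from .synthetic import SurfaceTruth, simulate_screen

log = logging.getLogger("qpop")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Flat configuration for the full pipeline.

    Exactly one viability source is required: ``readout`` (a design file
    with a viability column) or ``truth_surface`` (a surface file used to
    simulate a screen with ``noise_sd`` Gaussian noise).
    """

    panel: str
    out_dir: str
    readout: str | None = None
    design: str | None = None
    truth_surface: str | None = None
    noise_sd: float = 0.0
    oa_strength: int = 4
    ridge: float = 0.0
    k: list[int] = field(default_factory=lambda: [3])
    top: int = 10
    regimens: str | None = None
    surface_map_pair: list[str] | None = None
    grid_resolution: int = 25
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def run_pipeline(config: RunConfig) -> dict:
    """Execute design-validate -> fit -> rank -> lookup and write all outputs.

    Returns a report dict (also written as ``summary.txt`` / ``report.json``
    in the output directory).  Stage errors propagate as package exceptions;
    outputs written before the failure are retained.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = config.as_dict()
    report: dict = {"seed": config.seed, "stages": []}

    panel = qio.read_panel(config.panel)
    report["panel"] = {"n": panel.n, "L": panel.L, "drugs": panel.names}
    log.info("panel: %d drugs, L=%d", panel.n, panel.L)

    for kk in config.k:
        if not 1 <= kk <= panel.n:
            raise ValidationError(f"requested k={kk} outside 1..{panel.n}")

    # --- design + viability -------------------------------------------------
    if config.readout:
        design = qio.read_design(config.readout, panel)
        if design.viability is None:
            raise ValidationError(f"readout file {config.readout} has no viability column")
    else:
        if config.design:
            design = qio.read_design(config.design, panel)
        else:
            design = build_oacd(panel, oa_strength=config.oa_strength, seed=config.seed)
            log.info("built OACD with %d runs", design.n_runs)
        if config.truth_surface is None:
            raise ValidationError(
                "config needs either a readout file or a truth_surface to simulate from"
            )
        truth = qio.read_surface(config.truth_surface, panel)
        design = simulate_screen(
            SurfaceTruth(surface=truth, noise_sd=config.noise_sd), design, seed=config.seed
        )
        log.info("simulated screen (noise_sd=%g, seed=%d)", config.noise_sd, config.seed)
    qio.write_design(design, out / "design.csv", seed=config.seed, config=cfg)
    report["stages"].append("design")
    report["design"] = {"n_runs": design.n_runs}

    # --- validation ---------------------------------------------------------
    diag = validate_design(design)
    report["design_diagnostics"] = {
        "estimable": diag.estimable,
        "rank": diag.rank,
        "n_terms": diag.n_terms,
        "max_oa_correlation": diag.max_oa_correlation,
        "messages": diag.messages,
    }
    report["stages"].append("validate")
    log.info("design estimable: %s (rank %d/%d)", diag.estimable, diag.rank, diag.n_terms)

    # --- fit ----------------------------------------------------------------
    surface = fit_surface(design, regularization=config.ridge)
    qio.write_surface(surface, out / "surface.csv", seed=config.seed)
    report["stages"].append("fit")
    report["fit"] = surface.diagnostics
    log.info("fit: R^2=%.4f", surface.diagnostics["r_squared"])

    # --- rank + regimens ----------------------------------------------------
    regimens = qio.read_regimens(config.regimens) if config.regimens else []
    report["rankings"] = {}
    for kk in config.k:
        ranking = rank_combinations(surface, kk)
        qio.write_ranking(ranking, out / f"ranking_k{kk}.csv", seed=config.seed, config=cfg)
        m = min(config.top, len(ranking))
        top = [
            {
                "rank": rank,
                "score": score,
                "drugs": [panel.names[i] for i in a.members],
                "levels": list(a.levels),
            }
            for a, score, rank in top_combinations(ranking, m)
        ]
        entry = {"n_combinations": len(ranking), "top": top, "regimens": {}}
        for reg in regimens:
            if len(reg.members) != kk:
                continue
            best_rank, _ = locate_regimen(ranking, reg)
            entry["regimens"][reg.name] = {
                "rank": best_rank,
                "of": len(ranking),
            }
            log.info("regimen %s: rank %d of %d (k=%d)", reg.name, best_rank, len(ranking), kk)
        report["rankings"][kk] = entry
    report["stages"].append("rank")

    # --- optional response-surface map --------------------------------------
    if config.surface_map_pair:
        pair = tuple(config.surface_map_pair)
        grid = response_surface_map(surface, pair, config.grid_resolution)
        qio.write_grid(grid, out / "surface_map.csv", seed=config.seed)
        report["stages"].append("surface-map")

    # --- summary ------------------------------------------------------------
    (out / "report.json").write_text(json.dumps(report, indent=2, default=float) + "\n")
    (out / "summary.txt").write_text(_summary_text(report, cfg))
    return report


def _summary_text(report: dict, cfg: dict) -> str:
    lines = [
        qio.provenance_header(seed=report["seed"], config=cfg).rstrip(),
        f"panel: {report['panel']['n']} drugs ({', '.join(report['panel']['drugs'])})",
        f"design: {report['design']['n_runs']} runs; estimable="
        f"{report['design_diagnostics']['estimable']}",
        f"fit: R^2={report['fit']['r_squared']:.4f}, "
        f"residual_sd={report['fit']['residual_sd']:.4f}",
    ]
    for kk, entry in report["rankings"].items():
        lines.append(f"-- k={kk}: {entry['n_combinations']} combinations")
        for t in entry["top"]:
            combo = " + ".join(
                f"{d}@{lv}" for d, lv in zip(t["drugs"], t["levels"])
            )
            lines.append(f"   rank {t['rank']:>5}  score {t['score']: .4f}  {combo}")
        for name, info in entry["regimens"].items():
            lines.append(f"   regimen {name}: rank {info['rank']} of {info['of']}")
    return "\n".join(lines) + "\n"
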