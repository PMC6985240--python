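"""CSV schemas, provenance headers and table round-tripping.

All files are comma-separated UTF-8 with a mandatory header row and ``.``
decimals.  Files written by this package start with ``#``-prefixed
provenance comment lines (tool version, config hash, seed); readers skip
any such lines, so round trips are lossless.

Schemas
-------
panel         drug,unit,c0,c1,...         (c0 must be 0)
design        run_id,<drug...>,viability,replicate[,portion]
              (viability column optional for design-only files)
surface       term,estimate               (+ JSON diagnostics sidecar)
dose_response label,dose,response,replicate
combo         label,dose_<A>,dose_<B>,response,replicate
regimen       regimen,drug[,level]        (long form)
ranking       rank,score,drug1,level1,...,drugK,levelK
ci            fa,CI,d_<A>,d_<B>,D_<A>,D_<B>,verdict
"""

from __future__ import annotations

import hashlib
import io as _io
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import SchemaError, ValidationError
from .panel import DesignTable, Drug, DrugPanel
from .pharmacodynamics import CombinationIndexResult, ResponseSurfaceGrid
from .ranking import CombinationRanking, Regimen
from .surface import QuadraticSurface, term_names

__all__ = [
    "read_table",
    "read_panel",
    "write_panel",
    "read_design",
    "write_design",
    "read_surface",
    "write_surface",
    "read_dose_response",
    "write_dose_response",
    "read_regimens",
    "write_ranking",
    "write_ci",
    "write_grid",
    "provenance_header",
]

SCHEMAS = ("panel", "design", "dose_response", "combo", "regimen", "surface")


def provenance_header(seed: int | None = None, config: dict | None = None) -> str:
    """Comment block recording tool version, config hash and seed."""
    cfg_hash = hashlib.sha256(
        json.dumps(config or {}, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]
    lines = [f"# qpop {__version__}", f"# config_hash={cfg_hash}"]
    if seed is not None:
        lines.append(f"# seed={seed}")
    return "\n".join(lines) + "\n"


def _write_csv(df: pd.DataFrame, path, seed=None, config=None) -> None:
    path = Path(path)
    buf = _io.StringIO()
    df.to_csv(buf, index=False)
    path.write_text(provenance_header(seed=seed, config=config) + buf.getvalue())


def _read_csv(path, schema_id: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"{schema_id} file not found: {path}")
    try:
        df = pd.read_csv(path, comment="#", skip_blank_lines=True,
                         float_precision="round_trip")
    except Exception as exc:
        raise SchemaError(f"{path}: cannot parse as CSV ({exc})") from exc
    if df.empty and df.columns.empty:
        raise SchemaError(f"{path}: no header row")
    return df


def _require_columns(df: pd.DataFrame, cols, path, schema_id: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: {schema_id} file missing column(s) {missing}; has {list(df.columns)}"
        )


def _numeric(df: pd.DataFrame, col: str, path) -> np.ndarray:
    vals = pd.to_numeric(df[col], errors="coerce")
    bad = vals.isna() & df[col].notna()
    if bad.any():
        row = int(bad.idxmax())
        raise SchemaError(
            f"{path}: non-numeric value {df[col].iloc[row]!r} in column {col!r}, "
            f"data row {row + 1}"
        )
    if vals.isna().any():
        row = int(vals.isna().idxmax())
        raise SchemaError(f"{path}: empty cell in column {col!r}, data row {row + 1}")
    return vals.to_numpy()


# ---------------------------------------------------------------------------
# panel


def read_panel(path) -> DrugPanel:
    df = _read_csv(path, "panel")
    _require_columns(df, ["drug", "unit", "c0", "c1"], path, "panel")
    conc_cols = sorted(
        (c for c in df.columns if c.startswith("c") and c[1:].isdigit()),
        key=lambda c: int(c[1:]),
    )
    drugs = []
    for _, row in df.iterrows():
        conc = [float(row[c]) for c in conc_cols if pd.notna(row[c])]
        try:
            drugs.append(Drug(name=str(row["drug"]), concentrations=tuple(conc), dose_unit=str(row["unit"])))
        except ValidationError as exc:
            raise SchemaError(f"{path}: {exc}") from exc
    try:
        return DrugPanel(tuple(drugs))
    except ValidationError as exc:
        raise SchemaError(f"{path}: {exc}") from exc


def write_panel(panel: DrugPanel, path, seed=None) -> None:
    n_levels = panel.L + 1
    rows = [
        {"drug": d.name, "unit": d.dose_unit,
         **{f"c{i}": d.concentrations[i] for i in range(n_levels)}}
        for d in panel.drugs
    ]
    _write_csv(pd.DataFrame(rows), path, seed=seed)


# ---------------------------------------------------------------------------
# design


def read_design(path, panel: DrugPanel) -> DesignTable:
    df = _read_csv(path, "design")
    _require_columns(df, ["run_id"] + panel.names, path, "design")
    if df["run_id"].duplicated().any():
        dup = df.loc[df["run_id"].duplicated(), "run_id"].iloc[0]
        raise SchemaError(f"{path}: duplicate run_id {dup!r}")
    runs = np.column_stack([_numeric(df, name, path) for name in panel.names])
    if not np.allclose(runs, np.round(runs)):
        i, j = np.argwhere(~np.isclose(runs, np.round(runs)))[0]
        raise SchemaError(
            f"{path}: non-integer coded level {runs[i, j]} for drug "
            f"{panel.names[j]!r}, data row {i + 1}"
        )
    runs = runs.astype(int)
    if runs.min() < 0 or runs.max() > panel.L:
        i, j = np.argwhere((runs < 0) | (runs > panel.L))[0]
        raise SchemaError(
            f"{path}: coded level {runs[i, j]} for drug {panel.names[j]!r} outside "
            f"0..{panel.L}, data row {i + 1}"
        )
    viability = None
    if "viability" in df.columns and df["viability"].notna().any():
        viability = _numeric(df, "viability", path)
        if not np.all(np.isfinite(viability)):
            row = int(np.flatnonzero(~np.isfinite(viability))[0])
            raise SchemaError(f"{path}: non-finite viability, data row {row + 1}")
    replicate = None
    if "replicate" in df.columns and df["replicate"].notna().any():
        replicate = _numeric(df, "replicate", path).astype(int)
    portion = None
    if "portion" in df.columns and df["portion"].notna().any():
        portion = df["portion"].to_numpy(dtype=object)
    try:
        return DesignTable(panel=panel, runs=runs, viability=viability,
                           replicate=replicate, portion=portion)
    except ValidationError as exc:
        raise SchemaError(f"{path}: {exc}") from exc


def write_design(design: DesignTable, path, seed=None, config=None) -> None:
    data = {"run_id": [f"r{i:04d}" for i in range(design.n_runs)]}
    for j, name in enumerate(design.panel.names):
        data[name] = design.runs[:, j]
    if design.viability is not None:
        data["viability"] = design.viability
    data["replicate"] = design.replicate
    if design.portion is not None:
        data["portion"] = design.portion
    _write_csv(pd.DataFrame(data), path, seed=seed, config=config)


# ---------------------------------------------------------------------------
# surface


def read_surface(path, panel: DrugPanel) -> QuadraticSurface:
    df = _read_csv(path, "surface")
    _require_columns(df, ["term", "estimate"], path, "surface")
    estimates = dict(zip(df["term"], _numeric(df, "estimate", path)))
    expected = term_names(panel)
    missing = [t for t in expected if t not in estimates]
    if missing:
        raise SchemaError(f"{path}: surface file missing term(s) {missing[:5]}")
    coefs = np.array([estimates[t] for t in expected])
    diagnostics = {}
    sidecar = Path(path).with_suffix(".json")
    if sidecar.exists():
        diagnostics = json.loads(sidecar.read_text())
    return QuadraticSurface.from_coefficients(panel, coefs, diagnostics)


def write_surface(surface: QuadraticSurface, path, seed=None) -> None:
    df = pd.DataFrame(
        {"term": term_names(surface.panel), "estimate": surface.coefficients}
    )
    _write_csv(df, path, seed=seed)
    if surface.diagnostics:
        Path(path).with_suffix(".json").write_text(
            json.dumps(surface.diagnostics, indent=2, default=float) + "\n"
        )


# ---------------------------------------------------------------------------
# dose-response / combo / regimen


def read_dose_response(path):
    """-> dict label -> (doses, responses) preserving file order."""
    df = _read_csv(path, "dose_response")
    _require_columns(df, ["label", "dose", "response"], path, "dose_response")
    doses = _numeric(df, "dose", path)
    resp = _numeric(df, "response", path)
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for label in pd.unique(df["label"]):
        sel = (df["label"] == label).to_numpy()
        out[str(label)] = (doses[sel], resp[sel])
    return out


def write_dose_response(tables: dict, path, seed=None) -> None:
    frames = []
    for label, (d, r) in tables.items():
        frames.append(pd.DataFrame({"label": label, "dose": d, "response": r,
                                    "replicate": 1}))
    _write_csv(pd.concat(frames, ignore_index=True), path, seed=seed)


def read_combo(path):
    """-> (component labels, (n,2) dose array, response vector)."""
    df = _read_csv(path, "combo")
    dose_cols = [c for c in df.columns if c.startswith("dose_")]
    if len(dose_cols) != 2:
        raise SchemaError(
            f"{path}: combo file needs exactly 2 dose_<drug> columns, found {dose_cols}"
        )
    _require_columns(df, ["response"], path, "combo")
    doses = np.column_stack([_numeric(df, c, path) for c in dose_cols])
    resp = _numeric(df, "response", path)
    labels = [c[len("dose_"):] for c in dose_cols]
    return labels, doses, resp


def write_combo(labels, doses, responses, path, seed=None) -> None:
    doses = np.asarray(doses, dtype=float)
    df = pd.DataFrame({
        "label": "+".join(labels),
        f"dose_{labels[0]}": doses[:, 0],
        f"dose_{labels[1]}": doses[:, 1],
        "response": responses,
        "replicate": 1,
    })
    _write_csv(df, path, seed=seed)


def read_regimens(path) -> list[Regimen]:
    df = _read_csv(path, "regimen")
    _require_columns(df, ["regimen", "drug"], path, "regimen")
    has_levels = "level" in df.columns and df["level"].notna().any()
    regimens = []
    for name in pd.unique(df["regimen"]):
        sub = df[df["regimen"] == name]
        members = tuple(str(d) for d in sub["drug"])
        levels = None
        if has_levels:
            levels = tuple(int(v) for v in sub["level"])
        try:
            regimens.append(Regimen(name=str(name), members=members, levels=levels))
        except ValidationError as exc:
            raise SchemaError(f"{path}: {exc}") from exc
    return regimens


# ---------------------------------------------------------------------------
# outputs


def ranking_frame(ranking: CombinationRanking, top: int | None = None) -> pd.DataFrame:
    names = ranking.surface.panel.names
    rows = []
    for assignment, score, rank in ranking.entries():
        row = {"rank": rank, "score": score}
        for pos, (m, lv) in enumerate(zip(assignment.members, assignment.levels), 1):
            row[f"drug{pos}"] = names[m]
            row[f"level{pos}"] = lv
        rows.append(row)
        if top is not None and rank >= top:
            break
    return pd.DataFrame(rows)


def write_ranking(ranking: CombinationRanking, path, top=None, seed=None, config=None) -> None:
    _write_csv(ranking_frame(ranking, top=top), path, seed=seed, config=config)


def write_ci(result: CombinationIndexResult, path, seed=None) -> None:
    la, lb = (result.component_labels + ["A", "B"])[:2]
    df = pd.DataFrame({
        "fa": result.fa,
        "CI": result.ci,
        f"d_{la}": result.component_doses[:, 0],
        f"d_{lb}": result.component_doses[:, 1],
        f"D_{la}": result.iso_effective_doses[:, 0],
        f"D_{lb}": result.iso_effective_doses[:, 1],
        "verdict": result.verdicts,
    })
    _write_csv(df, path, seed=seed)


def write_grid(grid: ResponseSurfaceGrid, path, seed=None) -> None:
    rows = []
    for i, a in enumerate(grid.dose_a):
        for j, b in enumerate(grid.dose_b):
            rows.append({f"dose_{grid.drug_a}": a, f"dose_{grid.drug_b}": b,
                         "viability": grid.viability[i, j]})
    _write_csv(pd.DataFrame(rows), path, seed=seed)


# ---------------------------------------------------------------------------
# generic entry point


def read_table(path, schema_id: str, panel: DrugPanel | None = None):
    """Parse a file under a named schema; panel required where indicated."""
    if schema_id == "panel":
        return read_panel(path)
    if schema_id == "design":
        if panel is None:
            raise ValidationError("design schema requires a panel")
        return read_design(path, panel)
    if schema_id == "surface":
        if panel is None:
            raise ValidationError("surface schema requires a panel")
        return read_surface(path, panel)
    if schema_id == "dose_response":
        return read_dose_response(path)
    if schema_id == "combo":
        return read_combo(path)
    if schema_id == "regimen":
        return read_regimens(path)
    raise ValidationError(f"unknown schema {schema_id!r}; known: {SCHEMAS}")
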