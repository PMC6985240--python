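"""Drug panels, coded dose levels and screening-design construction.

A panel is an ordered list of drugs, each with a vehicle concentration (0)
and ``L`` strictly increasing non-zero concentrations.  Doses enter the
modelling layer only as integer coded levels ``0..L`` (0 = vehicle);
concentrations appear at I/O boundaries via :func:`coded_to_concentration`.

The screening design is an orthogonal-array composite: a two-level
orthogonal array over the two non-zero levels (mapped to -1/+1 on the
regression scale), single-drug axial runs that exercise every level
including vehicle, and one or more all-vehicle center runs.  The two-level
portion is drawn from a verified catalogue: Plackett-Burman / Hadamard
arrays for main-effect screening (strength 2), their fold-over (strength 3),
or regular resolution-V fractional factorials (strength 4) which make the
full second-order polynomial estimable.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import DesignError, ValidationError

__all__ = [
    "Drug",
    "DrugPanel",
    "DoseVector",
    "DesignTable",
    "DesignDiagnostics",
    "build_oacd",
    "validate_design",
    "coded_to_concentration",
    "concentration_to_coded",
    "coded_value",
]


@dataclass(frozen=True)
class Drug:
    """A drug with its on-grid concentrations.

    ``concentrations[0]`` must be exactly 0 (vehicle); the remaining
    entries are the non-zero dose levels in strictly increasing order.
    """

    name: str
    concentrations: tuple[float, ...]
    dose_unit: str = "uM"

    def __post_init__(self):
        if not self.name:
            raise ValidationError("drug name must be non-empty")
        conc = tuple(float(c) for c in self.concentrations)
        object.__setattr__(self, "concentrations", conc)
        if len(conc) < 2:
            raise ValidationError(
                f"drug {self.name!r}: needs vehicle plus >=1 non-zero concentration"
            )
        if conc[0] != 0.0:
            raise ValidationError(
                f"drug {self.name!r}: first concentration must be 0 (vehicle), got {conc[0]}"
            )
        if not all(np.isfinite(conc)):
            raise ValidationError(f"drug {self.name!r}: non-finite concentration")
        if any(b <= a for a, b in zip(conc, conc[1:])):
            raise ValidationError(
                f"drug {self.name!r}: concentrations must be strictly increasing"
            )

    @property
    def n_levels(self) -> int:
        """Number of non-zero levels L."""
        return len(self.concentrations) - 1


@dataclass(frozen=True)
class DrugPanel:
    """Ordered collection of drugs sharing a common coded-level range."""

    drugs: tuple[Drug, ...]

    def __post_init__(self):
        drugs = tuple(self.drugs)
        object.__setattr__(self, "drugs", drugs)
        if len(drugs) < 2:
            raise ValidationError("panel needs at least 2 drugs")
        names = [d.name for d in drugs]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValidationError(f"duplicate drug names in panel: {dupes}")
        levels = {d.n_levels for d in drugs}
        if len(levels) != 1:
            raise ValidationError(
                f"all drugs must expose the same number of non-zero levels, got {sorted(levels)}"
            )

    @property
    def n(self) -> int:
        return len(self.drugs)

    @property
    def L(self) -> int:
        """Non-zero levels per drug."""
        return self.drugs[0].n_levels

    @property
    def names(self) -> list[str]:
        return [d.name for d in self.drugs]

    def index_of(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise ValidationError(f"drug {name!r} not in panel") from None


@dataclass(frozen=True)
class DoseVector:
    """Coded levels for every drug in a panel; 0 = vehicle."""

    levels: tuple[int, ...]

    def __post_init__(self):
        object.__setattr__(self, "levels", tuple(int(v) for v in self.levels))

    def validate(self, panel: DrugPanel) -> "DoseVector":
        if len(self.levels) != panel.n:
            raise ValidationError(
                f"dose vector length {len(self.levels)} != panel size {panel.n}"
            )
        for name, lv in zip(panel.names, self.levels):
            if not 0 <= lv <= panel.L:
                raise ValidationError(
                    f"coded level {lv} for drug {name!r} outside 0..{panel.L}"
                )
        return self


@dataclass
class DesignTable:
    """Experimental runs (coded levels) with optional viability readouts.

    ``portion`` labels each run "oa" / "axial" / "center" when the table
    came from :func:`build_oacd`; user-supplied tables may leave it empty.
    """

    panel: DrugPanel
    runs: np.ndarray  # (n_runs, n) int
    viability: np.ndarray | None = None
    replicate: np.ndarray | None = None
    portion: np.ndarray | None = None

    def __post_init__(self):
        self.runs = np.asarray(self.runs, dtype=int)
        if self.runs.ndim != 2 or self.runs.shape[0] == 0:
            raise ValidationError("design needs a non-empty 2-D run matrix")
        if self.runs.shape[1] != self.panel.n:
            raise ValidationError(
                f"run matrix has {self.runs.shape[1]} columns, panel has {self.panel.n} drugs"
            )
        if self.runs.min() < 0 or self.runs.max() > self.panel.L:
            bad = np.argwhere((self.runs < 0) | (self.runs > self.panel.L))[0]
            raise ValidationError(
                f"run {bad[0]}, drug {self.panel.names[bad[1]]!r}: coded level "
                f"{self.runs[tuple(bad)]} outside 0..{self.panel.L}"
            )
        if self.viability is not None:
            self.viability = np.asarray(self.viability, dtype=float)
            if self.viability.shape != (self.n_runs,):
                raise ValidationError(
                    f"viability length {self.viability.size} != run count {self.n_runs}"
                )
            if not np.all(np.isfinite(self.viability)):
                idx = int(np.flatnonzero(~np.isfinite(self.viability))[0])
                raise ValidationError(f"non-finite viability at run {idx}")
        if self.replicate is None:
            self.replicate = np.ones(self.n_runs, dtype=int)
        else:
            self.replicate = np.asarray(self.replicate, dtype=int)
            if self.replicate.shape != (self.n_runs,):
                raise ValidationError("replicate ids must match run count")
        if self.portion is not None:
            self.portion = np.asarray(self.portion, dtype=object)
            if self.portion.shape != (self.n_runs,):
                raise ValidationError("portion labels must match run count")

    @property
    def n_runs(self) -> int:
        return self.runs.shape[0]

    def dose_vectors(self) -> list[DoseVector]:
        return [DoseVector(tuple(row)) for row in self.runs]

    def with_viability(self, viability: Sequence[float]) -> "DesignTable":
        return DesignTable(
            panel=self.panel,
            runs=self.runs.copy(),
            viability=np.asarray(viability, dtype=float),
            replicate=None if self.replicate is None else self.replicate.copy(),
            portion=None if self.portion is None else self.portion.copy(),
        )


# ---------------------------------------------------------------------------
# coded regression scale


def coded_value(level: int, L: int) -> float:
    """Regression-scale value of a coded level.

    Vehicle maps to the origin so the fitted intercept is the predicted
    all-vehicle viability; the L non-zero levels are spread over [-1, +1]
    (for L=2: level 1 -> -1, level 2 -> +1, matching the two-level OA).
    """
    if level == 0:
        return 0.0
    if L == 1:
        return 1.0
    return -1.0 + 2.0 * (level - 1) / (L - 1)


def coded_to_concentration(panel: DrugPanel, dv: DoseVector) -> np.ndarray:
    """Concentration of every drug for a coded dose vector."""
    dv.validate(panel)
    return np.array(
        [d.concentrations[lv] for d, lv in zip(panel.drugs, dv.levels)], dtype=float
    )


def concentration_to_coded(panel: DrugPanel, concentrations: Sequence[float]) -> DoseVector:
    """Inverse of :func:`coded_to_concentration` for on-grid concentrations."""
    conc = np.asarray(concentrations, dtype=float)
    if conc.shape != (panel.n,):
        raise ValidationError(
            f"expected {panel.n} concentrations, got {conc.size}"
        )
    levels = []
    for d, c in zip(panel.drugs, conc):
        matches = [i for i, g in enumerate(d.concentrations) if np.isclose(g, c, rtol=1e-12, atol=0.0) or g == c]
        if not matches:
            raise ValidationError(
                f"concentration {c} for drug {d.name!r} is not on the grid {list(d.concentrations)}"
            )
        levels.append(matches[0])
    return DoseVector(tuple(levels))


# ---------------------------------------------------------------------------
# two-level orthogonal arrays

# Plackett-Burman cyclic generator rows (orthogonality machine-verified).
_PB_ROWS = {
    12: (1, 1, -1, 1, 1, 1, -1, -1, -1, 1, -1),
    20: (1, 1, -1, -1, 1, 1, 1, 1, -1, 1, -1, 1, -1, -1, -1, -1, 1, 1, -1),
    24: (1, 1, 1, 1, 1, -1, 1, -1, 1, 1, -1, -1, 1, 1, -1, -1, 1, -1, 1, -1, -1, -1, -1),
}

# Regular resolution-V fractions: n -> (base factor count, generator bitmasks
# over base factors).  Each extra factor is the product of the masked base
# columns; all defining words have length >= 5, so every two-factor
# interaction is clear of main effects and of other two-factor interactions.
_RES5_CATALOG = {
    5: (4, (0b1111,)),
    6: (5, (0b1111,)),
    7: (6, (0b1111,)),
    8: (6, (0b001111, 0b110011)),
    9: (7, (0b0001111, 0b0110011)),
    10: (7, (0b0001111, 0b0110011, 0b1010101)),
    11: (7, (0b0001111, 0b0110011, 0b1010101, 0b1101010)),
}

MAX_PANEL_STRENGTH4 = max(_RES5_CATALOG)
MAX_PANEL_STRENGTH2 = max(_PB_ROWS) - 1


def _hadamard_columns(n_runs: int) -> np.ndarray:
    """Columns 1..n_runs-1 of a Sylvester Hadamard matrix (strength-2 OA)."""
    k = int(np.log2(n_runs))
    H = np.array([[1]])
    for _ in range(k):
        H = np.block([[H, H], [H, -H]])
    return H[:, 1:]


def _pb_array(n_runs: int) -> np.ndarray:
    row = np.array(_PB_ROWS[n_runs])
    M = np.array([np.roll(row, i) for i in range(n_runs - 1)])
    return np.vstack([M, -np.ones(n_runs - 1, dtype=int)])


def _two_level_oa(n: int, strength: int) -> np.ndarray:
    """A +-1 orthogonal array with n columns and the requested strength."""
    if strength == 4:
        if n <= 4:
            # full factorial: smallest array where all interactions are clear
            rows = np.array(list(itertools.product((-1, 1), repeat=n)), dtype=int)
            return rows
        if n not in _RES5_CATALOG:
            raise DesignError(
                f"no strength-4 orthogonal array available for {n} drugs; "
                f"largest supported panel is {MAX_PANEL_STRENGTH4}"
            )
        base, gens = _RES5_CATALOG[n]
        core = np.array(list(itertools.product((-1, 1), repeat=base)), dtype=int)
        cols = [core[:, i] for i in range(base)]
        for mask in gens:
            prod = np.ones(core.shape[0], dtype=int)
            for i in range(base):
                if mask >> i & 1:
                    prod = prod * core[:, i]
            cols.append(prod)
        return np.column_stack(cols)
    if strength in (2, 3):
        sizes = sorted(set(_PB_ROWS) | {4, 8, 16})
        usable = [N for N in sizes if N - 1 >= n]
        if not usable:
            raise DesignError(
                f"no two-level orthogonal array available for {n} drugs; "
                f"largest supported panel is {MAX_PANEL_STRENGTH2}"
            )
        N = usable[0]
        arr = _pb_array(N) if N in _PB_ROWS else _hadamard_columns(N)
        arr = arr[:, :n]
        if strength == 3:
            arr = np.vstack([arr, -arr])  # fold-over lifts strength 2 -> 3
        return arr
    raise DesignError(f"unsupported oa_strength {strength}; use 2, 3 or 4")


def build_oacd(
    panel: DrugPanel,
    oa_strength: int = 4,
    seed: int = 0,
    n_center: int = 1,
) -> DesignTable:
    """Construct the composite screening design for a two-non-zero-level panel.

    Concatenates (i) a two-level orthogonal array over coded levels {1, 2}
    (regression scale -1/+1), (ii) axial runs exercising each drug alone at
    every non-zero level, and (iii) ``n_center`` all-vehicle runs.  With the
    default ``oa_strength=4`` the full quadratic model is estimable from the
    result.  ``seed`` only shuffles run order; the run set is deterministic.
    """
    if panel.L != 2:
        raise DesignError(
            f"composite construction requires exactly 2 non-zero levels, panel has {panel.L}"
        )
    if n_center < 1:
        raise ValidationError("need at least one vehicle-control center run")
    n = panel.n
    oa = _two_level_oa(n, oa_strength)
    oa_levels = np.where(oa > 0, 2, 1)

    axial = []
    for i in range(n):
        for lv in (1, 2):
            row = np.zeros(n, dtype=int)
            row[i] = lv
            axial.append(row)
    axial = np.array(axial, dtype=int)

    center = np.zeros((n_center, n), dtype=int)

    runs = np.vstack([oa_levels, axial, center])
    portion = np.array(
        ["oa"] * oa_levels.shape[0] + ["axial"] * axial.shape[0] + ["center"] * n_center,
        dtype=object,
    )
    order = np.random.default_rng(seed).permutation(runs.shape[0])
    return DesignTable(panel=panel, runs=runs[order], portion=portion[order])


# ---------------------------------------------------------------------------
# diagnostics


@dataclass
class DesignDiagnostics:
    """Report from :func:`validate_design`."""

    level_counts: dict[str, dict[int, int]]
    max_oa_correlation: float
    oa_correlations: dict[tuple[str, str], float]
    estimable: bool
    rank: int
    n_terms: int
    confounded_terms: list[str] = field(default_factory=list)
    messages: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return self.estimable and not self.messages


def validate_design(design: DesignTable) -> DesignDiagnostics:
    """Check level coverage, OA-portion orthogonality and model estimability.

    Always returns a report; ``passed`` is False when the quadratic model of
    the fitting stage would be rank-deficient or a drug never leaves a level.
    """
    from .surface import quadratic_model_matrix, term_names  # deferred: avoids cycle

    panel = design.panel
    messages: list[str] = []

    level_counts: dict[str, dict[int, int]] = {}
    for j, name in enumerate(panel.names):
        counts = {lv: int(np.sum(design.runs[:, j] == lv)) for lv in range(panel.L + 1)}
        level_counts[name] = counts
        missing = [lv for lv, c in counts.items() if c == 0]
        if missing:
            messages.append(f"drug {name!r} never appears at level(s) {missing}")

    if design.portion is not None:
        oa_rows = design.runs[design.portion == "oa"]
    else:
        oa_rows = design.runs[np.all(design.runs > 0, axis=1)]
    oa_correlations: dict[tuple[str, str], float] = {}
    max_corr = 0.0
    if oa_rows.shape[0] >= 2:
        X = np.array([[coded_value(lv, panel.L) for lv in row] for row in oa_rows])
        Xc = X - X.mean(axis=0)
        sd = Xc.std(axis=0)
        for i, j in itertools.combinations(range(panel.n), 2):
            if sd[i] == 0 or sd[j] == 0:
                corr = 0.0
            else:
                corr = float(np.mean(Xc[:, i] * Xc[:, j]) / (sd[i] * sd[j]))
            oa_correlations[(panel.names[i], panel.names[j])] = corr
            max_corr = max(max_corr, abs(corr))

    M = quadratic_model_matrix(design.runs, panel.L)
    names = term_names(panel)
    n_terms = M.shape[1]
    rank = int(np.linalg.matrix_rank(M))
    estimable = rank == n_terms
    confounded: list[str] = []
    if not estimable:
        # null-space directions point at the confounded terms
        _, s, Vt = np.linalg.svd(M, full_matrices=True)
        tol = max(M.shape) * np.finfo(float).eps * (s[0] if s.size else 1.0)
        null = Vt[rank:]
        weight = np.max(np.abs(null), axis=0) if null.size else np.zeros(n_terms)
        confounded = [names[i] for i in np.flatnonzero(weight > 1e-8)]
        messages.append(
            f"quadratic model not estimable: rank {rank} < {n_terms}; "
            f"confounded terms: {confounded}"
        )

    return DesignDiagnostics(
        level_counts=level_counts,
        max_oa_correlation=max_corr,
        oa_correlations=oa_correlations,
        estimable=estimable,
        rank=rank,
        n_terms=n_terms,
        confounded_terms=confounded,
        messages=messages,
    )
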