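"""Dose-response pharmacodynamics.

Four-parameter logistic (4PL) curve fitting for single agents and
combinations, median-effect fitting, Chou-Talalay combination indices for
fixed-ratio series, and two-drug response-surface maps.

Conventions: responses are normalized viability (fraction of vehicle
control); fraction affected is ``fa = 1 - viability`` clipped to the open
unit interval before log transforms.  The default combination index is the
mutually-exclusive (Loewe) form ``CI = sum_i d_i / D_i(fa)``, for which the
sham self-combination identity CI = 1 holds exactly.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .errors import FitError, ValidationError
from .surface import QuadraticSurface, evaluate_coded

__all__ = [
    "DoseResponseCurve",
    "MedianEffectFit",
    "CombinationIndexResult",
    "ResponseSurfaceGrid",
    "fit_4pl",
    "fit_median_effect",
    "combination_index",
    "response_surface_map",
    "response_surface_map_from_grid",
    "fraction_affected",
    "four_pl",
]

FA_EPS = 1e-6


def four_pl(dose, top, bottom, ic50, hill):
    """response = bottom + (top - bottom) / (1 + (dose/ic50)^hill)."""
    dose = np.asarray(dose, dtype=float)
    return bottom + (top - bottom) / (1.0 + (dose / ic50) ** hill)


def fraction_affected(viability, eps: float = FA_EPS) -> np.ndarray:
    """fa = 1 - viability, clipped to (eps, 1-eps) for log-transform safety."""
    return np.clip(1.0 - np.asarray(viability, dtype=float), eps, 1.0 - eps)


@dataclass(frozen=True)
class DoseResponseCurve:
    """Fitted 4PL parameters for one agent or combination."""

    label: str
    top: float
    bottom: float
    ic50: float | None
    hill: float | None
    residual_sd: float
    dose_unit: str = ""
    no_dose_effect: bool = False
    n_points: int = 0

    def __post_init__(self):
        if not self.no_dose_effect:
            if self.ic50 is None or self.ic50 <= 0:
                raise ValidationError("ic50 must be positive")
            if self.hill is None or self.hill == 0 or not np.isfinite(self.hill):
                raise ValidationError("hill slope must be finite and non-zero")
            if self.top <= self.bottom:
                raise ValidationError("top asymptote must exceed bottom")

    def predict(self, dose):
        if self.no_dose_effect:
            return np.full_like(np.asarray(dose, dtype=float), self.top)
        return four_pl(dose, self.top, self.bottom, self.ic50, self.hill)


def _4pl_residuals(params, log_dose, response):
    top, bottom, log_ic50, hill = params
    return bottom + (top - bottom) / (1.0 + np.exp(hill * (log_dose - log_ic50))) - response


def fit_4pl(
    doses,
    responses,
    label: str = "",
    dose_unit: str = "",
    noise_floor: float = 0.01,
) -> DoseResponseCurve:
    """Least-squares 4PL fit with deterministic multi-start initialization.

    Requires >= 5 distinct positive doses.  Flat data (response range below
    ``noise_floor``) is flagged ``no_dose_effect`` with ic50 undetermined
    rather than force-fitted.  The fit is performed on log-dose, making the
    result invariant to dose-unit rescaling up to the same rescaling of
    ic50.
    """
    doses = np.asarray(doses, dtype=float)
    responses = np.asarray(responses, dtype=float)
    if doses.shape != responses.shape:
        raise ValidationError("doses and responses must have the same length")
    if np.any(doses <= 0) or not np.all(np.isfinite(doses)):
        raise ValidationError("doses must be positive and finite")
    if not np.all(np.isfinite(responses)):
        raise ValidationError("responses must be finite")
    if np.unique(doses).size < 5:
        raise ValidationError(
            f"need >= 5 distinct doses, got {np.unique(doses).size}"
        )

    # average replicates per dose for the flatness probe only
    resp_range = float(responses.max() - responses.min())
    if resp_range < noise_floor:
        return DoseResponseCurve(
            label=label,
            top=float(responses.mean()),
            bottom=float(responses.mean()),
            ic50=None,
            hill=None,
            residual_sd=float(responses.std(ddof=0)),
            dose_unit=dose_unit,
            no_dose_effect=True,
            n_points=doses.size,
        )

    log_dose = np.log(doses)
    lo, hi = float(responses.min()), float(responses.max())
    span = hi - lo
    # deterministic starts: ic50 across log-dose quantiles, both hill signs
    ic50_starts = np.quantile(log_dose, [0.2, 0.35, 0.5, 0.65, 0.8])
    trend = stats.linregress(log_dose, responses).slope
    hill_signs = (1.0, -1.0) if trend < 0 else (-1.0, 1.0)

    bounds_lo = [lo - span, lo - span, log_dose.min() - np.log(1e4), -20.0]
    bounds_hi = [hi + span, hi + span, log_dose.max() + np.log(1e4), 20.0]

    best = None
    for lic50, hsign in itertools.product(ic50_starts, hill_signs):
        x0 = np.array([hi, lo, lic50, hsign])
        try:
            res = optimize.least_squares(
                _4pl_residuals,
                x0,
                args=(log_dose, responses),
                bounds=(bounds_lo, bounds_hi),
                xtol=1e-15,
                ftol=1e-15,
                gtol=1e-15,
                max_nfev=5000,
            )
        except Exception:  # singular step etc. -> try next start
            continue
        if res.success and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        raise FitError(f"4PL fit failed to converge for {label!r} from all starts")

    top, bottom, log_ic50, hill = best.x
    if top < bottom:  # equivalent parameterization; normalize to top > bottom
        top, bottom, hill = bottom, top, -hill
    if abs(hill) < 1e-12 or top - bottom < 1e-12:
        raise FitError(
            f"4PL fit degenerate for {label!r} (flat within bounds)", best_attempt=best
        )
    dof = max(doses.size - 4, 1)
    return DoseResponseCurve(
        label=label,
        top=float(top),
        bottom=float(bottom),
        ic50=float(np.exp(log_ic50)),
        hill=float(hill),
        residual_sd=float(np.sqrt(2.0 * best.cost / dof)),
        dose_unit=dose_unit,
        n_points=doses.size,
    )


@dataclass(frozen=True)
class MedianEffectFit:
    """Median-effect line fa/fu = (D/Dm)^m fitted on the log-log scale."""

    Dm: float
    m: float
    r: float = 1.0
    n_points: int = 0
    label: str = ""

    def __post_init__(self):
        if self.Dm <= 0 or not np.isfinite(self.Dm):
            raise ValidationError("Dm must be positive and finite")
        if self.m == 0 or not np.isfinite(self.m):
            raise ValidationError("median-effect slope must be finite and non-zero")

    def iso_effective_dose(self, fa) -> np.ndarray:
        """Dose producing fraction affected fa: D = Dm * (fa/(1-fa))^(1/m)."""
        fa = np.asarray(fa, dtype=float)
        return self.Dm * (fa / (1.0 - fa)) ** (1.0 / self.m)

    def fa_at(self, dose) -> np.ndarray:
        dose = np.asarray(dose, dtype=float)
        ratio = (dose / self.Dm) ** self.m
        return ratio / (1.0 + ratio)


def fit_median_effect(doses, fraction_affected_values, label: str = "") -> MedianEffectFit:
    """Linear regression of log(fa/(1-fa)) on log(D).

    Points with fa outside the open interval (0, 1) are excluded with a
    warning; at least 3 interior points are required.
    """
    doses = np.asarray(doses, dtype=float)
    fa = np.asarray(fraction_affected_values, dtype=float)
    if doses.shape != fa.shape:
        raise ValidationError("doses and fraction-affected must align")
    if np.any(doses <= 0):
        raise ValidationError("doses must be positive")
    interior = (fa > 0.0) & (fa < 1.0)
    if np.any(~interior):
        warnings.warn(
            f"excluding {int(np.sum(~interior))} point(s) with fa outside (0,1)",
            stacklevel=2,
        )
    if int(interior.sum()) < 3:
        raise ValidationError(
            f"median-effect fit needs >= 3 points with fa in (0,1), got {int(interior.sum())}"
        )
    d, f = doses[interior], fa[interior]
    res = stats.linregress(np.log(d), np.log(f / (1.0 - f)))
    m = float(res.slope)
    if m == 0:
        raise FitError("median-effect slope is zero; no dose effect")
    Dm = float(np.exp(-res.intercept / m))
    return MedianEffectFit(Dm=Dm, m=m, r=float(res.rvalue), n_points=int(interior.sum()), label=label)


@dataclass
class CombinationIndexResult:
    """Combination indices along a combination dose series."""

    fa: np.ndarray
    ci: np.ndarray
    component_doses: np.ndarray  # (n_points, n_components)
    iso_effective_doses: np.ndarray  # (n_points, n_components)
    verdicts: list[str]
    component_labels: list[str] = field(default_factory=list)
    form: str = "exclusive"
    n_skipped: int = 0


def combination_index(
    single_fits,
    combo_doses,
    combo_fa,
    form: str = "exclusive",
    additive_band: float = 0.05,
) -> CombinationIndexResult:
    """Chou-Talalay combination index at each combination point.

    For each point with fa in (0,1): ``D_i(fa) = Dm_i (fa/(1-fa))^(1/m_i)``
    and ``CI = sum_i d_i / D_i`` (mutually-exclusive / Loewe form); the
    non-exclusive variant adds the two-drug cross term.  Points at fa 0 or
    1 are skipped with a warning.  Verdicts use ``additive_band``:
    CI < 1-band synergy, CI > 1+band antagonism, else additive.
    """
    fits = list(single_fits)
    if len(fits) < 2:
        raise ValidationError("combination index needs >= 2 component fits")
    d = np.atleast_2d(np.asarray(combo_doses, dtype=float))
    fa = np.asarray(combo_fa, dtype=float)
    if d.shape[0] != fa.size:
        raise ValidationError("combo doses and fa must align")
    if d.shape[1] != len(fits):
        raise ValidationError(
            f"{d.shape[1]} dose columns for {len(fits)} component fits"
        )
    if form not in ("exclusive", "nonexclusive"):
        raise ValidationError("form must be 'exclusive' or 'nonexclusive'")
    if form == "nonexclusive" and len(fits) != 2:
        raise ValidationError("non-exclusive CI implemented for 2 components only")

    keep = (fa > 0.0) & (fa < 1.0)
    n_skipped = int(np.sum(~keep))
    if n_skipped:
        warnings.warn(
            f"skipping {n_skipped} point(s) with fa at 0 or 1 (CI undefined)",
            stacklevel=2,
        )
    fa_k, d_k = fa[keep], d[keep]
    D = np.column_stack([f.iso_effective_dose(fa_k) for f in fits])
    terms = d_k / D
    ci = terms.sum(axis=1)
    if form == "nonexclusive":
        ci = ci + terms[:, 0] * terms[:, 1]
    verdicts = [
        "synergy" if c < 1.0 - additive_band else ("antagonism" if c > 1.0 + additive_band else "additive")
        for c in ci
    ]
    return CombinationIndexResult(
        fa=fa_k,
        ci=ci,
        component_doses=d_k,
        iso_effective_doses=D,
        verdicts=verdicts,
        component_labels=[f.label for f in fits],
        form=form,
        n_skipped=n_skipped,
    )


@dataclass
class ResponseSurfaceGrid:
    """Rectangular viability grid over a two-drug dose plane."""

    drug_a: str
    drug_b: str
    dose_a: np.ndarray
    dose_b: np.ndarray
    viability: np.ndarray  # (len(dose_a), len(dose_b))
    scale: str = "coded"

    def __post_init__(self):
        self.viability = np.asarray(self.viability, dtype=float)
        if self.viability.shape != (self.dose_a.size, self.dose_b.size):
            raise ValidationError("viability grid shape must match dose axes")
        if not np.all(np.isfinite(self.viability)):
            raise ValidationError("non-finite viability on grid")


def response_surface_map(
    surface: QuadraticSurface,
    pair: tuple[str, str],
    grid_resolution: int = 25,
) -> ResponseSurfaceGrid:
    """Predicted viability over a drug pair's coded dose rectangle.

    All other drugs are held at vehicle (coded origin).  The rectangle
    spans the coded range [-1, +1] of each drug; resolution 2 evaluates
    exactly the four corners.
    """
    if grid_resolution < 2:
        raise ValidationError("grid resolution must be >= 2")
    name_a, name_b = pair
    ia, ib = surface.panel.index_of(name_a), surface.panel.index_of(name_b)
    if ia == ib:
        raise ValidationError("pair must name two distinct drugs")
    xa = np.linspace(-1.0, 1.0, grid_resolution)
    xb = np.linspace(-1.0, 1.0, grid_resolution)
    A, B = np.meshgrid(xa, xb, indexing="ij")
    X = np.zeros((A.size, surface.panel.n))
    X[:, ia] = A.ravel()
    X[:, ib] = B.ravel()
    Z = evaluate_coded(surface, X).reshape(A.shape)
    return ResponseSurfaceGrid(
        drug_a=name_a, drug_b=name_b, dose_a=xa, dose_b=xb, viability=Z, scale="coded"
    )


def response_surface_map_from_grid(
    dose_a,
    dose_b,
    viability,
    pair: tuple[str, str],
    grid_resolution: int = 25,
) -> ResponseSurfaceGrid:
    """Bilinear interpolation of a measured two-drug viability grid."""
    from scipy.interpolate import RegularGridInterpolator

    if grid_resolution < 2:
        raise ValidationError("grid resolution must be >= 2")
    dose_a = np.asarray(dose_a, dtype=float)
    dose_b = np.asarray(dose_b, dtype=float)
    viability = np.asarray(viability, dtype=float)
    if viability.shape != (dose_a.size, dose_b.size):
        raise ValidationError("measured grid shape must match dose axes")
    interp = RegularGridInterpolator((dose_a, dose_b), viability, method="linear")
    xa = np.linspace(dose_a.min(), dose_a.max(), grid_resolution)
    xb = np.linspace(dose_b.min(), dose_b.max(), grid_resolution)
    A, B = np.meshgrid(xa, xb, indexing="ij")
    Z = interp(np.column_stack([A.ravel(), B.ravel()])).reshape(A.shape)
    return ResponseSurfaceGrid(
        drug_a=pair[0], drug_b=pair[1], dose_a=xa, dose_b=xb, viability=Z,
        scale="concentration",
    )


def plot_response_surface(grid: ResponseSurfaceGrid, path: str) -> None:
    """Write a heat-map image of a response-surface grid."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    mesh = ax.pcolormesh(
        grid.dose_b, grid.dose_a, grid.viability, shading="auto", cmap="viridis"
    )
    fig.colorbar(mesh, ax=ax, label="viability")
    ax.set_xlabel(f"{grid.drug_b} ({grid.scale})")
    ax.set_ylabel(f"{grid.drug_a} ({grid.scale})")
    ax.set_title(f"{grid.drug_a} x {grid.drug_b}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
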