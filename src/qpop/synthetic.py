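"""Ground-truth generators for end-to-end testing without experimental data.

Two generator families:

* :class:`SurfaceTruth` — a known quadratic surface plus Gaussian readout
  noise, used to simulate a combinatorial screen on any design table.
* :class:`HillComboTruth` — two single-agent Hill (4PL, top=1/bottom=0)
  curves plus a Loewe interaction parameter ``alpha``; fixed-ratio
  combination responses are built by inverting the Loewe relation
  ``sum_i d_i / D_i(fa) = alpha`` so that downstream combination-index
  analysis recovers CI = alpha exactly in the noise-free case
  (alpha < 1 synergy, 1 additive, > 1 antagonism).

All generators are pure functions of (truth, design, seed).

The bundled 11-drug fixture panel is synthetic: drug names echo the
T-cell-lymphoma screening context, but every concentration is invented.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .errors import ValidationError
from .panel import DesignTable, Drug, DrugPanel
from .surface import QuadraticSurface, predict_many

__all__ = [
    "SurfaceTruth",
    "HillComboTruth",
    "ComboSeries",
    "simulate_screen",
    "simulate_combo_series",
    "fixture_panel",
    "planted_truth",
]


@dataclass(frozen=True)
class SurfaceTruth:
    """A generating quadratic surface with additive Gaussian readout noise."""

    surface: QuadraticSurface
    noise_sd: float = 0.0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be non-negative")


def simulate_screen(truth: SurfaceTruth, design: DesignTable, seed: int = 0) -> DesignTable:
    """Viability readouts for every design run: surface value + noise.

    Replicate runs (identical level rows) receive independent noise draws.
    Deterministic given (truth, design, seed).
    """
    if truth.surface.panel.names != design.panel.names:
        raise ValidationError("truth panel does not match design panel")
    if truth.surface.panel.L != design.panel.L:
        raise ValidationError("truth and design disagree on level count")
    rng = np.random.default_rng(seed)
    y = predict_many(truth.surface, design.runs)
    y = y + rng.normal(0.0, truth.noise_sd, size=y.shape)
    return design.with_viability(y)


@dataclass(frozen=True)
class HillComboTruth:
    """Two-drug ground truth: per-drug Hill curves + Loewe interaction alpha.

    Curves are constrained to top=1, bottom=0 (full-range viability), which
    makes the Hill curve coincide with the median-effect model
    (Dm = ic50, m = hill) and the Loewe inversion exact.
    """

    labels: tuple[str, str]
    ic50: tuple[float, float]
    hill: tuple[float, float]
    loewe_alpha: float = 1.0
    noise_sd: float = 0.0

    def __post_init__(self):
        if self.loewe_alpha <= 0:
            raise ValidationError("loewe_alpha must be positive")
        if any(v <= 0 for v in self.ic50):
            raise ValidationError("ic50 truths must be positive")
        if any(h <= 0 for h in self.hill):
            raise ValidationError("hill truths must be positive")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be non-negative")

    def single_fa(self, component: int, dose) -> np.ndarray:
        """Fraction affected of one agent alone (Hill / median-effect form)."""
        d = np.asarray(dose, dtype=float)
        ratio = (d / self.ic50[component]) ** self.hill[component]
        return ratio / (1.0 + ratio)

    def iso_dose(self, component: int, fa: float) -> float:
        """Single-agent dose producing fraction affected fa."""
        return self.ic50[component] * (fa / (1.0 - fa)) ** (1.0 / self.hill[component])

    def combo_fa(self, d1: float, d2: float) -> float:
        """Fraction affected of the combination at component doses (d1, d2).

        Solves sum_i d_i / D_i(fa) = alpha for fa (the dose pair behaves as
        a Loewe-additive mixture of doses d_i / alpha).
        """
        if d1 <= 0 and d2 <= 0:
            return 0.0

        def excess(fa):
            return (
                d1 / self.iso_dose(0, fa) + d2 / self.iso_dose(1, fa) - self.loewe_alpha
            )

        return float(brentq(excess, 1e-12, 1.0 - 1e-12, xtol=1e-15, rtol=1e-15))


@dataclass
class ComboSeries:
    """A simulated fixed-ratio combination experiment with matched singles."""

    truth: HillComboTruth
    ratio: tuple[float, float]
    combo_doses: np.ndarray  # (n_points, 2) component doses
    combo_viability: np.ndarray
    single_doses: tuple[np.ndarray, np.ndarray]
    single_viability: tuple[np.ndarray, np.ndarray]
    seed: int = 0
    noise_sd: float = field(default=0.0)


def simulate_combo_series(
    truth: HillComboTruth,
    ratio: tuple[float, float] = (1.0, 1.0),
    n_points: int = 8,
    dilution: float = 2.0,
    seed: int = 0,
) -> ComboSeries:
    """Fixed-ratio dilution series for the combination plus matched singles.

    The series is geometric (factor ``dilution``) centered on the total
    dose at which the combination reaches half effect; single-agent series
    are centered on each ic50.  Viability = 1 - fa + Gaussian noise.
    """
    if n_points < 5:
        raise ValidationError("need >= 5 points in a dilution series")
    if dilution <= 1:
        raise ValidationError("dilution factor must exceed 1")
    r = np.asarray(ratio, dtype=float)
    if r.shape != (2,) or np.any(r <= 0):
        raise ValidationError("ratio must be two positive numbers")
    r = r / r.sum()

    rng = np.random.default_rng(seed)
    steps = np.arange(n_points) - (n_points - 1) / 2.0
    factors = dilution**steps

    # total dose putting the mixture at fa = 0.5
    t50 = truth.loewe_alpha / (r[0] / truth.ic50[0] + r[1] / truth.ic50[1])
    totals = t50 * factors
    combo_doses = np.column_stack([r[0] * totals, r[1] * totals])
    combo_fa = np.array([truth.combo_fa(d1, d2) for d1, d2 in combo_doses])
    combo_viability = 1.0 - combo_fa + rng.normal(0.0, truth.noise_sd, n_points)

    single_doses = []
    single_viability = []
    for comp in (0, 1):
        d = truth.ic50[comp] * factors
        v = 1.0 - truth.single_fa(comp, d) + rng.normal(0.0, truth.noise_sd, n_points)
        single_doses.append(d)
        single_viability.append(v)

    return ComboSeries(
        truth=truth,
        ratio=(float(r[0]), float(r[1])),
        combo_doses=combo_doses,
        combo_viability=combo_viability,
        single_doses=(single_doses[0], single_doses[1]),
        single_viability=(single_viability[0], single_viability[1]),
        seed=seed,
        noise_sd=truth.noise_sd,
    )


def simulate_dose_response(
    ic50: float,
    hill: float,
    doses,
    n_replicates: int = 3,
    noise_sd: float = 0.0,
    seed: int = 0,
    top: float = 1.0,
    bottom: float = 0.0,
):
    """Single-agent 4PL readouts with replicate-level Gaussian noise.

    Returns (doses, responses) with each dose repeated ``n_replicates``
    times; deterministic given seed.
    """
    from .pharmacodynamics import four_pl

    if ic50 <= 0 or hill == 0:
        raise ValidationError("need positive ic50 and non-zero hill")
    if n_replicates < 1:
        raise ValidationError("need >= 1 replicate")
    rng = np.random.default_rng(seed)
    d = np.repeat(np.asarray(doses, dtype=float), n_replicates)
    y = four_pl(d, top, bottom, ic50, hill) + rng.normal(0.0, noise_sd, d.size)
    return d, y


# ---------------------------------------------------------------------------
# fixtures

_FIXTURE_DRUGS = [
    # (name, unit, c1, c2) -- synthetic concentrations, not measured data
    ("bortezomib", "uM", 0.01, 0.1),
    ("panobinostat", "uM", 0.001, 0.01),
    ("pralatrexate", "uM", 1.0, 10.0),
    ("cisplatin", "uM", 1.0, 10.0),
    ("cytarabine", "uM", 0.5, 5.0),
    ("l-asparaginase", "IU/ml", 0.1, 1.0),
    ("gemcitabine", "uM", 0.05, 0.5),
    ("dexamethasone", "uM", 0.1, 1.0),
    ("etoposide", "uM", 0.5, 5.0),
    ("methotrexate", "uM", 0.05, 0.5),
    ("vinorelbine", "uM", 0.01, 0.1),
]


def fixture_panel(n: int = 11) -> DrugPanel:
    """Synthetic 11-drug, two-non-zero-level panel (invented concentrations)."""
    if not 2 <= n <= len(_FIXTURE_DRUGS):
        raise ValidationError(f"fixture panel supports 2..{len(_FIXTURE_DRUGS)} drugs")
    return DrugPanel(
        tuple(
            Drug(name=name, concentrations=(0.0, c1, c2), dose_unit=unit)
            for name, unit, c1, c2 in _FIXTURE_DRUGS[:n]
        )
    )


def planted_truth(
    panel: DrugPanel,
    members: tuple[str, ...] = ("cisplatin", "cytarabine", "l-asparaginase"),
    member_linear: float = -0.15,
    member_interaction: float = -0.08,
    baseline: float = 1.0,
) -> QuadraticSurface:
    """Truth surface whose unique best k-combination is ``members`` at top level.

    Member drugs get negative linear coefficients (favoring the high coded
    level) and mutually negative interactions; all other coefficients are
    zero, giving a widely separated optimum for recovery tests.
    """
    import itertools as it

    idx = {panel.index_of(m) for m in members}
    n = panel.n
    beta_lin = np.zeros(n)
    for i in idx:
        beta_lin[i] = member_linear
    beta_int = np.zeros(n * (n - 1) // 2)
    for p, (i, j) in enumerate(it.combinations(range(n), 2)):
        if i in idx and j in idx:
            beta_int[p] = member_interaction
    return QuadraticSurface(
        panel=panel,
        beta0=baseline,
        beta_lin=beta_lin,
        beta_quad=np.zeros(n),
        beta_int=beta_int,
    )
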