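"""Experiment orchestration and linear-quadratic dose-response analysis.

``run_experiment`` drives the full pipeline — track sampling, dose scoring,
DSB induction, repair, classification — over a dose ladder with many
histories per dose, aggregates aberration yields per category, fits the
linear-quadratic law y(D) = αD + βD² by weighted least squares with a
parametric bootstrap, and produces the derived reports (traversal tables,
population averages over a nuclear-size distribution, the simple:complex
ratio extrapolated to one mean nuclear traversal).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
import pandas as pd

from ._rng import as_rng
from .geometry import (GenomeModel, Karyotype, NucleusGeometry,
                       RadiusDistribution, build_genome)
from .irradiation import (IonBeam, IrradiationVolume,
                          RadialDoseModel, mean_traversals, sample_tracks,
                          score_dose_grid)
from .damage import DamageParameters, induce_dsbs
from .repair import RepairParameters, simulate_repair
from .aberrations import AberrationTally, analyze_history

#: default dose ladder: 7 points spanning 0.05–1 Gy
DEFAULT_DOSES_GY = (0.05, 0.1, 0.2, 0.4, 0.6, 0.8, 1.0)

_CATEGORIES = ("simple_exchanges", "complex_exchanges", "total_exchanges")


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything needed to reproduce one dose-response experiment."""

    nucleus: NucleusGeometry
    beam: IonBeam
    karyotype: Karyotype | None = None
    intermingle: bool = True
    doses_gy: tuple[float, ...] = DEFAULT_DOSES_GY
    histories_per_dose: int = 1000
    damage: DamageParameters = field(default_factory=DamageParameters)
    repair: RepairParameters = field(default_factory=RepairParameters)
    seed: int = 0
    near_field_um: float = 2.0
    min_fragment_bp: int = 0

    def __post_init__(self):
        if any(d <= 0 for d in self.doses_gy):
            raise ValueError("doses must be positive")
        if self.histories_per_dose < 1:
            raise ValueError("histories_per_dose must be >= 1")


@dataclass
class DoseResponseCurve:
    """Mean yield ± SE per dose point for one aberration category."""

    category: str
    doses_gy: np.ndarray          # mean scored dose Dav per point
    yields: np.ndarray
    std_errors: np.ndarray
    n_histories: int

    def __post_init__(self):
        if not (len(self.doses_gy) == len(self.yields)
                == len(self.std_errors)):
            raise ValueError("curve arrays must have equal length")


@dataclass
class LQFit:
    """α, β of y = αD + βD² with bootstrap uncertainty."""

    alpha: float                 # Gy⁻¹
    beta: float                  # Gy⁻²
    alpha_sd: float
    beta_sd: float
    alpha_ci95: tuple[float, float]
    beta_ci95: tuple[float, float]
    alpha_boot: np.ndarray = field(repr=False)
    beta_boot: np.ndarray = field(repr=False)

    def predict(self, dose_gy):
        d = np.asarray(dose_gy, dtype=float)
        out = self.alpha * d + self.beta * d ** 2
        return float(out) if out.ndim == 0 else out


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    genome: GenomeModel
    tallies: pd.DataFrame         # one row per (dose index, history)
    curves: dict[str, DoseResponseCurve]


# ---------------------------------------------------------------------------
# genome cache: one conformation per geometry (the default protocol)
# ---------------------------------------------------------------------------

_GENOME_CACHE: dict[tuple, GenomeModel] = {}


def cached_genome(nucleus: NucleusGeometry, karyotype: Karyotype | None,
                  intermingle: bool, seed: int) -> GenomeModel:
    key = (tuple(nucleus.semi_axes),
           id(karyotype) if karyotype is not None else None,
           intermingle, seed)
    if key not in _GENOME_CACHE:
        _GENOME_CACHE[key] = build_genome(
            nucleus, karyotype, intermingle=intermingle, seed=seed)
    return _GENOME_CACHE[key]


def run_history(genome: GenomeModel, beam: IonBeam, dose_gy: float,
                damage: DamageParameters, repair: RepairParameters,
                seed=None, volume: IrradiationVolume | None = None,
                model: RadialDoseModel | None = None,
                near_field_um: float = 2.0,
                min_fragment_bp: int = 0) -> tuple[AberrationTally, float]:
    """One complete history; returns (tally, scored volume-average dose)."""
    rng = as_rng(seed)
    volume = volume or IrradiationVolume.for_nucleus(genome.nucleus)
    tracks = sample_tracks(volume, beam, dose_gy, rng)
    grid = score_dose_grid(tracks, model=model, volume=volume,
                           near_field_um=near_field_um)
    dsbs = induce_dsbs(genome, grid, damage, rng)
    _, events = simulate_repair(dsbs, repair, rng)
    _, _, tally = analyze_history(genome.karyotype, dsbs, events,
                                  min_fragment_bp=min_fragment_bp)
    return tally, grid.mean_dose_gy


def run_experiment(config: ExperimentConfig,
                   genome: GenomeModel | None = None) -> ExperimentResult:
    """Full multi-dose, multi-history experiment.

    History seeds are split deterministically from (master seed, dose index,
    history index), so runs are reproducible and parallelisable without
    stream overlap.
    """
    if genome is None:
        genome = cached_genome(config.nucleus, config.karyotype,
                               config.intermingle, config.seed)
    volume = IrradiationVolume.for_nucleus(config.nucleus)
    model = RadialDoseModel.for_beam(config.beam)
    rows = []
    for di, dose in enumerate(config.doses_gy):
        for h in range(config.histories_per_dose):
            ss = np.random.SeedSequence(
                entropy=config.seed, spawn_key=(di, h))
            tally, dav = run_history(
                genome, config.beam, dose, config.damage, config.repair,
                seed=np.random.default_rng(ss), volume=volume, model=model,
                near_field_um=config.near_field_um,
                min_fragment_bp=config.min_fragment_bp)
            row = tally.to_dict()
            row.update(dose_index=di, dose_gy=dose, history=h,
                       scored_dose_gy=dav)
            rows.append(row)
    tallies = pd.DataFrame(rows)
    curves = {}
    for cat in _CATEGORIES:
        g = tallies.groupby("dose_index")
        dav = g["scored_dose_gy"].mean().to_numpy()
        mean = g[cat].mean().to_numpy()
        se = (g[cat].std(ddof=1) / math.sqrt(config.histories_per_dose)
              ).to_numpy()
        curves[cat] = DoseResponseCurve(cat, dav, mean, se,
                                        config.histories_per_dose)
    return ExperimentResult(config, genome, tallies, curves)


# ---------------------------------------------------------------------------
# LQ fitting
# ---------------------------------------------------------------------------

def _wls_lq(doses: np.ndarray, yields: np.ndarray,
            weights: np.ndarray) -> tuple[float, float]:
    X = np.column_stack([doses, doses ** 2])
    sw = np.sqrt(weights)
    coef, *_ = np.linalg.lstsq(X * sw[:, None], yields * sw, rcond=None)
    return float(coef[0]), float(coef[1])


def fit_lq(curve: DoseResponseCurve, n_boot: int = 1000,
           seed=None) -> LQFit:
    """Weighted least-squares LQ fit with a parametric bootstrap.

    Weights are 1/SE²; points with zero SE (noise-free input) fall back to
    equal weights.  The bootstrap resamples each point from
    Normal(mean, SE), refits, and reports percentile 95% intervals.
    """
    d = np.asarray(curve.doses_gy, dtype=float)
    y = np.asarray(curve.yields, dtype=float)
    se = np.asarray(curve.std_errors, dtype=float)
    if len(d) < 3:
        raise ValueError("need at least 3 dose points")
    if np.allclose(d, d[0]):
        raise ValueError("all doses equal: singular design")
    if (se > 0).all():
        w = 1.0 / se ** 2
    else:
        w = np.ones_like(d)
    alpha, beta = _wls_lq(d, y, w)
    rng = as_rng(seed)
    boots = np.empty((n_boot, 2))
    for b in range(n_boot):
        yb = y + se * rng.standard_normal(len(y))
        boots[b] = _wls_lq(d, yb, w)
    a_b, b_b = boots[:, 0], boots[:, 1]
    return LQFit(
        alpha=alpha, beta=beta,
        alpha_sd=float(a_b.std(ddof=1)), beta_sd=float(b_b.std(ddof=1)),
        alpha_ci95=(float(np.percentile(a_b, 2.5)),
                    float(np.percentile(a_b, 97.5))),
        beta_ci95=(float(np.percentile(b_b, 2.5)),
                   float(np.percentile(b_b, 97.5))),
        alpha_boot=a_b, beta_boot=b_b)


def population_average(curves: list[DoseResponseCurve],
                       distribution: RadiusDistribution) -> DoseResponseCurve:
    """Frequency-weighted pointwise mean of per-radius dose responses."""
    if len(curves) != len(distribution.radii_um):
        raise ValueError("one curve per radius is required")
    d0 = np.asarray(curves[0].doses_gy)
    for c in curves[1:]:
        if len(c.doses_gy) != len(d0) or \
                not np.allclose(c.doses_gy, d0, rtol=0.05):
            raise ValueError("curves must share their dose points")
    w = np.asarray(distribution.frequencies)
    yields = np.stack([c.yields for c in curves])
    ses = np.stack([c.std_errors for c in curves])
    return DoseResponseCurve(
        category=curves[0].category,
        doses_gy=w @ np.stack([c.doses_gy for c in curves]),
        yields=w @ yields,
        std_errors=np.sqrt((w[:, None] ** 2 * ses ** 2).sum(axis=0)),
        n_histories=curves[0].n_histories)


def sc_ratio_at_unit_traversal(fit_simple: LQFit, fit_complex: LQFit,
                               nucleus: NucleusGeometry, beam: IonBeam
                               ) -> float:
    """Simple:complex exchange ratio at the dose giving one mean traversal.

    Solves λ(D₁) = 1 (λ is linear in dose) and evaluates both LQ fits there.
    """
    lam_per_gy = mean_traversals(nucleus, beam, 1.0)
    d1 = 1.0 / lam_per_gy
    y_c = fit_complex.predict(d1)
    if y_c == 0:
        raise ZeroDivisionError(
            "complex-exchange yield is zero at the unit-traversal dose; "
            "the s:c ratio is undefined")
    return fit_simple.predict(d1) / y_c


def traversal_report(geometries: list[NucleusGeometry],
                  beams: list[IonBeam]) -> pd.DataFrame:
    """Geometry table: semi-axes, irradiated area A, volume V, and the mean
    nuclear traversals per Gy for each beam."""
    rows = []
    for nuc in geometries:
        row = {
            "x_um": nuc.semi_axis_x,
            "y_um": nuc.semi_axis_y,
            "z_um": nuc.semi_axis_z,
            "A_um2": nuc.projected_area_um2("z"),
            "V_um3": nuc.volume_um3,
        }
        for b in beams:
            row[f"{b.species}_{b.energy_mev_u:g}"] = mean_traversals(
                nuc, dc_replace(b, axis="z"), 1.0)
        rows.append(row)
    return pd.DataFrame(rows)
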