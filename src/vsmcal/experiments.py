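"""The three computational experiments: mitochondrial-calcium bifurcation
scan, elevated-calcium reference run with clearance bookkeeping, and the
flux-rescaling sweep, plus the back-of-envelope tissue calculation.

All experiments start from the calibrated resting state and are fully
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import CA_MIT_REST
from .oscillation import OscillationSummary, detect_oscillation
from .params import ParameterSet
from .simulate import SimulationError, Trajectory, simulate
from .state import CellState

__all__ = ["BifurcationScan", "SweepResult", "hopf_scan", "reference_run",
           "alpha_sweep", "tissue_envelope"]

T_RUN = 1800.0              # s, the 30-minute horizon of the study
CA_MIT_ELEVATED = 0.25      # uM, the reference elevated matrix calcium
CLASSIFY_WINDOW = 600.0     # s, trailing window used for classification
OUTPUT_DT = 0.25            # s, sampling interval for analysis


@dataclass(frozen=True)
class BifurcationScan:
    ca_mit: np.ndarray                  # uM grid (including refinements)
    summaries: list                     # OscillationSummary per point
    threshold: float | None             # uM, onset of sustained oscillation
    envelope_min: np.ndarray            # post-transient min of Ca_cyt
    envelope_max: np.ndarray            # post-transient max of Ca_cyt

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for x, s, lo, hi in zip(self.ca_mit, self.summaries,
                                self.envelope_min, self.envelope_max):
            rows.append({
                "Ca_mit": x, "oscillatory": s.oscillatory,
                "amplitude": s.amplitude,
                "dominant_period": s.dominant_period,
                "Ca_cyt_mean": s.period_averaged.get("Ca_cyt", np.nan),
                "Ca_cyt_min": lo, "Ca_cyt_max": hi,
            })
        return pd.DataFrame(rows).sort_values("Ca_mit", ignore_index=True)


@dataclass(frozen=True)
class SweepResult:
    table: pd.DataFrame = field(repr=False)
    ca_mit: float = CA_MIT_ELEVATED

    @property
    def inward_fraction(self) -> float:
        """Fraction of successful cells with net inward (negative)
        period-averaged mitochondria->cytosol flux at the 30-minute mark."""
        ok = self.table[self.table["success"]]
        return float((ok["J_mit_avg"] < 0).mean())

    @property
    def oscillatory_fraction(self) -> float:
        ok = self.table[self.table["success"]]
        return float(ok["oscillatory"].mean())


def _classify(traj: Trajectory) -> OscillationSummary:
    """Classification on the trailing window (hysteresis-safe near onset)."""
    return detect_oscillation(
        traj, analysis_window=CLASSIFY_WINDOW,
        observables=("Ca_cyt", "J_mit_to_cyt", "J_ecs_to_cyt", "tension"))


def hopf_scan(params: ParameterSet, baseline: CellState,
              ca_mit_range: tuple = (0.1, 0.5), n_points: int = 9,
              refine: bool = True, refine_width: float = 0.005,
              t_max: float = T_RUN) -> BifurcationScan:
    """Locate the onset of sustained oscillations over a Ca_mit grid.

    Simulates ``t_max`` seconds from the calibrated rest state at each grid
    point; with ``refine``, bisects the first quiescent->oscillatory bracket
    down to ``refine_width``.  The threshold is the bracket midpoint, or
    None when the classification never changes sign on the grid.
    """
    lo, hi = ca_mit_range
    if not 0.0 < lo < hi:
        raise ValueError("ca_mit_range must be an increasing positive pair")
    grid = list(np.linspace(lo, hi, n_points))
    results: dict[float, tuple] = {}

    def run(x: float):
        if x not in results:
            traj = simulate(baseline, params.replace(Ca_mit=x), t_max,
                            output_dt=OUTPUT_DT)
            s = _classify(traj)
            sel = traj.times >= s.transient_end
            results[x] = (s, float(traj.Ca_cyt[sel].min()),
                          float(traj.Ca_cyt[sel].max()))
        return results[x][0]

    flags = [run(x).oscillatory for x in grid]
    threshold = None
    bracket = None
    for a, b, fa, fb in zip(grid, grid[1:], flags, flags[1:]):
        if not fa and fb:
            bracket = (a, b)
            break
    if bracket is not None:
        a, b = bracket
        if refine:
            while b - a > refine_width:
                m = 0.5 * (a + b)
                if run(m).oscillatory:
                    b = m
                else:
                    a = m
        threshold = 0.5 * (a + b)

    xs = np.array(sorted(results))
    summaries = [results[x][0] for x in xs]
    env_min = np.array([results[x][1] for x in xs])
    env_max = np.array([results[x][2] for x in xs])
    return BifurcationScan(ca_mit=xs, summaries=summaries,
                           threshold=threshold,
                           envelope_min=env_min, envelope_max=env_max)


def reference_run(params: ParameterSet, baseline: CellState,
                  ca_mit: float = CA_MIT_ELEVATED,
                  t_max: float = T_RUN) -> tuple[Trajectory, dict]:
    """The elevated-matrix-calcium time course and its clearance report."""
    p = params.replace(Ca_mit=ca_mit)
    traj = simulate(baseline, p, t_max, output_dt=OUTPUT_DT)
    summary = _classify(traj)
    sel = traj.times >= summary.transient_end
    report = {
        "ca_mit": ca_mit,
        "t_max": t_max,
        "Ca_sink_final": float(traj.column("Ca_sink")[-1]),
        "Ca_source_final": float(traj.column("Ca_source")[-1]),
        "tension_min": float(traj.tension[sel].min()),
        "tension_max": float(traj.tension[sel].max()),
        "atp_cumulative": (params.protons_per_Ca / params.protons_per_ATP
                           * float(traj.column("Ca_source")[-1])),
        "oscillation": summary.to_dict(),
    }
    return traj, report


def alpha_sweep(params: ParameterSet, baseline: CellState,
                points_per_axis: int = 7,
                ca_mit: float = CA_MIT_ELEVATED,
                t_max: float = T_RUN) -> SweepResult:
    """Rescale the three compartment aggregates on a log-uniform grid.

    Each cell multiplies (J_er->cyt, J_mit->cyt, J_ecs->cyt) by its
    (alpha_er, alpha_mit, alpha_pm) in [0.1, 10], runs ``t_max`` seconds from
    the calibrated rest state (which every rescaling preserves), classifies
    oscillation on the trailing window and records the period-averaged
    boundary fluxes there.  Failed cells are flagged, not fatal.
    """
    alphas = np.logspace(-1.0, 1.0, points_per_axis)
    rows = []
    for ae in alphas:
        for am in alphas:
            for ap in alphas:
                p = params.replace(Ca_mit=ca_mit, alpha_er=ae,
                                   alpha_mit=am, alpha_pm=ap)
                row = {"alpha_er": ae, "alpha_mit": am, "alpha_pm": ap,
                       "success": True, "oscillatory": False,
                       "amplitude": np.nan, "dominant_period": np.nan,
                       "J_mit_avg": np.nan, "J_ecs_avg": np.nan}
                try:
                    traj = simulate(baseline, p, t_max, output_dt=OUTPUT_DT)
                    s = _classify(traj)
                    row.update(
                        oscillatory=s.oscillatory, amplitude=s.amplitude,
                        dominant_period=(np.nan if s.dominant_period is None
                                         else s.dominant_period),
                        J_mit_avg=s.period_averaged["J_mit_to_cyt"],
                        J_ecs_avg=s.period_averaged["J_ecs_to_cyt"],
                    )
                except SimulationError:
                    row["success"] = False
                rows.append(row)
    return SweepResult(table=pd.DataFrame(rows), ca_mit=ca_mit)


def tissue_envelope(params: ParameterSet, ecs_fraction: float = 0.2,
                    cell_fraction: float = 0.8, ecs_conc: float = 1300.0,
                    conc_drop: float = 0.1, ecs_volume_drop: float = 0.5,
                    dilution_factor: float | None = None) -> dict:
    """Acute-phase tissue bookkeeping (no simulation).

    ``transfer_percent``: share of the initial extracellular calcium content
    that moves into cells when the ECS concentration falls to ``conc_drop``
    of baseline while the ECS volume shrinks to ``ecs_volume_drop`` of
    baseline.  ``effective_load``: cytosol-referenced concentration the cell
    compartment receives, ecs_conc * ecs_fraction / cell_fraction
    (equivalently ecs_conc / dilution_factor).  ``ecs_conc`` in uM.
    """
    if not 0.0 < cell_fraction < 1.0:
        raise ValueError("cell_fraction must lie in (0, 1)")
    if not 0.0 < ecs_fraction < 1.0 or ecs_fraction + cell_fraction > 1.0 + 1e-12:
        raise ValueError("volume fractions must lie in (0,1) and sum to <= 1")
    if ecs_conc < 0.0:
        raise ValueError("ecs_conc must be non-negative")
    transfer = 100.0 * (1.0 - conc_drop * ecs_volume_drop)
    if ecs_conc == 0.0:
        transfer = 0.0
    if dilution_factor is None:
        load = ecs_conc * ecs_fraction / cell_fraction
    else:
        load = ecs_conc / dilution_factor
    return {"transfer_percent": float(transfer),
            "effective_load": float(load)}
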