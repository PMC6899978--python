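"""Design evaluation: per-pulse metrics, cross-GIRF comparisons, sweeps.

The headline metrics per pulse are the maximal refocusing-profile
deviation (``max_es``: |b|^2 from 0 out-of-slice and from 1 in-slice,
over both domains, transition bands excluded), the maximal in-slice phase
deviation from the per-slice mean (``max_ep_rad``), the global SAR
estimate and the pulse duration.  Evaluation can use a different transfer
function than the one the pulse was designed with, which quantifies the
cost of a design/hardware mismatch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bloch import refocusing_profile, simulate
from .girf import TransferFunction, apply_girf
from .objective import (DesignProblem, phase_violations, sar_estimate)
from .waveforms import GradientWaveform, RFWaveform, TimeGrid


@dataclass
class Metrics:
    """Table-style evaluation metrics of one pulse."""

    t_ms: float
    max_es: float
    max_ep_rad: float
    sar_w_per_kg: float
    design_girf: str = "Hi"
    eval_girf: str = "Hi"

    def as_dict(self) -> dict:
        return {
            "T_ms": self.t_ms,
            "max_es": self.max_es,
            "max_ep_rad": self.max_ep_rad,
            "SARe_W_per_kg": self.sar_w_per_kg,
            "design_girf": self.design_girf,
            "eval_girf": self.eval_girf,
        }


def evaluate_design(rf: RFWaveform, grad: GradientWaveform, grid: TimeGrid,
                    problem: DesignProblem,
                    eval_girf: TransferFunction | None = None,
                    design_label: str = "Hi") -> Metrics:
    """Filter the gradient with the evaluation transfer function, simulate,
    and extract the metrics."""
    if eval_girf is None:
        g_real = grad.gs
        label = "Hi"
    else:
        g_real = apply_girf(grad, eval_girf, grid)
        label = eval_girf.label
    prof = simulate(rf, g_real, grid, problem.space)
    mag, phase = refocusing_profile(prof)
    in_mask, out_mask, _ = problem.domains()
    dev_out = float(np.max(mag[out_mask])) if np.any(out_mask) else 0.0
    dev_in = float(np.max(1.0 - mag[in_mask])) if np.any(in_mask) else 0.0
    pv = phase_violations(phase, problem.spec, problem.bounds, problem.space)
    max_ep = float(max(np.max(v) for v in pv)) + problem.bounds.e_p
    return Metrics(
        t_ms=grid.duration * 1e3,
        max_es=max(dev_out, dev_in),
        max_ep_rad=max_ep,
        sar_w_per_kg=sar_estimate(rf, grid, problem.sar),
        design_girf=design_label,
        eval_girf=label,
    )


def cross_girf_matrix(designs: dict, girfs: dict,
                      problem: DesignProblem) -> list[Metrics]:
    """Metrics for every (design, evaluation transfer function) pair.

    ``designs`` maps a label to ``(rf, grad, grid)``; ``girfs`` maps a
    label to a :class:`TransferFunction` or None for the ideal response.
    """
    table = []
    for dlabel, (rf, grad, grid) in designs.items():
        for _, tf in girfs.items():
            table.append(evaluate_design(rf, grad, grid, problem, tf,
                                         design_label=dlabel))
    return table


def metrics_table_csv(rows: list[Metrics]) -> str:
    """Render metrics as CSV with the customary column order."""
    lines = ["design_girf,eval_girf,max_es,max_ep_rad,SARe_W_per_kg,T_ms"]
    for m in rows:
        lines.append(f"{m.design_girf},{m.eval_girf},{m.max_es:.6g},"
                     f"{m.max_ep_rad:.6g},{m.sar_w_per_kg:.6g},{m.t_ms:.6g}")
    return "\n".join(lines) + "\n"


def parameter_sweep(cases: list[dict], base: dict,
                    solve: bool = False) -> list[dict]:
    """PINS (and optionally optimized) metrics over a parameter grid.

    ``cases`` is a list of parameter overrides applied to ``base``
    (keys: mb, thk, fov, tbwp, and the hardware/bound entries accepted by
    :func:`girfpulse.config.make_problem`).  Failures are recorded per
    cell and the sweep continues.
    """
    from .config import make_problem, pins_initial

    rows = []
    for case in cases:
        params = dict(base)
        params.update(case)
        row = dict(case)
        try:
            problem, hw, tau = make_problem(params)
            rf, grad, grid, _ = pins_initial(params, problem)
            m = evaluate_design(rf, grad, grid, problem, problem.girf,
                                design_label="PINS")
            row["pins_T_ms"] = grid.duration * 1e3
            row["pins_max_es"] = m.max_es
            row["pins_SARe"] = m.sar_w_per_kg
            if solve:
                from .optimizer import solve_time_optimal
                from .waveforms import ControlVector
                x0 = ControlVector(rf.r, rf.theta, grad.s, grid)
                result = solve_time_optimal(problem, x0)
                row["opt_T_ms"] = result.duration_ms
                mo = evaluate_design(result.rf, result.grad, result.grid,
                                     problem, problem.girf)
                row["opt_max_es"] = mo.max_es
        except Exception as exc:  # per-cell failure, sweep continues
            row["error"] = str(exc)
        rows.append(row)
    return rows
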