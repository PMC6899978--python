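"""Projected quasi-Newton lower level and bilevel minimum-duration search.

For a fixed pulse duration the penalized cost is minimized over the
box-constrained controls with limited-memory BFGS (projection handled by
the box bounds of the solver); every 20 iterations the penalty weights are
re-balanced, and the penalty exponent is doubled when the inner iteration
stagnates.  The outer level shrinks the duration geometrically while the
lower level stays feasible, then bisects in the number of raster samples
between the last feasible and the first infeasible duration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize

from .adjoint import cost_and_gradient
from .objective import (DesignProblem, PenaltyState, adapt_weights,
                        continue_p, max_violations, sar_estimate)
from .waveforms import (ControlVector, GradientWaveform, RFWaveform,
                        TimeGrid, integrate_slew, project_controls)


class InfeasibleInitialError(RuntimeError):
    """The lower-level solve at the initial duration did not reach
    feasibility; fix the initializer (or relax the profile bounds)."""


@dataclass
class SolverOptions:
    """Tunable solver parameters (documented defaults)."""

    lbfgs_memory: int = 20
    max_rounds: int = 30           # rounds of `adapt_every` inner iterations
    adapt_every: int = 20
    ls_max: int = 40
    shrink_rho: float = 0.97
    p_max: int = 32
    tol_violation: float = 1e-3
    tol_decrease: float = 1e-6
    stagnation_decrease: float = 1e-5


@dataclass
class SolveReport:
    """History of one fixed-duration solve."""

    final_penalty: object = None
    iterations: int = 0
    rounds: int = 0
    final_cost: float = np.nan
    breakdown: dict = field(default_factory=dict)
    violations: dict = field(default_factory=dict)
    cost_history: list = field(default_factory=list)
    p_history: list = field(default_factory=list)
    weight_history: list = field(default_factory=list)
    converged: bool = False


@dataclass
class DesignResult:
    """Optimized waveforms with their design-time metadata."""

    rf: RFWaveform
    grad: GradientWaveform
    grid: TimeGrid
    problem: DesignProblem
    report: SolveReport
    accepted_durations: list = field(default_factory=list)
    solve_reports: list = field(default_factory=list)

    @property
    def duration_ms(self) -> float:
        return self.grid.duration * 1e3


def _scales(problem: DesignProblem) -> tuple[float, float, float]:
    return problem.hw.rmax, 1.0, problem.hw.smax


def solve_fixed_T(problem: DesignProblem, x0: ControlVector,
                  pen0: PenaltyState | None = None,
                  options: SolverOptions | None = None):
    """Minimize the penalized cost at fixed duration.

    Returns ``(x, report)``.  The controls are optimized in units scaled
    by the hardware bounds so the quasi-Newton model is well conditioned;
    in real-valued mode the RF phase entries are frozen at their initial
    {0, pi} pattern by degenerate box bounds.
    """
    opts = options or SolverOptions()
    pen = pen0 if pen0 is not None else PenaltyState()
    pen = replace(pen, adapt_every=opts.adapt_every, p_max=opts.p_max)
    grid = x0.grid
    n = grid.n_intervals
    sr, st, ss = _scales(problem)
    x = project_controls(x0, problem.hw)

    if problem.real_valued:
        # optimize the signed real amplitude directly (phase frozen at 0;
        # a negative amplitude stands for phase pi), so sub-pulse signs
        # can flip continuously through zero during the optimization
        signed = x.r * np.cos(x.theta)
        x = ControlVector(signed, np.zeros(n), x.s, grid)
        r_bounds = [(-1.0, 1.0)] * n
        theta_bounds = [(0.0, 0.0)] * n
    else:
        r_bounds = [(0.0, 1.0)] * n
        theta_bounds = [(-np.pi, np.pi)] * n
    bounds = (r_bounds + theta_bounds + [(-1.0, 1.0)] * n)
    scale = np.concatenate([np.full(n, sr), np.full(n, st), np.full(n, ss)])

    report = SolveReport()

    pen_box = [pen]
    fscale_box = [1.0]

    def fun(u):
        xv = ControlVector.unpack(u * scale, grid)
        bd, g = cost_and_gradient(xv, problem, pen_box[0])
        fs = fscale_box[0]
        return bd.total / fs, g.pack() * scale / fs

    u = x.pack() / scale
    stalled = 0
    prev_max_viol = np.inf
    for rnd in range(opts.max_rounds):
        pen_box[0] = pen
        j_start = fun(u)[0] * fscale_box[0]
        # rescale so the line search operates on an O(1) objective
        fscale_box[0] = max(abs(j_start), 1e-300)
        res = minimize(fun, u, jac=True, method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": opts.adapt_every,
                                "maxcor": opts.lbfgs_memory,
                                "maxls": opts.ls_max,
                                "ftol": 1e-15, "gtol": 1e-15})
        u = res.x
        j_now = float(res.fun) * fscale_box[0]
        fscale_box[0] = 1.0
        report.iterations += int(res.nit)
        report.rounds += 1
        xv = ControlVector.unpack(u * scale, grid)
        viol = max_violations(xv, problem)
        report.cost_history.append(j_now)
        report.p_history.append(pen.p)
        report.weight_history.append({
            "mu_rf": pen.mu_rf, "mu_g": pen.mu_g, "mu_out": pen.mu_out,
            "mu_in": pen.mu_in, "mu_p": pen.mu_p})
        max_viol = max(viol["magnitude"], viol["phase"], viol["gradient"])
        feasible = max_viol <= opts.tol_violation
        decrease = abs(j_start - j_now) / max(abs(j_start), 1e-300)
        stagnated = decrease < opts.stagnation_decrease or res.nit == 0
        stalled = stalled + 1 if res.nit == 0 else 0
        if feasible and (decrease < opts.tol_decrease
                         or res.nit < opts.adapt_every):
            report.converged = True
            break
        if stalled >= 3:
            break  # no progress possible at this penalty scale
        sar_now = sar_estimate(xv.r, grid, problem.sar)
        pen = adapt_weights(pen, viol, problem.bounds, sar_now, problem.sar)
        # sharpen toward max-violation control only once the residuals are
        # at the scale of the bounds, otherwise large p stalls the search
        near = max_viol <= min(problem.bounds.e_in, problem.bounds.e_out)
        viol_stuck = max_viol > 0.9 * prev_max_viol
        if near and (stagnated or viol_stuck) and pen.p < pen.p_max:
            pen = continue_p(pen)
        prev_max_viol = max_viol

    xv = ControlVector.unpack(u * scale, grid)
    if problem.real_valued:
        # back to the canonical (amplitude >= 0, phase in {0, pi}) form
        xv = ControlVector(np.abs(xv.r),
                           np.where(xv.r < 0, np.pi, 0.0), xv.s, grid)
    xv = project_controls(xv, problem.hw)
    bd, _ = cost_and_gradient(xv, problem, pen)
    report.final_cost = bd.total
    report.breakdown = bd.as_dict()
    report.violations = max_violations(xv, problem)
    report.final_penalty = pen
    return xv, report


def _is_feasible(report: SolveReport, tol: float) -> bool:
    v = report.violations
    return max(v["magnitude"], v["phase"], v["gradient"]) <= tol


def solve_time_optimal(problem: DesignProblem, x0: ControlVector,
                       pen0: PenaltyState | None = None,
                       options: SolverOptions | None = None) -> DesignResult:
    """Bilevel minimum-duration search.

    Solves at the initial duration (raising
    :class:`InfeasibleInitialError` if even that solve ends infeasible),
    then shrinks the sample count by ``shrink_rho`` while the re-solved
    problem stays feasible, and finally bisects between the last feasible
    and first infeasible counts down to a single raster sample.
    """
    from .waveforms import resample_controls

    opts = options or SolverOptions()
    tol = opts.tol_violation
    x_best, rep = solve_fixed_T(problem, x0, pen0, opts)
    rep_best = rep
    if not _is_feasible(rep, tol):
        raise InfeasibleInitialError(
            f"initial duration {x0.grid.duration * 1e3:.3f} ms did not reach "
            f"feasibility (violations {rep.violations}); fix the initializer")
    accepted = [x_best.grid.duration]
    reports = [rep]
    x_anchor = x_best  # first feasible solution; robust warm-start source

    def rescaled(src: ControlVector, n_intervals: int) -> ControlVector:
        grid_new = src.grid.with_intervals(n_intervals)
        x_init = resample_controls(src, grid_new,
                                   real_valued=problem.real_valued)
        # time-rescaling invariance of the spin dynamics: playing the same
        # pulse faster requires B1 and gradient scaled by 1/rho (slew by
        # 1/rho^2); the projection then clips whatever exceeds hardware,
        # which is exactly what the re-solve must repair
        rho = n_intervals / src.grid.n_intervals
        x_init = ControlVector(x_init.r / rho, x_init.theta,
                               x_init.s / rho ** 2, grid_new)
        return project_controls(x_init, problem.hw)

    def attempt(n_intervals: int):
        # warm-start from the last accepted solution; if that basin fails,
        # retry once from the initial-duration solution, whose larger
        # hardware margins tolerate the rescaling better
        x_try, rep_try = solve_fixed_T(problem, rescaled(x_best, n_intervals),
                                       pen0, opts)
        if not _is_feasible(rep_try, tol) and x_anchor is not x_best:
            x_alt, rep_alt = solve_fixed_T(
                problem, rescaled(x_anchor, n_intervals), pen0, opts)
            if _is_feasible(rep_alt, tol):
                return x_alt, rep_alt
        return x_try, rep_try

    n_feas = x_best.grid.n_intervals
    n_infeas = None
    while n_infeas is None:
        n_try = int(np.floor(n_feas * opts.shrink_rho))
        if n_try >= n_feas:
            n_try = n_feas - 1
        if n_try < 2:
            break
        x_try, rep_try = attempt(n_try)
        reports.append(rep_try)
        if _is_feasible(rep_try, tol):
            x_best, n_feas, rep_best = x_try, n_try, rep_try
            accepted.append(x_try.grid.duration)
        else:
            n_infeas = n_try
    while n_infeas is not None and n_feas - n_infeas > 1:
        n_try = (n_feas + n_infeas) // 2
        x_try, rep_try = attempt(n_try)
        reports.append(rep_try)
        if _is_feasible(rep_try, tol):
            x_best, n_feas, rep_best = x_try, n_try, rep_try
            accepted.append(x_try.grid.duration)
        else:
            n_infeas = n_try

    grad = integrate_slew(x_best.s, x_best.grid)
    if problem.real_valued:
        rf = RFWaveform.from_signed_real(x_best.r * np.cos(x_best.theta))
    else:
        rf = RFWaveform(x_best.r, x_best.theta)
    return DesignResult(rf, grad, x_best.grid, problem, rep_best,
                        accepted_durations=accepted, solve_reports=reports)
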