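"""Independent verification oracles for the ODE engine.

Two deliberately simple integrators cross-check the adaptive solver:

* a closed-form one-compartment solution for piecewise-constant zero-order
  input with first-order elimination, exact per segment;
* an explicit fixed-step RK4 integrator driven by the same model
  right-hand side, stepping segment by segment so input discontinuities
  fall on step boundaries, with automatic step halving when instability
  is detected.

Both are test instruments only; the production path is the adaptive
stiff-capable solver in :mod:`alpbtk.pbtk_core`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class OracleSpec:
    kind: str = "fixed_step"      # or "analytic_1cmt"
    dt: float = 0.25              # days, fixed_step only
    tolerance: float = 1e-3       # relative

    def __post_init__(self):
        if self.dt <= 0 or self.tolerance <= 0:
            raise ValueError("dt and tolerance must be positive")


def analytic_one_compartment(k_el: float, segments, a0: float, times) -> np.ndarray:
    """Exact amount A(t) for zero-order input segments and first-order loss.

    ``segments`` is a list of (t0, t1, rate) with contiguous coverage from
    times[0]; within each, A(t) = A0 e^{-k dt} + (R/k)(1 - e^{-k dt}).
    """
    if k_el <= 0:
        raise ValueError("k_el must be positive")
    times = np.asarray(times, dtype=float)
    out = np.empty_like(times)
    a = a0
    idx = 0
    for t0, t1, rate in segments:
        while idx < times.size and times[idx] <= t1 + 1e-12:
            dt = times[idx] - t0
            e = math.exp(-k_el * dt)
            out[idx] = a * e + rate / k_el * (1.0 - e)
            idx += 1
        e = math.exp(-k_el * (t1 - t0))
        a = a * e + rate / k_el * (1.0 - e)
    if idx < times.size:
        raise ValueError("requested times extend past the input segments")
    return out


def fixed_step_oracle(simulator, individual=None, dt: float = 0.25, grid=None):
    """Explicit RK4 integration of the simulator's own right-hand side.

    Returns (grid_times, amounts matrix) matching SimulationResult layout.
    If the trajectory blows up (non-finite or runaway norm), the step is
    halved and the whole integration restarted, down to dt = 1/512 day.
    """
    from .pbtk_core import COMPARTMENTS

    grid = simulator.default_grid() if grid is None else np.asarray(grid, dtype=float)
    s = getattr(individual, "sc_mult", 1.0)
    mults = (
        getattr(individual, "oral_f_mult", 1.0),
        getattr(individual, "gfr_mult", 1.0),
        getattr(individual, "dist_mult", 1.0),
        s,
    )
    segments = simulator._segments(s)
    p = simulator.params
    y0 = np.array([p.birth_amounts.get(c, 0.0) for c in COMPARTMENTS], dtype=float)
    bound = max(1.0, 1e6 * (y0.sum() + 1e4))

    while dt >= 1.0 / 512.0:
        seg_const = [0.0, 0.0]
        rhs, _ = simulator._make_rhs(mults, seg_const)
        y = y0.copy()
        out = {0.0: y.copy()}
        ok = True
        for t0, t1, tier, sc_rate in segments:
            seg_const[0], seg_const[1] = tier, sc_rate
            inner = grid[(grid > t0 + 1e-12) & (grid < t1 - 1e-12)]
            nodes = np.concatenate(([t0], inner, [t1]))
            for a, b in zip(nodes[:-1], nodes[1:]):
                nstep = max(1, int(math.ceil((b - a) / dt)))
                h = (b - a) / nstep
                t = a
                with np.errstate(over="ignore", invalid="ignore"):
                    for _ in range(nstep):
                        k1 = rhs(t, y)
                        k2 = rhs(t + h / 2, y + h / 2 * k1)
                        k3 = rhs(t + h / 2, y + h / 2 * k2)
                        k4 = rhs(t + h, y + h * k3)
                        y = y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
                        t += h
                        if not np.abs(y).max() < bound:  # catches NaN too
                            ok = False
                            break
                if not ok:
                    break
                out[b] = y.copy()
            if not ok:
                break
        if ok:
            tgrid = np.array(sorted(set(grid) & set(out) | {0.0}))
            Y = np.array([out[t] for t in tgrid]).T
            return tgrid, Y
        dt /= 2.0
    raise RuntimeError("fixed-step oracle unstable even at the smallest step")
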