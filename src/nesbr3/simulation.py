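"""Monte-Carlo study of the ML estimators: average estimates, bias, MSE.

For each design cell (sample size x indeterminacy endpoint) the harness
draws ``reps`` samples by inverse transform, refits the model with the
cell's indeterminacy held at its true value, and aggregates

    AE   = sum(v_hat_i) / reps
    Bias = AE - v
    MSE  = sum((v_hat_i - v)**2) / reps

per parameter.  Per-replicate seeds come from a spawned counter-based
stream so every cell is independently reproducible; failed fits are
excluded from the aggregates and counted explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import NesBr3Params, rvs
from .errors import ConvergenceError, ParameterError
from .estimation import DEFAULT_SEED, FitOptions, fit_model

__all__ = ["SimDesign", "CellSummary", "SimSummary", "run_simulation", "summarize_to_table"]

_PARAM_NAMES = ("lam", "theta")
_STATS = ("ae", "bias", "mse")

# light optimizer profile: heuristic start + small grid, cheap enough for
# thousands of refits while still avoiding the worst local optima
_SIM_FIT_OPTS = FitOptions(grid_points=2, grid_halfwidth=1.0, compute_se=False)


@dataclass(frozen=True)
class SimDesign:
    """Simulation design: sample sizes, replicate count, truth per endpoint."""

    n_values: tuple[int, ...]
    true_params: tuple[NesBr3Params, NesBr3Params]
    reps: int = 500
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if len(self.n_values) == 0:
            raise ParameterError("n_values must be non-empty")
        if any(int(n) < 2 for n in self.n_values):
            raise ParameterError("every sample size must be >= 2")
        if int(self.reps) < 1:
            raise ParameterError("reps must be >= 1")
        object.__setattr__(self, "n_values", tuple(int(n) for n in self.n_values))
        object.__setattr__(self, "reps", int(self.reps))


@dataclass(frozen=True)
class CellSummary:
    """Aggregates for one (n, endpoint) cell."""

    n: int
    endpoint: str  # 'lower' or 'upper'
    truth: NesBr3Params
    ae: dict[str, float]
    bias: dict[str, float]
    mse: dict[str, float]
    failures: int
    reps: int
    estimates: np.ndarray = field(repr=False)  # (successes, 2)


@dataclass(frozen=True)
class SimSummary:
    design: SimDesign
    cells: tuple[CellSummary, ...]

    def cell(self, n: int, endpoint: str) -> CellSummary:
        for c in self.cells:
            if c.n == n and c.endpoint == endpoint:
                return c
        raise KeyError(f"no cell for n={n}, endpoint={endpoint!r}")


def _run_cell(
    n: int,
    endpoint: str,
    truth: NesBr3Params,
    reps: int,
    seeds,
    fit_opts: FitOptions,
) -> CellSummary:
    estimates = []
    failures = 0
    for ss in seeds:
        rng = np.random.default_rng(ss)
        x = rvs(n, truth, rng)
        try:
            fit = fit_model("nesbr3", x, opts=fit_opts, indet=truth.indet)
        except ConvergenceError:
            failures += 1
            continue
        estimates.append([fit.estimates["lam"], fit.estimates["theta"]])
    est = np.asarray(estimates, dtype=float).reshape(-1, 2)
    if est.shape[0] == 0:
        return CellSummary(
            n=n, endpoint=endpoint, truth=truth,
            ae={}, bias={}, mse={}, failures=failures, reps=reps, estimates=est,
        )
    truth_vec = np.array([truth.lam, truth.theta])
    ae = est.mean(axis=0)
    bias = ae - truth_vec
    mse = ((est - truth_vec) ** 2).mean(axis=0)
    return CellSummary(
        n=n,
        endpoint=endpoint,
        truth=truth,
        ae=dict(zip(_PARAM_NAMES, ae.tolist())),
        bias=dict(zip(_PARAM_NAMES, bias.tolist())),
        mse=dict(zip(_PARAM_NAMES, mse.tolist())),
        failures=failures,
        reps=reps,
        estimates=est,
    )


def run_simulation(design: SimDesign, fit_opts: FitOptions | None = None) -> SimSummary:
    """Run the full design; deterministic for a given design (incl. seed)."""
    fit_opts = fit_opts or _SIM_FIT_OPTS
    root = np.random.SeedSequence(design.seed)
    cells = []
    # one spawned child stream per (n, endpoint) cell, then one per replicate,
    # so any cell can be re-run in isolation
    cell_specs = [
        (n, ep, truth)
        for n in design.n_values
        for ep, truth in zip(("lower", "upper"), design.true_params)
    ]
    children = root.spawn(len(cell_specs))
    for (n, ep, truth), child in zip(cell_specs, children):
        rep_seeds = child.spawn(design.reps)
        cells.append(_run_cell(n, ep, truth, design.reps, rep_seeds, fit_opts))
    return SimSummary(design=design, cells=tuple(cells))


def summarize_to_table(summary: SimSummary):
    """Flatten a :class:`SimSummary` into one row per sample size.

    Columns are ``<stat>_<param>_<endpoint>`` (2 params x 3 statistics x
    2 endpoints = 12 value columns) plus ``n`` and the failure counts.
    """
    import pandas as pd

    if not summary.cells:
        raise ParameterError("summary has no cells")
    rows = []
    for n in summary.design.n_values:
        row: dict[str, float] = {"n": n}
        for ep in ("lower", "upper"):
            c = summary.cell(n, ep)
            for stat in _STATS:
                for name in _PARAM_NAMES:
                    row[f"{stat}_{name}_{ep}"] = getattr(c, stat).get(name, float("nan"))
            row[f"failures_{ep}"] = c.failures
        rows.append(row)
    return pd.DataFrame(rows)
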