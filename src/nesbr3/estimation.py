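"""Maximum-likelihood fitting and information-criterion model selection.

The neutrosophic fit is a pair of classical two-parameter fits: the lower
endpoint of the indeterminacy interval is fitted to the lower-endpoint
data and the upper endpoint to the upper-endpoint data, each with the
classical (I = 0) Burr-III likelihood.  Comparator models (Burr-XII,
Weibull, Nadarajah-Haghighi) are fitted to the lower-endpoint data.

Optimization is derivative-free simplex over log-parameters from a 4x4
log-grid of starts around a quantile/scale-matching heuristic, followed by
a quasi-Newton polish; published score equations for this family contain
typos and are not used.  Standard errors come from the inverse observed
information (central-difference Hessian at the MLE).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import approx_fprime, minimize

from .core import IndeterminacyInterval, NesBr3Params, log_pdf
from .datasets import NeutroSample
from .errors import (
    ConvergenceError,
    DataError,
    ParameterError,
    UndefinedCriterionError,
)

__all__ = [
    "ICSet",
    "FitResult",
    "FitOptions",
    "information_criteria",
    "neg_loglik_nesbr3",
    "fit_nesbr3",
    "fit_comparator",
    "fit_model",
    "standard_errors",
    "model_comparison",
    "MODELS",
]

DEFAULT_SEED = 20240511


@dataclass(frozen=True)
class ICSet:
    """Akaike, corrected-Akaike, Bayesian and Hannan-Quinn criteria."""

    aic: float
    caic: float
    bic: float
    hqic: float


def information_criteria(loglik: float, n: int, k: int) -> ICSet:
    """Standard IC definitions from a single log-likelihood.

    AIC = 2k - 2l; CAIC = AIC + 2k(k+1)/(n-k-1); BIC = k ln n - 2l;
    HQIC = 2k ln(ln n) - 2l.
    """
    if n <= k + 1:
        raise UndefinedCriterionError(
            f"CAIC undefined for n <= k + 1 (n={n}, k={k})"
        )
    aic = 2.0 * k - 2.0 * loglik
    return ICSet(
        aic=aic,
        caic=aic + 2.0 * k * (k + 1) / (n - k - 1),
        bic=k * math.log(n) - 2.0 * loglik,
        hqic=2.0 * k * math.log(math.log(n)) - 2.0 * loglik,
    )


@dataclass(frozen=True)
class FitOptions:
    """Controls the multi-start optimizer.

    ``grid_points`` is the per-axis size of the log-grid of starting values
    (0 disables the grid, keeping only the heuristic start — useful inside
    large simulations).  ``jitter_starts`` adds that many random log-space
    perturbations of the heuristic start, seeded by ``seed``.
    """

    grid_points: int = 4
    grid_halfwidth: float = 1.5
    jitter_starts: int = 0
    seed: int = DEFAULT_SEED
    ftol: float = 1e-10
    xtol: float = 1e-8
    max_iter: int = 5000
    grad_tol: float = 1e-3
    compute_se: bool = True


@dataclass(frozen=True)
class FitResult:
    """One converged two-parameter ML fit."""

    model: str
    estimates: dict[str, float]
    std_errors: dict[str, float] | None
    loglik: float
    n: int
    k: int
    ics: ICSet
    converged: bool
    n_starts_used: int
    indet: float = 0.0
    label: str = ""

    @property
    def params(self) -> np.ndarray:
        return np.array(list(self.estimates.values()))


# --- model registry ---------------------------------------------------------


def _nll_nesbr3(params: np.ndarray, x: np.ndarray, indet: float = 0.0) -> float:
    lam, theta = params
    p = NesBr3Params(lam, theta, indet)
    return -float(np.sum(log_pdf(x, p)))


def _nll_burr12(params: np.ndarray, x: np.ndarray) -> float:
    c, kappa = params
    lx = np.log(x)
    return -float(
        np.sum(np.log(c) + np.log(kappa) + (c - 1.0) * lx - (kappa + 1.0) * np.logaddexp(0.0, c * lx))
    )


def _nll_weibull(params: np.ndarray, x: np.ndarray) -> float:
    a, b = params
    lx = np.log(x)
    return -float(np.sum(np.log(a) + np.log(b) + (b - 1.0) * lx - a * np.exp(b * lx)))


def _nll_nh(params: np.ndarray, x: np.ndarray) -> float:
    a, b = params
    g = np.log1p(b * x)
    return -float(np.sum(np.log(a) + np.log(b) + (a - 1.0) * g + 1.0 - np.exp(a * g)))


def _start_nesbr3(x: np.ndarray) -> np.ndarray:
    # quantile matching: theta from the interquartile spread at lam = 1,
    # then lam from the median
    q1, med, q3 = np.quantile(x, [0.25, 0.5, 0.75])
    denom = np.log(q1) - np.log(q3)
    theta = (np.log(3.0) - np.log(1.0 / 3.0)) / denom if denom < 0 else -1.0
    if not (0.05 < theta < 50):
        theta = 1.0
    lam = np.log(2.0) / np.log1p(med ** -theta)
    if not (np.isfinite(lam) and 1e-3 < lam < 1e3):
        lam = 1.0
    return np.array([lam, theta])


def _start_weibull(x: np.ndarray) -> np.ndarray:
    s = np.std(np.log(x))
    b = 1.2 / s if s > 0 else 1.0
    a = 1.0 / np.mean(x**b)
    return np.array([a, b])


def _start_nh(x: np.ndarray) -> np.ndarray:
    return np.array([1.0, 1.0 / np.mean(x)])


def _start_burr12(x: np.ndarray) -> np.ndarray:
    s = np.std(np.log(x))
    c = 1.0 / s if s > 0 else 1.0
    m = np.median(x)
    kappa = np.log(2.0) / np.log1p(m**c)
    if not (np.isfinite(kappa) and 1e-3 < kappa < 1e3):
        kappa = 1.0
    return np.array([c, kappa])


@dataclass(frozen=True)
class _ModelSpec:
    name: str
    param_names: tuple[str, str]
    nll: callable
    heuristic_start: callable


MODELS: dict[str, _ModelSpec] = {
    "nesbr3": _ModelSpec("nesbr3", ("lam", "theta"), _nll_nesbr3, _start_nesbr3),
    "burr12": _ModelSpec("burr12", ("c", "kappa"), _nll_burr12, _start_burr12),
    "weibull": _ModelSpec("weibull", ("a", "b"), _nll_weibull, _start_weibull),
    "nh": _ModelSpec("nh", ("alpha", "beta"), _nll_nh, _start_nh),
}


# --- generic multi-start MLE -------------------------------------------------


def _validate_sample(x) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise DataError("sample must be a non-empty 1-d array")
    if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
        raise DataError("sample values must be finite and strictly positive")
    return arr


def neg_loglik_nesbr3(sample, lam: float, theta: float, indet: float = 0.0) -> float:
    """Negative log-likelihood of the sample under the given parameters."""
    x = _validate_sample(sample)
    return _nll_nesbr3(np.array([float(lam), float(theta)]), x, indet)


def _safe_obj(nll, x, extra_args):
    def f(logp: np.ndarray) -> float:
        if np.any(np.abs(logp) > 50):
            return 1e12
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            val = nll(np.exp(logp), x, *extra_args)
        return val if np.isfinite(val) else 1e12

    return f


def _starting_points(spec: _ModelSpec, x: np.ndarray, opts: FitOptions) -> list[np.ndarray]:
    h = np.log(spec.heuristic_start(x))
    starts = [h]
    if opts.grid_points > 0:
        offs = np.linspace(-opts.grid_halfwidth, opts.grid_halfwidth, opts.grid_points)
        for da in offs:
            for db in offs:
                starts.append(h + np.array([da, db]))
    if opts.jitter_starts > 0:
        rng = np.random.default_rng(opts.seed)
        for _ in range(opts.jitter_starts):
            starts.append(h + rng.normal(scale=0.5, size=2))
    return starts


def fit_model(
    model: str,
    sample,
    opts: FitOptions | None = None,
    indet: float = 0.0,
    label: str = "",
) -> FitResult:
    """Multi-start ML fit of one registered model to a crisp sample."""
    if model not in MODELS:
        raise ParameterError(f"unknown model {model!r}; available: {sorted(MODELS)}")
    spec = MODELS[model]
    opts = opts or FitOptions()
    x = _validate_sample(sample)
    extra = (indet,) if model == "nesbr3" else ()
    obj = _safe_obj(spec.nll, x, extra)

    best = None
    starts = _starting_points(spec, x, opts)
    for s in starts:
        res = minimize(
            obj,
            s,
            method="Nelder-Mead",
            options=dict(xatol=opts.xtol, fatol=opts.ftol, maxiter=opts.max_iter),
        )
        if best is None or res.fun < best.fun:
            best = res
    # quasi-Newton polish on log-parameters
    polished = minimize(obj, best.x, method="BFGS", options=dict(gtol=1e-10, maxiter=500))
    if polished.fun <= best.fun:
        best = polished
    grad = approx_fprime(best.x, obj, 1e-7)
    converged = bool(np.isfinite(best.fun) and best.fun < 1e11 and np.linalg.norm(grad) < opts.grad_tol)
    if not np.isfinite(best.fun) or best.fun >= 1e11:
        raise ConvergenceError(
            f"{model}: no admissible optimum found after {len(starts)} starts",
            diagnostics={"starts": len(starts), "best_objective": float(best.fun)},
        )
    params = np.exp(best.x)
    estimates = dict(zip(spec.param_names, params.tolist()))
    loglik = -float(best.fun)
    ics = information_criteria(loglik, n=x.size, k=2)
    fit = FitResult(
        model=model,
        estimates=estimates,
        std_errors=None,
        loglik=loglik,
        n=int(x.size),
        k=2,
        ics=ics,
        converged=converged,
        n_starts_used=len(starts),
        indet=indet,
        label=label,
    )
    if opts.compute_se:
        fit = replace(fit, std_errors=standard_errors(fit, x))
    return fit


def standard_errors(fit: FitResult, sample) -> dict[str, float] | None:
    """SEs from the inverse observed information at the MLE.

    The Hessian of the negative log-likelihood is computed by central
    differences in the natural parameters with steps scaled to parameter
    magnitude; a non-positive-definite Hessian yields ``None`` with a
    warning rather than bogus numbers.
    """
    x = _validate_sample(sample)
    spec = MODELS[fit.model]
    extra = (fit.indet,) if fit.model == "nesbr3" else ()

    def f(params: np.ndarray) -> float:
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            return spec.nll(params, x, *extra)

    p = fit.params
    h = 1e-4 * np.maximum(np.abs(p), 1e-3)
    m = p.size
    H = np.empty((m, m))
    for i in range(m):
        for j in range(i, m):
            pp = p.copy()

            def f_at(di, dj):
                q = p.copy()
                q[i] += di
                q[j] += dj
                return f(q)

            H[i, j] = H[j, i] = (
                f_at(h[i], h[j]) - f_at(h[i], -h[j]) - f_at(-h[i], h[j]) + f_at(-h[i], -h[j])
            ) / (4.0 * h[i] * h[j])
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        warnings.warn("observed information is singular; standard errors unavailable", RuntimeWarning)
        return None
    diag = np.diag(cov)
    if np.any(diag <= 0) or not np.all(np.isfinite(diag)):
        warnings.warn(
            "observed information is not positive definite; standard errors unavailable",
            RuntimeWarning,
        )
        return None
    return dict(zip(spec.param_names, np.sqrt(diag).tolist()))


def fit_nesbr3(
    nsample: NeutroSample,
    indet: IndeterminacyInterval | None = None,
    opts: FitOptions | None = None,
) -> tuple[FitResult, FitResult]:
    """Fit the neutrosophic model: one classical Burr-III fit per endpoint.

    The lower (upper) endpoint result is the classical I = 0 fit to the
    lower (upper) endpoint data; the indeterminacy interval itself enters
    through the data construction, not through an extra Jacobian.
    """
    if len(nsample) == 0:
        raise DataError("sample is empty")
    indet = indet or nsample.indet
    lower = fit_model("nesbr3", nsample.lower, opts=opts, indet=0.0, label="lower")
    upper = fit_model("nesbr3", nsample.upper, opts=opts, indet=0.0, label="upper")
    return lower, upper


def fit_comparator(model: str, sample, opts: FitOptions | None = None) -> FitResult:
    """Fit one comparator model (burr12, weibull or nh) to a crisp sample."""
    if model not in ("burr12", "weibull", "nh"):
        raise ParameterError(
            f"comparator must be one of burr12, weibull, nh; got {model!r}"
        )
    return fit_model(model, sample, opts=opts)


# --- comparison report -------------------------------------------------------


@dataclass(frozen=True)
class ComparisonRow:
    model: str
    fit: object  # FitResult or (FitResult, FitResult) for the neutrosophic pair
    failed: bool = False
    message: str = ""


def _fmt_pair(lo: float, hi: float, nd: int = 3) -> str:
    return f"[{lo:.{nd}f}, {hi:.{nd}f}]"


def model_comparison(
    nsample: NeutroSample,
    models: tuple[str, ...] = ("nesbr3", "burr12", "weibull", "nh"),
    opts: FitOptions | None = None,
):
    """Fit all requested models and rank them by AIC.

    The neutrosophic model is reported as a [lower, upper] interval per
    quantity and ranked by its lower-endpoint AIC; comparators are fitted
    to the lower-endpoint data.  Ties are broken by BIC, then model name.

    Returns
    -------
    (rows, table) : (list of ComparisonRow, pandas.DataFrame)
        ``rows`` carry the full fit objects; ``table`` is a flat report
        with one row per model, ranked, suitable for CSV export.
    """
    import pandas as pd

    if len(models) < 1:
        raise ParameterError("at least one model is required")
    rows: list[ComparisonRow] = []
    for m in models:
        try:
            if m == "nesbr3":
                fit = fit_nesbr3(nsample, opts=opts)
            else:
                fit = fit_comparator(m, nsample.lower, opts=opts)
            rows.append(ComparisonRow(model=m, fit=fit))
        except ConvergenceError as exc:
            rows.append(ComparisonRow(model=m, fit=None, failed=True, message=str(exc)))

    def sort_key(row: ComparisonRow):
        if row.failed:
            return (1, float("inf"), float("inf"), row.model)
        f = row.fit[0] if isinstance(row.fit, tuple) else row.fit
        return (0, f.ics.aic, f.ics.bic, row.model)

    rows.sort(key=sort_key)

    records = []
    for rank, row in enumerate(rows, start=1):
        if row.failed:
            records.append(
                {"rank": None, "model": row.model, "failed": True, "note": row.message}
            )
            continue
        if isinstance(row.fit, tuple):
            lo, hi = row.fit
            names = list(lo.estimates)
            rec = {"rank": rank, "model": row.model, "failed": False, "note": ""}
            for name in names:
                rec[name] = _fmt_pair(lo.estimates[name], hi.estimates[name])
                if lo.std_errors and hi.std_errors:
                    rec[f"se_{name}"] = _fmt_pair(lo.std_errors[name], hi.std_errors[name])
            for ic in ("aic", "caic", "bic", "hqic"):
                rec[ic] = _fmt_pair(getattr(lo.ics, ic), getattr(hi.ics, ic))
            rec["loglik"] = _fmt_pair(lo.loglik, hi.loglik, nd=4)
        else:
            f = row.fit
            rec = {"rank": rank, "model": row.model, "failed": False, "note": ""}
            for name, val in f.estimates.items():
                rec[name] = f"{val:.4g}"
                if f.std_errors:
                    rec[f"se_{name}"] = f"{f.std_errors[name]:.4g}"
            for ic in ("aic", "caic", "bic", "hqic"):
                rec[ic] = f"{getattr(f.ics, ic):.3f}"
            rec["loglik"] = f"{f.loglik:.4f}"
        records.append(rec)
    return rows, pd.DataFrame(records)
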