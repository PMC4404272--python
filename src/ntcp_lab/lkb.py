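"""Lyman-Kutcher-Burman NTCP model with gEUD DVH reduction.

The model reduces each patient's dose-volume histogram to a single
generalized equivalent uniform dose

    gEUD = (sum_i v_i * d_i**(1/n)) ** n

and maps it to a complication probability through a probit dose-response

    NTCP = Phi(t),    t = (gEUD - D50) / (m * D50)

with D50 the uniform dose giving 50% complication probability, m the
inverse slope and n in (0, 1] the volume-effect exponent (n -> 0: serial
organ, max dose dominates; n = 1: parallel organ, mean dose).

Parameters are estimated by maximizing the Bernoulli log-likelihood of
the observed binary outcomes with a multistart Nelder-Mead simplex in an
unconstrained reparameterization (log D50, log m, logit n). Uncertainty
is quantified by fixed-nuisance profile-likelihood intervals,
iso-likelihood contours in the three parameter planes, an NTCP
confidence bundle, and bootstrap resampling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize, special, stats
from sklearn.base import BaseEstimator, ClassifierMixin

from .dvh_io import Cohort, CumulativeDVH, DifferentialDVH, cumulative_to_differential

__all__ = [
    "LKBParams",
    "LKBFitResult",
    "ProfileInterval",
    "ContourResult",
    "ConfidenceBundle",
    "BootstrapResult",
    "LKBProbitModel",
    "compute_geud",
    "lkb_ntcp",
    "cohort_log_likelihood",
    "fit_lkb",
    "profile_interval",
    "iso_likelihood_contour",
    "ntcp_confidence_bundle",
    "bootstrap_fit",
    "NonIdentifiableError",
    "ConvergenceError",
]

_NTCP_CLIP = 1e-12  # probability floor before taking logs

# admissible ranges for profile scans (physical / numerical bounds)
_PARAM_RANGES = {"d50": (1.0, 1e4), "m": (1e-4, 10.0), "n": (1e-6, 1.0)}

_DEFAULT_STARTS = tuple(
    (d50, m, n)
    for d50 in (60.0, 80.0, 100.0)
    for m in (0.2, 0.4)
    for n in (0.05, 0.2, 0.5)
)


class NonIdentifiableError(ValueError):
    """Cohort has only one outcome class; the dose-response is not identifiable."""


class ConvergenceError(RuntimeError):
    """No optimizer start converged."""


@dataclass(frozen=True)
class LKBParams:
    """LKB parameter triple (D50 [Gy], m, n)."""

    d50: float
    m: float
    n: float

    def __post_init__(self) -> None:
        if not self.d50 > 0:
            raise ValueError(f"d50 must be > 0 Gy, got {self.d50}")
        if not self.m > 0:
            raise ValueError(f"m must be > 0, got {self.m}")
        if not 0 < self.n <= 1:
            raise ValueError(f"n must be in (0, 1], got {self.n}")

    def as_array(self) -> np.ndarray:
        return np.array([self.d50, self.m, self.n])


@dataclass(frozen=True)
class LKBFitResult:
    params: LKBParams
    llh: float
    converged: bool
    n_evaluations: int
    starts: tuple[tuple[LKBParams, float], ...]  # (initial params, final llh) per start


@dataclass(frozen=True)
class ProfileInterval:
    parameter_name: str
    lower: float
    upper: float
    target_llh: float
    lower_open: bool = False  # True if the threshold was not crossed inside the range
    upper_open: bool = False


@dataclass(frozen=True)
class ContourResult:
    plane: tuple[str, str]
    segments: tuple[np.ndarray, ...]  # each (k, 2) array of (param1, param2) points
    threshold: float
    open_at_boundary: bool

    @property
    def points(self) -> np.ndarray:
        if not self.segments:
            return np.empty((0, 2))
        return np.vstack(self.segments)


@dataclass(frozen=True)
class ConfidenceBundle:
    dose_grid: np.ndarray
    best_curve: np.ndarray
    envelope_min: np.ndarray
    envelope_max: np.ndarray
    curves: np.ndarray  # (n_param_sets, len(dose_grid))
    param_sets: tuple[LKBParams, ...]


@dataclass(frozen=True)
class BootstrapResult:
    samples: tuple[LKBParams, ...]
    means: dict[str, float]
    sds: dict[str, float]
    n_runs: int
    subsample_size: int
    n_failed: int
    seed: int

    def sample_array(self) -> np.ndarray:
        return np.array([[p.d50, p.m, p.n] for p in self.samples])


# ---------------------------------------------------------------------------
# gEUD and the probit response
# ---------------------------------------------------------------------------

def compute_geud(dvh: DifferentialDVH, n: float) -> float:
    """Generalized equivalent uniform dose of a differential DVH.

    Evaluated in log space, gEUD = exp(n * logsumexp(log v_i + log d_i / n)),
    so that exponents 1/n of several hundred (serial organs) do not
    overflow. Zero-dose or zero-volume bins contribute nothing.
    """
    if not 0 < n <= 1:
        raise ValueError(f"volume exponent n must be in (0, 1], got {n}")
    d = dvh.bin_doses
    v = dvh.bin_volumes
    ok = (v > 0) & (d > 0)
    if not ok.any():
        return 0.0
    log_terms = np.log(v[ok]) + np.log(d[ok]) / n
    return float(np.exp(n * special.logsumexp(log_terms)))


def lkb_ntcp(geud: float | np.ndarray, params: LKBParams) -> float | np.ndarray:
    """Probit NTCP at a given gEUD: Phi((gEUD - D50) / (m * D50))."""
    t = (np.asarray(geud, dtype=float) - params.d50) / (params.m * params.d50)
    out = stats.norm.cdf(t)
    return float(out) if np.isscalar(geud) or np.ndim(geud) == 0 else out


# ---------------------------------------------------------------------------
# vectorized cohort likelihood
# ---------------------------------------------------------------------------

class _CohortArrays:
    """Padded per-patient differential-DVH arrays for fast LLH evaluation."""

    def __init__(self, dvhs: Sequence[CumulativeDVH | DifferentialDVH], y: np.ndarray):
        ddvhs = [
            d if isinstance(d, DifferentialDVH) else cumulative_to_differential(d)
            for d in dvhs
        ]
        width = max(d.bin_doses.size for d in ddvhs)
        n_pat = len(ddvhs)
        self.log_v = np.full((n_pat, width), -np.inf)
        self.log_d = np.zeros((n_pat, width))
        for i, dd in enumerate(ddvhs):
            v, d = dd.bin_volumes, dd.bin_doses
            ok = (v > 0) & (d > 0)
            k = int(ok.sum())
            self.log_v[i, :k] = np.log(v[ok])
            self.log_d[i, :k] = np.log(d[ok])
        self.y = np.asarray(y, dtype=bool)

    def geud(self, n: float) -> np.ndarray:
        # manual logsumexp along axis 1 (rows are never all -inf)
        a = self.log_v + self.log_d / n
        amax = a.max(axis=1, keepdims=True)
        return np.exp(
            n * (np.log(np.sum(np.exp(a - amax), axis=1)) + amax[:, 0])
        )

    def llh(self, d50: float, m: float, n: float) -> float:
        t = (self.geud(n) - d50) / (m * d50)
        p = np.clip(special.ndtr(t), _NTCP_CLIP, 1 - _NTCP_CLIP)
        return float(np.sum(np.log(p[self.y])) + np.sum(np.log1p(-p[~self.y])))


def _cohort_arrays(cohort: Cohort) -> _CohortArrays:
    return _CohortArrays(cohort.dvhs, cohort.outcomes)


def cohort_log_likelihood(cohort: Cohort, params: LKBParams) -> float:
    """Bernoulli log-likelihood of the cohort's late-toxicity outcomes:
    sum of log NTCP_i over events plus log(1 - NTCP_i) over non-events,
    with NTCP_i clipped to [1e-12, 1 - 1e-12] before the log."""
    return _cohort_arrays(cohort).llh(params.d50, params.m, params.n)


# ---------------------------------------------------------------------------
# maximum-likelihood fitting
# ---------------------------------------------------------------------------

def _to_unconstrained(p: LKBParams) -> np.ndarray:
    return np.array([np.log(p.d50), np.log(p.m), special.logit(p.n)])


def _from_unconstrained(z: np.ndarray) -> tuple[float, float, float]:
    return float(np.exp(z[0])), float(np.exp(z[1])), float(special.expit(z[2]))


def _fit_arrays(
    arrays: _CohortArrays,
    starts: Iterable[LKBParams],
    xatol: float = 1e-6,
    fatol: float = 1e-8,
    maxiter: int = 5000,
) -> LKBFitResult:
    if arrays.y.all() or not arrays.y.any():
        raise NonIdentifiableError(
            "cohort must contain at least one event and one non-event"
        )

    def neg_llh(z: np.ndarray) -> float:
        d50, m, n = _from_unconstrained(z)
        if n <= 0 or n > 1:  # expit can hit exactly 0/1 at extreme z
            return np.inf
        return -arrays.llh(d50, m, n)

    results = []
    n_eval = 0
    any_converged = False
    for start in starts:
        res = optimize.minimize(
            neg_llh,
            _to_unconstrained(start),
            method="Nelder-Mead",
            options={"xatol": xatol, "fatol": fatol, "maxiter": maxiter},
        )
        n_eval += res.nfev
        any_converged = any_converged or bool(res.success)
        results.append((start, res))
    if not any_converged:
        msgs = {r.message for _, r in results}
        raise ConvergenceError(f"no Nelder-Mead start converged: {msgs}")
    best_start, best = min(results, key=lambda sr: sr[1].fun)
    d50, m, n = _from_unconstrained(best.x)
    return LKBFitResult(
        params=LKBParams(d50, m, n),
        llh=-float(best.fun),
        converged=bool(best.success),
        n_evaluations=n_eval,
        starts=tuple((s, -float(r.fun)) for s, r in results),
    )


def fit_lkb(
    cohort: Cohort,
    starts: Sequence[LKBParams] | None = None,
    xatol: float = 1e-6,
    fatol: float = 1e-8,
    maxiter: int = 5000,
) -> LKBFitResult:
    """Maximum-likelihood LKB fit by multistart Nelder-Mead.

    Runs the simplex from every start (default: a 3 x 2 x 3 grid over
    D50 in {60, 80, 100} Gy, m in {0.2, 0.4}, n in {0.05, 0.2, 0.5}) in
    the unconstrained (log D50, log m, logit n) space and returns the
    best converged optimum.
    """
    if starts is None:
        starts = [LKBParams(*s) for s in _DEFAULT_STARTS]
    return _fit_arrays(_cohort_arrays(cohort), starts, xatol, fatol, maxiter)


class LKBProbitModel(BaseEstimator, ClassifierMixin):
    """Scikit-learn style estimator for the LKB NTCP model.

    Parameters
    ----------
    starts : sequence of (d50, m, n) tuples or None
        Multistart grid for the Nelder-Mead fit; None uses the default grid.
    xatol, fatol : float
        Simplex convergence tolerances (parameters / log-likelihood).
    maxiter : int
        Maximum simplex iterations per start.

    Attributes
    ----------
    d50_, m_, n_ : float
        Fitted parameters.
    llh_ : float
        Log-likelihood at the optimum.
    result_ : LKBFitResult
        Full fit diagnostics.

    ``X`` is a sequence of :class:`CumulativeDVH` (or differential) DVHs,
    ``y`` the binary late-toxicity outcomes.
    """

    def __init__(self, starts=None, xatol: float = 1e-6, fatol: float = 1e-8,
                 maxiter: int = 5000):
        self.starts = starts
        self.xatol = xatol
        self.fatol = fatol
        self.maxiter = maxiter

    def fit(self, X: Sequence[CumulativeDVH | DifferentialDVH], y):
        y = np.asarray(y, dtype=int)
        if len(X) != y.size:
            raise ValueError("X and y have different lengths")
        starts = (
            [LKBParams(*s) for s in self.starts]
            if self.starts is not None
            else [LKBParams(*s) for s in _DEFAULT_STARTS]
        )
        arrays = _CohortArrays(X, y)
        res = _fit_arrays(arrays, starts, self.xatol, self.fatol, self.maxiter)
        self.result_ = res
        self.d50_, self.m_, self.n_ = res.params.d50, res.params.m, res.params.n
        self.llh_ = res.llh
        self.classes_ = np.array([0, 1])
        return self

    @property
    def params_(self) -> LKBParams:
        return self.result_.params

    def predict_proba(self, X: Sequence[CumulativeDVH | DifferentialDVH]) -> np.ndarray:
        p = np.array([lkb_ntcp(self.geud(dvh), self.params_) for dvh in X])
        return np.column_stack([1 - p, p])

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def geud(self, dvh: CumulativeDVH | DifferentialDVH) -> float:
        ddvh = dvh if isinstance(dvh, DifferentialDVH) else cumulative_to_differential(dvh)
        return compute_geud(ddvh, self.n_)


# ---------------------------------------------------------------------------
# profile likelihood
# ---------------------------------------------------------------------------

def _llh_threshold(llh_max: float, confidence: float, df: int = 1) -> float:
    return llh_max - 0.5 * stats.chi2.ppf(confidence, df)


def profile_interval(
    cohort: Cohort,
    fit: LKBFitResult,
    parameter_name: str,
    confidence: float = 0.95,
    df: int = 1,
    rel_tol: float = 1e-6,
) -> ProfileInterval:
    """Fixed-nuisance profile-likelihood interval for one LKB parameter.

    The named parameter is scanned away from its ML estimate (the other
    two held at their ML values) on a geometric grid until the
    log-likelihood drops below ``llh_max - chi2.ppf(confidence, df)/2``;
    the crossing is then refined by bisection. If the threshold is not
    crossed inside the admissible range the endpoint is reported as the
    range bound with an open flag.
    """
    if parameter_name not in _PARAM_RANGES:
        raise ValueError(f"unknown parameter {parameter_name!r}")
    arrays = _cohort_arrays(cohort)
    mle = {"d50": fit.params.d50, "m": fit.params.m, "n": fit.params.n}
    threshold = _llh_threshold(fit.llh, confidence, df)

    def llh_at(value: float) -> float:
        vals = dict(mle)
        vals[parameter_name] = value
        return arrays.llh(vals["d50"], vals["m"], vals["n"])

    lo_bound, hi_bound = _PARAM_RANGES[parameter_name]
    center = mle[parameter_name]

    def scan(direction: int) -> tuple[float, bool]:
        bound = hi_bound if direction > 0 else lo_bound
        factor = 1.02 if direction > 0 else 1 / 1.02
        prev = center
        value = center * factor
        while (value < bound) if direction > 0 else (value > bound):
            if llh_at(value) < threshold:
                root = optimize.brentq(
                    lambda v: llh_at(v) - threshold, *sorted((prev, value)),
                    xtol=rel_tol * max(center, 1e-12),
                )
                return float(root), False
            prev = value
            value *= factor
        if llh_at(bound) < threshold:
            root = optimize.brentq(
                lambda v: llh_at(v) - threshold, *sorted((prev, bound)),
                xtol=rel_tol * max(center, 1e-12),
            )
            return float(root), False
        return float(bound), True

    upper, upper_open = scan(+1)
    lower, lower_open = scan(-1)
    return ProfileInterval(
        parameter_name=parameter_name,
        lower=lower,
        upper=upper,
        target_llh=threshold,
        lower_open=lower_open,
        upper_open=upper_open,
    )


# ---------------------------------------------------------------------------
# iso-likelihood contours and the NTCP bundle
# ---------------------------------------------------------------------------

def _plane_grid(
    cohort_arrays: _CohortArrays,
    fit: LKBFitResult,
    plane: tuple[str, str],
    grid: int,
    span: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Log-likelihood surface over a geometric grid in a parameter plane,
    the third parameter fixed at its ML estimate."""
    mle = {"d50": fit.params.d50, "m": fit.params.m, "n": fit.params.n}
    axes = []
    for name in plane:
        lo_b, hi_b = _PARAM_RANGES[name]
        c = mle[name]
        lo = max(c / span, lo_b)
        hi = min(c * span, hi_b)
        axes.append(np.geomspace(lo, hi, grid))
    ax1, ax2 = axes
    llh = np.empty((grid, grid))
    for i, v1 in enumerate(ax1):
        for j, v2 in enumerate(ax2):
            vals = dict(mle)
            vals[plane[0]] = v1
            vals[plane[1]] = v2
            llh[i, j] = cohort_arrays.llh(vals["d50"], vals["m"], vals["n"])
    return ax1, ax2, llh


def iso_likelihood_contour(
    cohort: Cohort,
    fit: LKBFitResult,
    plane: tuple[str, str],
    confidence: float = 0.95,
    grid: int = 60,
    span: float = 2.5,
    df: int = 1,
    refine: bool = True,
) -> ContourResult:
    """Iso-likelihood contour at the profile threshold in one parameter plane.

    The log-likelihood is evaluated on a ``grid`` x ``grid`` geometric
    grid spanning ``span``-fold around the ML estimate (clipped to the
    admissible ranges), the third parameter fixed at its ML value, and
    the level set at ``llh_max - chi2.ppf(confidence, df)/2`` is traced
    by marching squares. With ``refine`` each traced point is then
    projected onto the exact level set by a 1-D root-find along the ray
    from the ML estimate (in log-parameter space), removing the
    interpolation error of the coarse grid. Contours cut off by the
    grid boundary are flagged open.
    """
    from skimage import measure

    for name in plane:
        if name not in _PARAM_RANGES:
            raise ValueError(f"unknown parameter {name!r}")
    arrays = _cohort_arrays(cohort)
    threshold = _llh_threshold(fit.llh, confidence, df)
    ax1, ax2, llh = _plane_grid(arrays, fit, plane, grid, span)
    raw = measure.find_contours(llh, threshold)

    mle = {"d50": fit.params.d50, "m": fit.params.m, "n": fit.params.n}
    z_mle = np.log([mle[plane[0]], mle[plane[1]]])

    def llh_at(z: np.ndarray) -> float:
        vals = dict(mle)
        vals[plane[0]], vals[plane[1]] = np.exp(z)
        return arrays.llh(vals["d50"], vals["m"], vals["n"])

    def refine_point(pt: np.ndarray) -> np.ndarray:
        direction = np.log(pt) - z_mle
        if not np.any(direction):
            return pt
        # max admissible scale along the ray before leaving the ranges
        t_cap = np.inf
        for k, name in enumerate(plane):
            lo, hi = np.log(_PARAM_RANGES[name])
            if direction[k] > 0:
                t_cap = min(t_cap, (hi - z_mle[k]) / direction[k])
            elif direction[k] < 0:
                t_cap = min(t_cap, (lo - z_mle[k]) / direction[k])
        f = lambda t: llh_at(z_mle + t * direction) - threshold
        t_hi = 1.0
        while f(t_hi) > 0:
            t_hi *= 1.3
            if t_hi >= t_cap:
                return pt  # threshold not crossed inside the range
        try:
            t_star = optimize.brentq(f, 0.0, t_hi, xtol=1e-10)
        except ValueError:
            return pt
        return np.exp(z_mle + t_star * direction)

    segments = []
    open_at_boundary = False
    for seg in raw:
        # fractional indices -> parameter values (linear interp on the log axes)
        i, j = seg[:, 0], seg[:, 1]
        p1 = np.exp(np.interp(i, np.arange(len(ax1)), np.log(ax1)))
        p2 = np.exp(np.interp(j, np.arange(len(ax2)), np.log(ax2)))
        pts = np.column_stack([p1, p2])
        if refine:
            pts = np.array([refine_point(p) for p in pts])
        segments.append(pts)
        closed = np.allclose(seg[0], seg[-1])
        if not closed:
            open_at_boundary = True
    return ContourResult(
        plane=tuple(plane),
        segments=tuple(segments),
        threshold=threshold,
        open_at_boundary=open_at_boundary,
    )


def ntcp_confidence_bundle(
    cohort: Cohort,
    fit: LKBFitResult,
    contours: Sequence[ContourResult],
    dose_grid: np.ndarray,
) -> ConfidenceBundle:
    """NTCP-vs-gEUD curves for every parameter set on the iso-likelihood
    contours, plus the pointwise min/max envelope (which always contains
    the best-fit curve)."""
    dose_grid = np.asarray(dose_grid, dtype=float)
    mle = {"d50": fit.params.d50, "m": fit.params.m, "n": fit.params.n}
    param_sets: list[LKBParams] = []
    for contour in contours:
        for p1, p2 in contour.points:
            vals = dict(mle)
            vals[contour.plane[0]] = p1
            vals[contour.plane[1]] = p2
            try:
                param_sets.append(LKBParams(vals["d50"], vals["m"], vals["n"]))
            except ValueError:
                continue  # grid point just outside the admissible range
    best_curve = np.asarray(lkb_ntcp(dose_grid, fit.params))
    if param_sets:
        curves = np.array([lkb_ntcp(dose_grid, p) for p in param_sets])
        env_min = np.minimum(curves.min(axis=0), best_curve)
        env_max = np.maximum(curves.max(axis=0), best_curve)
    else:
        curves = best_curve[None, :]
        env_min = best_curve.copy()
        env_max = best_curve.copy()
    return ConfidenceBundle(
        dose_grid=dose_grid,
        best_curve=best_curve,
        envelope_min=env_min,
        envelope_max=env_max,
        curves=curves,
        param_sets=tuple(param_sets),
    )


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def bootstrap_fit(
    cohort: Cohort,
    n_runs: int = 2000,
    subsample_size: int | None = None,
    seed: int = 0,
    replace: bool = True,
    starts: Sequence[LKBParams] | None = None,
) -> BootstrapResult:
    """Bootstrap spread of the ML parameter estimates.

    Each run draws ``subsample_size`` patients (default: cohort size)
    with replacement using a generator seeded by ``seed``, refits the
    model, and records the fitted parameters. Runs whose resample has a
    single outcome class, or whose fit fails, are skipped and counted.
    By default each refit starts the simplex from the full-cohort ML
    estimate; pass ``starts`` for a multistart refit.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    size = len(cohort) if subsample_size is None else int(subsample_size)
    if size > len(cohort) and not replace:
        raise ValueError("subsample_size cannot exceed cohort size without replacement")
    rng = np.random.default_rng(seed)
    full = fit_lkb(cohort, starts=starts)
    default_starts = [full.params]
    arrays = _cohort_arrays(cohort)
    samples: list[LKBParams] = []
    n_failed = 0
    n_pat = len(cohort)
    for _ in range(n_runs):
        idx = rng.choice(n_pat, size=size, replace=replace)
        sub = _CohortArrays.__new__(_CohortArrays)
        sub.log_v = arrays.log_v[idx]
        sub.log_d = arrays.log_d[idx]
        sub.y = arrays.y[idx]
        try:
            res = _fit_arrays(sub, starts if starts is not None else default_starts)
        except (NonIdentifiableError, ConvergenceError):
            n_failed += 1
            continue
        samples.append(res.params)
    if len(samples) < 0.1 * n_runs:
        raise ConvergenceError(
            f"only {len(samples)}/{n_runs} bootstrap fits succeeded "
            f"(subsample size {size}, events in cohort: {int(arrays.y.sum())})"
        )
    arr = np.array([[p.d50, p.m, p.n] for p in samples])
    names = ("d50", "m", "n")
    return BootstrapResult(
        samples=tuple(samples),
        means={k: float(v) for k, v in zip(names, arr.mean(axis=0))},
        sds={k: float(v) for k, v in zip(names, arr.std(axis=0, ddof=1))},
        n_runs=n_runs,
        subsample_size=size,
        n_failed=n_failed,
        seed=seed,
    )
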