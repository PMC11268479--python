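"""Fitting of individual stopped-flow transients.

The workhorse model is a sum of decaying exponentials with an offset and an
optional sloping baseline::

    A(t) = sum_i A_i * exp(-kobs_i * t) + offset [+ slope * t]

Observed rate constants (kobs) are eigenvalues of the underlying linearised
kinetic system, not elementary rate constants; phases are always reported
sorted by descending kobs.  The burst variant (two exponentials plus a
linear steady-state term) describes multiple-turnover transients in which a
rapid pre-steady-state burst precedes turnover limited by product release.

Sums of exponentials are notoriously multi-modal to fit.  The strategy here:

1. a greedy variable-projection search over a log-spaced rate grid (for
   fixed rates the amplitudes, offset and slope are a linear least-squares
   subproblem), which yields a near-global starting point cheaply;
2. a ladder of additional multi-starts with rates log-spaced across the
   observed time window;
3. Levenberg-Marquardt polish of every start in log-rate space (positivity
   by construction), keeping the best sum of squares.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import lmfit
import numpy as np
from scipy.stats import norm

from .constants import OpticalModel
from .transient import Transient

__all__ = [
    "FitError",
    "PhaseFit",
    "BurstFit",
    "LinearFit",
    "PhaseSelection",
    "truncate_dead_time",
    "fit_multiexponential",
    "select_n_phases",
    "fit_burst",
    "tail_linear_fit",
    "absorbance_to_concentration",
    "estimate_initial_concentration",
    "runs_test_pvalue",
]

DEAD_TIME = 0.002


class FitError(RuntimeError):
    """Raised on non-convergence; carries the best attempt in ``best``."""

    def __init__(self, message, best=None):
        super().__init__(message)
        self.best = best


# ---------------------------------------------------------------------------
# containers


@dataclass
class PhaseFit:
    """Result of a multi-exponential fit.

    Phases are sorted by descending kobs (ties broken by amplitude
    magnitude).  ``delta_a_total`` is the total fitted amplitude change
    (the sum of the A_i).  ``aicc`` is the corrected Akaike information
    criterion; ``runs_pvalue`` the one-sided (too-few-runs) Wald-Wolfowitz
    p-value of the residual sign sequence.
    """

    n_phases: int
    amplitudes: np.ndarray
    rates: np.ndarray
    offset: float
    slope: float | None
    amplitude_errs: np.ndarray | None
    rate_errs: np.ndarray | None
    offset_err: float | None
    slope_err: float | None
    time: np.ndarray = field(repr=False)
    residuals: np.ndarray = field(repr=False)
    ssr: float
    aicc: float
    runs_pvalue: float

    def __post_init__(self) -> None:
        if len(self.amplitudes) != self.n_phases or len(self.rates) != self.n_phases:
            raise ValueError("n_phases must match the number of (A_i, kobs_i) pairs")
        if np.any(np.asarray(self.rates) <= 0):
            raise ValueError("observed rate constants must be positive")
        if np.any(np.diff(self.rates) >= 0):
            raise ValueError("rates must be strictly descending")

    @property
    def delta_a_total(self) -> float:
        return float(np.sum(self.amplitudes))

    @property
    def n_parameters(self) -> int:
        return 2 * self.n_phases + 1 + (self.slope is not None)

    def model(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.full_like(t, self.offset)
        for a, k in zip(self.amplitudes, self.rates):
            out += a * np.exp(-k * t)
        if self.slope is not None:
            out += self.slope * t
        return out

    def a_at_time_zero(self) -> float:
        """Fitted absorbance extrapolated to t = 0 (offset + sum A_i)."""
        return float(self.offset + np.sum(self.amplitudes))


@dataclass
class BurstFit:
    """Two burst phases plus a linear steady-state term (and offset).

    kburst1 > kburst2 > 0; for a decaying signal the steady-state slope is
    negative (substrate consumption during turnover).
    """

    amplitude1: float
    kburst1: float
    amplitude2: float
    kburst2: float
    slope: float
    offset: float
    phase_fit: PhaseFit = field(repr=False)

    def __post_init__(self) -> None:
        if not (self.kburst1 > self.kburst2 > 0):
            raise ValueError("require kburst1 > kburst2 > 0")

    @property
    def total_burst_amplitude(self) -> float:
        return self.amplitude1 + self.amplitude2

    def a_at_time_zero(self) -> float:
        return self.phase_fit.a_at_time_zero()


@dataclass
class LinearFit:
    slope: float
    intercept: float
    slope_err: float
    intercept_err: float
    n_points: int

    def predict(self, t):
        return self.intercept + self.slope * np.asarray(t, dtype=float)


@dataclass
class PhaseSelection:
    """Outcome of phase-count model selection with per-candidate diagnostics."""

    n_selected: int
    fits: dict[int, PhaseFit]
    table: list[dict]

    @property
    def best(self) -> PhaseFit:
        return self.fits[self.n_selected]


# ---------------------------------------------------------------------------
# basic operations


def truncate_dead_time(t: Transient, dead_time: float = DEAD_TIME) -> Transient:
    """Discard data recorded before the instrument dead time."""
    mask = t.time >= dead_time
    if not mask.any():
        raise ValueError(f"transient lies entirely within the {dead_time} s dead time")
    if mask.all():
        return t
    return Transient(t.time[mask], t.absorbance[mask], dict(t.meta))


def tail_linear_fit(t: Transient, window: tuple[float, float] = (3.0, 10.0)) -> LinearFit:
    """Ordinary least squares on the points inside ``window`` only.

    Used on the slow tail of a transient, after the exponential phases have
    decayed, to measure an initial linear rate free from bias by the
    exponential terms.
    """
    lo, hi = window
    mask = (t.time >= lo) & (t.time <= hi)
    if mask.sum() < 3:
        raise ValueError(f"need at least 3 points in window [{lo}, {hi}] s, got {mask.sum()}")
    x, y = t.time[mask], t.absorbance[mask]
    coeffs, cov = np.polyfit(x, y, 1, cov=True)
    return LinearFit(
        slope=float(coeffs[0]),
        intercept=float(coeffs[1]),
        slope_err=float(np.sqrt(cov[0, 0])),
        intercept_err=float(np.sqrt(cov[1, 1])),
        n_points=int(mask.sum()),
    )


def absorbance_to_concentration(
    delta_a: float, om: OpticalModel, mode: str = "conversion"
) -> float:
    """Convert an absorbance change (AU) to concentration (uM).

    mode 'substrate' divides by eps_substrate * path (a pure-substrate
    signal), 'product' by eps_product * path, and 'conversion' by
    (eps_substrate - eps_product) * path (the change accompanying
    substrate -> product conversion).
    """
    if not math.isfinite(delta_a):
        raise ValueError("delta_a must be finite")
    eps = {
        "substrate": om.eps_substrate,
        "product": om.eps_product,
        "conversion": om.delta_eps,
    }.get(mode)
    if eps is None:
        raise ValueError(f"mode must be substrate|product|conversion, got {mode!r}")
    denom = eps * om.path_length * 1.0e-6
    if denom == 0:
        raise ZeroDivisionError("zero extinction-coefficient denominator")
    return delta_a / denom


# ---------------------------------------------------------------------------
# multi-exponential engine


def _design_matrix(t: np.ndarray, rates: np.ndarray, with_slope: bool) -> np.ndarray:
    cols = [np.exp(-k * t) for k in rates]
    cols.append(np.ones_like(t))
    if with_slope:
        cols.append(t)
    return np.column_stack(cols)


def _varpro_ssr(t, y, rates, with_slope):
    """Amplitudes/offset/slope by linear lstsq at fixed rates; returns (ssr, coeffs)."""
    X = _design_matrix(t, np.asarray(rates, dtype=float), with_slope)
    coeffs, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coeffs
    return float(resid @ resid), coeffs


def _rate_grid(t: np.ndarray, points_per_decade: int = 6) -> np.ndarray:
    k_lo = 0.2 / t[-1]
    k_hi = 2.0 / max(t[0], 1e-9)
    n = max(8, int(np.ceil(np.log10(k_hi / k_lo) * points_per_decade)))
    return np.geomspace(k_lo, k_hi, n)


def _greedy_varpro_rates(t, y, n_phases, with_slope):
    """Forward selection of rates from a log grid by variable projection."""
    grid = _rate_grid(t)
    chosen: list[float] = []
    for _ in range(n_phases):
        best_k, best_ssr = None, np.inf
        for k in grid:
            if any(abs(np.log(k / c)) < 0.2 for c in chosen):
                continue
            ssr, _ = _varpro_ssr(t, y, chosen + [k], with_slope)
            if ssr < best_ssr:
                best_ssr, best_k = ssr, k
        chosen.append(best_k if best_k is not None else grid[len(chosen) % len(grid)])
    return np.array(chosen)


def _ladder_starts(t: np.ndarray, n_phases: int, n_starts: int) -> list[np.ndarray]:
    """Rate ladders log-spaced over the decades of the observed window."""
    lo = math.log10(0.2 / t[-1])
    hi = math.log10(2.0 / max(t[0], 1e-9))
    starts = []
    for j in range(n_starts):
        frac = (j + 0.5) / n_starts
        centre = lo + frac * (hi - lo)
        half_span = (hi - lo) * 0.25 + 0.5
        logs = np.linspace(centre - half_span, centre + half_span, max(n_phases, 1))
        starts.append(10.0 ** logs)
    return starts


def _polish(t, y, rates0, with_slope, weights=None):
    """Levenberg-Marquardt refinement in log-rate space from one start."""
    rates0 = np.sort(np.asarray(rates0, dtype=float))[::-1]
    _, coeffs = _varpro_ssr(t, y, rates0, with_slope)
    n = len(rates0)
    params = lmfit.Parameters()
    for i, (k, a) in enumerate(zip(rates0, coeffs[:n])):
        params.add(f"logk{i}", value=math.log10(max(k, 1e-12)), min=-12, max=12)
        params.add(f"amp{i}", value=float(a))
    params.add("offset", value=float(coeffs[n]))
    if with_slope:
        params.add("slope", value=float(coeffs[n + 1]))

    def residual(p):
        model = np.full_like(t, p["offset"].value)
        for i in range(n):
            model = model + p[f"amp{i}"].value * np.exp(-(10.0 ** p[f"logk{i}"].value) * t)
        if with_slope:
            model = model + p["slope"].value * t
        r = model - y
        return r if weights is None else r * weights

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = lmfit.minimize(residual, params, method="leastsq", nan_policy="raise")
    return result


def _aicc(n_points: int, ssr: float, n_params: int) -> float:
    k = n_params + 1  # +1 for the noise variance
    if n_points - k - 1 <= 0:
        return np.inf
    ssr = max(ssr, 1e-300)
    return n_points * math.log(ssr / n_points) + 2 * k + 2 * k * (k + 1) / (n_points - k - 1)


def runs_test_pvalue(residuals: np.ndarray) -> float:
    """One-sided Wald-Wolfowitz runs test on residual signs.

    Small p means fewer sign runs than expected for exchangeable residuals,
    i.e. systematic structure left by an underfitting model.
    """
    signs = np.asarray(residuals) > 0
    n1 = int(signs.sum())
    n2 = signs.size - n1
    if n1 == 0 or n2 == 0:
        return 0.0
    runs = 1 + int(np.sum(signs[1:] != signs[:-1]))
    n = n1 + n2
    mean = 1 + 2 * n1 * n2 / n
    var = 2 * n1 * n2 * (2 * n1 * n2 - n) / (n * n * (n - 1))
    if var <= 0:
        return 0.0
    z = (runs - mean + 0.5) / math.sqrt(var)
    return float(norm.cdf(z))


def _result_to_phasefit(result, t, y, n_phases, with_slope) -> PhaseFit:
    p = result.params
    rates = np.array([10.0 ** p[f"logk{i}"].value for i in range(n_phases)])
    amps = np.array([p[f"amp{i}"].value for i in range(n_phases)])
    rate_errs = np.empty(n_phases)
    amp_errs = np.empty(n_phases)
    for i in range(n_phases):
        lke = p[f"logk{i}"].stderr
        rate_errs[i] = rates[i] * math.log(10) * lke if lke is not None else np.nan
        ae = p[f"amp{i}"].stderr
        amp_errs[i] = ae if ae is not None else np.nan
    # sort descending by rate; tie-break by amplitude magnitude
    order = np.lexsort((-np.abs(amps), -rates))
    rates, amps = rates[order], amps[order]
    rate_errs, amp_errs = rate_errs[order], amp_errs[order]
    # collapse exact duplicates that would violate strict descent
    for i in range(1, n_phases):
        if rates[i] >= rates[i - 1]:
            rates[i] = np.nextafter(rates[i - 1], 0.0)
    offset = float(p["offset"].value)
    offset_err = p["offset"].stderr
    slope = float(p["slope"].value) if with_slope else None
    slope_err = p["slope"].stderr if with_slope else None
    model = np.full_like(t, offset)
    for a, k in zip(amps, rates):
        model += a * np.exp(-k * t)
    if with_slope:
        model += slope * t
    resid = y - model
    ssr = float(resid @ resid)
    n_params = 2 * n_phases + 1 + with_slope
    return PhaseFit(
        n_phases=n_phases,
        amplitudes=amps,
        rates=rates,
        offset=offset,
        slope=slope,
        amplitude_errs=amp_errs,
        rate_errs=rate_errs,
        offset_err=offset_err,
        slope_err=slope_err,
        time=t,
        residuals=resid,
        ssr=ssr,
        aicc=_aicc(t.size, ssr, n_params),
        runs_pvalue=runs_test_pvalue(resid),
    )


def fit_multiexponential(
    transient: Transient,
    n_phases: int,
    *,
    with_slope: bool = False,
    n_starts: int = 8,
    weights: np.ndarray | None = None,
    warm_start: PhaseFit | None = None,
) -> PhaseFit:
    """Nonlinear least squares of a sum of ``n_phases`` exponentials.

    Multi-start initialisation (greedy variable-projection search plus a
    ladder of ``n_starts`` log-spaced rate sets); optimisation in log-rate
    space so rates stay positive by construction.  ``warm_start`` seeds one
    extra start from a previous fit with fewer phases (guaranteeing the sum
    of squares never worsens as phases are added).  Unweighted least
    squares by default (homoscedastic instrument noise); pass ``weights``
    to override.

    Raises :class:`FitError` carrying the best attempt if no start
    converges.
    """
    if n_phases not in (1, 2, 3):
        raise ValueError(f"n_phases must be 1, 2 or 3, got {n_phases}")
    t = transient.time
    y = transient.absorbance
    if t.size < 2 * n_phases + 2 + with_slope:
        raise ValueError("too few points for the requested number of phases")

    starts = [_greedy_varpro_rates(t, y, n_phases, with_slope)]
    starts += _ladder_starts(t, n_phases, n_starts)
    if warm_start is not None and warm_start.n_phases < n_phases:
        extra = warm_start.rates[0] * 10.0 ** np.arange(1, n_phases - warm_start.n_phases + 1)
        starts.append(np.concatenate([warm_start.rates, extra]))

    best: PhaseFit | None = None
    last_error: Exception | None = None
    for rates0 in starts:
        try:
            result = _polish(t, y, rates0, with_slope, weights)
            fit = _result_to_phasefit(result, t, y, n_phases, with_slope)
        except Exception as exc:  # singular design, failed step, etc.
            last_error = exc
            continue
        if best is None or fit.ssr < best.ssr:
            best = fit
    if best is None:
        raise FitError(
            f"no multi-exponential start converged (n_phases={n_phases}): {last_error}",
            best=None,
        )
    return best


def select_n_phases(
    transient: Transient,
    max_phases: int = 3,
    *,
    with_slope: bool = False,
    margin: float = 10.0,
    alpha: float = 0.01,
    n_starts: int = 8,
) -> PhaseSelection:
    """Choose the number of exponential phases supported by a transient.

    Fits n = 1..max_phases and selects the smallest n whose corrected
    information criterion lies within ``margin`` of the best candidate AND
    whose residual sign sequence passes a runs test at level ``alpha``.  A
    fit whose RMS residual is below 1e-7 of the signal range is treated as
    exact (parsimony floor, so that numerically perfect fits are not
    penalised into extra phases).  If no candidate passes, the candidate
    with the best information criterion is returned; diagnostics for every
    n are always reported.
    """
    fits: dict[int, PhaseFit] = {}
    warm = None
    for n in range(1, max_phases + 1):
        fits[n] = fit_multiexponential(
            transient, n, with_slope=with_slope, n_starts=n_starts, warm_start=warm
        )
        warm = fits[n]
    best_aicc = min(f.aicc for f in fits.values())
    signal_range = float(np.ptp(transient.absorbance))
    floor = 1e-7 * max(signal_range, 1e-12)
    table = []
    chosen = None
    for n in sorted(fits):
        f = fits[n]
        rms = math.sqrt(f.ssr / f.time.size)
        exact = rms < floor
        passes = exact or (f.aicc <= best_aicc + margin and f.runs_pvalue >= alpha)
        table.append(
            {
                "n_phases": n,
                "ssr": f.ssr,
                "aicc": f.aicc,
                "runs_pvalue": f.runs_pvalue,
                "rms": rms,
                "exact": exact,
                "passes": passes,
            }
        )
        if passes and chosen is None:
            chosen = n
    if chosen is None:
        chosen = min(fits, key=lambda n: fits[n].aicc)
    return PhaseSelection(n_selected=chosen, fits=fits, table=table)


def fit_burst(
    transient: Transient,
    *,
    n_starts: int = 8,
    weights: np.ndarray | None = None,
) -> BurstFit:
    """Two exponential burst phases plus a linear steady-state term.

    The model for a multiple-turnover transient in which a fast
    pre-steady-state burst (approximately stoichiometric with enzyme)
    precedes turnover limited by product release; the linear term carries
    the steady-state rate.
    """
    fit = fit_multiexponential(
        transient, 2, with_slope=True, n_starts=n_starts, weights=weights
    )
    return BurstFit(
        amplitude1=float(fit.amplitudes[0]),
        kburst1=float(fit.rates[0]),
        amplitude2=float(fit.amplitudes[1]),
        kburst2=float(fit.rates[1]),
        slope=float(fit.slope),
        offset=float(fit.offset),
        phase_fit=fit,
    )


def estimate_initial_concentration(
    transient: Transient,
    om: OpticalModel,
    *,
    fit: PhaseFit | BurstFit | None = None,
    n_phases: int | None = None,
) -> float:
    """Substrate concentration at t = 0 from the fitted absorbance.

    Extrapolates the fitted model to t = 0 (offset + sum of amplitudes; the
    slope term vanishes there) and converts in substrate mode.  This is how
    the starting concentration is measured in practice, since uncatalysed
    cyclisation and substrate loss to the flow system make the nominal
    value unreliable.

    If no fit is supplied one is produced: with ``n_phases`` given, a fit
    with that many phases; otherwise automatic phase selection.
    """
    if fit is None:
        if np.ptp(transient.absorbance) < 1e-12:
            # flat trace: nothing decays, A(0) is just the mean signal
            a0 = float(np.mean(transient.absorbance))
            return absorbance_to_concentration(a0, om, "substrate")
        if n_phases is not None:
            fit = fit_multiexponential(transient, n_phases)
        else:
            fit = select_n_phases(transient).best
    a0 = fit.a_at_time_zero()
    return absorbance_to_concentration(a0, om, "substrate")
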