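"""Concentration-dependence analysis of observed rate constants.

This module turns per-transient fit results into intrinsic rate and
equilibrium constants:

* linear kobs-vs-[S] fits (one-step binding: kobs = kon[S] + koff);
* classical Haldane substrate inhibition,
  kobs(S) = kmax * S / (Km + S * (1 + S/Ki));
* the two-step (induced-rearrangement) binding model, whose slow observed
  rate is the smaller-magnitude eigenvalue of the 2x2 linearised system,
  kobs = (p - sqrt(p^2 - 4r)) / 2 with
  p = kon1*S + koff1 + kon2 + koff2 and
  r = kon1*S*kon2 + koff1*koff2 + kon1*S*koff2;
* steady-state Michaelis-Menten turnover, v/E0 = kcat*S/(Km + S);
* the uncatalysed (spontaneous) cyclisation rate from no-enzyme controls;
* assembly of the full constant table with provenance.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import lmfit
import numpy as np
import pandas as pd

from .constants import OpticalModel
from .fitting import absorbance_to_concentration
from .transient import Transient

__all__ = [
    "RateSeries",
    "LinearRateFit",
    "SubstrateInhibitionFit",
    "OneStepFit",
    "TwoStepParams",
    "TwoStepFit",
    "MichaelisMentenFit",
    "KspontEstimate",
    "ConstantEntry",
    "ConstantsTable",
    "fit_kobs_linear",
    "fit_substrate_inhibition",
    "fit_one_step_binding",
    "two_step_kobs",
    "two_step_eigenvalues",
    "fit_two_step_binding",
    "fit_michaelis_menten",
    "estimate_kspont",
    "subtract_background",
    "assemble_constants",
]


# ---------------------------------------------------------------------------
# series container


@dataclass
class RateSeries:
    """Replicate-averaged observed rates as a function of [S].

    ``conc`` is the per-concentration mean of the *estimated* starting
    substrate concentration (uM), ``mean``/``std`` the replicate statistics
    of the named observed rate constant (s^-1), ``n_rep`` the replicate
    count.  Values are averaged per concentration before any
    concentration-series fit, matching stopped-flow practice.
    """

    conc: np.ndarray
    mean: np.ndarray
    std: np.ndarray | None = None
    n_rep: np.ndarray | None = None
    name: str = "kobs"

    def __post_init__(self) -> None:
        self.conc = np.asarray(self.conc, dtype=float)
        self.mean = np.asarray(self.mean, dtype=float)
        if self.std is not None:
            self.std = np.asarray(self.std, dtype=float)
        if self.conc.shape != self.mean.shape:
            raise ValueError("conc and mean must have the same shape")
        if np.any(self.conc <= 0):
            raise ValueError("concentrations must be positive")

    def __len__(self) -> int:
        return self.conc.size

    @classmethod
    def from_replicates(cls, groups: dict[float, list[float]], name: str = "kobs") -> "RateSeries":
        """Build from {concentration: [replicate values]}."""
        conc = np.array(sorted(groups))
        mean = np.array([np.mean(groups[c]) for c in conc])
        std = np.array([np.std(groups[c], ddof=1) if len(groups[c]) > 1 else 0.0 for c in conc])
        n = np.array([len(groups[c]) for c in conc])
        return cls(conc, mean, std, n, name)

    def weights(self) -> np.ndarray | None:
        """1/std weights when every std is finite and positive, else None."""
        if self.std is None or np.any(~np.isfinite(self.std)) or np.any(self.std <= 0):
            return None
        return 1.0 / self.std


# ---------------------------------------------------------------------------
# linear fits


@dataclass
class LinearRateFit:
    slope: float
    intercept: float
    slope_err: float
    intercept_err: float

    def predict(self, S):
        return self.intercept + self.slope * np.asarray(S, dtype=float)


def fit_kobs_linear(series: RateSeries) -> LinearRateFit:
    """Straight-line fit of an observed-rate series against [S].

    Weighted least squares (weights 1/std) when replicate standard
    deviations are available; the slope is unconstrained in sign (observed
    rates may fall with [S] when weaker-binding conformations accumulate).
    """
    if len(series) < 3:
        raise ValueError("need at least 3 concentrations for a linear fit")
    if np.ptp(series.conc) == 0:
        raise ValueError("degenerate design: all concentrations equal")
    w = series.weights()
    coeffs, cov = np.polyfit(series.conc, series.mean, 1, w=w, cov="unscaled" if w is not None else True)
    return LinearRateFit(
        slope=float(coeffs[0]),
        intercept=float(coeffs[1]),
        slope_err=float(np.sqrt(cov[0, 0])),
        intercept_err=float(np.sqrt(cov[1, 1])),
    )


@dataclass
class OneStepFit:
    """One-step binding: kobs = kon[S] + koff."""

    kon: float
    koff: float
    kon_err: float
    koff_err: float
    negative_intercept: bool = False

    def predict(self, S):
        return self.koff + self.kon * np.asarray(S, dtype=float)


def fit_one_step_binding(series: RateSeries) -> OneStepFit:
    """Linear fit read as binding kinetics: slope = kon, intercept = koff.

    A negative fitted intercept is physically meaningless and is flagged
    (with a warning) rather than clamped.
    """
    lin = fit_kobs_linear(series)
    negative = lin.intercept < 0
    if negative:
        warnings.warn(
            f"one-step binding fit has negative intercept {lin.intercept:.3g} s^-1; "
            "koff is not resolved by these data",
            stacklevel=2,
        )
    return OneStepFit(
        kon=lin.slope,
        koff=lin.intercept,
        kon_err=lin.slope_err,
        koff_err=lin.intercept_err,
        negative_intercept=negative,
    )


# ---------------------------------------------------------------------------
# substrate inhibition (Haldane)


@dataclass
class SubstrateInhibitionFit:
    """kobs(S) = kmax * S / (Km + S * (1 + S/Ki))."""

    kmax: float
    km: float
    ki: float
    kmax_err: float
    km_err: float
    ki_err: float

    @property
    def s_optimum(self) -> float:
        """[S] at which the fitted curve is maximal: sqrt(Km * Ki)."""
        return math.sqrt(self.km * self.ki)

    def predict(self, S):
        S = np.asarray(S, dtype=float)
        return self.kmax * S / (self.km + S * (1.0 + S / self.ki))


def _haldane(S, kmax, km, ki):
    return kmax * S / (km + S * (1.0 + S / ki))


def fit_substrate_inhibition(series: RateSeries, n_starts: int = 6) -> SubstrateInhibitionFit:
    """Fit the classical Haldane substrate-inhibition form.

    Multi-start over log-spaced (Km, Ki) guesses with positivity bounds.
    Requires enough concentrations to span the turnover maximum.
    """
    if len(series) < 5:
        raise ValueError("need at least 5 concentrations spanning the maximum")
    S, y = series.conc, series.mean
    w = series.weights()
    s_med = float(np.median(S))
    best = None
    for km0 in np.geomspace(0.2 * s_med, 5 * s_med, n_starts // 2 or 1):
        for ki0 in np.geomspace(s_med, 100 * s_med, 2):
            params = lmfit.Parameters()
            params.add("kmax", value=float(y.max() * 2), min=0)
            params.add("km", value=float(km0), min=1e-12)
            params.add("ki", value=float(ki0), min=1e-12)

            def residual(p):
                r = _haldane(S, p["kmax"].value, p["km"].value, p["ki"].value) - y
                return r if w is None else r * w

            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = lmfit.minimize(residual, params, method="leastsq")
            except Exception:
                continue
            ssr = float(np.sum(np.asarray(res.residual) ** 2))
            if best is None or ssr < best[0]:
                best = (ssr, res)
    if best is None:
        raise RuntimeError("substrate-inhibition fit did not converge from any start")
    p = best[1].params
    return SubstrateInhibitionFit(
        kmax=p["kmax"].value, km=p["km"].value, ki=p["ki"].value,
        kmax_err=p["kmax"].stderr or np.nan,
        km_err=p["km"].stderr or np.nan,
        ki_err=p["ki"].stderr or np.nan,
    )


# ---------------------------------------------------------------------------
# two-step binding


@dataclass(frozen=True)
class TwoStepParams:
    """Association (kon1/koff1) then first-order rearrangement (kon2/koff2).

    kon1 in uM^-1 s^-1; the others s^-1.  kon2 is the forward
    rearrangement to the reactive conformation, koff2 its reverse.
    """

    kon1: float
    koff1: float
    kon2: float
    koff2: float

    def __post_init__(self) -> None:
        for name in ("kon1", "koff1", "kon2", "koff2"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")


def _two_step_p_r(params: TwoStepParams, S):
    S = np.asarray(S, dtype=float)
    p = params.kon1 * S + params.koff1 + params.kon2 + params.koff2
    r = (
        params.kon1 * S * params.kon2
        + params.koff1 * params.koff2
        + params.kon1 * S * params.koff2
    )
    return p, r


def two_step_kobs(params: TwoStepParams, S):
    """Slow observed rate of the two-step binding system at substrate S.

    Returns (p - q)/2 with q = sqrt(p^2 - 4r): the smaller-magnitude
    eigenvalue of the 2x2 linearised kinetic matrix.  The discriminant is
    non-negative for any non-negative rate constants; a guard raises if
    float noise would make it meaningfully negative.
    """
    p, r = _two_step_p_r(params, S)
    disc = p * p - 4.0 * r
    tol = 1e-9 * np.maximum(p * p, 1.0)
    if np.any(disc < -tol):
        raise ValueError("discriminant p^2 - 4r is negative beyond numerical tolerance")
    q = np.sqrt(np.maximum(disc, 0.0))
    out = 0.5 * (p - q)
    return float(out) if np.isscalar(S) or np.ndim(S) == 0 else out


def two_step_eigenvalues(params: TwoStepParams, S):
    """Both relaxation rates, (slow, fast) = ((p - q)/2, (p + q)/2)."""
    p, r = _two_step_p_r(params, S)
    q = np.sqrt(np.maximum(p * p - 4.0 * r, 0.0))
    return 0.5 * (p - q), 0.5 * (p + q)


@dataclass
class TwoStepFit:
    params: TwoStepParams
    errs: dict
    boundary_flags: dict
    ssr: float

    @property
    def at_boundary(self) -> bool:
        return any(self.boundary_flags.values())


def fit_two_step_binding(series: RateSeries, n_starts: int = 8) -> TwoStepFit:
    """Nonlinear least squares of the two-step slow observed rate.

    Multi-start over log-spaced parameter guesses.  The four parameters of
    this model are weakly constrained by a single kobs(S) curve, so wide
    uncertainties are expected and reported as-is; parameters collapsing to
    the zero boundary are flagged (``boundary_flags``), not silently
    returned as genuine estimates.
    """
    if len(series) < 5:
        raise ValueError("need at least 5 concentrations for the two-step fit")
    S, y = series.conc, series.mean
    w = series.weights()
    scale = float(max(y.max(), 1e-9))
    slope_guess = max((y[-1] - y[0]) / (S[-1] - S[0]), scale / S[-1] / 10)

    best = None
    rng_factors = np.geomspace(0.1, 10.0, n_starts)
    for f in rng_factors:
        params = lmfit.Parameters()
        params.add("log_kon1", value=math.log10(max(slope_guess * f, 1e-9)), min=-12, max=6)
        params.add("log_koff1", value=math.log10(scale * f), min=-12, max=6)
        params.add("log_kon2", value=math.log10(scale / f if f else scale), min=-12, max=6)
        params.add("log_koff2", value=math.log10(scale * 0.5), min=-12, max=6)

        def residual(p):
            tp = TwoStepParams(
                10.0 ** p["log_kon1"].value,
                10.0 ** p["log_koff1"].value,
                10.0 ** p["log_kon2"].value,
                10.0 ** p["log_koff2"].value,
            )
            r = two_step_kobs(tp, S) - y
            return r if w is None else r * w

        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = lmfit.minimize(residual, params, method="leastsq")
        except Exception:
            continue
        ssr = float(np.sum(np.asarray(res.residual) ** 2))
        if best is None or ssr < best[0]:
            best = (ssr, res)
    if best is None:
        raise RuntimeError("two-step binding fit did not converge from any start")
    ssr, res = best
    vals = {}
    errs = {}
    flags = {}
    # scale for boundary detection: a rate-like parameter this far below the
    # observed kobs magnitude is numerically zero for these data
    rate_scale = float(max(np.max(np.abs(y)), 1e-12))
    for name in ("kon1", "koff1", "kon2", "koff2"):
        lp = res.params[f"log_{name}"]
        vals[name] = 10.0 ** lp.value
        errs[name] = (
            vals[name] * math.log(10) * lp.stderr if lp.stderr is not None else np.nan
        )
        scale = rate_scale / float(S.max()) if name == "kon1" else rate_scale
        flags[name] = lp.value <= -10.0 or vals[name] < 1e-4 * scale
    return TwoStepFit(params=TwoStepParams(**vals), errs=errs, boundary_flags=flags, ssr=ssr)


# ---------------------------------------------------------------------------
# Michaelis-Menten


@dataclass
class MichaelisMentenFit:
    """v / E0 = kcat * S / (Km + S)."""

    kcat: float
    km: float
    kcat_err: float
    km_err: float

    @property
    def kcat_per_min(self) -> float:
        return self.kcat * 60.0

    def predict(self, S, E0=1.0):
        S = np.asarray(S, dtype=float)
        return E0 * self.kcat * S / (self.km + S)


def fit_michaelis_menten(series: RateSeries, E0: float, n_starts: int = 5) -> MichaelisMentenFit:
    """Fit background-subtracted initial velocities (uM/s) to the MM form.

    ``series.mean`` holds velocities v at each S; the model is
    v = E0 * kcat * S / (Km + S), so kcat comes out in s^-1.
    """
    if len(series) < 4:
        raise ValueError("need at least 4 concentrations for a Michaelis-Menten fit")
    if E0 <= 0:
        raise ValueError("E0 must be positive")
    S, v = series.conc, series.mean
    w = series.weights()
    kcat_guess = float(v.max() / E0)
    best = None
    for km0 in np.geomspace(0.05 * np.median(S), 5 * np.median(S), n_starts):
        params = lmfit.Parameters()
        params.add("kcat", value=max(kcat_guess, 1e-9), min=0)
        params.add("km", value=float(km0), min=1e-9)

        def residual(p):
            r = E0 * p["kcat"].value * S / (p["km"].value + S) - v
            return r if w is None else r * w

        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = lmfit.minimize(residual, params, method="leastsq")
        except Exception:
            continue
        ssr = float(np.sum(np.asarray(res.residual) ** 2))
        if best is None or ssr < best[0]:
            best = (ssr, res)
    if best is None:
        raise RuntimeError("Michaelis-Menten fit did not converge from any start")
    p = best[1].params
    return MichaelisMentenFit(
        kcat=p["kcat"].value, km=p["km"].value,
        kcat_err=p["kcat"].stderr or np.nan, km_err=p["km"].stderr or np.nan,
    )


# ---------------------------------------------------------------------------
# spontaneous cyclisation and background subtraction


@dataclass
class KspontEstimate:
    value: float
    std: float
    per_transient: list = field(default_factory=list)


def estimate_kspont(transients: list[Transient], om: OpticalModel) -> KspontEstimate:
    """First-order spontaneous cyclisation constant from no-enzyme controls.

    Each transient (linear 10 s timebase, E0 = 0) is fitted to a straight
    line; the slope (AU/s) is converted to a conversion rate (uM/s) and
    divided by that transient's own A(t=0)-derived starting concentration,
    giving a first-order constant that is averaged across repeats and
    concentrations.  Rising absorbance (positive slope) is an error: the
    substrate chromophore can only be lost.
    """
    if not transients:
        raise ValueError("no transients given")
    per = []
    for tr in transients:
        x, y = tr.time, tr.absorbance
        coeffs = np.polyfit(x, y, 1)
        slope, intercept = float(coeffs[0]), float(coeffs[1])
        span = float(np.ptp(y))
        rise = slope * (x[-1] - x[0])
        if slope > 0 and rise > max(0.05 * span, 1e-9):
            raise ValueError(
                f"rising absorbance (slope {slope:.3g} AU/s) in an uncatalysed control"
            )
        rate = absorbance_to_concentration(max(-slope, 0.0), om, "conversion")  # uM/s
        s0 = absorbance_to_concentration(intercept, om, "substrate")
        k = rate / s0 if s0 > 0 else 0.0
        per.append({"S0_est": s0, "rate_um_per_s": rate, "kspont": k})
    values = np.array([p["kspont"] for p in per])
    return KspontEstimate(
        value=float(values.mean()),
        std=float(values.std(ddof=1)) if values.size > 1 else 0.0,
        per_transient=per,
    )


def subtract_background(observed_rate: float, spont_rate: float) -> float:
    """Remove the uncatalysed conversion rate from an observed rate (uM/s).

    Floored at zero with a warning when the background exceeds the
    observation (pure noise regime).
    """
    if not (math.isfinite(observed_rate) and math.isfinite(spont_rate)):
        raise ValueError("rates must be finite")
    corrected = observed_rate - spont_rate
    if corrected < 0:
        warnings.warn(
            f"background rate {spont_rate:.3g} exceeds observed rate "
            f"{observed_rate:.3g}; flooring at 0",
            stacklevel=2,
        )
        return 0.0
    return corrected


# ---------------------------------------------------------------------------
# constants table


@dataclass
class ConstantEntry:
    name: str
    value: float
    std: float | None
    units: str
    provenance: str
    approximate: bool = False


@dataclass
class ConstantsTable:
    """Assembled intrinsic rate and equilibrium constants with provenance."""

    entries: dict[str, ConstantEntry]

    def __getitem__(self, name: str) -> ConstantEntry:
        return self.entries[name]

    def __contains__(self, name: str) -> bool:
        return name in self.entries

    def value(self, name: str) -> float:
        return self.entries[name].value

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "name": e.name,
                "value": e.value,
                "std": e.std,
                "units": e.units,
                "provenance": e.provenance,
            }
            for e in self.entries.values()
        ]
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path: str | Path | None = None):
        payload = {
            name: {
                "value": e.value,
                "std": e.std,
                "units": e.units,
                "provenance": e.provenance,
                "approximate": e.approximate,
            }
            for name, e in self.entries.items()
        }
        if path is None:
            return payload
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")
        return payload

    def compare(self, reference: dict) -> pd.DataFrame:
        """Relative deviations against a reference {name: {value, std}} table."""
        rows = []
        for name, ref in reference.items():
            if name not in self.entries:
                continue
            ours = self.entries[name].value
            rel = (ours - ref["value"]) / ref["value"] if ref["value"] != 0 else np.nan
            rows.append(
                {
                    "name": name,
                    "value": ours,
                    "reference": ref["value"],
                    "relative_deviation": rel,
                }
            )
        return pd.DataFrame(rows)


def assemble_constants(
    one_step: OneStepFit,
    two_step: TwoStepFit,
    mm_fit: MichaelisMentenFit,
    kspont_fit: KspontEstimate,
    *,
    k3: tuple[float, float] | None = None,
    k3r: tuple[float, float] | None = None,
) -> ConstantsTable:
    """Map the component fits onto the reaction-scheme constants.

    k1/k1r from the fast-burst one-step fit, k2/k2r/k4/k4r from the
    two-step fit of the slow burst, k6 = kcat from the steady state,
    kspont from the uncatalysed controls.  k3/k3r (the dead-end
    conformation) are optional (value, std) pairs derived from the slow
    tail and are marked approximate.  Equilibrium constants are recomputed
    exactly from the assembled rate constants.
    """
    for label, fitobj in (
        ("one-step binding fit", one_step),
        ("two-step binding fit", two_step),
        ("Michaelis-Menten fit", mm_fit),
        ("spontaneous-rate estimate", kspont_fit),
    ):
        if fitobj is None:
            raise ValueError(f"missing required component: {label}")

    e = {}
    e["k1"] = ConstantEntry("k1", one_step.kon, one_step.kon_err, "uM^-1 s^-1",
                            "slope of one-step fit to fast burst phase (kburst1)")
    e["k1r"] = ConstantEntry("k1r", one_step.koff, one_step.koff_err, "s^-1",
                             "intercept of one-step fit to fast burst phase (kburst1)")
    tp, terr = two_step.params, two_step.errs
    e["k2"] = ConstantEntry("k2", tp.kon1, terr["kon1"], "uM^-1 s^-1",
                            "two-step fit to slow burst phase (kburst2): kon1")
    e["k2r"] = ConstantEntry("k2r", tp.koff1, terr["koff1"], "s^-1",
                             "two-step fit to slow burst phase (kburst2): koff1")
    e["k4"] = ConstantEntry("k4", tp.kon2, terr["kon2"], "s^-1",
                            "two-step fit to slow burst phase (kburst2): kon2")
    e["k4r"] = ConstantEntry("k4r", tp.koff2, terr["koff2"], "s^-1",
                             "two-step fit to slow burst phase (kburst2): koff2")
    if k3 is not None:
        e["k3"] = ConstantEntry("k3", k3[0], k3[1], "uM^-1 s^-1",
                                "3-10 s tail linear rate (order-of-magnitude)", True)
    if k3r is not None:
        e["k3r"] = ConstantEntry("k3r", k3r[0], k3r[1], "s^-1",
                                 "slowest single-turnover phase kobs3 (order-of-magnitude)", True)
    e["k6"] = ConstantEntry("k6", mm_fit.kcat, mm_fit.kcat_err, "s^-1",
                            "Michaelis-Menten fit of background-subtracted steady-state velocities (kcat)")
    e["kspont"] = ConstantEntry("kspont", kspont_fit.value, kspont_fit.std, "s^-1",
                                "linear fits of uncatalysed controls, averaged over repeats")

    # derived equilibrium constants, recomputed exactly from their parents
    def ratio(num, den):
        if e[den].value == 0:
            return math.nan
        return e[num].value / e[den].value

    e["K1"] = ConstantEntry("K1", ratio("k1r", "k1"), None, "uM", "k1r / k1")
    e["K2"] = ConstantEntry("K2", ratio("k2r", "k2"), None, "uM", "k2r / k2")
    if "k3" in e and "k3r" in e:
        e["K3"] = ConstantEntry("K3", ratio("k3r", "k3"), None, "uM", "k3r / k3", True)
    e["K4"] = ConstantEntry("K4", ratio("k4r", "k4"), None, "dimensionless", "k4r / k4")
    e["Kapp"] = ConstantEntry("Kapp", e["K2"].value * e["K4"].value, None, "uM", "K2 * K4")
    return ConstantsTable(entries=e)
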