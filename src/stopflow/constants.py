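"""Parameter containers for the AbyU reaction cycle.

The reaction scheme distinguishes three experimentally resolvable
enzyme-substrate binding conformations:

* ``ES``  -- the productive conformation, formed directly (k1/k1r) and
  committed to cyclisation (k5);
* ``ES2`` -- a sub-optimal conformation (k2/k2r) that rearranges in situ to
  ``ES`` (k4/k4r) before it can react;
* ``ES3`` -- a non-productive, dead-end conformation (k3/k3r) whose only exit
  is dissociation.

Cyclisation (k5, very fast) yields the enzyme-product complex ``EP``;
product release (k6, rate limiting) regenerates free enzyme.  Free substrate
also cyclises spontaneously (kspont) without the enzyme.

Units: concentrations in uM, time in s.  Bimolecular constants are
uM^-1 s^-1, unimolecular constants s^-1.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, replace
from importlib import resources
from pathlib import Path

__all__ = [
    "RateConstants",
    "OpticalModel",
    "DerivedConstants",
    "derived_constants",
    "load_reference_table",
]

_RATE_FIELDS = (
    "k1", "k1r", "k2", "k2r", "k3", "k3r", "k4", "k4r", "k5", "k6", "kspont",
)


def _check_nonnegative(name: str, value: float) -> None:
    if not math.isfinite(value) or value < 0:
        raise ValueError(f"rate constant {name} must be finite and >= 0, got {value!r}")


@dataclass(frozen=True)
class RateConstants:
    """The full rate-constant set of the reaction scheme.

    Parameters
    ----------
    k1, k1r : float
        Substrate binding to / dissociation from the productive
        conformation ES (uM^-1 s^-1 and s^-1).
    k2, k2r : float
        Binding to / dissociation from the sub-optimal conformation ES2.
    k3, k3r : float
        Binding to / dissociation from the non-productive conformation ES3.
    k4, k4r : float
        First-order rearrangement ES2 -> ES and its reverse (s^-1).
    k5 : float
        Cyclisation ES -> EP (s^-1).  Not measurable (very fast relative to
        every other step); defaults to 100 s^-1 in the bundled set, and the
        simulated observables at t > 0.1 s are insensitive to its exact
        value once it exceeds that default.
    k6 : float
        Product release EP -> E + P (s^-1); the rate-limiting step.
    kspont : float
        Effective first-order rate of spontaneous (uncatalysed) substrate
        cyclisation (s^-1).  Set ``spont_second_order=True`` to treat the
        same numeric value as a second-order constant (rate = kspont * S^2).
    """

    k1: float
    k1r: float
    k2: float
    k2r: float
    k3: float
    k3r: float
    k4: float
    k4r: float
    k5: float
    k6: float
    kspont: float
    spont_second_order: bool = False

    def __post_init__(self) -> None:
        for name in _RATE_FIELDS:
            _check_nonnegative(name, getattr(self, name))

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        d = {name: getattr(self, name) for name in _RATE_FIELDS}
        if self.spont_second_order:
            d["spont_second_order"] = True
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RateConstants":
        return cls(**d)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "RateConstants":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def replace(self, **changes) -> "RateConstants":
        return replace(self, **changes)

    @classmethod
    def abyu_defaults(cls) -> "RateConstants":
        """The experimentally determined constant set bundled with the package."""
        text = resources.files("stopflow.data").joinpath("abyu_rate_constants.json").read_text()
        return cls.from_dict(json.loads(text))


@dataclass(frozen=True)
class OpticalModel:
    """Beer-Lambert projection of the species pool onto 325 nm absorbance.

    The substrate's triene absorbs at 325 nm (eps = 13 200 M^-1 cm^-1) and
    the chromophore is lost on cyclisation (product eps = 1085 M^-1 cm^-1).
    Bound-but-uncyclised substrate absorbs as free substrate: conformational
    constriction of the side chain does not contribute at 325 nm.
    """

    eps_substrate: float = 13200.0
    eps_product: float = 1085.0
    path_length: float = 1.0

    def __post_init__(self) -> None:
        if not (self.eps_substrate > self.eps_product > 0):
            raise ValueError(
                "require eps_substrate > eps_product > 0, got "
                f"{self.eps_substrate!r} and {self.eps_product!r}"
            )
        if not (math.isfinite(self.path_length) and self.path_length > 0):
            raise ValueError(f"path_length must be positive, got {self.path_length!r}")

    @property
    def delta_eps(self) -> float:
        """Absorbance-coefficient change on conversion, M^-1 cm^-1."""
        return self.eps_substrate - self.eps_product

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "OpticalModel":
        return cls(**d)


@dataclass(frozen=True)
class DerivedConstants:
    """Stepwise equilibrium constants derived from the rate constants.

    K1..K3 are dissociation constants (uM) of the three binding
    conformations, K4 the dimensionless ES/ES2 rearrangement equilibrium
    (k4r/k4) and Kapp = K2 * K4 the apparent overall constant of the
    two-step binding route.
    """

    K1: float
    K2: float
    K3: float
    K4: float
    Kapp: float

    def to_dict(self) -> dict:
        return asdict(self)


def derived_constants(rc: RateConstants) -> DerivedConstants:
    """Compute the equilibrium constants K1..K4 and Kapp from ``rc``.

    Each K is the exact ratio reverse/forward of its step; Kapp = K2 * K4.
    Raises ``ZeroDivisionError`` naming the constant if a forward constant
    is zero.
    """
    ratios = {}
    for name, fwd, rev in (
        ("K1", "k1", "k1r"),
        ("K2", "k2", "k2r"),
        ("K3", "k3", "k3r"),
        ("K4", "k4", "k4r"),
    ):
        forward = getattr(rc, fwd)
        if forward == 0:
            raise ZeroDivisionError(
                f"cannot form {name}: forward constant {fwd} is zero"
            )
        ratios[name] = getattr(rc, rev) / forward
    return DerivedConstants(Kapp=ratios["K2"] * ratios["K4"], **ratios)


def load_reference_table() -> dict:
    """The published constant set (value, std, units per entry).

    Used by comparison reports; K3 is intentionally absent because the
    printed value is inconsistent with the printed k3r/k3 ratio (apparent
    unit typo); the package always recomputes the ratio instead.
    """
    text = resources.files("stopflow.data").joinpath("abyu_reference_table.json").read_text()
    return json.loads(text)
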