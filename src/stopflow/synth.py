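"""Seeded, instrument-realistic synthetic stopped-flow transients.

Reproduces the stopped-flow experiment designs used to characterise AbyU:

* single-turnover: large enzyme excess (400 uM enzyme vs tens of uM
  substrate), logarithmic timebase over 1000 s (15 cycles x 200 points);
* multiple-turnover (burst): 1 uM enzyme vs up to 54 uM substrate,
  logarithmic timebase;
* uncatalysed controls: no enzyme, linear 10 s timebase.

Instrument realism: a 2 ms dead time before the first recorded point,
additive iid Gaussian noise in absorbance, and an optional fractional loss
of substrate to the flow-system tubing before mixing (so that the true
starting concentration must be estimated from A(t = 0), as with the real
instrument).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .constants import OpticalModel, RateConstants
from .scheme import simulate_scheme, trajectory_to_absorbance
from .transient import Transient

__all__ = [
    "TimebaseSpec",
    "NoiseSpec",
    "ExperimentDesign",
    "make_timebase",
    "generate_transient",
    "generate_experiment_set",
    "write_experiment_set",
    "read_experiment_set",
    "regenerate_experiment_set",
    "single_turnover_design",
    "single_turnover_short_design",
    "multiple_turnover_design",
    "uncatalysed_design",
]

DEAD_TIME = 0.002  # s; instrument cannot record before this


@dataclass(frozen=True)
class TimebaseSpec:
    """Sampling grid specification.

    Logarithmic mode emulates the instrument's cycle structure: the window
    [dead_time, duration] is covered by cycles x points_per_cycle
    geometrically spaced points (the instrument distributes each cycle's
    points logarithmically; the union is a geometric ladder, which is what
    matters for fitting).  Linear mode is an even grid of ``total_points``
    starting at the dead time with spacing duration / (total_points - 1).
    """

    mode: str = "logarithmic"
    duration: float = 1000.0
    cycles: int = 15
    points_per_cycle: int = 200
    total_points: int = 500
    dead_time: float = DEAD_TIME

    def __post_init__(self) -> None:
        if self.mode not in ("logarithmic", "linear"):
            raise ValueError(f"mode must be 'logarithmic' or 'linear', got {self.mode!r}")
        if self.dead_time < 0:
            raise ValueError("dead_time must be >= 0")
        if self.duration <= self.dead_time:
            raise ValueError(
                f"duration ({self.duration} s) must exceed dead_time ({self.dead_time} s)"
            )
        if min(self.cycles, self.points_per_cycle, self.total_points) < 1:
            raise ValueError("point counts must be >= 1")

    @property
    def n_points(self) -> int:
        if self.mode == "logarithmic":
            return self.cycles * self.points_per_cycle
        return self.total_points

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "duration": self.duration,
            "cycles": self.cycles,
            "points_per_cycle": self.points_per_cycle,
            "total_points": self.total_points,
            "dead_time": self.dead_time,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TimebaseSpec":
        return cls(**d)


@dataclass(frozen=True)
class NoiseSpec:
    """Additive Gaussian absorbance noise plus pre-mix substrate loss.

    ``substrate_loss_fraction`` models the substrate's weak affinity for
    the flow-system plastics: the concentration actually delivered to the
    cell is (1 - fraction) times nominal.
    """

    sigma: float = 0.002
    seed: int = 0
    substrate_loss_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if not (0.0 <= self.substrate_loss_fraction < 1.0):
            raise ValueError("substrate_loss_fraction must be in [0, 1)")

    def to_dict(self) -> dict:
        return {
            "sigma": self.sigma,
            "seed": self.seed,
            "substrate_loss_fraction": self.substrate_loss_fraction,
        }


@dataclass(frozen=True)
class ExperimentDesign:
    """A family of transients: one regime, one E0, several S0, replicates."""

    regime: str  # single_turnover | multiple_turnover | uncatalysed
    E0: float
    S0_values: tuple
    replicates: int = 3
    timebase: TimebaseSpec = field(default_factory=TimebaseSpec)
    noise: NoiseSpec = field(default_factory=NoiseSpec)

    def __post_init__(self) -> None:
        object.__setattr__(self, "S0_values", tuple(float(s) for s in self.S0_values))
        if self.regime not in ("single_turnover", "multiple_turnover", "uncatalysed"):
            raise ValueError(f"unknown regime {self.regime!r}")
        if self.regime == "single_turnover" and self.E0 <= max(self.S0_values):
            raise ValueError("single_turnover requires enzyme excess: E0 > max(S0)")
        if self.regime == "uncatalysed" and self.E0 != 0:
            raise ValueError("uncatalysed requires E0 = 0")
        if not (1 <= self.replicates <= 12):
            raise ValueError("replicates must be between 1 and 12")

    @property
    def n_transients(self) -> int:
        return len(self.S0_values) * self.replicates

    def to_dict(self) -> dict:
        return {
            "regime": self.regime,
            "E0": self.E0,
            "S0_values": list(self.S0_values),
            "replicates": self.replicates,
            "timebase": self.timebase.to_dict(),
            "noise": self.noise.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentDesign":
        d = dict(d)
        d["timebase"] = TimebaseSpec.from_dict(d["timebase"])
        d["noise"] = NoiseSpec(**d["noise"])
        d["S0_values"] = tuple(d["S0_values"])
        return cls(**d)


def make_timebase(spec: TimebaseSpec) -> np.ndarray:
    """Build the sampling grid for ``spec`` (strictly increasing, seconds)."""
    if spec.mode == "logarithmic":
        start = spec.dead_time if spec.dead_time > 0 else spec.duration * 1e-6
        return np.geomspace(start, spec.duration, spec.n_points)
    return spec.dead_time + np.linspace(0.0, spec.duration, spec.total_points)


def _transient_seed(base_seed: int, index: int) -> int:
    """Deterministic per-transient seed derived from the design seed."""
    ss = np.random.SeedSequence([int(base_seed), int(index)])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def generate_transient(
    rc: RateConstants,
    om: OpticalModel,
    E0: float,
    S0: float,
    tb: TimebaseSpec,
    noise: NoiseSpec,
) -> Transient:
    """One synthetic transient: simulate, project to absorbance, add noise.

    Deterministic given ``noise.seed``; with sigma = 0 the output equals the
    noiseless simulator projection on the same grid.  The *effective* S0
    delivered to the cell is reduced by ``substrate_loss_fraction``; the
    metadata records both nominal and effective values (ground truth for
    recovery scoring).
    """
    s_eff = S0 * (1.0 - noise.substrate_loss_fraction)
    grid = make_timebase(tb)
    traj = simulate_scheme(rc, E0, s_eff, grid)
    clean = trajectory_to_absorbance(traj, om)
    absorbance = clean.absorbance
    if noise.sigma > 0:
        rng = np.random.default_rng(noise.seed)
        absorbance = absorbance + rng.normal(0.0, noise.sigma, size=absorbance.size)
    meta = {
        "E0": E0,
        "S0_nominal": S0,
        "S0_effective": s_eff,
        "sigma": noise.sigma,
        "seed": noise.seed,
        "dead_time": tb.dead_time,
        "timebase": tb.to_dict(),
        "optical": om.to_dict(),
        "rate_constants": rc.to_dict(),
        "noiseless": noise.sigma == 0,
    }
    return Transient(grid, absorbance, meta)


def generate_experiment_set(
    design: ExperimentDesign,
    rc: RateConstants,
    om: OpticalModel,
) -> tuple[list[Transient], dict]:
    """All transients of a design plus a manifest that regenerates them.

    One transient per (S0, replicate); per-transient seeds are derived
    deterministically from the design's base seed so the manifest alone
    reproduces the data set bit-for-bit.
    """
    transients: list[Transient] = []
    records = []
    index = 0
    for S0 in design.S0_values:
        for rep in range(design.replicates):
            seed = _transient_seed(design.noise.seed, index)
            nspec = replace(design.noise, seed=seed)
            tr = generate_transient(rc, om, design.E0, S0, design.timebase, nspec)
            tr.meta["regime"] = design.regime
            tr.meta["replicate"] = rep
            transients.append(tr)
            records.append(
                {
                    "file": f"{design.regime}_S{S0:g}uM_rep{rep}.csv",
                    "S0_nominal": S0,
                    "S0_effective": tr.meta["S0_effective"],
                    "replicate": rep,
                    "seed": seed,
                }
            )
            index += 1
    manifest = {
        "design": design.to_dict(),
        "rate_constants": rc.to_dict(),
        "optical": om.to_dict(),
        "transients": records,
    }
    return transients, manifest


def write_experiment_set(
    transients: list[Transient], manifest: dict, outdir: str | Path
) -> Path:
    """Write one CSV per transient plus ``manifest.json``; returns manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for tr, rec in zip(transients, manifest["transients"]):
        tr.to_csv(outdir / rec["file"])
    mpath = outdir / f"manifest_{manifest['design']['regime']}.json"
    mpath.write_text(json.dumps(manifest, indent=2) + "\n")
    return mpath


def read_experiment_set(manifest_path: str | Path) -> tuple[list[Transient], dict]:
    """Load a written experiment set; metadata is rebuilt from the manifest."""
    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    design = manifest["design"]
    transients = []
    for rec in manifest["transients"]:
        meta = {
            "E0": design["E0"],
            "S0_nominal": rec["S0_nominal"],
            "S0_effective": rec["S0_effective"],
            "sigma": design["noise"]["sigma"],
            "seed": rec["seed"],
            "dead_time": design["timebase"]["dead_time"],
            "timebase": design["timebase"],
            "optical": manifest["optical"],
            "rate_constants": manifest["rate_constants"],
            "regime": design["regime"],
            "replicate": rec["replicate"],
            "noiseless": design["noise"]["sigma"] == 0,
        }
        transients.append(Transient.from_csv(manifest_path.parent / rec["file"], meta))
    return transients, manifest


def regenerate_experiment_set(manifest: dict) -> list[Transient]:
    """Re-create the exact transients described by a manifest (determinism)."""
    design = ExperimentDesign.from_dict(manifest["design"])
    rc = RateConstants.from_dict(manifest["rate_constants"])
    om = OpticalModel.from_dict(manifest["optical"])
    transients, _ = generate_experiment_set(design, rc, om)
    return transients


# -- default designs (the study conditions) --------------------------------


def single_turnover_design(
    *, seed: int = 0, sigma: float = 0.002, replicates: int = 3,
    substrate_loss_fraction: float = 0.0,
) -> ExperimentDesign:
    """Enzyme excess, long logarithmic timebase for 3-phase deconvolution.

    400 uM enzyme against a substrate series of 5-100 uM; 1000 s
    logarithmic timebase with 15 cycles x 200 points.
    """
    return ExperimentDesign(
        regime="single_turnover",
        E0=400.0,
        S0_values=(5.0, 10.0, 25.0, 50.0, 75.0, 100.0),
        replicates=replicates,
        timebase=TimebaseSpec("logarithmic", 1000.0, 15, 200),
        noise=NoiseSpec(sigma, seed, substrate_loss_fraction),
    )


def single_turnover_short_design(
    *, seed: int = 1, sigma: float = 0.002, replicates: int = 3,
    substrate_loss_fraction: float = 0.0,
) -> ExperimentDesign:
    """Enzyme excess over 10 s, for the 3-10 s linear tail analysis."""
    return ExperimentDesign(
        regime="single_turnover",
        E0=400.0,
        S0_values=(5.0, 10.0, 25.0, 50.0, 75.0, 100.0),
        replicates=replicates,
        timebase=TimebaseSpec("logarithmic", 10.0, 10, 200),
        noise=NoiseSpec(sigma, seed, substrate_loss_fraction),
    )


def multiple_turnover_design(
    *, seed: int = 2, sigma: float = 0.002, replicates: int = 3,
    substrate_loss_fraction: float = 0.0,
) -> ExperimentDesign:
    """Substrate excess over 1 uM enzyme: burst + steady-state regime."""
    return ExperimentDesign(
        regime="multiple_turnover",
        E0=1.0,
        S0_values=(5.0, 10.0, 18.0, 27.0, 36.0, 45.0, 54.0),
        replicates=replicates,
        timebase=TimebaseSpec("logarithmic", 10.0, 10, 200),
        noise=NoiseSpec(sigma, seed, substrate_loss_fraction),
    )


def uncatalysed_design(
    *, seed: int = 3, sigma: float = 0.002, replicates: int = 3,
    substrate_loss_fraction: float = 0.0,
) -> ExperimentDesign:
    """No enzyme: spontaneous cyclisation only, linear 10 s timebase."""
    return ExperimentDesign(
        regime="uncatalysed",
        E0=0.0,
        S0_values=(10.0, 50.0, 100.0),
        replicates=replicates,
        timebase=TimebaseSpec("linear", 10.0, total_points=500),
        noise=NoiseSpec(sigma, seed, substrate_loss_fraction),
    )
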