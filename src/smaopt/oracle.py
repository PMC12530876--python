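"""Synthetic bulk-phase density oracle.

Stands in for the molecular-dynamics simulations that map Lennard-Jones
parameters to the liquid density of n-octane at 293.15 K / 1 bar.  The oracle
reproduces the qualitative landscape of that mapping rather than any specific
simulation engine:

* a **smooth** sigmoidal backbone, monotone decreasing in the molecular
  volume proxy ``v = 8*sigma_C^3 + 18*sigma_H^3`` (8 carbons, 18 hydrogens):
  small atoms pack densely, large atoms blow the liquid up.  The backbone is
  calibrated so its 700 kg/m^3 level set crosses the interior of the feasible
  box, giving the optimizer a realizable target.
* a **rugged** perturbation in the (sigma_H, eps_C) plane — a product of
  sinusoids whose amplitude grows with eps_C — creating alternating bands of
  above/below-target density at a length scale much shorter than the box,
  which is what makes grid designs alias and flexible regressors necessary.
* Gaussian **noise** emulating finite-length sampling error, and a small
  **failure probability** producing invalid records with implausible
  densities, emulating crashed or unconverged runs.

The closed form below is the package's single source of ground truth: every
verification step re-evaluates it.

    rho(p) = clamp(smooth(v(p)) + rugged(p) + noise, 0, cap)
    smooth(v) = offset + amplitude * logistic(-(v - ref_volume) * steepness)
    rugged(p) = rugged_amp * eps_C * sin(2*pi*sigma_H / wavelength_sigma_H)
                                   * sin(2*pi*eps_C / wavelength_eps_C)
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.special import expit

from .data import DensityDataset, DensityRecord
from .errors import ContractError
from .space import LJParamSet

#: hard cap on any reported density, kg/m^3
DENSITY_CAP = 2000.0


@dataclass(frozen=True)
class OracleConfig:
    """Parameters of the synthetic density landscape.

    Defaults emulate the study conditions: target 700 kg/m^3, a smooth
    transition spanning the feasible box, rugged sigma_H/eps_C coupling with
    ~5 oscillations across the box, 5 kg/m^3 sampling noise, and a 5% chance
    that a pseudo-simulation fails outright.
    """

    target_density: float = 700.0  # kg/m^3
    amplitude: float = 1000.0      # kg/m^3, total smooth swing
    offset: float = 200.0          # kg/m^3, large-volume asymptote
    steepness: float = 10.0        # 1/nm^3, sharpness of the transition
    ref_volume: float = 0.15       # nm^3, volume proxy at the 700 level set
    rugged_amp: float = 60.0       # kg m^-3 per kJ mol^-1 of eps_C
    wavelength_sigma_H: float = 0.06   # nm
    wavelength_eps_C: float = 0.25     # kJ/mol
    noise_sd: float = 5.0          # kg/m^3
    failure_prob: float = 0.05
    master_seed: int = 0
    cap: float = DENSITY_CAP

    def __post_init__(self) -> None:
        if self.amplitude < 0 or self.rugged_amp < 0 or self.noise_sd < 0:
            raise ContractError("amplitudes and noise must be >= 0")
        if self.wavelength_sigma_H <= 0 or self.wavelength_eps_C <= 0:
            raise ContractError("wavelengths must be > 0")
        if not 0.0 <= self.failure_prob <= 1.0:
            raise ContractError("failure probability must be in [0, 1]")

    def noiseless(self) -> "OracleConfig":
        """Deterministic smooth+rugged landscape (no noise, no failures)."""
        return replace(self, noise_sd=0.0, failure_prob=0.0)

    def smooth_only(self) -> "OracleConfig":
        """Pure sigmoidal backbone: ruggedness, noise and failures off."""
        return replace(self, rugged_amp=0.0, noise_sd=0.0, failure_prob=0.0)

    def mild(self) -> "OracleConfig":
        """Mildly rugged variant used for end-to-end recovery studies.

        "Mild" means ruggedness at the sampling-noise scale: the maximum
        perturbation amplitude (at the largest well depth) is about twice the
        noise standard deviation, emulating the benign near-target region of a
        landscape a trained surrogate can represent to about 1%.
        """
        return replace(self, rugged_amp=8.0, failure_prob=0.0)


def volume_proxy(params: np.ndarray) -> np.ndarray:
    """Molecular volume proxy ``8*sigma_C^3 + 18*sigma_H^3`` in nm^3."""
    params = np.atleast_2d(np.asarray(params, dtype=float))
    return 8.0 * params[:, 0] ** 3 + 18.0 * params[:, 1] ** 3


def smooth_density(params: np.ndarray, cfg: OracleConfig) -> np.ndarray:
    """The monotone sigmoidal backbone evaluated at (n, 4) parameter rows."""
    v = volume_proxy(params)
    return cfg.offset + cfg.amplitude * expit(-(v - cfg.ref_volume) * cfg.steepness)


def rugged_density(params: np.ndarray, cfg: OracleConfig) -> np.ndarray:
    """The short-wavelength perturbation in the (sigma_H, eps_C) plane."""
    params = np.atleast_2d(np.asarray(params, dtype=float))
    sigma_H, eps_C = params[:, 1], params[:, 2]
    return (
        cfg.rugged_amp
        * eps_C
        * np.sin(2.0 * np.pi * sigma_H / cfg.wavelength_sigma_H)
        * np.sin(2.0 * np.pi * eps_C / cfg.wavelength_eps_C)
    )


def true_density(params: np.ndarray, cfg: OracleConfig) -> np.ndarray:
    """Noise-free landscape value (smooth + rugged, clamped)."""
    rho = smooth_density(params, cfg) + rugged_density(params, cfg)
    return np.clip(rho, 0.0, cfg.cap)


def _point_seed(master_seed: int, index: int) -> int:
    """Stable per-point seed; independent of evaluation order."""
    return int(np.random.SeedSequence((master_seed, index)).generate_state(1)[0])


def oracle_density(p: LJParamSet, cfg: OracleConfig, draw_seed: int) -> DensityRecord:
    """One pseudo-simulation: landscape value + noise, or a failed run.

    Deterministic given ``(p, cfg, draw_seed)``.  Failed runs are marked
    invalid and report an implausible density (0 or above the plausibility
    window), mimicking crashed or unconverged simulations.
    """
    rng = np.random.default_rng(draw_seed)
    failed = rng.uniform() < cfg.failure_prob
    if failed:
        # half the failures report zero, half an absurdly high density
        density = 0.0 if rng.uniform() < 0.5 else float(rng.uniform(0.8, 1.0) * cfg.cap)
        return DensityRecord(p.sigma_C, p.sigma_H, p.eps_C, p.eps_H, density, False)
    rho = float(true_density(p.as_array(), cfg)[0])
    if cfg.noise_sd > 0:
        rho += float(rng.normal(0.0, cfg.noise_sd))
    rho = float(np.clip(rho, 0.0, cfg.cap))
    return DensityRecord(p.sigma_C, p.sigma_H, p.eps_C, p.eps_H, rho, True)


def evaluate_samples(
    points: "np.ndarray | Sequence[LJParamSet]",
    cfg: OracleConfig,
    name: str = "dataset",
) -> DensityDataset:
    """Run the oracle over a point set; one record per point, in order.

    Per-point random streams are derived from ``(cfg.master_seed, index)`` so
    the dataset is independent of evaluation order or chunking.
    """
    if isinstance(points, np.ndarray):
        arr = np.atleast_2d(points)
    else:
        arr = np.array([p.as_array() for p in points])
    if arr.size == 0:
        raise ContractError("evaluate_samples needs at least one point")
    densities = np.empty(len(arr))
    valid = np.empty(len(arr), dtype=bool)
    for i, row in enumerate(arr):
        rec = oracle_density(
            LJParamSet.from_array(row), cfg, _point_seed(cfg.master_seed, i)
        )
        densities[i] = rec.density
        valid[i] = rec.valid
    return DensityDataset.from_arrays(name, arr, densities, valid)


def oracle_predictor(cfg: OracleConfig, noiseless: bool = True):
    """A density callable with the surrogate ``predict`` signature.

    Used as the reference mode of the optimizer: the ground-truth landscape
    itself plays the role of the surrogate.
    """
    eff = cfg.noiseless() if noiseless else cfg

    def predict(p: "LJParamSet | np.ndarray") -> "float | np.ndarray":
        arr = p.as_array() if isinstance(p, LJParamSet) else np.asarray(p, dtype=float)
        out = true_density(arr, eff)
        return float(out[0]) if arr.ndim == 1 else out

    return predict
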