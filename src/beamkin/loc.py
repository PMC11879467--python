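"""Modified line-of-centers threshold law, beam-broadening Monte Carlo, E0 fit.

Endothermic ion-molecule cross sections near threshold follow the modified
line-of-centers (LOC) law

    sigma(E) = sigma0 * (E + E_vib + E_rot - E0)^n / E        for excess > 0,

where E is the center-of-mass collision energy, E_vib and E_rot the
reactants' internal energies, E0 the 0 K threshold, and n a fit exponent
measuring how efficiently translation drives the reaction.  A measured
excitation function is the LOC curve convolved over everything that smears
the collision energy in a real beam: the lab-frame energy spread of the ion
beam, thermal (Doppler) motion of the target gas, Boltzmann internal-energy
distributions of both partners, and — for slow reactions — the kinetic
shift from the finite detection window.  The convolution is performed by
explicit Monte Carlo sampling of all four effects, and E0 is extracted by
least-squares matching of the simulated curve to the data with the exponent
n scanned over a plausible interval.
"""

from __future__ import annotations

import logging
import math
from collections.abc import Callable, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import minimize_scalar

from .constants import (
    AMU_TO_KG,
    CM1_TO_EV,
    EV_TO_J,
    FWHM_TO_SD,
    KB_EV,
    KB_J,
    T_ION,
)
from .errors import ConfigurationError, DegenerateDataError, FitError
from .collisions import reduced_mass

__all__ = [
    "LOCParams",
    "BeamConditions",
    "CrossSectionCurve",
    "ThresholdFit",
    "loc_sigma",
    "sample_vibrational_energy",
    "sample_rotational_energy",
    "sample_internal_energy",
    "simulate_convolved_sigma",
    "fit_threshold",
]

logger = logging.getLogger(__name__)

_ROT_DOF = {"atom": 0, "linear": 2, "nonlinear": 3}


@dataclass(frozen=True)
class LOCParams:
    """Line-of-centers parameters: normalization, 0 K threshold, exponent.

    ``sigma0`` carries units A^2 * eV^(1-n); ``e0`` is in eV; ``n`` is
    dimensionless and positive.
    """

    sigma0: float
    e0: float
    n: float

    def __post_init__(self) -> None:
        if self.sigma0 < 0:
            raise ValueError("sigma0 must be >= 0")
        if self.e0 < 0:
            raise ValueError("e0 must be >= 0")
        if self.n <= 0:
            raise ValueError("n must be > 0")


@dataclass(frozen=True)
class BeamConditions:
    """Everything the broadening Monte Carlo samples from.

    Temperatures in K (the ion thermalizes to the instrument's 310 K by
    default; the neutral target shares it unless stated otherwise), the
    lab-frame ion energy spread as a Gaussian FWHM in eV, reactant masses in
    amu, the detection time window in seconds for kinetic-shift weighting,
    and the vibrational frequencies (cm^-1) plus rotor type of each partner
    for internal-energy sampling.
    """

    m_ion: float
    m_neutral: float
    t_ion: float = T_ION
    t_neutral: float = T_ION
    fwhm_lab: float = 0.65
    detection_window: float = 1e-4
    ion_frequencies: tuple[float, ...] = ()
    neutral_frequencies: tuple[float, ...] = ()
    ion_rotational_model: str = "nonlinear"
    neutral_rotational_model: str = "nonlinear"

    def __post_init__(self) -> None:
        object.__setattr__(self, "ion_frequencies", tuple(float(f) for f in self.ion_frequencies))
        object.__setattr__(
            self, "neutral_frequencies", tuple(float(f) for f in self.neutral_frequencies)
        )
        if self.m_ion <= 0 or self.m_neutral <= 0:
            raise ConfigurationError("masses must be > 0")
        if self.t_ion <= 0 or self.t_neutral <= 0:
            raise ConfigurationError("temperatures must be > 0")
        if self.fwhm_lab < 0:
            raise ConfigurationError("fwhm_lab must be >= 0")
        if self.detection_window <= 0:
            raise ConfigurationError("detection_window must be > 0")
        for model in (self.ion_rotational_model, self.neutral_rotational_model):
            if model not in _ROT_DOF:
                raise ConfigurationError(f"unknown rotational model {model!r}")

    @property
    def reduced_mass(self) -> float:
        return reduced_mass(self.m_ion, self.m_neutral)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "BeamConditions":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigurationError(f"{path}: expected a mapping of beam settings")
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigurationError(f"{path}: {exc}") from exc

    def to_yaml(self, path: str | Path) -> None:
        block = {
            "m_ion": self.m_ion,
            "m_neutral": self.m_neutral,
            "t_ion": self.t_ion,
            "t_neutral": self.t_neutral,
            "fwhm_lab": self.fwhm_lab,
            "detection_window": self.detection_window,
            "ion_frequencies": list(self.ion_frequencies),
            "neutral_frequencies": list(self.neutral_frequencies),
            "ion_rotational_model": self.ion_rotational_model,
            "neutral_rotational_model": self.neutral_rotational_model,
        }
        Path(path).write_text(yaml.safe_dump(block, sort_keys=False))


@dataclass(frozen=True)
class CrossSectionCurve:
    """An energy-resolved cross-section curve: (E_CM / eV, sigma / A^2)."""

    e_cm: np.ndarray
    sigma: np.ndarray
    sigma_err: np.ndarray | None = None

    def __post_init__(self) -> None:
        e = np.asarray(self.e_cm, dtype=float)
        s = np.asarray(self.sigma, dtype=float)
        object.__setattr__(self, "e_cm", e)
        object.__setattr__(self, "sigma", s)
        if self.sigma_err is not None:
            err = np.asarray(self.sigma_err, dtype=float)
            object.__setattr__(self, "sigma_err", err)
            if err.shape != e.shape:
                raise ValueError("sigma_err must match e_cm in length")
        if e.ndim != 1 or s.shape != e.shape:
            raise ValueError("e_cm and sigma must be 1-D arrays of equal length")
        if np.any(np.diff(e) <= 0):
            raise ValueError("e_cm grid must be strictly increasing")
        if np.any(s < 0):
            raise ValueError("cross sections must be >= 0")

    def __len__(self) -> int:
        return len(self.e_cm)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"E_CM_eV": self.e_cm, "sigma_A2": self.sigma})
        if self.sigma_err is not None:
            df["sigma_err_A2"] = self.sigma_err
        return df

    def write(self, path: str | Path) -> None:
        """Write as a tab-delimited table with unit-bearing column names."""
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path: str | Path) -> "CrossSectionCurve":
        df = pd.read_csv(path, sep="\t", comment="#")
        err = df["sigma_err_A2"].to_numpy() if "sigma_err_A2" in df else None
        return cls(df["E_CM_eV"].to_numpy(), df["sigma_A2"].to_numpy(), err)


# ---------------------------------------------------------------------------
# The threshold law
# ---------------------------------------------------------------------------

def _loc_raw(e_cm, params: LOCParams, e_vib=0.0, e_rot=0.0):
    """Vectorized LOC law; returns 0 where E_CM <= 0 or excess <= 0."""
    e = np.asarray(e_cm, dtype=float)
    excess = e + e_vib + e_rot - params.e0
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(
            (excess > 0) & (e > 0),
            params.sigma0 * np.where(excess > 0, excess, 1.0) ** params.n / np.where(e > 0, e, 1.0),
            0.0,
        )
    return out


def loc_sigma(e_cm, params: LOCParams, e_vib: float = 0.0, e_rot: float = 0.0):
    """Modified line-of-centers cross section in A^2.

    ``sigma0 * (E_CM + E_vib + E_rot - E0)^n / E_CM`` when the excess
    energy is positive, else 0.  Continuous at threshold for any n > 0.
    Raises on non-positive E_CM.
    """
    e = np.asarray(e_cm, dtype=float)
    if np.any(e <= 0):
        raise ValueError("e_cm must be > 0")
    out = _loc_raw(e, params, e_vib, e_rot)
    return float(out) if np.isscalar(e_cm) else out


# ---------------------------------------------------------------------------
# Internal-energy sampling
# ---------------------------------------------------------------------------

def _shape(size) -> tuple[int, ...]:
    return (size,) if np.isscalar(size) else tuple(size)


def sample_vibrational_energy(
    frequencies: Sequence[float], temperature: float, size, rng: np.random.Generator
) -> np.ndarray:
    """Quantum Boltzmann vibrational energy above ZPE, eV, per harmonic mode.

    Each mode's quantum number follows P(v) ~ exp(-v h nu / kT) (a geometric
    distribution); the mean converges to h nu / (exp(h nu/kT) - 1).
    """
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    shp = _shape(size)
    freqs = np.asarray(list(frequencies), dtype=float)
    if freqs.size == 0:
        return np.zeros(shp)
    hv = freqs * CM1_TO_EV
    p = -np.expm1(-hv / (KB_EV * temperature))
    quanta = rng.geometric(p.reshape((-1,) + (1,) * len(shp)), size=(len(hv), *shp)) - 1
    return np.tensordot(hv, quanta, axes=(0, 0))


def sample_rotational_energy(
    rotational_model: str, temperature: float, size, rng: np.random.Generator
) -> np.ndarray:
    """Classical rotational energy in eV: Gamma(dof/2, kT), dof = 0, 2, or 3."""
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    dof = _ROT_DOF[rotational_model]
    shp = _shape(size)
    if dof == 0:
        return np.zeros(shp)
    return rng.gamma(dof / 2.0, KB_EV * temperature, size=shp)


def sample_internal_energy(
    frequencies: Sequence[float],
    rotational_model: str,
    temperature: float,
    n_samples: int,
    seed: int = 0,
) -> np.ndarray:
    """Total internal (vibrational + rotational) energy samples in eV."""
    rng = np.random.default_rng(seed)
    return sample_vibrational_energy(frequencies, temperature, n_samples, rng) + (
        sample_rotational_energy(rotational_model, temperature, n_samples, rng)
    )


# ---------------------------------------------------------------------------
# Monte Carlo convolution over beam conditions
# ---------------------------------------------------------------------------

def simulate_convolved_sigma(
    params: LOCParams,
    conditions: BeamConditions,
    e_cm_nominal,
    n_samples: int = 1000,
    seed: int = 0,
    kinetic_shift: Callable[[np.ndarray], np.ndarray] | None = None,
) -> CrossSectionCurve:
    """LOC cross section convolved over all experimental broadening sources.

    For each nominal center-of-mass energy the simulation draws, per Monte
    Carlo sample:

    * a lab-frame ion energy from a Gaussian of the stated FWHM,
    * a neutral velocity vector from the Maxwell-Boltzmann distribution at
      ``t_neutral`` (Doppler broadening enters through exact recomputation
      of the relative kinetic energy, not an analytic width),
    * vibrational and rotational energies of both partners from their
      Boltzmann distributions,

    evaluates the LOC law at the sampled energies and, when a rate function
    ``k(E_total)`` in 1/s is supplied, weights each sample by the detection
    probability ``1 - exp(-k * detection_window)`` (the kinetic shift).
    The per-grid-point mean is returned with its Monte Carlo standard error
    in ``sigma_err``.  Deterministic for a fixed seed.
    """
    grid = np.atleast_1d(np.asarray(e_cm_nominal, dtype=float))
    if np.any(grid <= 0):
        raise ConfigurationError("nominal E_CM grid must be positive")
    if n_samples < 1:
        raise ConfigurationError("n_samples must be >= 1")
    c = conditions
    rng = np.random.default_rng(seed)
    shape = (len(grid), n_samples)

    frac = c.m_neutral / (c.m_ion + c.m_neutral)
    e_lab = grid[:, None] / frac
    if c.fwhm_lab > 0:
        e_lab = e_lab + rng.normal(0.0, c.fwhm_lab * FWHM_TO_SD, shape)
        e_lab = np.clip(e_lab, 0.0, None)
    else:
        e_lab = np.broadcast_to(e_lab, shape)

    v_ion = np.sqrt(2.0 * e_lab * EV_TO_J / (c.m_ion * AMU_TO_KG))
    sd_n = math.sqrt(KB_J * c.t_neutral / (c.m_neutral * AMU_TO_KG))
    v_nx = rng.normal(0.0, sd_n, shape)
    v_ny = rng.normal(0.0, sd_n, shape)
    v_nz = rng.normal(0.0, sd_n, shape)
    mu_kg = c.reduced_mass * AMU_TO_KG
    e_rel = 0.5 * mu_kg * ((v_ion - v_nz) ** 2 + v_nx**2 + v_ny**2) / EV_TO_J

    e_vib = sample_vibrational_energy(c.ion_frequencies, c.t_ion, shape, rng)
    e_vib += sample_vibrational_energy(c.neutral_frequencies, c.t_neutral, shape, rng)
    e_rot = sample_rotational_energy(c.ion_rotational_model, c.t_ion, shape, rng)
    e_rot += sample_rotational_energy(c.neutral_rotational_model, c.t_neutral, shape, rng)

    sigma = _loc_raw(e_rel, params, e_vib, e_rot)
    if kinetic_shift is not None:
        k = np.asarray(kinetic_shift(e_rel + e_vib + e_rot), dtype=float)
        sigma = sigma * (-np.expm1(-k * c.detection_window))

    mean = sigma.mean(axis=1)
    if n_samples > 1:
        se = sigma.std(axis=1, ddof=1) / math.sqrt(n_samples)
    else:
        se = np.zeros_like(mean)
    return CrossSectionCurve(grid, mean, se)


# ---------------------------------------------------------------------------
# Threshold fitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ThresholdFit:
    """Result of a threshold fit.

    ``e0_unc_n_scan`` is half the spread of fitted E0 values over the
    acceptable exponents, ``e0_unc_ecm`` the energy-scale uncertainty of
    the E_CM grid, and ``e0_uncertainty`` their quadrature combination; the
    components are reported separately because how the two should be merged
    is a convention, not a derivation.
    """

    params: LOCParams
    objective: float
    e0_unc_n_scan: float
    e0_unc_ecm: float
    e0_uncertainty: float
    n_scan: pd.DataFrame = field(repr=False)

    def best_curve(
        self, conditions: BeamConditions, e_cm, n_samples: int = 2000, seed: int = 0
    ) -> CrossSectionCurve:
        """Simulated best-fit curve on an arbitrary grid."""
        return simulate_convolved_sigma(self.params, conditions, e_cm, n_samples, seed)


def _weights(data: CrossSectionCurve) -> np.ndarray:
    """1/err^2 where uncertainties are supplied, else uniform.

    Below-threshold points often carry vanishing or numerically tiny
    uncertainties (no signal, no scatter); taken literally these would
    dominate the objective by many orders of magnitude.  Errors are
    therefore floored at 1% of the largest quoted error, which caps the
    weight span at four orders of magnitude while leaving the weighting of
    all significant points untouched.
    """
    if data.sigma_err is None or not np.any(data.sigma_err > 0):
        return np.ones_like(data.sigma)
    err = data.sigma_err.copy()
    floor = 0.01 * err.max()
    err[err < floor] = floor
    return 1.0 / err**2


def _profiled_objective(
    e0: float,
    n: float,
    data: CrossSectionCurve,
    conditions: BeamConditions,
    weights: np.ndarray,
    n_samples: int,
    sim_seed: int,
    kinetic_shift,
) -> tuple[float, float]:
    """Weighted SSE at (e0, n) with sigma0 profiled out analytically.

    The LOC law is linear in sigma0, so for a unit-normalization simulation
    with predicted curve yhat the optimal normalization is
    ``sigma0 = sum(w y yhat) / sum(w yhat^2)`` (clipped at 0).  The same
    ``sim_seed`` is used for every call (common random numbers) so the
    objective is a deterministic, optimizable function of e0.
    """
    trial = LOCParams(1.0, max(e0, 0.0), n)
    sim = simulate_convolved_sigma(
        trial, conditions, data.e_cm, n_samples, sim_seed, kinetic_shift
    )
    yhat = sim.sigma
    denom = float(np.sum(weights * yhat**2))
    if denom <= 0.0:
        return float(np.sum(weights * data.sigma**2)), 0.0
    sigma0 = max(float(np.sum(weights * data.sigma * yhat)) / denom, 0.0)
    obj = float(np.sum(weights * (data.sigma - sigma0 * yhat) ** 2))
    return obj, sigma0


def fit_threshold(
    data: CrossSectionCurve,
    conditions: BeamConditions,
    n_range: tuple[float, float] = (2.4, 2.5),
    init: LOCParams | None = None,
    n_samples: int = 512,
    seed: int = 0,
    n_step: float = 0.1,
    e0_halfwidth: float = 0.8,
    ecm_uncertainty: float = 0.05,
    acceptable_window: float = 0.10,
    kinetic_shift: Callable[[np.ndarray], np.ndarray] | None = None,
) -> ThresholdFit:
    """Extract (sigma0, E0, n) by matching the convolved model to data.

    For each exponent n on a grid of step ``n_step`` over ``n_range``, E0 is
    optimized by a coarse scan plus bounded 1-D refinement of the weighted
    least-squares objective (sigma0 profiled out analytically; common random
    numbers across objective calls).  The best (sigma0, E0, n) is returned
    together with an E0 uncertainty built from half the E0 spread over
    "acceptable" exponents — those whose objective lies within
    ``acceptable_window`` of the minimum — combined in quadrature with the
    ``ecm_uncertainty`` of the energy scale.
    """
    if len(data) < 5:
        raise DegenerateDataError("need at least 5 data points spanning the threshold")
    if not np.any(data.sigma > 0):
        raise DegenerateDataError("all-zero cross sections carry no threshold information")
    if n_range[1] < n_range[0]:
        raise ConfigurationError("n_range must satisfy n_min <= n_max")

    weights = _weights(data)
    if init is None:
        onset = data.e_cm[np.argmax(data.sigma >= 0.1 * data.sigma.max())]
        init = LOCParams(1.0, float(onset), 2.4)

    n_values = np.arange(n_range[0], n_range[1] + 0.5 * n_step, n_step)
    lo = max(data.e_cm[0] * 0.05, init.e0 - e0_halfwidth)
    hi = init.e0 + e0_halfwidth
    coarse = np.linspace(lo, hi, 17)
    rows = []
    for n in n_values:
        objs = [
            _profiled_objective(
                e0, n, data, conditions, weights, n_samples, seed, kinetic_shift
            )[0]
            for e0 in coarse
        ]
        i_best = int(np.argmin(objs))
        b_lo = coarse[max(i_best - 1, 0)]
        b_hi = coarse[min(i_best + 1, len(coarse) - 1)]
        res = minimize_scalar(
            lambda e0: _profiled_objective(
                e0, n, data, conditions, weights, n_samples, seed, kinetic_shift
            )[0],
            bounds=(b_lo, b_hi),
            method="bounded",
            options={"xatol": 1e-3},
        )
        if not np.isfinite(res.fun):
            raise FitError(
                f"threshold fit failed to converge at n={n:.2f}: "
                f"objective={res.fun!r}, e0={res.x!r}"
            )
        obj, sigma0 = _profiled_objective(
            float(res.x), n, data, conditions, weights, n_samples, seed, kinetic_shift
        )
        logger.info("n=%.2f  E0=%.4f eV  sigma0=%.4g  objective=%.6g", n, res.x, sigma0, obj)
        rows.append({"n": float(n), "e0_eV": float(res.x), "sigma0": sigma0, "objective": obj})

    scan = pd.DataFrame(rows)
    best = scan.loc[scan["objective"].idxmin()]
    acceptable = scan[scan["objective"] <= (1.0 + acceptable_window) * best["objective"]]
    unc_n = 0.5 * float(acceptable["e0_eV"].max() - acceptable["e0_eV"].min())
    total = math.hypot(unc_n, ecm_uncertainty)
    return ThresholdFit(
        params=LOCParams(float(best["sigma0"]), float(best["e0_eV"]), float(best["n"])),
        objective=float(best["objective"]),
        e0_unc_n_scan=unc_n,
        e0_unc_ecm=ecm_uncertainty,
        e0_uncertainty=total,
        n_scan=scan,
    )
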