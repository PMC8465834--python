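"""Synthetic trajectories with the statistical structure the analysis assumes.

Stands in for the MD/QM-MM production runs so every analysis stage is testable
without molecular-simulation software: donor/acceptor site-energy traces whose
gap ramps from −2 eV to zero at a configurable equalization time (clamped
afterwards) under stationary Ornstein–Uhlenbeck noise; fs-sampled
potential-like signals carrying harmonics in the 100–3000 cm⁻¹ band; and toy
solvated point-charge snapshots (fixed solute sites plus reorienting
water-like dipoles) writable as multi-model PQR.

All generators are pure functions of (config, seed); replicate ``i`` uses seed
``base_seed + i``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import lfilter

from .constants import THZ_TO_WAVENUMBER
from .electrostatics import ChargeSnapshot
from .errors import ConfigError, InvalidParameterError
from .trajectory import SiteEnergyTrace, Trace

__all__ = [
    "TraceConfig",
    "SnapshotConfig",
    "ou_process",
    "generate_gap_trace",
    "generate_potential_signal",
    "generate_snapshot_series",
]


def ou_process(
    n: int,
    dt: float,
    sigma: float,
    tau_c: float,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Stationary Ornstein–Uhlenbeck sequence by exact discretization.

    x_{t+1} = x_t e^{−dt/τc} + σ √(1 − e^{−2dt/τc}) ξ_t with x_0 ~ N(0, σ²),
    so every marginal is N(0, σ²) and the lag-k autocorrelation is
    e^{−k·dt/τc} for any step size.  Reproducible per seed.
    """
    if tau_c <= 0:
        raise InvalidParameterError(f"tau_c must be > 0, got {tau_c}")
    if sigma < 0:
        raise InvalidParameterError(f"sigma must be >= 0, got {sigma}")
    if n < 1:
        raise InvalidParameterError(f"n must be >= 1, got {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if sigma == 0.0:
        rng.standard_normal(n)  # keep the stream position deterministic
        return np.zeros(n)
    a = math.exp(-dt / tau_c)
    b = sigma * math.sqrt(1.0 - a * a)
    eps = rng.standard_normal(n)
    x = np.empty(n)
    x[0] = sigma * eps[0]
    if n > 1:
        # AR(1) recursion x_t = a x_{t-1} + b eps_t via a linear filter.
        x[1:], _ = lfilter([b], [1.0, -a], eps[1:], zi=np.array([a * x[0]]))
    return x


@dataclass(frozen=True)
class TraceConfig:
    """Parameters of the synthetic site-energy and potential generators.

    Defaults emulate the study conditions: 2 ns duration sampled every 0.5 ps,
    3 replicates, an initial donor−acceptor gap of −2.0 eV rising linearly at
    +2.5e−3 eV/ps (zero crossing at 800 ps, clamped afterwards), and OU noise
    of 0.15 eV standard deviation with a 10 ps correlation time on the gap.
    ``harmonics`` (wavenumber cm⁻¹, amplitude) feed the potential-like signal
    generator, which needs a fs-scale ``dt_ps``.
    """

    duration_ps: float = 2000.0
    dt_ps: float = 0.5
    initial_gap_eV: float = -2.0
    slope_eV_per_ps: float = 2.5e-3
    equalization_ps: float | None = None  # overrides slope when set
    clamp: bool = True
    sigma_eV: float = 0.15
    tau_c_ps: float = 10.0
    harmonics: tuple[tuple[float, float], ...] = ()
    mean_level: float = 0.0
    n_replicates: int = 3
    seed: int = 0
    acceptor_level_eV: float = -5.0
    common_mode_sigma_eV: float = 0.0

    def __post_init__(self) -> None:
        if self.duration_ps <= 0 or self.dt_ps <= 0:
            raise ConfigError("duration and sampling interval must be > 0")
        if self.sigma_eV < 0 or self.common_mode_sigma_eV < 0:
            raise ConfigError("noise sigma must be >= 0")
        if self.n_replicates < 1:
            raise ConfigError("n_replicates must be >= 1")
        if self.equalization_ps is not None and self.equalization_ps <= 0:
            raise ConfigError("equalization_ps must be > 0")

    @property
    def effective_slope(self) -> float:
        """Ramp slope in eV/ps (derived from the target crossing when set)."""
        if self.equalization_ps is not None:
            return -self.initial_gap_eV / self.equalization_ps
        return self.slope_eV_per_ps

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_ps / self.dt_ps)) + 1

    def time_grid(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.dt_ps


def generate_gap_trace(config: TraceConfig, replicate: int = 0) -> SiteEnergyTrace:
    """One replicate of donor/acceptor site-energy channels (eV).

    The acceptor channel fluctuates about a fixed level; the donor channel
    carries the deterministic gap ramp (clamped at zero after the crossing
    when ``clamp`` is set, emulating levels that stay degenerate once
    equalized).  Each channel receives independent OU noise of standard
    deviation σ/√2 so the *gap* noise has standard deviation σ; an optional
    common-mode OU term (cancelling in the gap) models correlated solvent
    drift.  Replicate seed = base seed + replicate index; bit-identical per
    (config, replicate).
    """
    if replicate < 0:
        raise InvalidParameterError("replicate index must be >= 0")
    times = config.time_grid()
    gap_det = config.initial_gap_eV + config.effective_slope * times
    if config.clamp:
        if config.initial_gap_eV < 0:
            gap_det = np.minimum(gap_det, 0.0)
        elif config.initial_gap_eV > 0:
            gap_det = np.maximum(gap_det, 0.0)
    rng = np.random.default_rng(config.seed + replicate)
    sigma_channel = config.sigma_eV / math.sqrt(2.0)
    noise_d = ou_process(times.size, config.dt_ps, sigma_channel, config.tau_c_ps, rng)
    noise_a = ou_process(times.size, config.dt_ps, sigma_channel, config.tau_c_ps, rng)
    common = (
        ou_process(times.size, config.dt_ps, config.common_mode_sigma_eV,
                   config.tau_c_ps, rng)
        if config.common_mode_sigma_eV > 0
        else 0.0
    )
    e_acceptor = config.acceptor_level_eV + noise_a + common
    e_donor = config.acceptor_level_eV + gap_det + noise_d + common
    return SiteEnergyTrace(
        times=times, e_donor=e_donor, e_acceptor=e_acceptor, replicate=replicate
    )


def generate_potential_signal(
    config: TraceConfig,
    seed: int | None = None,
    phases: Sequence[float] | None = None,
) -> Trace:
    """Potential-like signal: mean level + cosines + OU noise.

    Each configured harmonic (wavenumber cm⁻¹, amplitude) becomes a cosine at
    frequency ν̃/33.35641 THz with a random phase (or the supplied ``phases``);
    the sampling interval must resolve the fastest harmonic (Nyquist check).
    Designed so :func:`holehop.trajectory.fourier_spectrum` recovers the
    planted band.
    """
    times = config.time_grid()
    nyquist_thz = 0.5 / config.dt_ps
    rng = np.random.default_rng(config.seed if seed is None else seed)
    values = np.full(times.size, config.mean_level, dtype=float)
    if phases is not None and len(phases) != len(config.harmonics):
        raise ConfigError("phases must match the number of harmonics")
    for k, (wavenumber, amplitude) in enumerate(config.harmonics):
        freq_thz = wavenumber / THZ_TO_WAVENUMBER
        if freq_thz >= nyquist_thz:
            raise ConfigError(
                f"harmonic at {wavenumber} cm^-1 ({freq_thz:.3g} THz) is at or "
                f"above the Nyquist frequency {nyquist_thz:.3g} THz for "
                f"dt = {config.dt_ps} ps"
            )
        phi = rng.uniform(0.0, 2.0 * math.pi) if phases is None else float(phases[k])
        values += amplitude * np.cos(2.0 * math.pi * freq_thz * times + phi)
    values += ou_process(times.size, config.dt_ps, config.sigma_eV,
                         config.tau_c_ps, rng)
    return Trace(times=times, values=values, label="potential")


@dataclass(frozen=True)
class SnapshotConfig:
    """Toy solvated-system generator: fixed solute charges + water-like dipoles.

    Each dipole is two opposite fractional charges at fixed separation whose
    orientation random-walks on the unit sphere frame to frame; centers stay
    fixed.  ``solute_sites`` maps a site label to (x, y, z, charge) tuples.
    The defaults place a +1 e "G" cluster and a neutral "GGG" cluster in a
    20 Å box with 50 dipoles — a desk-scale stand-in for a solvated duplex.
    """

    box_ang: float = 20.0
    n_dipoles: int = 50
    dipole_charge_e: float = 0.4
    dipole_separation_ang: float = 1.0
    reorientation_sigma_rad: float = 0.3
    solute_sites: tuple[tuple[str, tuple[tuple[float, float, float, float], ...]], ...] = (
        ("G", (
            (6.0, 10.0, 10.0, 0.40),
            (6.8, 10.6, 10.0, 0.30),
            (6.8, 9.4, 10.0, 0.30),
        )),
        ("GGG", (
            (13.0, 10.0, 10.0, 0.20),
            (13.8, 10.6, 10.0, -0.20),
            (13.8, 9.4, 10.0, 0.10),
            (14.6, 10.0, 10.0, -0.10),
            (15.4, 10.6, 10.0, 0.15),
            (15.4, 9.4, 10.0, -0.15),
        )),
        # Counterions near each probed site: the environment of a cationic
        # solute stabilizes the hole, so site potentials come out negative.
        ("ions", (
            (6.5, 10.0, 13.5, -1.0),
            (14.2, 10.0, 13.8, -1.0),
        )),
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.box_ang <= 0 or self.n_dipoles < 0:
            raise ConfigError("box size must be > 0 and dipole count >= 0")
        if self.dipole_separation_ang <= 0:
            raise ConfigError("dipole separation must be > 0")


def _unit_rows(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def generate_snapshot_series(
    config: SnapshotConfig, n_frames: int
) -> list[ChargeSnapshot]:
    """Deterministic sequence of point-charge snapshots (PQR-writable).

    Solute atoms come first in file order (ids 1..n_solute, grouped by site),
    then the dipole atoms (+q then −q per dipole, net charge zero each).
    Orientations evolve by adding a Gaussian step to the unit vector and
    renormalizing.
    """
    if n_frames < 1:
        raise InvalidParameterError("n_frames must be >= 1")
    rng = np.random.default_rng(config.seed)
    solute_coords, solute_charges, solute_names = [], [], []
    sites: dict[str, list[int]] = {}
    atom_id = 1
    for label, atoms in config.solute_sites:
        sites[label] = []
        for x, y, z, q in atoms:
            solute_coords.append((x, y, z))
            solute_charges.append(q)
            solute_names.append("S")
            sites[label].append(atom_id)
            atom_id += 1
    solute_coords = np.array(solute_coords).reshape(-1, 3)
    solute_charges = np.array(solute_charges)

    n_dip = config.n_dipoles
    centers = rng.uniform(0.0, config.box_ang, size=(n_dip, 3))
    orient = _unit_rows(rng.standard_normal((n_dip, 3))) if n_dip else np.zeros((0, 3))
    half = 0.5 * config.dipole_separation_ang
    q_dip = config.dipole_charge_e

    snapshots: list[ChargeSnapshot] = []
    for _ in range(n_frames):
        if n_dip:
            plus = centers + half * orient
            minus = centers - half * orient
            dip_coords = np.empty((2 * n_dip, 3))
            dip_coords[0::2] = plus
            dip_coords[1::2] = minus
            dip_charges = np.empty(2 * n_dip)
            dip_charges[0::2] = q_dip
            dip_charges[1::2] = -q_dip
            coords = np.vstack([solute_coords, dip_coords])
            charges = np.concatenate([solute_charges, dip_charges])
            names = solute_names + ["W"] * (2 * n_dip)
        else:
            coords = solute_coords.copy()
            charges = solute_charges.copy()
            names = list(solute_names)
        snapshots.append(
            ChargeSnapshot(
                coords=coords, charges=charges, names=names,
                sites={k: list(v) for k, v in sites.items()},
            )
        )
        if n_dip:
            orient = _unit_rows(
                orient + config.reorientation_sigma_rad * rng.standard_normal((n_dip, 3))
            )
    return snapshots
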