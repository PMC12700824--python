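"""Brownian-dynamics simulation of photon-count traces and two-compartment FRAP.

The photon simulator propagates labeled oligomers through a periodic box
containing a 3D-Gaussian confocal detection profile

    W(r) = exp(-2 (x^2 + y^2) / w_xy^2 - 2 z^2 / w_z^2),

emitting Poisson-distributed counts in a green and a red channel at a fixed
bin width (default 100 µs, acquisitions of ~25 s).  It reproduces the raw
material of PCH/FCS/FCCS analysis — molecular brightness, occupancy and
diffusion-time information — for particles of known protomer number, label
stoichiometry and diffusion coefficient, with optional detector background,
green-to-red spectral bleedthrough and slow multiplicative drift.

The FRAP simulator integrates the two-compartment exchange model for a focus
whose two halves mix internally at rate ``k_int`` and exchange with an
unbleached pool at rate ``k_ex``; it generates noisy, normalized half-focus
redistribution curves of the kind quantified by the dip statistic in
:mod:`ffstools.frap`.

Photophysics (blinking, photobleaching of diffusing species), triplet
dynamics and detector dead time are deliberately outside the model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .exceptions import SizeError, ValidationError

__all__ = [
    "ConfocalVolume",
    "DEFAULT_VOLUME",
    "SpeciesSpec",
    "SimulationConfig",
    "PhotonTrace",
    "FRAPSimConfig",
    "simulate_trace",
    "simulate_frap",
    "psf_weight",
    "exchange_solution",
]


@dataclass(frozen=True)
class ConfocalVolume:
    """3D-Gaussian detection geometry.

    Parameters
    ----------
    w_xy : float
        Lateral 1/e^2 waist, µm.
    w_z : float
        Axial 1/e^2 waist, µm; must satisfy ``w_z >= w_xy``.

    The shape factor ``S = w_z / w_xy`` and the effective volume
    ``V_eff = pi^{3/2} w_xy^2 w_z`` (fl) are derived quantities.
    """

    w_xy: float
    w_z: float

    def __post_init__(self):
        if not (np.isfinite(self.w_xy) and np.isfinite(self.w_z)):
            raise ValidationError("confocal waists must be finite")
        if self.w_xy <= 0:
            raise ValidationError("w_xy must be positive")
        if self.w_z < self.w_xy:
            raise ValidationError("w_z must be >= w_xy")

    @property
    def S(self) -> float:
        """Shape factor w_z / w_xy (dimensionless)."""
        return self.w_z / self.w_xy

    @property
    def V_eff(self) -> float:
        """Effective volume pi^{3/2} w_xy^2 w_z, in fl (= µm^3)."""
        return math.pi ** 1.5 * self.w_xy**2 * self.w_z

    @classmethod
    def from_shape_factor(cls, v_eff_fl: float = 1.0, S: float = 6.0) -> "ConfocalVolume":
        """Solve waists from an effective volume and shape factor.

        The default (1 fl, S = 6) gives w_xy ≈ 0.311 µm and w_z ≈ 1.866 µm,
        typical of a confocal spot used for in-cell FCS.
        """
        if v_eff_fl <= 0 or S < 1:
            raise ValidationError("need v_eff_fl > 0 and S >= 1")
        w_xy = (v_eff_fl / (math.pi ** 1.5 * S)) ** (1.0 / 3.0)
        return cls(w_xy=w_xy, w_z=S * w_xy)


#: Default detection volume: ~1 fl with shape factor 6.
DEFAULT_VOLUME = ConfocalVolume.from_shape_factor(1.0, 6.0)


@dataclass(frozen=True)
class SpeciesSpec:
    """One diffusing oligomeric species.

    ``eps_g``/``eps_r`` are per-fluorophore molecular brightnesses at beam
    center (counts/s/molecule); a particle of ``n_protomers`` protomers, each
    carrying one fluorophore, emits ``n_protomers * eps`` at the center.
    ``mean_occupancy`` is the expected particle number inside V_eff.
    """

    n_protomers: int = 1
    eps_g: float = 1.0e4
    eps_r: float = 0.0
    D: float = 25.0  # µm^2/s
    mean_occupancy: float = 1.0

    def __post_init__(self):
        vals = (self.eps_g, self.eps_r, self.D, self.mean_occupancy)
        if not all(np.isfinite(v) for v in vals):
            raise ValidationError("species parameters must be finite")
        if self.n_protomers < 1:
            raise ValidationError("n_protomers must be >= 1")
        if self.eps_g < 0 or self.eps_r < 0:
            raise ValidationError("brightness must be >= 0")
        if self.D <= 0:
            raise ValidationError("D must be > 0")
        if self.mean_occupancy < 0:
            raise ValidationError("mean_occupancy must be >= 0")


@dataclass(frozen=True)
class SimulationConfig:
    volume: ConfocalVolume = DEFAULT_VOLUME
    species: tuple = ()
    bin_width: float = 1e-4  # s
    duration: float = 25.0  # s
    box_margin: float = 6.0  # box edge, in multiples of w_z
    background_g: float = 0.0  # counts/s
    background_r: float = 0.0
    bleed_g_to_r: float = 0.0
    drift_amplitude: float = 0.0
    seed: int = 0

    def __post_init__(self):
        scalars = (
            self.bin_width,
            self.duration,
            self.box_margin,
            self.background_g,
            self.background_r,
            self.bleed_g_to_r,
            self.drift_amplitude,
        )
        if not all(np.isfinite(v) for v in scalars):
            raise ValidationError("simulation parameters must be finite")
        if self.bin_width <= 0:
            raise ValidationError("bin_width must be > 0")
        if self.duration < 100 * self.bin_width:
            raise ValidationError("duration must be >= 100 bins")
        if not (0 <= self.bleed_g_to_r < 1):
            raise ValidationError("bleed_g_to_r must be in [0, 1)")
        if self.background_g < 0 or self.background_r < 0:
            raise ValidationError("background rates must be >= 0")
        if self.box_volume < 20 * self.volume.V_eff:
            raise ValidationError("box volume must be >= 20 * V_eff")

    @property
    def box_edge(self) -> float:
        """Cubic periodic box edge, µm."""
        return self.box_margin * self.volume.w_z

    @property
    def box_volume(self) -> float:
        """Box volume in fl (= µm^3)."""
        return self.box_edge**3

    @property
    def n_bins(self) -> int:
        return int(round(self.duration / self.bin_width))


@dataclass
class PhotonTrace:
    """Evenly binned two-channel photon counts."""

    bin_width: float
    counts_g: np.ndarray
    counts_r: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.counts_g = np.asarray(self.counts_g, dtype=np.int64)
        self.counts_r = np.asarray(self.counts_r, dtype=np.int64)
        if self.bin_width <= 0:
            raise ValidationError("bin_width must be > 0")
        if self.counts_g.shape != self.counts_r.shape or self.counts_g.ndim != 1:
            raise ValidationError("channels must be 1-D and of equal length")
        if (self.counts_g < 0).any() or (self.counts_r < 0).any():
            raise ValidationError("counts must be non-negative")

    def __len__(self) -> int:
        return self.counts_g.size

    @property
    def duration(self) -> float:
        return len(self) * self.bin_width

    def channel(self, name: str) -> np.ndarray:
        if name == "g":
            return self.counts_g
        if name == "r":
            return self.counts_r
        raise ValidationError(f"channel must be 'g' or 'r', got {name!r}")


def psf_weight(volume: ConfocalVolume, x, y, z):
    """Normalized detection profile W(r) at position(s) in µm (W(0) = 1)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    return np.exp(
        -2.0 * (x**2 + y**2) / volume.w_xy**2 - 2.0 * z**2 / volume.w_z**2
    )


def _particle_count(species: SpeciesSpec, config: SimulationConfig) -> int:
    return int(round(species.mean_occupancy * config.box_volume / config.volume.V_eff))


def simulate_trace(config: SimulationConfig) -> PhotonTrace:
    """Simulate a two-channel photon-count trace.

    Each species contributes ``round(mean_occupancy * V_box / V_eff)``
    particles performing independent Brownian walks (per-axis Gaussian steps
    of sd ``sqrt(2 D dt)``, one step per bin) in a periodic cubic box.  The
    per-bin expected count in each channel is the sum over particles of
    ``n_protomers * eps * bin_width * W(r)`` plus background; the red channel
    additionally receives ``bleed_g_to_r`` of the green particle signal.
    Optional drift multiplies expectations by ``1 + A sin(2 pi t / P)`` with
    period P = duration/2.  Counts are Poisson draws.

    The random stream splits deterministically from ``config.seed`` via
    ``numpy.random.SeedSequence``: child 0 drives photon (Poisson) noise, and
    child ``1 + i`` is the root of species ``i``, itself spawning one
    independent stream per particle.  Identical configs therefore produce
    bit-identical traces.
    """
    n_bins = config.n_bins
    if n_bins > 2**31 - 1:
        raise SizeError("duration/bin_width exceeds the supported trace length")
    dt = config.bin_width
    vol = config.volume
    edge = config.box_edge
    half = edge / 2.0

    root = np.random.SeedSequence(config.seed)
    photon_ss, *species_ss = root.spawn(1 + len(config.species))

    sig_g = np.zeros(n_bins)
    sig_r = np.zeros(n_bins)
    inv_wxy2 = 2.0 / vol.w_xy**2
    inv_wz2 = 2.0 / vol.w_z**2

    for spec, ss in zip(config.species, species_ss):
        n_part = _particle_count(spec, config)
        if n_part == 0 or (spec.eps_g == 0 and spec.eps_r == 0):
            continue
        step_sd = math.sqrt(2.0 * spec.D * dt)
        bright_g = spec.n_protomers * spec.eps_g * dt
        bright_r = spec.n_protomers * spec.eps_r * dt
        for pss in ss.spawn(n_part):
            rng = np.random.Generator(np.random.PCG64(pss))
            x0 = rng.uniform(-half, half, size=3)
            steps = rng.normal(0.0, step_sd, size=(n_bins, 3))
            pos = x0 + np.cumsum(steps, axis=0)
            # wrap into [-half, half)
            pos -= edge * np.floor((pos + half) / edge)
            w = np.exp(
                -(pos[:, 0] ** 2 + pos[:, 1] ** 2) * inv_wxy2
                - pos[:, 2] ** 2 * inv_wz2
            )
            if bright_g:
                sig_g += bright_g * w
            if bright_r:
                sig_r += bright_r * w

    lam_g = sig_g + config.background_g * dt
    lam_r = sig_r + config.bleed_g_to_r * sig_g + config.background_r * dt

    if config.drift_amplitude:
        t = (np.arange(n_bins) + 0.5) * dt
        period = config.duration / 2.0
        mod = 1.0 + config.drift_amplitude * np.sin(2.0 * math.pi * t / period)
        lam_g = lam_g * mod
        lam_r = lam_r * mod

    photon_rng = np.random.Generator(np.random.PCG64(photon_ss))
    counts_g = photon_rng.poisson(lam_g)
    counts_r = photon_rng.poisson(lam_r)
    meta = {
        "seed": config.seed,
        "duration": config.duration,
        "n_species": len(config.species),
        "box_edge_um": edge,
    }
    return PhotonTrace(config.bin_width, counts_g, counts_r, metadata=meta)


# ---------------------------------------------------------------------------
# Two-compartment half-focus FRAP simulator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FRAPSimConfig:
    """Half-focus FRAP exchange model parameters.

    ``k_int`` is the internal half-to-half mixing rate inside the focus and
    ``k_ex`` the exchange rate of either half with an effectively infinite
    unbleached pool (both 1/s).  ``noise_sd`` is the relative sd of additive
    Gaussian measurement noise on the normalized curves.
    """

    k_int: float = 1.0
    k_ex: float = 1.0
    dt: float = 0.02  # s
    duration: float = 10.0  # s
    noise_sd: float = 0.0
    n_prebleach: int = 5
    seed: int = 0

    def __post_init__(self):
        if not all(
            np.isfinite(v) for v in (self.k_int, self.k_ex, self.dt, self.duration, self.noise_sd)
        ):
            raise ValidationError("FRAP parameters must be finite")
        if self.k_int < 0 or self.k_ex < 0:
            raise ValidationError("rates must be >= 0")
        if self.dt <= 0 or self.duration <= 0:
            raise ValidationError("dt and duration must be > 0")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.n_prebleach < 3:
            raise ValidationError("need >= 3 pre-bleach samples")


def exchange_solution(t, k_int: float, k_ex: float):
    """Closed-form bleached/unbleached half intensities of the exchange model.

    B(t) = 1 - e^{-k_ex t}/2 - e^{-(2 k_int + k_ex) t}/2
    U(t) = 1 - e^{-k_ex t}/2 + e^{-(2 k_int + k_ex) t}/2

    with B(0) = 0, U(0) = 1 and an infinite pool at 1.  Used as the fitting
    model and as the analytic oracle for the numerically integrated simulator.
    """
    t = np.asarray(t, dtype=float)
    slow = np.exp(-k_ex * t)
    fast = np.exp(-(2.0 * k_int + k_ex) * t)
    return 1.0 - slow / 2.0 - fast / 2.0, 1.0 - slow / 2.0 + fast / 2.0


def _integrate_exchange(t_eval, k_int: float, k_ex: float):
    """Numerically integrate dB/dt = k_int (U-B) + k_ex (1-B) (and symm. U)."""

    def rhs(_t, y):
        b, u = y
        return [k_int * (u - b) + k_ex * (1.0 - b), k_int * (b - u) + k_ex * (1.0 - u)]

    if len(t_eval) == 0:
        return np.empty(0), np.empty(0)
    sol = solve_ivp(
        rhs,
        (0.0, float(t_eval[-1]) if t_eval[-1] > 0 else 1e-12),
        [0.0, 1.0],
        t_eval=t_eval,
        rtol=1e-10,
        atol=1e-12,
        method="DOP853",
    )
    return sol.y[0], sol.y[1]


def simulate_frap(config: FRAPSimConfig):
    """Simulate a normalized half-focus FRAP series (bleach at t = 0).

    The post-bleach curves come from numerical integration of the
    two-compartment ODE; a pre-bleach segment at level 1 is prepended and
    relative Gaussian noise (sd ``noise_sd``) is added to every sample.
    Deterministic for a given seed.
    """
    from .frap import FRAPSeries  # local import to avoid a cycle

    n_post = int(round(config.duration / config.dt)) + 1
    t_post = np.arange(n_post) * config.dt
    b, u = _integrate_exchange(t_post, config.k_int, config.k_ex)
    t_pre = -config.dt * np.arange(config.n_prebleach, 0, -1)
    pre = np.ones(config.n_prebleach)
    time = np.concatenate([t_pre, t_post])
    bleached = np.concatenate([pre, b])
    unbleached = np.concatenate([pre, u])
    if config.noise_sd > 0:
        rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(config.seed)))
        bleached = bleached + rng.normal(0.0, config.noise_sd, size=time.size)
        unbleached = unbleached + rng.normal(0.0, config.noise_sd, size=time.size)
    return FRAPSeries(
        time=time,
        bleached=bleached,
        unbleached=unbleached,
        prebleach_level=1.0,
        normalized=True,
        metadata={"seed": config.seed, "k_int": config.k_int, "k_ex": config.k_ex},
    )
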