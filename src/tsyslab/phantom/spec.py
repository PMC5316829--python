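"""Parameter objects for the synthetic fibre/imaging/physiology generators."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["NoiseModel", "PhantomSpec", "PhantomTruth", "Epoch", "SolutionProtocol",
           "CompartmentParams"]


@dataclass(frozen=True)
class NoiseModel:
    """Poisson photon noise (scaled) plus additive Gaussian read noise.

    ``photon_scale`` is photons per intensity unit; 0 disables the Poisson
    component.  ``read_noise_sd`` is in intensity units; 0 disables it.
    """

    photon_scale: float = 0.0
    read_noise_sd: float = 0.0

    def is_off(self) -> bool:
        return self.photon_scale == 0 and self.read_noise_sd == 0

    def apply(self, data: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        out = np.asarray(data, dtype=np.float64)
        if self.photon_scale > 0:
            out = rng.poisson(np.clip(out, 0, None) * self.photon_scale) / self.photon_scale
        if self.read_noise_sd > 0:
            out = out + rng.normal(0.0, self.read_noise_sd, size=out.shape)
        return out


@dataclass
class PhantomSpec:
    """Geometry/imaging parameters of the synthetic fibre.

    Lengths are in um except ``tubule_width`` and ``voxel_size`` (nm).  The
    fibre is a straight cylinder along the y (long image) axis, centred in
    the x-z cross-section of a ``grid_shape`` = (nz, ny, nx) voxel grid.
    """

    fibre_radius: float = 4.0
    fibre_length: float = 23.0
    sarcomere_length: float = 2.0
    tubule_width: float = 40.0          # nm
    target_tsys_volume_fraction: float = 1.0   # % of fibre volume
    longitudinal_radial_exponent: float = 4.0  # density ~ (r/R)^k; 0 = uniform
    transverse_pitch: float = 1.0       # um, grid pitch of the perforated planes
    vacuole_count: int = 0
    vacuole_axes: tuple[float, float, float] = (0.9, 1.0, 0.9)  # um diameters (x, y, z)
    vacuole_series_length: int = 3      # sarcomeres spanned by one series
    voxel_size: tuple[float, float, float] = (90.0, 90.0, 150.0)  # nm (dx, dy, dz)
    grid_shape: tuple[int, int, int] = (64, 256, 256)  # (nz, ny, nx)
    tubule_intensity: float = 1.0
    vacuole_intensity: float = 3.0
    fibre_glow: float = 0.0             # uniform in-fibre pedestal (raw-image glow)
    noise_model: NoiseModel = field(default_factory=NoiseModel)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fibre_radius", "fibre_length", "sarcomere_length", "tubule_width"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.target_tsys_volume_fraction < 100:
            raise ValueError("target_tsys_volume_fraction must be in (0, 100)")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be positive")
        if self.vacuole_count < 0 or self.vacuole_series_length < 1:
            raise ValueError("vacuole_count >= 0 and vacuole_series_length >= 1 required")
        if any(a * 1000.0 < self.tubule_width for a in self.vacuole_axes):
            raise ValueError("each vacuole axis must be >= tubule_width")
        if max(self.vacuole_axes) > 2 * self.fibre_radius:
            raise ValueError("vacuole axes exceed the fibre diameter")


@dataclass
class PhantomTruth:
    """Exact ground truth of a rendered phantom.

    ``centreline_segments`` is a list of (points_nm, label) with points in
    (z, y, x) nm and label 'transverse' | 'longitudinal'.  Vacuole and
    tubule masks are disjoint label sets whose union is the t-system;
    fractions are exact voxel-count fractions of the fibre mask.
    """

    centreline_segments: list
    tsys_mask: np.ndarray
    vacuole_mask: np.ndarray
    fibre_mask: np.ndarray
    tubule_volume_fraction: float
    vacuole_volume_fraction: float
    vacuole_count: int

    def recompute_fractions(self) -> tuple[float, float]:
        """Voxel-count fractions (tubule %, vacuole %) of fibre volume."""
        fibre = max(1, int(self.fibre_mask.sum()))
        tub = int((self.tsys_mask & ~self.vacuole_mask).sum())
        vac = int(self.vacuole_mask.sum())
        return 100.0 * tub / fibre, 100.0 * vac / fibre


@dataclass(frozen=True)
class Epoch:
    """One solution condition: duration, cytoplasmic [Ca2+], caffeine flag."""

    label: str
    duration_s: float
    cyto_ca_um: float
    caffeine: bool = False

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("epoch duration must be positive")
        if self.cyto_ca_um < 0:
            raise ValueError("cytoplasmic [Ca2+] must be non-negative")


@dataclass
class SolutionProtocol:
    """Ordered, contiguous solution epochs starting at t = 0."""

    epochs: list[Epoch]

    def __post_init__(self) -> None:
        if not self.epochs:
            raise ValueError("protocol must contain at least one epoch")
        labels = [e.label for e in self.epochs]
        if len(set(labels)) != len(labels):
            raise ValueError("epoch labels must be unique")

    @property
    def total_duration_s(self) -> float:
        return float(sum(e.duration_s for e in self.epochs))

    def epoch_at(self, t: float) -> Epoch:
        acc = 0.0
        for e in self.epochs:
            acc += e.duration_s
            if t < acc:
                return e
        return self.epochs[-1]

    def info(self) -> dict:
        return {e.label: {"cyto_ca_um": e.cyto_ca_um, "caffeine": e.caffeine}
                for e in self.epochs}


@dataclass
class CompartmentParams:
    """Two-compartment luminal Ca2+ rate model.

    Uptake is a pump rate (mM/s at full activation) scaled by a Hill
    function of cytoplasmic [Ca2+]; store-operated entry drains only the
    transverse-tubule compartment during caffeine epochs; the junction
    permeability exchanges Ca2+ between the two lumina (0 = fully
    restricted).  A small passive transverse-tubule leak gives the model
    finite steady states; the vacuole leak defaults to 0 (vacuoles retain
    their load).
    """

    uptake_rate_tt: float = 0.05     # mM/s at full activation
    uptake_rate_vac: float = 0.05
    soce_conductance_tt: float = 0.05  # /s, caffeine epochs only
    junction_permeability: float = 0.0  # /s
    leak_rate_tt: float = 0.02       # /s passive leak (steady states)
    leak_rate_vac: float = 0.0
    activation_kd_um: float = 0.5    # Hill K (n = 1) of uptake activation
    initial_ca_tt: float = 0.2       # mM
    initial_ca_vac: float = 0.2
    buffering_b: float = 1.0

    def __post_init__(self) -> None:
        for name in ("uptake_rate_tt", "uptake_rate_vac", "soce_conductance_tt",
                     "junction_permeability", "leak_rate_tt", "leak_rate_vac",
                     "initial_ca_tt", "initial_ca_vac"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.activation_kd_um <= 0:
            raise ValueError("activation_kd_um must be positive")

    def activation(self, cyto_ca_um: float) -> float:
        return cyto_ca_um / (self.activation_kd_um + cyto_ca_um)
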