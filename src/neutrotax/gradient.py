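"""Cross-channel chemoattractant gradient in a co-flow microfluidic channel.

Two streams — one carrying chemoattractant at concentration ``c0``, one plain
medium — enter a straight channel side by side and mix only by diffusion
across the channel width while they are advected downstream.  In the frame of
a fluid parcel the cross-channel profile obeys the 1-D diffusion equation on
``y ∈ [0, W]`` with no-flux walls and a step initial condition (``c = c0`` on
the source half ``y < W/2``).  The profile observed at downstream distance
``L`` with mean flow speed ``U`` is therefore the step diffused for the
residence (mixing) time ``τ = L / U``.

The model is deliberately one-dimensional: the fluorescence calibration it
emulates characterizes only the cross-channel intensity profile, and channel
height enters neither the profile shape nor the residence time at equal inlet
flows.  Taylor dispersion and the upstream pressure-balance hydraulics are
outside the model.

Concentrations are reported as the fraction ``c/c0 ∈ [0, 1]``; the
chemoattractant source wall is at ``y = 0``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import erf, erfc

__all__ = [
    "ChannelGeometry",
    "GradientProfile",
    "steady_profile",
    "establishment_time",
]

# Fourier number D*tau/W^2 above which the cosine eigenfunction series is
# used instead of the image-source erf series (the image series converges
# slowly once the diffusion length approaches the channel width).
_FOURIER_SWITCH = 0.05
_TERM_TOL = 1e-12


@dataclass(frozen=True)
class ChannelGeometry:
    """Migration-channel dimensions in micrometres.

    ``width`` is the cross-flow axis y along which the gradient forms;
    ``height`` is the (unused by the 1-D model) vertical dimension;
    ``length_downstream`` is the flow axis x.
    """

    width: float = 350.0
    height: float = 100.0
    length_downstream: float = 10_000.0

    def __post_init__(self) -> None:
        for name in ("width", "height", "length_downstream"):
            if not getattr(self, name) > 0:
                raise ValueError(f"ChannelGeometry.{name} must be > 0")


@dataclass(frozen=True)
class GradientProfile:
    """Normalized cross-channel concentration profile c(y)/c0.

    Invariants (checked on construction): concentrations in [0, 1] and
    monotone non-increasing from the source wall (y = 0) to the sink wall.
    """

    positions: np.ndarray
    concentrations: np.ndarray
    effective_time: float

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        con = np.asarray(self.concentrations, dtype=float)
        if pos.shape != con.shape or pos.ndim != 1:
            raise ValueError("positions and concentrations must be matching 1-D arrays")
        if np.any(con < -1e-9) or np.any(con > 1 + 1e-9):
            raise ValueError("concentrations must lie in [0, 1]")
        if np.any(np.diff(con) > 1e-9):
            raise ValueError("profile must be non-increasing toward the sink wall")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "concentrations", con)

    def to_text(self, path) -> None:
        """Write the profile as two-column delimited text (y_um, c_over_c0)."""
        np.savetxt(
            path,
            np.column_stack([self.positions, self.concentrations]),
            header="y_um\tc_over_c0",
            delimiter="\t",
            comments="# ",
        )

    def fluorescence_image(
        self, shape: tuple[int, int] = (64, 256), noise_sd: float = 0.01, seed: int = 0
    ) -> np.ndarray:
        """Emulate a 16-bit fluorescence calibration image of the gradient.

        Rows span the channel width; Gaussian read noise of ``noise_sd``
        (fraction of full scale) is added before quantization.
        """
        rng = np.random.default_rng(seed)
        y = np.linspace(self.positions[0], self.positions[-1], shape[0])
        col = np.interp(y, self.positions, self.concentrations)
        img = np.repeat(col[:, None], shape[1], axis=1)
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
        return (np.clip(img, 0.0, 1.0) * 65535).astype(np.uint16)


def _check_positive(**params: float) -> None:
    for name, value in params.items():
        if not value > 0:
            raise ValueError(f"{name} must be > 0, got {value!r}")


def _step_profile(y: np.ndarray, width: float, dtau: float) -> np.ndarray:
    """Diffused half-channel step on [0, width] with no-flux walls.

    ``dtau`` is D*tau (µm²).  Uses the image-source erf series at small
    Fourier number and the cosine eigenfunction series otherwise; both
    represent the same solution, truncated when terms fall below 1e-12.
    """
    if dtau == 0.0:
        c = np.where(y < width / 2, 1.0, 0.0)
        return np.where(np.isclose(y, width / 2), 0.5, c)

    fo = dtau / width**2
    if fo <= _FOURIER_SWITCH:
        # No-flux walls via even periodic images: the initial condition
        # extends to a square wave of period 2W whose "high" intervals are
        # [2kW - W/2, 2kW + W/2]; each contributes a pair of erfs.
        s = 2.0 * np.sqrt(dtau)

        def interval(k: int) -> np.ndarray:
            a = 2 * k * width - width / 2
            b = 2 * k * width + width / 2
            return 0.5 * (erf((y - a) / s) - erf((y - b) / s))

        c = interval(0)
        k = 1
        while True:
            term = interval(k) + interval(-k)
            c += term
            if np.max(np.abs(term)) < _TERM_TOL:
                return c
            k += 1
    else:
        # c = 1/2 + sum over odd n of (2/(n pi)) sin(n pi / 2) cos(n pi y / W) e^{-n^2 pi^2 Fo}
        c = np.full_like(y, 0.5, dtype=float)
        n = 1
        while True:
            amp = (2.0 / (n * np.pi)) * np.sin(n * np.pi / 2.0) * np.exp(-(n * np.pi) ** 2 * fo)
            if abs(amp) < _TERM_TOL:
                return np.clip(c, 0.0, 1.0)
            c += amp * np.cos(n * np.pi * y / width)
            n += 2


def steady_profile(
    geom: ChannelGeometry,
    diffusivity: float,
    mean_flow_speed: float,
    downstream_distance: float,
    n_points: int = 101,
) -> GradientProfile:
    """Steady cross-channel profile at a downstream observation station.

    Parameters
    ----------
    geom
        Channel geometry; only ``width`` enters the 1-D model.
    diffusivity
        Chemoattractant diffusivity in µm²/s (a 10 kDa dextran is of order
        100 µm²/s, i.e. 1e-10 m²/s).
    mean_flow_speed
        Mean downstream flow speed in µm/s.
    downstream_distance
        Distance from the channel junction to the observation station, µm.
    n_points
        Number of evenly spaced sample positions across the width.

    Returns
    -------
    GradientProfile
        Normalized profile with mixing time ``τ = L / U`` attached.
    """
    _check_positive(
        diffusivity=diffusivity,
        mean_flow_speed=mean_flow_speed,
        downstream_distance=downstream_distance,
        n_points=n_points,
    )
    tau = downstream_distance / mean_flow_speed
    y = np.linspace(0.0, geom.width, int(n_points))
    c = _step_profile(y, geom.width, diffusivity * tau)
    return GradientProfile(positions=y, concentrations=np.clip(c, 0.0, 1.0), effective_time=tau)


def establishment_time(
    geom: ChannelGeometry,
    diffusivity: float,
    mean_flow_speed: float,
    downstream_distance: float,
    tolerance: float,
) -> float:
    """Wall time for the observed profile to settle onto the steady profile.

    At start-up the channel holds plain medium; the incoming two-stream front
    is advected downstream at the mean flow speed while axial diffusion
    smears it.  The profile at the station is modeled as the steady profile
    scaled by the local new-fluid fraction ``w(t) = ½ erfc((L − Ut)/(2√(Dt)))``,
    so the max-pointwise deviation from steady state is
    ``(1 − w(t)) · max_y c_steady``.  The result is the smallest ``t`` at
    which that deviation is within ``tolerance`` (fraction of c0), and is
    never less than the advection time ``L / U``.
    """
    _check_positive(
        diffusivity=diffusivity,
        mean_flow_speed=mean_flow_speed,
        downstream_distance=downstream_distance,
    )
    if not 0.0 < tolerance <= 1.0:
        raise ValueError(f"tolerance must be in (0, 1], got {tolerance!r}")

    t_adv = downstream_distance / mean_flow_speed
    tau_mix = t_adv
    y = np.linspace(0.0, geom.width, 257)
    c_max = float(np.max(_step_profile(y, geom.width, diffusivity * tau_mix)))

    def deviation(t: float) -> float:
        arg = (downstream_distance - mean_flow_speed * t) / (
            2.0 * np.sqrt(diffusivity * t)
        )
        w = 0.5 * erfc(arg)
        return (1.0 - w) * c_max

    if deviation(t_adv) <= tolerance:
        return t_adv
    hi = t_adv * 2.0
    while deviation(hi) > tolerance:
        hi *= 2.0
        if hi > t_adv * 1e9:  # pragma: no cover - pathological parameters
            raise RuntimeError("establishment time search failed to bracket")
    return float(brentq(lambda t: deviation(t) - tolerance, t_adv, hi, xtol=1e-6 * t_adv))
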