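"""Synthetic initial conditions: band-pass noise, stripes, hexagons.

These generators produce the standard initial conditions of the
crystallization experiments: band-pass filtered Gaussian white noise (an
essentially random map whose pinwheel density is bounded below by π),
pinwheel-free stripe patterns, and hexagonal patterns for the real fields.
All randomness flows from an explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import GridSpec, KC_Z


@dataclass(frozen=True)
class InitSpec:
    """Serializable description of one field's initial condition.

    kind ∈ {bandpass_noise, stripes, hexagons, constant}. ``power`` is the
    target spatial mean of |f|² (see the field power P = ⟨|z|²⟩);
    ``wavelength ratio`` w scales the carrier wavenumber; orientation and
    phases select stripe/hexagon geometry; ``bandwidth`` is the relative
    annulus width of the band-pass filter.
    """

    kind: str
    power: float = 0.0
    w: float = 1.0
    bandwidth: float = 0.2
    orientation: float = 0.0
    amplitude: float | None = None
    phases: tuple[float, float, float] = (0.0, 0.0, 0.0)
    mean_offset: float = 0.0
    complex_valued: bool = True
    noise_power: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("bandpass_noise", "stripes", "hexagons",
                             "constant"):
            raise ValueError(f"unknown init kind {self.kind!r}")
        if self.power < 0:
            raise ValueError("target power must be nonnegative")
        if not 0 < self.bandwidth < 1:
            raise ValueError("bandwidth must lie in (0, 1)")


def bandpass_gwn(grid: GridSpec, kc: float = KC_Z, bandwidth: float = 0.2,
                 target_power: float = 1.0, seed: int = 0,
                 complex_valued: bool = True) -> np.ndarray:
    """Gaussian white noise filtered to the annulus |k/kc − 1| ≤ bandwidth/2.

    The result is normalized so that the realized power ⟨|f|²⟩ equals
    ``target_power`` exactly. The complex variant has independent real and
    imaginary parts; the real variant is a real field.
    """
    rng = np.random.default_rng(seed)
    shape = grid.shape
    k = np.sqrt(grid.k2())
    mask = np.abs(k / kc - 1.0) <= bandwidth / 2.0
    n_modes = int(mask.sum())
    if n_modes < 12:
        raise ValueError(
            f"band-pass annulus holds only {n_modes} lattice modes "
            "(need ≥ 12); enlarge the domain or the bandwidth")
    if complex_valued:
        noise = rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
        f = grid.ifft(mask * grid.fft(noise))
    else:
        noise = rng.standard_normal(shape)
        f = grid.ifft(mask * grid.fft(noise)).real
    p = np.mean(np.abs(f) ** 2)
    if p == 0.0:
        raise ValueError("degenerate zero noise realization")
    return f * np.sqrt(target_power / p)


def stripes(grid: GridSpec, k: tuple[float, float] | None = None,
            orientation: float = 0.0, kc: float = KC_Z,
            amplitude: float = 1.0, phase: float = 0.0) -> np.ndarray:
    """Pinwheel-free plane-wave stripe pattern z = A e^{i(k·x + φ)}.

    The wavevector is the lattice mode nearest to ``k`` (or to
    kc·(cos φ₀, sin φ₀) when given an orientation); an off-lattice request
    farther than half a lattice cell is rejected to prevent spectral leakage.
    """
    if k is None:
        k = (kc * np.cos(orientation), kc * np.sin(orientation))
    m, n = grid.nearest_mode(k)
    kx, ky = grid.mode_wavevector(m, n)
    if not (np.isclose(kx, k[0], atol=1e-9) and np.isclose(ky, k[1], atol=1e-9)):
        # tolerate snapping only within a small fraction of a lattice cell
        dk = np.hypot(kx - k[0], ky - k[1])
        cell = min(2 * np.pi / grid.lx, 2 * np.pi / grid.ly)
        if dk > 0.25 * cell:
            raise ValueError(
                f"wavevector {k} is off the grid lattice (nearest mode "
                f"({m}, {n}) at ({kx:.4f}, {ky:.4f}))")
    x, y = grid.coords()
    return amplitude * np.exp(1j * (kx * x + ky * y + phase))


def hexagon_triad(grid: GridSpec, kc: float = KC_Z):
    """Three lattice wavevectors at (approximately) mutual 120° on the
    critical circle, summing exactly to zero.

    Returns a list of three (kx, ky) tuples. Raises if the lattice cannot
    host a near-120° triad (angles off by more than 10°).
    """
    m1, n1 = grid.nearest_mode((kc, 0.0))
    k1 = np.array(grid.mode_wavevector(m1, n1))
    m2, n2 = grid.nearest_mode((-kc / 2, kc * np.sqrt(3) / 2))
    k2 = np.array(grid.mode_wavevector(m2, n2))
    k3 = -(k1 + k2)  # exact resonance on the lattice
    triad = [k1, k2, k3]
    angles = []
    for a, b in ((k1, k2), (k2, k3), (k3, k1)):
        cosang = np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b))
        angles.append(np.degrees(np.arccos(np.clip(cosang, -1, 1))))
    if any(abs(a - 120) > 10 for a in angles):
        raise ValueError(
            f"grid lattice cannot host a near-120° triad at kc={kc:.3f}; "
            f"achieved angles {[round(a, 2) for a in angles]}")
    return triad


def hexagons(grid: GridSpec, kc: float = KC_Z, amplitude: float = 1.0,
             phases: tuple[float, float, float] = (0.0, 0.0, 0.0),
             mean_offset: float = 0.0) -> np.ndarray:
    """Hexagonal pattern o = mean_offset + A Σ_j cos(k_j·x + φ_j).

    The three wavevectors sit (as close as the lattice allows) at mutual
    120° on the circle |k| = kc and sum exactly to zero. With resonant
    phases (φ₁+φ₂+φ₃ = 0) the extrema form a triangular lattice.
    """
    triad = hexagon_triad(grid, kc)
    x, y = grid.coords()
    o = np.full(grid.shape, float(mean_offset))
    for (kx, ky), ph in zip(triad, phases):
        o += amplitude * np.cos(kx * x + ky * y + ph)
    return o


def build_initial(spec: InitSpec, grid: GridSpec) -> np.ndarray:
    """Construct the field described by an :class:`InitSpec`."""
    kc = spec.w * KC_Z
    if spec.kind == "bandpass_noise":
        return bandpass_gwn(grid, kc=kc, bandwidth=spec.bandwidth,
                            target_power=spec.power, seed=spec.seed,
                            complex_valued=spec.complex_valued)
    if spec.kind == "stripes":
        amp = spec.amplitude if spec.amplitude is not None else np.sqrt(spec.power)
        f = stripes(grid, orientation=spec.orientation, kc=kc, amplitude=amp)
        if not spec.complex_valued:
            f = f.real
    elif spec.kind == "hexagons":
        amp = spec.amplitude if spec.amplitude is not None else np.sqrt(spec.power)
        f = hexagons(grid, kc=kc, amplitude=amp, phases=spec.phases,
                     mean_offset=spec.mean_offset)
    else:  # constant
        val = spec.amplitude if spec.amplitude is not None else 0.0
        f = np.full(grid.shape, val, dtype=complex if spec.complex_valued else float)
        f = f + spec.mean_offset
    if spec.noise_power > 0:
        f = f + bandpass_gwn(grid, kc=kc, bandwidth=spec.bandwidth,
                             target_power=spec.noise_power, seed=spec.seed,
                             complex_valued=spec.complex_valued)
    return f
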