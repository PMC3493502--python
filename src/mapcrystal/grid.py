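"""Periodic simulation grid and spectral helpers.

All lengths are measured in units of the OP column spacing Λ_z, so the OP
critical wavenumber is k_c,z = 2π. The domain is a flat torus of size
lx × ly discretized on an nx × ny mesh; Fourier transforms use the standard
half-open wavenumber lattice k_mn = 2π (m/lx, n/ly) with the DC mode at
index 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import fft as sfft

KC_Z = 2.0 * np.pi  # OP critical wavenumber in Λ_z = 1 units


@dataclass(frozen=True)
class GridSpec:
    """Periodic rectangular mesh.

    Parameters
    ----------
    nx, ny
        Mesh points along x and y (≥ 16 each).
    lx, ly
        Physical side lengths in units of the OP wavelength Λ_z.

    The number of wavelengths of every field wavelength used in a model must
    fit an integer number of times into ``lx`` and ``ly``; this is checked by
    :meth:`ModelSpec.validate_grid <mapcrystal.model.ModelSpec>` since the
    grid itself does not know the field wavelengths. The mesh must resolve
    the critical circle with at least 8 points per wavelength.
    """

    nx: int
    ny: int
    lx: float
    ly: float
    periodic: bool = True

    def __post_init__(self) -> None:
        if self.nx < 16 or self.ny < 16:
            raise ValueError("mesh must be at least 16x16")
        if self.lx <= 0 or self.ly <= 0:
            raise ValueError("domain lengths must be positive")
        if not self.periodic:
            raise ValueError("only periodic domains are supported")
        # ≥ 8 mesh points per Λ_z (finer-wavelength fields are checked by the
        # model, which knows its wavelength ratios)
        if self.nx / self.lx < 8 - 1e-9 or self.ny / self.ly < 8 - 1e-9:
            raise ValueError("mesh does not resolve the critical circle "
                             "(need ≥ 8 points per wavelength)")

    @property
    def shape(self) -> tuple[int, int]:
        """Array shape (ny, nx); x varies along the last axis."""
        return (self.ny, self.nx)

    @property
    def area(self) -> float:
        return self.lx * self.ly

    @property
    def dx(self) -> float:
        return self.lx / self.nx

    @property
    def dy(self) -> float:
        return self.ly / self.ny

    # --- coordinates and wavenumbers -------------------------------------

    def coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Mesh coordinate arrays (x, y), each of shape (ny, nx)."""
        x = np.arange(self.nx) * self.dx
        y = np.arange(self.ny) * self.dy
        return np.meshgrid(x, y)

    def wavenumbers(self) -> tuple[np.ndarray, np.ndarray]:
        """(kx, ky) arrays of shape (ny, nx) on the FFT lattice."""
        kx = 2 * np.pi * sfft.fftfreq(self.nx, d=self.dx)
        ky = 2 * np.pi * sfft.fftfreq(self.ny, d=self.dy)
        return np.meshgrid(kx, ky)

    def k2(self) -> np.ndarray:
        kx, ky = self.wavenumbers()
        return kx**2 + ky**2

    # --- spectral operators ----------------------------------------------

    def fft(self, f: np.ndarray) -> np.ndarray:
        return sfft.fft2(f)

    def ifft(self, fh: np.ndarray) -> np.ndarray:
        return sfft.ifft2(fh)

    def gradient(self, f: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Spectral gradient (∂x f, ∂y f). Real input gives real output."""
        kx, ky = self.wavenumbers()
        fh = sfft.fft2(f)
        gx = sfft.ifft2(1j * kx * fh)
        gy = sfft.ifft2(1j * ky * fh)
        if np.isrealobj(f):
            return gx.real, gy.real
        return gx, gy

    def divergence(self, fx: np.ndarray, fy: np.ndarray) -> np.ndarray:
        """Spectral divergence ∂x fx + ∂y fy."""
        kx, ky = self.wavenumbers()
        out = sfft.ifft2(1j * kx * sfft.fft2(fx) + 1j * ky * sfft.fft2(fy))
        if np.isrealobj(fx) and np.isrealobj(fy):
            return out.real
        return out

    def nearest_mode(self, kvec: tuple[float, float]) -> tuple[int, int]:
        """Integer mode numbers (m, n) of the lattice point closest to kvec."""
        m = round(kvec[0] * self.lx / (2 * np.pi))
        n = round(kvec[1] * self.ly / (2 * np.pi))
        return m, n

    def mode_wavevector(self, m: int, n: int) -> tuple[float, float]:
        return 2 * np.pi * m / self.lx, 2 * np.pi * n / self.ly
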