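"""Fields, operators, energies, and the coupled gradient-flow right-hand side.

The model couples a complex orientation-preference (OP) field z(x) to m real
columnar fields o_i(x) (ocular dominance, spatial frequency, ...). Each field
on its own follows supercritical Swift-Hohenberg dynamics; the fields
interact through symmetry-classified coupling energies U. The full dynamics
is the gradient descent

    ∂t z      = L̂_z z − |z|² z − δU/δz̄
    c_i ∂t o_i = L̂_i o_i − o_i³ + γ_i − δU/δo_i

with L̂_f = r_f − (k_c,f² + Δ)²/k_c,f⁴ diagonal in Fourier space, γ_i an
additive bias (contralateral eye bias for OD), and c_i the timescale constant
of field i relative to the OP field. Lengths are in units of Λ_z (so
k_c,z = 2π) and times are reported in units of the intrinsic timescale
τ = 1/r_z.

The coupling-energy family (area densities; ∇z·∇o = ∂x z ∂x o + ∂y z ∂y o is
a complex scalar):

    product2   α · o² |z|²
    product4   τ · o⁴ |z|⁴
    gradient2  β · |∇z·∇o|²
    gradient4  ε · |∇z·∇o|⁴

For a pair of two real fields z is replaced by the real field and |·| is the
absolute value. Multi-field models sum the pairwise terms.

Energies and forces are discretized consistently: every functional derivative
here is the exact (to round-off) gradient of the discretized energy, because
spectral differentiation is skew-adjoint under the discrete inner product.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import GridSpec, KC_Z

_VALID_KINDS = ("product2", "product4", "gradient2", "gradient4")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CouplingSpec:
    """One pairwise inter-map coupling term.

    kind is one of ``product2`` (α o²|z|²), ``product4`` (τ o⁴|z|⁴),
    ``gradient2`` (β |∇z·∇o|²), ``gradient4`` (ε |∇z·∇o|⁴); ``strength`` is
    the corresponding nonnegative coefficient, and ``pair`` holds the indices
    of the two coupled fields (0 = the complex OP field, 1..m = real fields).
    """

    kind: str
    strength: float
    pair: tuple[int, int] = (0, 1)

    def __post_init__(self) -> None:
        if self.kind not in _VALID_KINDS:
            raise ValueError(f"unknown coupling kind {self.kind!r}")
        if self.strength < 0:
            raise ValueError("coupling strength must be nonnegative")
        if self.pair[0] == self.pair[1]:
            raise ValueError("coupling pair indices must be distinct")
        object.__setattr__(self, "pair", tuple(sorted(self.pair)))


@dataclass(frozen=True)
class RealFieldSpec:
    """Parameters of one real columnar field.

    r: bifurcation parameter; gamma: constant bias (contralateral > 0 for
    OD); w: wavenumber ratio k_c,i / k_c,z; c: timescale constant relative to
    the OP field.
    """

    r: float
    gamma: float = 0.0
    w: float = 1.0
    c: float = 1.0

    def __post_init__(self) -> None:
        if self.w <= 0:
            raise ValueError("wavelength ratio w must be positive")
        if self.c <= 0:
            raise ValueError("timescale constant c must be positive")

    @property
    def kc(self) -> float:
        return self.w * KC_Z


@dataclass(frozen=True)
class ModelSpec:
    """Full model: OP bifurcation parameter, real fields, couplings, grid."""

    r_z: float
    fields: tuple[RealFieldSpec, ...] = ()
    couplings: tuple[CouplingSpec, ...] = ()
    grid: GridSpec | None = None

    def __post_init__(self) -> None:
        if self.r_z <= 0:
            raise ValueError("r_z must be positive")
        object.__setattr__(self, "fields", tuple(self.fields))
        object.__setattr__(self, "couplings", tuple(self.couplings))
        m = len(self.fields)
        for cp in self.couplings:
            if not all(0 <= i <= m for i in cp.pair):
                raise ValueError(f"coupling pair {cp.pair} references a "
                                 f"missing field (model has {m} real fields)")
        if self.grid is not None:
            self.validate_grid(self.grid)

    @property
    def n_real(self) -> int:
        return len(self.fields)

    @property
    def tau(self) -> float:
        """Intrinsic timescale τ = 1/r_z."""
        return 1.0 / self.r_z

    def validate_grid(self, grid: GridSpec, tol: float = 1e-9) -> None:
        """Enforce the integer-wavelength rule for every field wavelength.

        An integer number of wavelengths of each field must fit into lx and
        ly, otherwise the active modes of that field are disbalanced on the
        discrete critical circle.
        """
        for w in [1.0] + [f.w for f in self.fields]:
            for length, n in ((grid.lx, grid.nx), (grid.ly, grid.ny)):
                cycles = length * w
                if abs(cycles - round(cycles)) > tol:
                    raise ValueError(
                        f"{length} Λ_z does not hold an integer number of "
                        f"wavelengths of a field with w={w} ({cycles} cycles)")
                if n / cycles < 8 - 1e-9:
                    raise ValueError(
                        f"mesh resolves only {n / cycles:.2f} points per "
                        f"wavelength for field with w={w} (need ≥ 8)")


@dataclass
class FieldState:
    """All fields on the grid at time t.

    z is the complex OP field (shape ny×nx); os is the tuple of real fields.
    """

    t: float
    z: np.ndarray
    os: tuple[np.ndarray, ...] = ()

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=complex)
        self.os = tuple(np.asarray(o, dtype=float) for o in self.os)
        for o in self.os:
            if o.shape != self.z.shape:
                raise ValueError("all fields must share the grid shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.z.shape

    def copy(self) -> "FieldState":
        return FieldState(self.t, self.z.copy(),
                          tuple(o.copy() for o in self.os))


# ---------------------------------------------------------------------------
# stacked real representation (used by the implicit integrator)
# ---------------------------------------------------------------------------

def pack(state: FieldState) -> np.ndarray:
    """Stack (Re z, Im z, o_1..o_m) into a real array of shape (2+m, ny, nx)."""
    return np.stack([state.z.real, state.z.imag, *state.os])


def unpack(u: np.ndarray, t: float = 0.0) -> FieldState:
    """Inverse of :func:`pack`."""
    z = u[0] + 1j * u[1]
    return FieldState(t, z, tuple(u[2:]))


# ---------------------------------------------------------------------------
# linear operator
# ---------------------------------------------------------------------------

def linear_spectrum(k2, r: float, kc: float):
    """Growth rate λ(k) = r − (k_c² − k²)²/k_c⁴ of the Swift-Hohenberg operator.

    Maximal (= r) on the critical circle |k| = kc; λ(0) = r − 1; λ → −∞ for
    k → ∞.
    """
    if kc <= 0:
        raise ValueError("critical wavenumber kc must be positive")
    k2 = np.asarray(k2, dtype=float)
    kc2 = kc * kc
    return r - (kc2 - k2) ** 2 / (kc2 * kc2)


def apply_linear(f: np.ndarray, r: float, kc: float, grid: GridSpec) -> np.ndarray:
    """Apply L̂ = r − (k_c² + Δ)²/k_c⁴ spectrally (diagonal in Fourier space)."""
    if f.shape != grid.shape:
        raise ValueError(f"field shape {f.shape} != grid shape {grid.shape}")
    lam = linear_spectrum(grid.k2(), r, kc)
    out = grid.ifft(lam * grid.fft(f))
    if np.isrealobj(f):
        return out.real
    return out


# ---------------------------------------------------------------------------
# energies
# ---------------------------------------------------------------------------

def single_field_energy(state: FieldState, model: ModelSpec,
                        grid: GridSpec | None = None) -> float:
    """Area-averaged uncoupled energy of all fields.

    E = ⟨ −z̄ L̂_z z + ½|z|⁴ ⟩ + Σ_i ⟨ −½ o_i L̂_i o_i + ¼ o_i⁴ − γ_i o_i ⟩.
    The gradient descent of this functional (plus the coupling energy) is the
    model dynamics. An uncoupled OP stripe z = √r_z e^{i k_c x} has energy
    density −r_z²/2.
    """
    grid = grid or model.grid
    z = state.z
    e = np.mean(-(np.conj(z) * apply_linear(z, model.r_z, KC_Z, grid)).real
                + 0.5 * np.abs(z) ** 4)
    for o, fs in zip(state.os, model.fields):
        Lo = apply_linear(o, fs.r, fs.kc, grid)
        e += np.mean(-0.5 * o * Lo + 0.25 * o**4 - fs.gamma * o)
    return float(e)


def _pair_fields(state: FieldState, pair: tuple[int, int]):
    """Return (a, b, a_is_complex) for a coupling pair; the complex field, if
    present, is always first."""
    a, b = pair
    fa = state.z if a == 0 else state.os[a - 1]
    fb = state.os[b - 1]
    return fa, fb, a == 0


def coupling_energy(state: FieldState, couplings, grid: GridSpec) -> float:
    """Total area-averaged inter-map coupling energy U over all pairs."""
    e = 0.0
    for cp in couplings:
        if cp.strength == 0.0:
            continue
        fa, fb, _ = _pair_fields(state, cp.pair)
        if cp.kind == "product2":
            e += cp.strength * np.mean(np.abs(fa) ** 2 * fb**2)
        elif cp.kind == "product4":
            e += cp.strength * np.mean(np.abs(fa) ** 4 * fb**4)
        else:
            ax, ay = grid.gradient(fa)
            bx, by = grid.gradient(fb)
            s2 = np.abs(ax * bx + ay * by) ** 2
            if cp.kind == "gradient4":
                s2 = s2 * s2
            e += cp.strength * np.mean(s2)
    return float(e)


def coupling_force(state: FieldState, couplings, grid: GridSpec):
    """Negative functional derivatives −δU/δz̄ and −δU/δo_i of the coupling
    energy, i.e. the coupling terms entering the gradient-flow rhs.

    The returned arrays are exact discrete gradients of
    :func:`coupling_energy` (spectral derivatives are skew-adjoint on the
    grid), which is the correctness contract verified by the finite-difference
    tests.
    """
    fz = np.zeros(state.shape, dtype=complex)
    fos = [np.zeros(state.shape) for _ in state.os]

    # cache spectral gradients per field index
    grads: dict[int, tuple[np.ndarray, np.ndarray]] = {}

    def grad(idx: int):
        if idx not in grads:
            f = state.z if idx == 0 else state.os[idx - 1]
            grads[idx] = grid.gradient(f)
        return grads[idx]

    for cp in couplings:
        if cp.strength == 0.0:
            continue
        a, b = cp.pair
        fa, fb, a_complex = _pair_fields(state, cp.pair)
        if cp.kind in ("product2", "product4"):
            p = 1 if cp.kind == "product2" else 2
            # U = s |fa|^{2p} fb^{2p}
            if a_complex:
                # δU/δz̄ = s p |z|^{2p-2} z o^{2p};  δU/δo = s 2p o^{2p-1}|z|^{2p}
                fz -= cp.strength * p * np.abs(fa) ** (2 * p - 2) * fa * fb ** (2 * p)
                fos[b - 1] -= cp.strength * 2 * p * fb ** (2 * p - 1) * np.abs(fa) ** (2 * p)
            else:
                fos[a - 1] -= cp.strength * 2 * p * fa ** (2 * p - 1) * fb ** (2 * p)
                fos[b - 1] -= cp.strength * 2 * p * fb ** (2 * p - 1) * fa ** (2 * p)
        else:
            p = 1 if cp.kind == "gradient2" else 2
            ax, ay = grad(a)
            bx, by = grad(b)
            s = ax * bx + ay * by
            w = cp.strength * p * np.abs(s) ** (2 * p - 2)
            if a_complex:
                # δU/δz̄ = −∇·(w S ∇o);  δU/δo = −∇·(2 w Re(S̄ ∇z))
                fz += grid.divergence(w * s * bx, w * s * by)
                ws = 2.0 * (w * np.conj(s))
                fos[b - 1] += grid.divergence((ws * ax).real, (ws * ay).real)
            else:
                fos[a - 1] += grid.divergence(2 * w * s * bx, 2 * w * s * by)
                fos[b - 1] += grid.divergence(2 * w * s * ax, 2 * w * s * ay)
    return fz, fos


def total_energy(state: FieldState, model: ModelSpec,
                 grid: GridSpec | None = None) -> float:
    """Single-field energies plus coupling energy (area-averaged)."""
    grid = grid or model.grid
    return single_field_energy(state, model, grid) + coupling_energy(
        state, model.couplings, grid)


# ---------------------------------------------------------------------------
# right-hand side
# ---------------------------------------------------------------------------

def rhs(state: FieldState, model: ModelSpec,
        grid: GridSpec | None = None) -> FieldState:
    """Time derivatives of all fields (timescale constants folded in).

    Returns a :class:`FieldState` holding ∂t z and ∂t o_i = (L̂ o − o³ + γ −
    δU/δo)/c_i at the same time t.
    """
    grid = grid or model.grid
    z = state.z
    fz, fos = coupling_force(state, model.couplings, grid)
    dz = apply_linear(z, model.r_z, KC_Z, grid) - np.abs(z) ** 2 * z + fz
    dos = []
    for o, fs, fo in zip(state.os, model.fields, fos):
        do = apply_linear(o, fs.r, fs.kc, grid) - o**3 + fs.gamma + fo
        dos.append(do / fs.c)
    return FieldState(state.t, dz, tuple(dos))


def rhs_stacked(u: np.ndarray, model: ModelSpec) -> np.ndarray:
    """rhs on the stacked real representation (integrator entry point)."""
    d = rhs(unpack(u), model)
    return pack(d)
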