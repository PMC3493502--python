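"""Canonical experiment protocols for the crystallization studies.

These helpers encode the standard study conditions once, so that scripted
sweeps, tests, and reproduction runs all draw on the same definitions:

* OP field at r_z = 0.05, real (OD) field at r_o = 0.25 — the OD map is
  "dominant" (r_z/r_o ≪ 1), the regime where inter-map coupling can
  restructure the OP map.
* Contralateral OD bias γ = 0.2, the center of the γ-range in which the
  uncoupled OD dynamics selects hexagonal patch patterns at r_o = 0.25.
* High-order gradient coupling ε|∇z·∇o|⁴; ε_strong = 1e-3 sits well above
  the pinwheel-stabilization threshold at these amplitudes (hexagonal
  crystals form from every tested seed), ε_weak = 1e-5 near it (stripes,
  rhombic and hexagonal crystals compete).
* Initial conditions: band-pass filtered Gaussian white noise for the OP
  map with power 2% of the uncoupled stripe power r_z, and OD hexagons
  (amplitude −0.25 around mean +0.2) plus weak noise.
* Integration to t_end = 500 τ (τ = 1/r_z) with exponentially spaced
  frames, which reaches the attractor on the domains used here.
"""

from __future__ import annotations

import numpy as np

from .grid import GridSpec, KC_Z
from .integrate import FrameSet, IntegratorConfig, adaptive_integrate
from .model import CouplingSpec, FieldState, ModelSpec, RealFieldSpec
from .pinwheels import find_pinwheels, pinwheel_density
from .synthetic import bandpass_gwn, hexagons, stripes

R_Z = 0.05
R_O = 0.25
GAMMA_HEX = 0.2
EPS_STRONG = 1e-3
EPS_WEAK = 1e-5
INIT_POWER_FRACTION = 0.02
OD_HEX_AMPLITUDE = -0.25
OD_HEX_MEAN = 0.2


def coupled_model(grid: GridSpec, eps: float = EPS_STRONG,
                  kind: str = "gradient4", gamma: float = GAMMA_HEX,
                  r_z: float = R_Z, r_o: float = R_O,
                  w: float = 1.0) -> ModelSpec:
    """Two-map model: OP field coupled to one biased OD field."""
    couplings = (CouplingSpec(kind, eps),) if eps > 0 else ()
    return ModelSpec(r_z=r_z,
                     fields=(RealFieldSpec(r=r_o, gamma=gamma, w=w),),
                     couplings=couplings, grid=grid)


def multi_field_model(grid: GridSpec, n_real: int = 2,
                      eps: float = EPS_STRONG, r_z: float = R_Z,
                      r_o: float = R_O, gamma: float = 0.0) -> ModelSpec:
    """OP field plus ``n_real`` unbiased real fields, all mutually coupled
    with equal high-order gradient coupling strengths."""
    fields = tuple(RealFieldSpec(r=r_o, gamma=gamma) for _ in range(n_real))
    pairs = [(i, j) for i in range(n_real + 1) for j in range(i + 1, n_real + 1)]
    couplings = tuple(CouplingSpec("gradient4", eps, pair=p) for p in pairs)
    return ModelSpec(r_z=r_z, fields=fields, couplings=couplings, grid=grid)


def noise_hexagon_ic(model: ModelSpec, grid: GridSpec, seed: int,
                     op_stripes: bool = False) -> FieldState:
    """Standard initial condition of the crystallization runs.

    OP: band-pass noise at 2% of the stripe power r_z (or a saturated
    pinwheel-free stripe when ``op_stripes``); each real field: hexagons
    plus band-pass noise at 2% of its stripe power r_o.
    """
    if op_stripes:
        z0 = stripes(grid, orientation=0.0, amplitude=np.sqrt(model.r_z))
    else:
        z0 = bandpass_gwn(grid, target_power=INIT_POWER_FRACTION * model.r_z,
                          seed=seed)
    os_ = []
    for i, fs in enumerate(model.fields):
        o = hexagons(grid, kc=fs.kc, amplitude=OD_HEX_AMPLITUDE,
                     mean_offset=OD_HEX_MEAN if fs.gamma > 0 else 0.0)
        o = o + bandpass_gwn(grid, kc=fs.kc,
                             target_power=INIT_POWER_FRACTION * fs.r,
                             seed=seed + 1000 * (i + 1), complex_valued=False)
        os_.append(o)
    return FieldState(0.0, z0, tuple(os_))


def noise_ic(model: ModelSpec, grid: GridSpec, seed: int) -> FieldState:
    """Band-pass noise for every field (multi-map runs)."""
    z0 = bandpass_gwn(grid, target_power=INIT_POWER_FRACTION * model.r_z,
                      seed=seed)
    os_ = [bandpass_gwn(grid, kc=fs.kc,
                        target_power=INIT_POWER_FRACTION * fs.r,
                        seed=seed + 1000 * (i + 1), complex_valued=False)
           for i, fs in enumerate(model.fields)]
    return FieldState(0.0, z0, tuple(os_))


def crystallization_run(seed: int, eps: float = EPS_STRONG,
                        grid: GridSpec | None = None,
                        t_end_tau: float = 500.0, frame_count: int = 150,
                        op_stripes: bool = False,
                        gamma: float = GAMMA_HEX) -> FrameSet:
    """One full crystallization experiment (strong/weak/zero coupling)."""
    grid = grid or GridSpec(64, 64, 8, 8)
    model = coupled_model(grid, eps=eps, gamma=gamma)
    ic = noise_hexagon_ic(model, grid, seed, op_stripes=op_stripes)
    cfg = IntegratorConfig(t_end=t_end_tau * model.tau,
                           frame_count=frame_count)
    return adaptive_integrate(ic, model, cfg, seed=seed)


def tracked_run_summary(seed: int, eps: float, grid: GridSpec,
                        t_end_tau: float = 500.0, frame_count: int = 150,
                        match_radius: float = 0.2) -> dict:
    """Run one crystallization experiment and summarize its kinetics.

    Returns final density, survival fraction of t=0 pinwheels, survival
    fraction from the OP power-saturation frame (first frame with
    P ≥ 0.95 P_final), and the final-state classification.
    """
    from .tracking import power_series, survival_fractions, track

    fs = crystallization_run(seed, eps=eps, grid=grid, t_end_tau=t_end_tau,
                             frame_count=frame_count)
    psets = [find_pinwheels(st.z, grid, t=st.t, wavelength=1.0)
             for st in fs.frames]
    rho_final = pinwheel_density(psets[-1])
    tracks = track(psets, match_radius=match_radius, wavelength=1.0)
    s0 = float(survival_fractions(tracks, 0)["s"].iloc[-1])
    pw = power_series(fs.frames)
    p = pw[pw["field"] == "z"]["power"].to_numpy()
    jsat = int(np.argmax(p >= 0.95 * p[-1]))
    ssat = (float(survival_fractions(tracks, jsat)["s"].iloc[-1])
            if len(psets[jsat]) else float("nan"))
    return {"rho": rho_final, "s0": s0, "ssat": ssat,
            "label": classify_final_state(fs), "n_final": len(psets[-1]),
            "jsat": jsat, "seed": seed, "tracks": tracks}


def classify_final_state(fs: FrameSet, rho_tol: float = 0.8) -> str:
    """Classify a final OP pattern as stripes / rPWC / hPWC / other.

    Uses the pinwheel density of the final frame (0 for stripes, ≈3.5 for
    the rhombic and ≈5.2 for the hexagonal pinwheel crystal) together with
    the number of dominant Fourier mode pairs (1, 2, and 3 respectively).
    """
    st = fs[-1]
    grid = fs.model.grid
    rho = pinwheel_density(find_pinwheels(st.z, grid))
    zh = np.abs(np.fft.fft2(st.z)) ** 2
    top = np.sort(zh.ravel())[::-1]
    frac = np.cumsum(top) / top.sum()
    n_modes = int(np.searchsorted(frac, 0.8) + 1)
    if rho < rho_tol:
        return "stripes"
    if abs(rho - 3.5) <= rho_tol and n_modes <= 5:
        return "rPWC"
    if abs(rho - 5.2) <= rho_tol:
        return "hPWC"
    return "other"


def dominant_wavevector(f: np.ndarray, grid: GridSpec) -> np.ndarray:
    """Wavevector of the strongest non-DC Fourier mode (ky, kx order → (kx, ky))."""
    fh = np.abs(np.fft.fft2(f if np.iscomplexobj(f) else f - f.mean())) ** 2
    fh[0, 0] = 0.0
    j, i = np.unravel_index(np.argmax(fh), fh.shape)
    kx, ky = grid.wavenumbers()
    return np.array([kx[j, i], ky[j, i]])


def stripe_angle_between(f1: np.ndarray, f2: np.ndarray,
                         grid: GridSpec) -> float:
    """Acute angle (degrees) between the dominant wavevectors of two fields."""
    k1 = dominant_wavevector(f1, grid)
    k2 = dominant_wavevector(f2, grid)
    c = abs(np.dot(k1, k2)) / (np.linalg.norm(k1) * np.linalg.norm(k2))
    return float(np.degrees(np.arccos(np.clip(c, 0, 1))))
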