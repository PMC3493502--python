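"""Crystallization-kinetics statistics: tracking, rates, and layout measures.

Covers the full pinwheel bookkeeping used to characterize the kinetics of
pinwheel crystallization: OP power and maturation-time normalization,
charge-resolved nearest-neighbor distances on the torus, pinwheel-density
variability in circular regions with the SD(A) = c A^(−γ_v) power-law fit,
frame-to-frame matching of pinwheels into lineages, creation/annihilation
rates per hypercolumn, and survival fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .pinwheels import PinwheelSet


# ---------------------------------------------------------------------------
# power and maturation time
# ---------------------------------------------------------------------------

def power_series(frames) -> pd.DataFrame:
    """Spatially averaged power P = ⟨|f|²⟩ of every field per frame.

    Accepts a :class:`~mapcrystal.integrate.FrameSet` (or any sequence of
    states with ``t``, ``z``, ``os``). Returns a tidy DataFrame with columns
    t, field, power.
    """
    rows = []
    for st in frames:
        rows.append({"t": st.t, "field": "z",
                     "power": float(np.mean(np.abs(st.z) ** 2))})
        for i, o in enumerate(st.os):
            rows.append({"t": st.t, "field": f"o{i + 1}",
                         "power": float(np.mean(o**2))})
    if not rows:
        raise ValueError("need at least one frame")
    return pd.DataFrame(rows)


def maturation_time(t: np.ndarray, p: np.ndarray,
                    peak_margin: float = 0.01) -> float:
    """Maturation time T of a power curve.

    T is the time of the interior peak of P(t) if the curve has one
    (exceeding the final value by more than ``peak_margin`` relatively), and
    otherwise the first time P reaches 90% of its final value (linearly
    interpolated between samples). Developmental time is t′ = t/T.
    """
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    if t.size < 2:
        raise ValueError("power curve needs at least two samples")
    p_final = p[-1]
    m = int(np.argmax(p))
    if m not in (0, p.size - 1) and p[m] > p_final * (1.0 + peak_margin):
        return float(t[m])
    if p_final <= 0:
        raise ValueError("final power is not positive; series not saturated")
    # saturation sanity: the curve must have flattened at the end
    if p.size >= 3 and abs(p[-1] - p[-2]) > 0.05 * p_final:
        raise ValueError(
            f"power still changing by {abs(p[-1] - p[-2]) / p_final:.1%} "
            "between the last frames; integrate longer")
    thresh = 0.9 * p_final
    above = np.nonzero(p >= thresh)[0]
    j = int(above[0])
    if j == 0:
        return float(t[0])
    # linear interpolation of the crossing
    t0, t1 = t[j - 1], t[j]
    p0, p1 = p[j - 1], p[j]
    return float(t0 + (thresh - p0) / (p1 - p0) * (t1 - t0))


# ---------------------------------------------------------------------------
# torus geometry helpers
# ---------------------------------------------------------------------------

def _torus_delta(a: np.ndarray, b: np.ndarray, lx: float, ly: float):
    """Minimal-image displacement b − a for (N,2)/(M,2) position arrays."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    d = b[None, :, :] - a[:, None, :]
    d[..., 0] -= lx * np.round(d[..., 0] / lx)
    d[..., 1] -= ly * np.round(d[..., 1] / ly)
    return d


def torus_distances(a: np.ndarray, b: np.ndarray, lx: float, ly: float):
    """(N, M) matrix of minimal-image distances on the torus."""
    d = _torus_delta(np.atleast_2d(a), np.atleast_2d(b), lx, ly)
    return np.sqrt((d**2).sum(axis=-1))


def nn_distances(pws: PinwheelSet, wavelength: float | None = None,
                 mode: str = "any") -> np.ndarray:
    """Per-pinwheel nearest-neighbor distance in units of Λ.

    ``mode`` selects the neighbor class: ``any``, ``same`` (equal charge), or
    ``opposite``. Distances use the minimal-image torus metric (the map is
    periodically continued, so pinwheels near the frame border find their
    neighbors across it).
    """
    if mode not in ("any", "same", "opposite"):
        raise ValueError(f"unknown mode {mode!r}")
    lam = wavelength if wavelength is not None else pws.wavelength
    pos = pws.positions
    q = pws.charges
    n = len(pws)
    if n < 2:
        raise ValueError("need at least two pinwheels")
    dist = torus_distances(pos, pos, pws.grid.lx, pws.grid.ly)
    np.fill_diagonal(dist, np.inf)
    if mode == "any":
        sel = np.ones_like(dist, dtype=bool)
    elif mode == "same":
        sel = q[:, None] == q[None, :]
    else:
        sel = q[:, None] != q[None, :]
    np.fill_diagonal(sel, False)
    out = np.where(sel, dist, np.inf).min(axis=1)
    out = out[np.isfinite(out)]
    if out.size == 0:
        raise ValueError(f"no neighbor pairs in mode {mode!r}")
    return out / lam


# ---------------------------------------------------------------------------
# density variability in circular regions
# ---------------------------------------------------------------------------

def density_variability(pws: PinwheelSet, region_count: int = 20000,
                        area_range: tuple[float, float] = (0.25, 9.0),
                        n_bins: int = 30, max_per_bin: int = 1000,
                        min_per_bin: int = 10, seed: int = 0):
    """Pinwheel-density variability SD(A) over random circular regions.

    Circular regions with uniformly distributed centers and sizes (areas
    uniform over ``area_range``, in Λ² units) are sampled on the torus; per
    log-spaced area bin the standard deviation of the pinwheel density
    (count·Λ²/A) over at most ``max_per_bin`` regions is computed, and the
    power law SD = c A^(−γ_v) is least-squares fitted on log-log axes.

    Returns a dict with the binned table and fit parameters
    ``{"area", "sd", "count", "c", "gamma_v", "residual"}``.
    """
    grid = pws.grid
    lam = pws.wavelength
    a_lo, a_hi = (area_range[0] * lam**2, area_range[1] * lam**2)
    if a_hi > 0.25 * grid.area:
        raise ValueError("largest region area exceeds a quarter of the domain")
    rng = np.random.default_rng(seed)
    centers = rng.uniform(0, 1, size=(region_count, 2))
    centers[:, 0] *= grid.lx
    centers[:, 1] *= grid.ly
    areas = rng.uniform(a_lo, a_hi, size=region_count)
    radii = np.sqrt(areas / np.pi)
    pos = pws.positions
    if len(pws) == 0:
        raise ValueError("no pinwheels")
    dist = torus_distances(centers, pos, grid.lx, grid.ly)
    counts = (dist <= radii[:, None]).sum(axis=1)
    dens = counts * lam**2 / areas

    edges = np.geomspace(a_lo, a_hi, n_bins + 1)
    rows = []
    for k in range(n_bins):
        sel = np.nonzero((areas >= edges[k]) & (areas < edges[k + 1]))[0]
        sel = sel[:max_per_bin]
        if sel.size < min_per_bin:
            continue
        rows.append(((edges[k] * edges[k + 1]) ** 0.5 / lam**2,
                     float(np.std(dens[sel])), int(sel.size)))
    if len(rows) < 2:
        raise ValueError("not enough populated area bins for the SD(A) fit")
    table = np.array([r[:2] for r in rows])
    ok = table[:, 1] > 0
    logA = np.log(table[ok, 0])
    logS = np.log(table[ok, 1])
    coef = np.polyfit(logA, logS, 1)
    resid = float(np.sqrt(np.mean((np.polyval(coef, logA) - logS) ** 2)))
    return {"area": table[:, 0], "sd": table[:, 1],
            "count": np.array([r[2] for r in rows]),
            "c": float(np.exp(coef[1])), "gamma_v": float(-coef[0]),
            "residual": resid}


# ---------------------------------------------------------------------------
# tracking
# ---------------------------------------------------------------------------

@dataclass
class Lineage:
    """One pinwheel identity followed across consecutive frames."""

    lineage_id: int
    q: float
    first_frame: int
    positions: list[tuple[float, float]] = dc_field(default_factory=list)

    @property
    def last_frame(self) -> int:
        return self.first_frame + len(self.positions) - 1


@dataclass
class TrackTable:
    """Pinwheel lineages and per-frame-pair creation/annihilation counts.

    Satisfies N(t_{j+1}) = N(t_j) + created_j − annihilated_j for every
    consecutive frame pair by construction (asserted in :func:`track`).
    """

    lineages: list[Lineage]
    times: np.ndarray
    created: np.ndarray       # length n_frames−1
    annihilated: np.ndarray   # length n_frames−1
    match_radius: float
    wavelength: float

    @property
    def n_frames(self) -> int:
        return len(self.times)

    def alive_at(self, j: int) -> list[Lineage]:
        return [ln for ln in self.lineages
                if ln.first_frame <= j <= ln.last_frame]

    def counts(self) -> np.ndarray:
        n = np.zeros(self.n_frames, dtype=int)
        for ln in self.lineages:
            n[ln.first_frame:ln.last_frame + 1] += 1
        return n


def track(frame_pinwheels, match_radius: float = 0.2,
          wavelength: float | None = None) -> TrackTable:
    """Match pinwheels across time-ordered frames into lineages.

    Two pinwheels in consecutive frames are identified when they carry the
    same topological charge and their torus distance is below
    ``match_radius`` (in units of Λ). Matching is greedy by increasing
    distance and one-to-one; unmatched old pinwheels count as annihilated,
    unmatched new ones as created.
    """
    frames = list(frame_pinwheels)
    if not frames:
        raise ValueError("no frames to track")
    lam = wavelength if wavelength is not None else frames[0].wavelength
    radius = match_radius * lam
    grid = frames[0].grid

    times = np.array([f.t for f in frames])
    lineages: list[Lineage] = []
    next_id = 0
    current: list[Lineage] = []
    for p in frames[0].pinwheels:
        ln = Lineage(next_id, p.q, 0, [(p.x, p.y)])
        lineages.append(ln)
        current.append(ln)
        next_id += 1
    created = np.zeros(len(frames) - 1, dtype=int)
    annihilated = np.zeros(len(frames) - 1, dtype=int)

    for j in range(1, len(frames)):
        new = frames[j].pinwheels
        old_pos = np.array([ln.positions[-1] for ln in current]) \
            if current else np.zeros((0, 2))
        new_pos = np.array([[p.x, p.y] for p in new]) \
            if new else np.zeros((0, 2))
        matched_old: set[int] = set()
        matched_new: set[int] = set()
        if len(current) and len(new):
            dist = torus_distances(old_pos, new_pos, grid.lx, grid.ly)
            qs_old = np.array([ln.q for ln in current])
            qs_new = np.array([p.q for p in new])
            ok = (dist <= radius) & (qs_old[:, None] == qs_new[None, :])
            ii, kk = np.nonzero(ok)
            order = np.argsort(dist[ii, kk], kind="stable")
            for a, b in zip(ii[order], kk[order]):
                if a in matched_old or b in matched_new:
                    continue
                matched_old.add(int(a))
                matched_new.add(int(b))
                current[a].positions.append((new[b].x, new[b].y))
        survivors = [current[a] for a in sorted(matched_old)]
        annihilated[j - 1] = len(current) - len(matched_old)
        for b, p in enumerate(new):
            if b not in matched_new:
                ln = Lineage(next_id, p.q, j, [(p.x, p.y)])
                lineages.append(ln)
                survivors.append(ln)
                next_id += 1
                created[j - 1] += 1
        current = survivors
        # conservation identity (exact by construction)
        assert len(current) == len(new)

    table = TrackTable(lineages, times, created, annihilated, match_radius, lam)
    n = table.counts()
    assert np.all(n[1:] == n[:-1] + created - annihilated)
    return table


def event_rates(tracks: TrackTable, area: float,
                wavelength: float | None = None) -> pd.DataFrame:
    """Creation and annihilation rates per hypercolumn Λ² per unit time.

    rate_j = N_{c/a,j} / (Δt_j · area/Λ²) for each consecutive frame pair;
    the row time is the geometric midpoint of the interval.
    """
    if tracks.n_frames < 2:
        raise ValueError("need at least two frames")
    lam = wavelength if wavelength is not None else tracks.wavelength
    dt = np.diff(tracks.times)
    if np.any(dt <= 0):
        raise ValueError("frame times must be strictly increasing")
    hyper = area / lam**2
    tm = np.sqrt(np.maximum(tracks.times[:-1], 1e-300) * tracks.times[1:])
    return pd.DataFrame({
        "t": tm,
        "creation_rate": tracks.created / (dt * hyper),
        "annihilation_rate": tracks.annihilated / (dt * hyper),
    })


def survival_fractions(tracks: TrackTable, j0: int = 0):
    """Survival curve s(t0, t) and preserved fraction p(t).

    s(t0, t): fraction of the pinwheels alive at frame ``j0`` whose lineages
    extend (at least) to time t ≥ t0; s(t0, t0) = 1 and s is non-increasing.
    p(t): fraction of pinwheels alive at t that survive to the final frame;
    p(t_f) = 1. Returns a DataFrame with columns t, s, p over frames ≥ j0.
    """
    if not 0 <= j0 < tracks.n_frames:
        raise ValueError("t0 frame outside the tracked range")
    base = tracks.alive_at(j0)
    if not base:
        raise ValueError("no pinwheels at the reference frame")
    last = tracks.n_frames - 1
    rows = []
    for j in range(j0, tracks.n_frames):
        alive = tracks.alive_at(j)
        s = sum(1 for ln in base if ln.last_frame >= j) / len(base)
        if alive:
            p = sum(1 for ln in alive if ln.last_frame == last) / len(alive)
        else:
            p = np.nan
        rows.append({"t": tracks.times[j], "s": s, "p": p})
    return pd.DataFrame(rows)
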