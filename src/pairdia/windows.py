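"""Isolation-window scheme construction for pair-separating DIA.

The acquisition design combines two window populations over one scan range:

* **narrow target windows** (default 4 Th) drawn from a global grid so that
  the light and heavy members of each stable-isotope precursor pair fall in
  *adjacent, separate* windows and are fragmented independently;
* **wide profile windows** that tile the remaining m/z gaps for global
  proteome profiling, with widths either equal or proportional to a supplied
  precursor-density reference (narrow where precursors crowd, wide where the
  map is empty).

Windows are half-open ``[start, end)`` intervals in Thomson, so adjacent
windows can share a boundary without ambiguity: a precursor sitting exactly
on a boundary belongs to the right-hand window.

The default narrow grid has width 4 Th anchored at offset 1 (boundaries at
1 mod 4).  A heavy-Lys 2+ pair is spaced 8.0142/2 = 4.0071 Th apart, always
wider than the 4 Th cell, so the grid rule alone places the channels in
distinct cells; narrower spacings (e.g. heavy-Glu at 2+/3+) are resolved by
re-anchoring the pair's two windows on the light/heavy midpoint, flagged as
off-grid.
"""

from __future__ import annotations

import bisect
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .chem import IsotopePair

__all__ = [
    "NARROW_TARGET",
    "WIDE_PROFILE",
    "IsolationWindow",
    "WindowScheme",
    "PrecursorDensity",
    "SchemeError",
    "ValidationReport",
    "place_pair_windows",
    "design_scheme",
    "equal_width_scheme",
    "variable_width_scheme",
    "assign_window",
    "validate_scheme",
]

NARROW_TARGET = "narrow_target"
WIDE_PROFILE = "wide_profile"

_EPS = 1e-9


class SchemeError(ValueError):
    """Raised when a requested window scheme is infeasible."""


@dataclass(frozen=True)
class IsolationWindow:
    """Half-open isolation interval ``[start_mz, end_mz)`` in Th."""

    start_mz: float
    end_mz: float
    kind: str = WIDE_PROFILE
    id: int = 0
    off_grid: bool = False

    def __post_init__(self) -> None:
        if not self.start_mz < self.end_mz:
            raise ValueError(f"degenerate window [{self.start_mz}, {self.end_mz})")
        if self.kind not in (NARROW_TARGET, WIDE_PROFILE):
            raise ValueError(f"unknown window kind {self.kind!r}")

    @property
    def width(self) -> float:
        return self.end_mz - self.start_mz

    @property
    def center(self) -> float:
        return 0.5 * (self.start_mz + self.end_mz)

    def contains(self, mz: float) -> bool:
        return self.start_mz <= mz < self.end_mz


@dataclass(frozen=True)
class PrecursorDensity:
    """Weighted precursor positions (e.g. summed MS1 intensity per m/z bin)."""

    points: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if any(w < 0 for _, w in self.points):
            raise ValueError("density weights must be non-negative")

    @classmethod
    def from_arrays(cls, mz, weight) -> "PrecursorDensity":
        order = np.argsort(mz)
        return cls(tuple(zip(np.asarray(mz, float)[order], np.asarray(weight, float)[order])))

    @property
    def mz(self) -> np.ndarray:
        return np.array([m for m, _ in self.points])

    @property
    def weight(self) -> np.ndarray:
        return np.array([w for _, w in self.points])


@dataclass(frozen=True)
class WindowScheme:
    """An ordered, gap-free, non-overlapping tiling of the scan range."""

    windows: tuple[IsolationWindow, ...]
    scan_min: float
    scan_max: float
    narrow_width: float = 4.0
    wide_bounds: tuple[float, float] | None = None
    anchor_offset: float = 1.0

    def __post_init__(self) -> None:
        ws = tuple(sorted(self.windows, key=lambda w: w.start_mz))
        ws = tuple(replace(w, id=i) for i, w in enumerate(ws))
        object.__setattr__(self, "windows", ws)

    @property
    def narrow_windows(self) -> list[IsolationWindow]:
        return [w for w in self.windows if w.kind == NARROW_TARGET]

    @property
    def wide_windows(self) -> list[IsolationWindow]:
        return [w for w in self.windows if w.kind == WIDE_PROFILE]

    def counts(self) -> dict[str, int]:
        return {
            NARROW_TARGET: len(self.narrow_windows),
            WIDE_PROFILE: len(self.wide_windows),
        }

    def to_records(self) -> list[dict]:
        return [
            {
                "window_id": w.id,
                "start_mz": w.start_mz,
                "end_mz": w.end_mz,
                "center_mz": w.center,
                "width": w.width,
                "kind": w.kind,
            }
            for w in self.windows
        ]


# ---------------------------------------------------------------------------
# Narrow-window placement
# ---------------------------------------------------------------------------


def _grid_cell(mz: float, width: float, offset: float) -> tuple[float, float]:
    k = math.floor((mz - offset) / width)
    start = offset + k * width
    return start, start + width


def place_pair_windows(
    pair: IsotopePair,
    narrow_width: float = 4.0,
    anchor_offset: float = 1.0,
    scan_range: tuple[float, float] | None = None,
) -> tuple[IsolationWindow, IsolationWindow]:
    """Narrow windows isolating the light and heavy precursors separately.

    Windows come from the global grid of ``narrow_width`` anchored at
    ``anchor_offset`` (boundaries at ``offset + k*width``).  If both channels
    fall in the same grid cell — pair spacing below the window width — the
    pair's two windows are re-anchored locally so that the shared boundary is
    the light/heavy midpoint, and both windows are flagged ``off_grid``.
    """
    if narrow_width <= 0:
        raise ValueError("narrow width must be positive")
    for ion in (pair.light, pair.heavy):
        if scan_range is not None and not scan_range[0] <= ion.mz < scan_range[1]:
            raise SchemeError(
                f"precursor at {ion.mz:.4f} outside scan range {scan_range}"
            )
    cell_l = _grid_cell(pair.light.mz, narrow_width, anchor_offset)
    cell_h = _grid_cell(pair.heavy.mz, narrow_width, anchor_offset)
    if cell_l == cell_h:
        mid = 0.5 * (pair.light.mz + pair.heavy.mz)
        wl = IsolationWindow(mid - narrow_width, mid, NARROW_TARGET, off_grid=True)
        wh = IsolationWindow(mid, mid + narrow_width, NARROW_TARGET, off_grid=True)
    else:
        wl = IsolationWindow(*cell_l, NARROW_TARGET)
        wh = IsolationWindow(*cell_h, NARROW_TARGET)
    return wl, wh


# ---------------------------------------------------------------------------
# Wide-window tiling
# ---------------------------------------------------------------------------


def _density_boundaries(
    lo: float, hi: float, n: int, density: PrecursorDensity | None
) -> np.ndarray:
    """``n + 1`` boundaries over [lo, hi] at equal cumulative-density steps."""
    if n < 1:
        raise ValueError("window count must be >= 1")
    if density is None:
        return np.linspace(lo, hi, n + 1)
    grid = np.linspace(lo, hi, 2049)
    dens = np.interp(grid, density.mz, density.weight)
    if dens.max() <= 0:
        return np.linspace(lo, hi, n + 1)
    # tiny uniform floor keeps the cumulative strictly increasing across
    # zero-density stretches without visibly moving the quantiles
    dens = dens + dens.max() * 1e-9
    cum = cumulative_trapezoid(dens, grid, initial=0.0)
    targets = cum[-1] * np.arange(n + 1) / n
    bounds = np.interp(targets, cum, grid)
    bounds[0], bounds[-1] = lo, hi
    return bounds


def _gap_mass(lo: float, hi: float, density: PrecursorDensity | None) -> float:
    if density is None:
        return hi - lo
    grid = np.linspace(lo, hi, 513)
    dens = np.interp(grid, density.mz, density.weight)
    mass = float(np.trapezoid(dens, grid))
    return mass


def _largest_remainder(masses: list[float], total: int) -> list[int]:
    """Allocate ``total`` integer counts across gaps proportional to mass.

    Standard largest-remainder apportionment, with a final adjustment that
    guarantees every gap at least one window (taking from the largest
    allocation), so the result always sums exactly to ``total``.
    """
    n = len(masses)
    if total < n:
        raise SchemeError(f"cannot tile {n} gaps with only {total} wide windows")
    msum = sum(masses)
    if msum <= 0:
        quotas = [total / n] * n
    else:
        quotas = [total * m / msum for m in masses]
    counts = [int(math.floor(q)) for q in quotas]
    remainder = total - sum(counts)
    order = sorted(range(n), key=lambda i: quotas[i] - counts[i], reverse=True)
    for i in order[:remainder]:
        counts[i] += 1
    while any(c == 0 for c in counts):
        i0 = counts.index(0)
        imax = max(range(n), key=lambda i: counts[i])
        counts[i0] += 1
        counts[imax] -= 1
    return counts


def _clamp_rebalance(
    bounds: np.ndarray, wide_bounds: tuple[float, float] | None, gap_desc: str
) -> np.ndarray:
    """Clamp window widths into ``wide_bounds``, redistributing the slack.

    Iteratively pins violating widths at the bound and re-spreads the
    remaining span over the free windows in proportion to their current
    widths.  Raises :class:`SchemeError` if the gap cannot be tiled within
    the bounds at the allotted count.
    """
    if wide_bounds is None:
        return bounds
    lo_w, hi_w = wide_bounds
    widths = np.diff(bounds)
    n = len(widths)
    span = bounds[-1] - bounds[0]
    if span < n * lo_w - _EPS or span > n * hi_w + _EPS:
        raise SchemeError(
            f"gap {gap_desc} of span {span:.3f} Th cannot be tiled by {n} "
            f"windows within width bounds [{lo_w}, {hi_w}]"
        )
    for _ in range(200):
        clipped = np.clip(widths, lo_w, hi_w)
        slack = span - clipped.sum()
        if abs(slack) < 1e-10:
            widths = clipped
            break
        if slack > 0:
            free = clipped < hi_w - _EPS
            room = hi_w - clipped[free]
        else:
            free = clipped > lo_w + _EPS
            room = clipped[free] - lo_w
        if not free.any():  # pragma: no cover - guarded by feasibility check
            raise SchemeError(f"width rebalancing failed for gap {gap_desc}")
        share = np.minimum(np.abs(slack) * room / room.sum(), room)
        clipped[free] += math.copysign(1.0, slack) * share
        widths = clipped
    out = np.empty_like(bounds)
    out[0] = bounds[0]
    out[1:] = bounds[0] + np.cumsum(widths)
    out[-1] = bounds[-1]
    return out


def equal_width_scheme(
    scan_range: tuple[float, float], n: int
) -> WindowScheme:
    """``n`` contiguous equal-width windows over the scan range."""
    lo, hi = scan_range
    if n < 1:
        raise ValueError("need at least one window")
    if not lo < hi:
        raise ValueError(f"invalid scan range {scan_range}")
    bounds = np.linspace(lo, hi, n + 1)
    wins = tuple(
        IsolationWindow(bounds[i], bounds[i + 1], WIDE_PROFILE) for i in range(n)
    )
    return WindowScheme(wins, lo, hi)


def variable_width_scheme(
    scan_range: tuple[float, float],
    n: int,
    density: PrecursorDensity,
    wide_bounds: tuple[float, float] | None = None,
) -> WindowScheme:
    """``n`` windows with boundaries at equal cumulative-density quantiles.

    Dense m/z regions receive narrow windows and sparse regions wide ones; a
    uniform density reduces to :func:`equal_width_scheme`.  Widths are
    clamped to ``wide_bounds`` with rebalancing when given.
    """
    lo, hi = scan_range
    inside = (density.mz >= lo) & (density.mz < hi)
    if density.weight.max(initial=0.0) <= 0:
        raise SchemeError("precursor density is all zero")
    if not inside.any():
        raise SchemeError("no density points inside the scan range")
    bounds = _density_boundaries(lo, hi, n, density)
    bounds = _clamp_rebalance(bounds, wide_bounds, f"[{lo}, {hi})")
    wins = tuple(
        IsolationWindow(bounds[i], bounds[i + 1], WIDE_PROFILE) for i in range(n)
    )
    return WindowScheme(wins, lo, hi, wide_bounds=wide_bounds)


def design_scheme(
    pairs: list[IsotopePair],
    scan_range: tuple[float, float],
    narrow_width: float = 4.0,
    n_wide: int = 20,
    density: PrecursorDensity | None = None,
    wide_bounds: tuple[float, float] | None = None,
    anchor_offset: float = 1.0,
) -> WindowScheme:
    """Dual-population scheme: narrow pair-separating windows + wide tiling.

    One narrow window is produced per target precursor (identical windows
    arising from distinct pairs sharing a grid cell are merged), and the
    remaining m/z gaps are tiled by ``n_wide`` wide windows.  Wide windows
    are allocated across gaps by largest-remainder apportionment on the
    gap's density mass (gap width when no density is supplied), with per-gap
    boundaries at equal cumulative-density quantiles and widths clamped to
    ``wide_bounds``.
    """
    lo, hi = scan_range
    if not lo < hi:
        raise ValueError(f"invalid scan range {scan_range}")

    narrow: list[IsolationWindow] = []
    seen: set[tuple[float, float]] = set()
    for pair in pairs:
        for w in place_pair_windows(pair, narrow_width, anchor_offset, scan_range):
            key = (round(w.start_mz, 6), round(w.end_mz, 6))
            if key not in seen:
                seen.add(key)
                narrow.append(w)
    narrow.sort(key=lambda w: w.start_mz)
    for a, b in zip(narrow, narrow[1:]):
        if b.start_mz < a.end_mz - _EPS:
            raise SchemeError(
                f"narrow windows [{a.start_mz}, {a.end_mz}) and "
                f"[{b.start_mz}, {b.end_mz}) overlap; "
                "targets are too close for the configured narrow width"
            )
    # clip narrow windows to the scan range (targets are interior by the
    # placement precondition, so clipping only trims empty margin)
    narrow = [
        replace(w, start_mz=max(w.start_mz, lo), end_mz=min(w.end_mz, hi))
        for w in narrow
    ]

    gaps: list[tuple[float, float]] = []
    cursor = lo
    for w in narrow:
        if w.start_mz > cursor + _EPS:
            gaps.append((cursor, w.start_mz))
        cursor = w.end_mz
    if hi > cursor + _EPS:
        gaps.append((cursor, hi))

    wide: list[IsolationWindow] = []
    if gaps:
        if n_wide < len(gaps):
            raise SchemeError(
                f"{len(gaps)} gaps remain but only {n_wide} wide windows allotted"
            )
        masses = [_gap_mass(a, b, density) for a, b in gaps]
        counts = _largest_remainder(masses, n_wide)
        for (a, b), c in zip(gaps, counts):
            bounds = _density_boundaries(a, b, c, density)
            bounds = _clamp_rebalance(bounds, wide_bounds, f"[{a:.2f}, {b:.2f})")
            wide.extend(
                IsolationWindow(bounds[i], bounds[i + 1], WIDE_PROFILE)
                for i in range(c)
            )
    elif n_wide:
        raise SchemeError("no gaps left to tile but n_wide > 0")

    return WindowScheme(
        tuple(narrow) + tuple(wide),
        lo,
        hi,
        narrow_width=narrow_width,
        wide_bounds=wide_bounds,
        anchor_offset=anchor_offset,
    )


# ---------------------------------------------------------------------------
# Lookup and validation
# ---------------------------------------------------------------------------


def assign_window(scheme: WindowScheme, mz: float) -> int:
    """Id of the unique window with ``start <= mz < end``."""
    if not scheme.scan_min <= mz < scheme.scan_max:
        raise ValueError(
            f"m/z {mz} outside scan range [{scheme.scan_min}, {scheme.scan_max})"
        )
    starts = [w.start_mz for w in scheme.windows]
    i = bisect.bisect_right(starts, mz) - 1
    w = scheme.windows[i]
    if not w.contains(mz):  # only possible if the scheme has a hole
        raise ValueError(f"m/z {mz} falls in a coverage hole of the scheme")
    return w.id


@dataclass(frozen=True)
class ValidationReport:
    coverage_ok: bool
    overlap_ok: bool
    widths_ok: bool
    counts: dict[str, int] = field(default_factory=dict)
    pair_separation_ok: tuple[bool, ...] = ()

    @property
    def all_ok(self) -> bool:
        return (
            self.coverage_ok
            and self.overlap_ok
            and self.widths_ok
            and all(self.pair_separation_ok)
        )


def validate_scheme(
    scheme: WindowScheme, pairs: list[IsotopePair] = ()
) -> ValidationReport:
    """Machine-readable check of the scheme invariants.

    ``pair_separation_ok[i]`` is true iff the light and heavy precursors of
    ``pairs[i]`` land in *different* windows — the property the narrow
    windows exist to guarantee, and exactly what wide fixed windows violate.
    """
    ws = scheme.windows
    coverage = bool(ws) and abs(ws[0].start_mz - scheme.scan_min) < 1e-6
    overlap = True
    for a, b in zip(ws, ws[1:]):
        if b.start_mz < a.end_mz - 1e-6:
            overlap = False
        if b.start_mz > a.end_mz + 1e-6:
            coverage = False
    if ws and abs(ws[-1].end_mz - scheme.scan_max) > 1e-6:
        coverage = False

    widths_ok = True
    if scheme.wide_bounds is not None:
        lo_w, hi_w = scheme.wide_bounds
        widths_ok = all(
            lo_w - 1e-6 <= w.width <= hi_w + 1e-6 for w in scheme.wide_windows
        )

    separation: list[bool] = []
    for pair in pairs:
        try:
            separation.append(
                assign_window(scheme, pair.light.mz)
                != assign_window(scheme, pair.heavy.mz)
            )
        except ValueError:
            separation.append(False)

    return ValidationReport(
        coverage_ok=coverage,
        overlap_ok=overlap,
        widths_ok=widths_ok,
        counts=scheme.counts(),
        pair_separation_ok=tuple(separation),
    )
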