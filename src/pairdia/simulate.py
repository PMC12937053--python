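"""Synthetic panels, DIA acquisition simulation, and calibration series.

The simulator makes the whole workflow testable without instrument data:
it generates realistic tryptic-like light/heavy peptide panels, "acquires"
a mixture under any window scheme (each precursor is fragmented in the one
window that isolates it, and coisolated species sum into a composite MS2
spectrum), produces isotope-dilution calibration series with lognormal
multiplicative noise and truncated-normal blanks, and draws Gaussian XIC
peaks for the chromatogram utilities.

Every generator takes an integer seed and is deterministic under it.
Fragment-intensity profiles are drawn once per peptide *sequence*, so the
light and heavy channels of a pair share the same relative fragment
pattern — which is what makes the summed fragment L/H ratio equal the
underlying amount ratio in the noise-free limit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chem import (
    CANONICAL_RESIDUES,
    IsotopePair,
    LabeledPeptide,
    LabelKind,
    fragment_series,
    make_pair,
    precursor_ion,
)
from .metrics import Chromatogram
from .quant import CalibrationLevel
from .windows import WindowScheme, assign_window

__all__ = [
    "SimulatedSpecies",
    "SimulatedMixture",
    "WindowAcquisition",
    "AcquisitionResult",
    "synth_panel",
    "simulate_acquisition",
    "extract_pair_measurement_areas",
    "simulate_calibration_series",
    "simulate_chromatogram",
]

# residues allowed in random peptide interiors: canonical minus the
# basic/acidic residues that would create internal cleavage sites
_INTERIOR = sorted(CANONICAL_RESIDUES - set("KRE"))


def synth_panel(
    n_pairs: int,
    scan_range: tuple[float, float] = (400.0, 1000.0),
    charge: int = 2,
    label_kind: LabelKind | str = LabelKind.HEAVY_K,
    seed: int = 0,
    min_separation: float = 12.0,
    max_attempts: int = 20000,
) -> list[IsotopePair]:
    """Random tryptic-like light/heavy pairs with precursors in range.

    Sequences are 7-16 residues ending in the label's anchor residue (K for
    heavy Lys, E for heavy Glu) with cleavage-site-free interiors.  Pairs
    are rejection-sampled until all light precursors are at least
    ``min_separation`` Th apart and both channels of every pair lie inside
    the scan range; deterministic under ``seed``.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    kind = LabelKind(label_kind)
    if kind is LabelKind.NONE:
        raise ValueError("panel pairs require a heavy label kind")
    terminal = "K" if kind is LabelKind.HEAVY_K else "E"
    rng = np.random.default_rng(seed)
    pairs: list[IsotopePair] = []
    centers: list[float] = []
    lo, hi = scan_range
    for _ in range(max_attempts):
        if len(pairs) == n_pairs:
            break
        length = int(rng.integers(7, 17))
        seq = "".join(rng.choice(_INTERIOR, size=length - 1)) + terminal
        pair = make_pair(seq, charge, kind)
        if not (lo <= pair.light.mz < hi and lo <= pair.heavy.mz < hi):
            continue
        if any(abs(pair.light.mz - c) < min_separation for c in centers):
            continue
        pairs.append(pair)
        centers.append(pair.light.mz)
    if len(pairs) < n_pairs:
        raise ValueError(
            f"could not place {n_pairs} pairs in {scan_range} with "
            f"{min_separation} Th separation"
        )
    return pairs


@dataclass(frozen=True)
class SimulatedSpecies:
    peptide: LabeledPeptide
    charge: int
    amount: float  # fmol
    rt: float = 30.0  # minutes

    def __post_init__(self) -> None:
        if self.amount < 0:
            raise ValueError("amount must be >= 0")


@dataclass(frozen=True)
class SimulatedMixture:
    species: tuple[SimulatedSpecies, ...]
    seed: int = 0

    @classmethod
    def from_pairs(
        cls,
        pairs: list[IsotopePair],
        light_amounts,
        heavy_amount: float = 25.0,
        seed: int = 0,
    ) -> "SimulatedMixture":
        """Mixture with each pair's light channel at its own amount and the
        heavy internal standard at a fixed spike."""
        light_amounts = list(light_amounts)
        if len(light_amounts) != len(pairs):
            raise ValueError("one light amount per pair required")
        sp = []
        for pair, amt in zip(pairs, light_amounts):
            sp.append(SimulatedSpecies(pair.light.peptide, pair.charge, amt))
            sp.append(SimulatedSpecies(pair.heavy.peptide, pair.charge, heavy_amount))
        return cls(tuple(sp), seed)


def _fragment_profile(sequence: str, n_frags: int, seed: int) -> np.ndarray:
    """Fixed per-ion relative intensities, reproducible per (seed, sequence)."""
    child = np.random.default_rng(
        [seed, *(ord(c) for c in sequence)]
    )
    profile = child.uniform(0.05, 1.0, size=n_frags)
    return profile / profile.max()


@dataclass(frozen=True)
class WindowAcquisition:
    window_id: int
    precursors: tuple[SimulatedSpecies, ...]
    spectrum_mz: tuple[float, ...]
    spectrum_intensity: tuple[float, ...]


@dataclass(frozen=True)
class AcquisitionResult:
    windows: dict[int, WindowAcquisition]
    #: per-pair interference: (pair index, same_window, colliding fragment names)
    interference: tuple[tuple[int, bool, tuple[str, ...]], ...] = ()

    def window_of(self, mz_to_id: int) -> WindowAcquisition:
        return self.windows[mz_to_id]


def simulate_acquisition(
    mixture: SimulatedMixture,
    scheme: WindowScheme,
    mz_tolerance: float = 0.01,
    pairs: list[IsotopePair] | None = None,
) -> AcquisitionResult:
    """Assign species to isolation windows and build composite MS2 spectra.

    Each species contributes its theoretical singly-charged b/y fragment
    spectrum — intensities proportional to its amount times a fixed
    per-sequence fragment profile — to the single window that isolates its
    precursor.  For every light/heavy pair found in the mixture (or given
    explicitly) the interference report lists the fragments whose light and
    heavy m/z collide within ``mz_tolerance`` while both precursors sit in
    the same window; a pair-separating scheme yields no collisions.
    """
    per_window: dict[int, list[tuple[SimulatedSpecies, np.ndarray, np.ndarray]]] = {}
    assignments: dict[int, int] = {}
    for idx, sp in enumerate(mixture.species):
        ion = precursor_ion(sp.peptide, sp.charge)
        wid = assign_window(scheme, ion.mz)
        assignments[idx] = wid
        frags = fragment_series(sp.peptide)
        mzs = np.array([f.mz for f in frags])
        profile = _fragment_profile(sp.peptide.sequence, len(frags), mixture.seed)
        per_window.setdefault(wid, []).append((sp, mzs, sp.amount * profile))

    windows: dict[int, WindowAcquisition] = {}
    for wid, entries in per_window.items():
        mz_all = np.concatenate([m for _, m, _ in entries])
        int_all = np.concatenate([i for _, _, i in entries])
        order = np.argsort(mz_all)
        windows[wid] = WindowAcquisition(
            wid,
            tuple(sp for sp, _, _ in entries),
            tuple(mz_all[order]),
            tuple(int_all[order]),
        )

    if pairs is None:
        pairs = _find_pairs(mixture)
    report = []
    for pidx, pair in enumerate(pairs):
        try:
            wl = assign_window(scheme, pair.light.mz)
            wh = assign_window(scheme, pair.heavy.mz)
        except ValueError:
            continue
        same = wl == wh
        colliding: list[str] = []
        if same:
            fl = fragment_series(pair.light.peptide)
            fh = fragment_series(pair.heavy.peptide)
            colliding = [
                a.name for a, b in zip(fl, fh) if abs(a.mz - b.mz) <= mz_tolerance
            ]
        report.append((pidx, same, tuple(colliding)))
    return AcquisitionResult(windows, tuple(report))


def _find_pairs(mixture: SimulatedMixture) -> list[IsotopePair]:
    light = {}
    heavy = {}
    for sp in mixture.species:
        key = (sp.peptide.sequence, sp.charge)
        if sp.peptide.is_heavy:
            heavy[key] = sp
        else:
            light[key] = sp
    pairs = []
    for key in sorted(light.keys() & heavy.keys()):
        pairs.append(
            IsotopePair(
                precursor_ion(light[key].peptide, key[1]),
                precursor_ion(heavy[key].peptide, key[1]),
            )
        )
    return pairs


def extract_pair_measurement_areas(
    result: AcquisitionResult,
    scheme: WindowScheme,
    pair: IsotopePair,
    mz_tolerance: float = 0.005,
) -> dict[str, tuple[float, float]]:
    """Per-fragment (light, heavy) intensities read from the composite spectra.

    Each channel's fragments are looked up, within ``mz_tolerance``, in the
    spectrum of the window that isolated that channel's precursor.  Under a
    coisolating scheme both channels read from the same composite spectrum,
    so shared b ions return the summed light+heavy signal — the interference
    the narrow-window design removes.
    """
    out: dict[str, tuple[float, float]] = {}
    for channel, ion in (("light", pair.light), ("heavy", pair.heavy)):
        wid = assign_window(scheme, ion.mz)
        if wid not in result.windows:
            continue
        acq = result.windows[wid]
        smz = np.asarray(acq.spectrum_mz)
        sint = np.asarray(acq.spectrum_intensity)
        for frag in fragment_series(ion.peptide):
            hits = np.abs(smz - frag.mz) <= mz_tolerance
            val = float(sint[hits].sum())
            prev = out.get(frag.name, (0.0, 0.0))
            out[frag.name] = (
                (val, prev[1]) if channel == "light" else (prev[0], val)
            )
    return out


def simulate_calibration_series(
    true_slope: float,
    true_intercept: float,
    levels=(0.5, 1.0, 5.0, 25.0, 100.0, 500.0),
    reps: int = 3,
    noise_cv: float = 0.05,
    n_blanks: int = 3,
    blank_sd: float = 0.0,
    seed: int = 0,
) -> list[CalibrationLevel]:
    """Isotope-dilution calibration series with multiplicative noise.

    Replicate ratios at nominal ``x`` are ``(m*x + b) * LN(1, cv)`` with a
    lognormal factor of unit mean and coefficient of variation ``noise_cv``;
    blank responses are normal(b, blank_sd) truncated at zero.  The default
    levels span four orders of magnitude, emulating a serial dilution of
    light peptide against a fixed heavy spike.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p(noise_cv**2))
    mu = -0.5 * sigma**2  # unit-mean lognormal
    out: list[CalibrationLevel] = []
    if n_blanks >= 1:
        blanks = rng.normal(true_intercept, blank_sd, size=n_blanks)
        out.append(CalibrationLevel(0.0, tuple(np.clip(blanks, 0.0, None))))
    for x in levels:
        expected = true_slope * x + true_intercept
        if noise_cv == 0:
            ratios = np.full(reps, expected)
        else:
            ratios = expected * rng.lognormal(mu, sigma, size=reps)
        out.append(CalibrationLevel(float(x), tuple(ratios)))
    return out


def simulate_chromatogram(
    amount: float,
    rt: float = 30.0,
    width: float = 0.1,
    noise_sd: float = 0.0,
    seed: int = 0,
    time_step: float | None = None,
    span: float = 8.0,
    baseline: float = 0.0,
) -> Chromatogram:
    """Gaussian elution peak with area equal to ``amount`` plus white noise.

    ``width`` is the Gaussian sigma in minutes; the trace covers
    ``rt +/- span*width`` so that ample flanking background exists, and
    ``peak_bounds`` are set at +/- 3 sigma.  A constant ``baseline`` offset
    keeps additive noise away from the zero-intensity clip.
    """
    if width <= 0:
        raise ValueError("peak width must be positive")
    if amount < 0:
        raise ValueError("amount must be >= 0")
    dt = time_step if time_step is not None else width / 25.0
    t = np.arange(rt - span * width, rt + span * width + dt / 2, dt)
    signal = baseline + amount / (width * np.sqrt(2 * np.pi)) * np.exp(
        -0.5 * ((t - rt) / width) ** 2
    )
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        signal = signal + rng.normal(0.0, noise_sd, size=len(t))
    signal = np.clip(signal, 0.0, None)
    return Chromatogram(
        tuple(t), tuple(signal), peak_bounds=(rt - 3 * width, rt + 3 * width)
    )
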