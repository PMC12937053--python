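"""Stable-isotope-dilution absolute quantification.

Light endogenous peptides are quantified against spiked heavy internal
standards: the light-to-heavy (L/H) ratio of summed fragment peak areas is
interpolated on an external calibration line ``y = m*x + b`` fitted over a
dilution series of the light peptide at fixed heavy spike.  Curve quality is
summarised by R², the residual standard deviation Sy|x, and detection limits
LOD = 3*Sa/m and LOQ = 10*Sa/m where Sa is the standard deviation of blank
responses — hence LOQ/LOD = 10/3 identically.

Conventions: ordinary (unweighted) least squares on the replicate-mean ratio
per level; blanks (nominal 0) participate in the fit and define Sa; negative
interpolated amounts are reported with a flag rather than clipped, so that a
below-blank response remains visible downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .chem import FragmentIon, IsotopePair, LabeledPeptide, classify_pair_fragments

__all__ = [
    "TransitionMeasurement",
    "CalibrationLevel",
    "CalibrationCurve",
    "QuantResult",
    "lh_ratio",
    "fit_calibration",
    "quantify",
    "relative_error",
    "replicate_cv",
    "mutant_metrics",
]


@dataclass(frozen=True)
class TransitionMeasurement:
    """One fragment's integrated peak area in one channel of one replicate."""

    replicate: str
    peptide: LabeledPeptide | str
    channel: str  # 'light' | 'heavy'
    fragment: FragmentIon | str  # ion or its name, e.g. "y4"
    peak_area: float
    background: float = 0.0

    def __post_init__(self) -> None:
        if self.channel not in ("light", "heavy"):
            raise ValueError(f"channel must be 'light' or 'heavy', got {self.channel!r}")
        if self.peak_area < 0 or self.background < 0:
            raise ValueError("peak area and background must be non-negative")

    @property
    def fragment_name(self) -> str:
        return self.fragment if isinstance(self.fragment, str) else self.fragment.name


def lh_ratio(
    measurements: list[TransitionMeasurement],
    fragments: set[str] | None = None,
    *,
    pair: IsotopePair | None = None,
    coisolated: bool = False,
    mz_tolerance: float = 0.01,
) -> float:
    """Summed light over summed heavy peak area across selected fragments.

    ``fragments`` restricts the sum to named ions.  When ``coisolated`` is
    true the selection is *additionally* intersected with the fragments that
    remain channel-unique under coisolation of ``pair`` (for C-terminal
    labels, the y series) — shared ions carry signal from both channels and
    would bias the ratio toward 1.
    """
    allowed = fragments
    if coisolated:
        if pair is None:
            raise ValueError("coisolated ratio requires the isotope pair")
        part = classify_pair_fragments(pair, coisolated=True, mz_tolerance=mz_tolerance)
        unique = {f.name for f in part.unique_light}
        allowed = unique if allowed is None else (allowed & unique)
        if not allowed:
            raise ValueError(
                "no channel-unique fragments remain under the coisolating "
                "scheme; quantification requires pair-separating windows"
            )

    def selected(m: TransitionMeasurement) -> bool:
        return allowed is None or m.fragment_name in allowed

    light = sum(m.peak_area for m in measurements if m.channel == "light" and selected(m))
    heavy = sum(m.peak_area for m in measurements if m.channel == "heavy" and selected(m))
    n_sel = sum(1 for m in measurements if selected(m))
    if n_sel == 0:
        raise ValueError("fragment selection left no measurements")
    if heavy == 0:
        raise ZeroDivisionError("summed heavy peak area is zero; L/H ratio undefined")
    return light / heavy


@dataclass(frozen=True)
class CalibrationLevel:
    """One calibrator: nominal spiked amount and its replicate L/H ratios."""

    nominal_amount: float  # fmol
    ratios: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.nominal_amount < 0:
            raise ValueError("nominal amount must be >= 0")
        if not self.ratios:
            raise ValueError("level carries no replicate ratios")

    @property
    def is_blank(self) -> bool:
        return self.nominal_amount == 0

    @property
    def mean_ratio(self) -> float:
        return float(np.mean(self.ratios))


@dataclass(frozen=True)
class CalibrationCurve:
    slope: float  # ratio per fmol
    intercept: float
    r_squared: float
    sy_x: float
    s_a: float | None  # std dev of blank ratios; None without >=2 blanks
    lod: float | None  # fmol, 3*Sa/m
    loq: float | None  # fmol, 10*Sa/m
    cal_min: float  # smallest non-zero nominal
    cal_max: float  # largest nominal
    n_points: int
    warnings: tuple[str, ...] = ()


def fit_calibration(
    levels: list[CalibrationLevel], fit_on: str = "means"
) -> CalibrationCurve:
    """Ordinary least squares of L/H ratio against nominal amount.

    ``fit_on='means'`` (default) regresses the replicate-mean ratio per
    level; ``'replicates'`` uses every replicate point.  Blanks enter the
    fit and, with at least two blank replicates, define Sa and thus
    LOD/LOQ; otherwise the detection limits are reported unavailable.
    """
    if fit_on not in ("means", "replicates"):
        raise ValueError("fit_on must be 'means' or 'replicates'")
    nonzero = sorted({lv.nominal_amount for lv in levels if not lv.is_blank})
    if len(nonzero) < 3:
        raise ValueError("calibration requires >= 3 distinct non-zero levels")

    if fit_on == "means":
        x = np.array([lv.nominal_amount for lv in levels], float)
        y = np.array([lv.mean_ratio for lv in levels], float)
    else:
        x = np.array([lv.nominal_amount for lv in levels for _ in lv.ratios], float)
        y = np.array([r for lv in levels for r in lv.ratios], float)
    if np.ptp(x) == 0:
        raise ValueError("singular design: all calibrators at the same nominal")

    res = stats.linregress(x, y)
    m, b = float(res.slope), float(res.intercept)
    resid = y - (m * x + b)
    n = len(x)
    sy_x = math.sqrt(float(np.sum(resid**2)) / (n - 2)) if n > 2 else 0.0

    blank_ratios = [r for lv in levels if lv.is_blank for r in lv.ratios]
    warnings: list[str] = []
    if m < 0:
        warnings.append("negative slope: calibration is not usable for interpolation")
    if len(blank_ratios) >= 2:
        s_a = float(np.std(blank_ratios, ddof=1))
        lod = 3 * s_a / m if m != 0 else None
        loq = 10 * s_a / m if m != 0 else None
    else:
        s_a = lod = loq = None
        warnings.append("fewer than 2 blank replicates: LOD/LOQ unavailable")

    return CalibrationCurve(
        slope=m,
        intercept=b,
        r_squared=float(res.rvalue**2),
        sy_x=sy_x,
        s_a=s_a,
        lod=lod,
        loq=loq,
        cal_min=nonzero[0],
        cal_max=max(lv.nominal_amount for lv in levels),
        n_points=n,
        warnings=tuple(warnings),
    )


@dataclass(frozen=True)
class QuantResult:
    amount: float  # fmol
    concentration: float | None  # fmol per ug sample peptide
    below_lod: bool
    below_loq: bool
    extrapolated: bool
    cv: float | None = None
    relative_error: float | None = None

    def __post_init__(self) -> None:
        if self.below_lod and not self.below_loq:
            raise ValueError("below_lod implies below_loq (LOD < LOQ)")


def quantify(
    curve: CalibrationCurve,
    ratio: float,
    sample_peptide_mass: float | None = None,
) -> QuantResult:
    """Interpolate an observed L/H ratio to an absolute amount.

    ``amount = (ratio - intercept) / slope``; a negative amount (response
    below the blank line) is reported as-is with the ``below_lod`` flag.
    ``extrapolated`` marks amounts beyond the calibrated range.
    """
    if curve.slope == 0:
        raise ZeroDivisionError("calibration slope is zero")
    amount = (ratio - curve.intercept) / curve.slope
    below_lod = curve.lod is not None and amount < curve.lod
    below_loq = below_lod or (curve.loq is not None and amount < curve.loq)
    extrapolated = amount > curve.cal_max or amount < 0
    conc = amount / sample_peptide_mass if sample_peptide_mass else None
    return QuantResult(
        amount=amount,
        concentration=conc,
        below_lod=below_lod,
        below_loq=below_loq,
        extrapolated=extrapolated,
    )


def relative_error(actual: float, measured: float) -> float:
    """Signed relative error ``(actual - measured) / actual``.

    The magnitude is what is reported as "% RE"; the sign preserves the
    direction of the deviation.
    """
    if actual == 0:
        raise ZeroDivisionError("relative error undefined for actual = 0")
    return (actual - measured) / actual


def replicate_cv(values) -> float:
    """Coefficient of variation: sample standard deviation over the mean."""
    arr = np.asarray(list(values), float)
    if arr.size < 2:
        raise ValueError("CV requires at least 2 replicates")
    mean = arr.mean()
    if mean == 0:
        raise ZeroDivisionError("CV undefined for zero mean")
    return float(arr.std(ddof=1) / mean)


@dataclass(frozen=True)
class MutantMetrics:
    ratio: float  # mutant / wild type
    fraction: float  # mutant / (mutant + wild type)

    @property
    def ratio_display(self) -> float:
        return round(self.ratio, 1)

    @property
    def fraction_percent(self) -> int:
        return round(self.fraction * 100)


def mutant_metrics(mutant_conc: float, wt_conc: float) -> MutantMetrics:
    """Mutant-to-wild-type ratio and mutant fraction of total.

    The fraction is the protein-level analogue of a genomic variant allele
    frequency.  Display convention rounds the ratio to one decimal and the
    fraction to integer percent.
    """
    if wt_conc == 0:
        raise ZeroDivisionError("mutant/WT ratio undefined for zero WT concentration")
    if mutant_conc + wt_conc == 0:
        raise ZeroDivisionError("mutant fraction undefined for zero total")
    return MutantMetrics(
        ratio=mutant_conc / wt_conc,
        fraction=mutant_conc / (mutant_conc + wt_conc),
    )
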