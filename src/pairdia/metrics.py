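"""Spectrum similarity, chromatogram utilities, and profiling statistics.

Contains the measurement-side helpers around the acquisition design: cosine
similarity between peak lists (used to confirm that mutant and wild-type
peptides produce distinguishable spectra), trapezoidal XIC peak areas with
optional linear baseline subtraction, a robust median/MAD signal-to-noise
estimate, and the global-profiling layer (per-sample median centering,
pathway mean z-scores, and the fold-change + rank-sum differential
expression filter with Benjamini-Hochberg correction).

Abundance matrices are plain :class:`pandas.DataFrame` objects with proteins
as rows, samples as columns, log2 intensities as values and ``NaN`` marking
missing observations (handled by pairwise deletion; imputation is pluggable
upstream and deliberately not built in).
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "Spectrum",
    "Chromatogram",
    "cosine_similarity",
    "xic_area",
    "snr",
    "median_center",
    "pathway_zscore",
    "dep_filter",
]


@dataclass(frozen=True)
class Spectrum:
    """A centroided peak list with strictly increasing m/z."""

    mz: tuple[float, ...]
    intensity: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.mz) != len(self.intensity):
            raise ValueError("mz and intensity lengths differ")
        if any(b <= a for a, b in zip(self.mz, self.mz[1:])):
            raise ValueError("m/z values must be strictly increasing")
        if any(i < 0 for i in self.intensity):
            raise ValueError("intensities must be non-negative")

    @classmethod
    def from_peaks(cls, peaks) -> "Spectrum":
        peaks = sorted(peaks)
        return cls(tuple(p[0] for p in peaks), tuple(p[1] for p in peaks))

    def normalized(self) -> "Spectrum":
        base = max(self.intensity, default=0.0)
        if base == 0:
            return self
        return Spectrum(self.mz, tuple(i / base for i in self.intensity))


def cosine_similarity(a: Spectrum, b: Spectrum, mz_tolerance: float = 0.02) -> float:
    """Normalized dot product of two peak lists after greedy peak matching.

    Candidate matches within ``mz_tolerance`` are accepted closest-first and
    each peak is used at most once; unmatched peaks contribute nothing to
    the cross term but keep their full weight in the norms, so extra peaks
    in either spectrum lower the score.  Bounded in [0, 1]; 1 for identical
    (or proportional) spectra, 0 for disjoint m/z sets.
    """
    if not a.mz or not b.mz:
        raise ValueError("cannot compare empty spectra")
    ia = np.asarray(a.intensity, float)
    ib = np.asarray(b.intensity, float)
    if ia.max() == 0 or ib.max() == 0:
        raise ValueError("cannot compare all-zero spectra")
    mza = np.asarray(a.mz)
    mzb = np.asarray(b.mz)
    cands = [
        (abs(mza[i] - mzb[j]), i, j)
        for i in range(len(mza))
        for j in range(len(mzb))
        if abs(mza[i] - mzb[j]) <= mz_tolerance
    ]
    cands.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    dot = 0.0
    for _, i, j in cands:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        dot += ia[i] * ib[j]
    denom = float(np.linalg.norm(ia) * np.linalg.norm(ib))
    return min(1.0, dot / denom)


@dataclass(frozen=True)
class Chromatogram:
    """Intensity trace over retention time (minutes)."""

    times: tuple[float, ...]
    intensities: tuple[float, ...]
    peak_bounds: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if len(self.times) != len(self.intensities):
            raise ValueError("times and intensities lengths differ")
        if any(b <= a for a, b in zip(self.times, self.times[1:])):
            raise ValueError("times must be strictly increasing")
        if any(i < 0 for i in self.intensities):
            raise ValueError("intensities must be non-negative")
        if self.peak_bounds is not None:
            t0, t1 = self.peak_bounds
            if not (self.times[0] <= t0 < t1 <= self.times[-1]):
                raise ValueError(
                    f"peak bounds {self.peak_bounds} outside time range "
                    f"[{self.times[0]}, {self.times[-1]}]"
                )


def xic_area(chrom: Chromatogram, baseline: bool = True) -> float:
    """Trapezoidal peak area over ``peak_bounds`` (whole trace if unset).

    With ``baseline=True`` a straight line drawn between the boundary
    intensities is subtracted, so a flat trace integrates to zero.
    """
    t = np.asarray(chrom.times, float)
    y = np.asarray(chrom.intensities, float)
    if chrom.peak_bounds is not None:
        t0, t1 = chrom.peak_bounds
        inner = (t > t0) & (t < t1)
        tt = np.concatenate([[t0], t[inner], [t1]])
        yy = np.concatenate([[np.interp(t0, t, y)], y[inner], [np.interp(t1, t, y)]])
    else:
        tt, yy = t, y
    if len(tt) < 2:
        raise ValueError("need at least 2 points inside the integration bounds")
    area = float(np.trapezoid(yy, tt))
    if baseline:
        base = 0.5 * (yy[0] + yy[-1]) * (tt[-1] - tt[0])
        area -= base
    return area


def snr(
    chrom: Chromatogram,
    min_background_points: int = 5,
    noise_floor: float = 1e-6,
) -> float:
    """Robust signal-to-noise: (apex - median background) / (1.4826 * MAD).

    Background is taken from the points flanking ``peak_bounds`` on both
    sides (at least ``min_background_points`` each); the MAD-derived noise
    estimate is floored at ``noise_floor`` so a perfectly flat background
    yields a finite ratio.
    """
    if chrom.peak_bounds is None:
        raise ValueError("SNR requires peak_bounds")
    t = np.asarray(chrom.times, float)
    y = np.asarray(chrom.intensities, float)
    t0, t1 = chrom.peak_bounds
    inside = (t >= t0) & (t <= t1)
    left = y[t < t0]
    right = y[t > t1]
    if len(left) < min_background_points or len(right) < min_background_points:
        raise ValueError(
            f"need >= {min_background_points} background points on each side"
        )
    if not inside.any():
        raise ValueError("no points inside peak bounds")
    background = np.concatenate([left, right])
    med = float(np.median(background))
    noise = max(1.4826 * float(stats.median_abs_deviation(background)), noise_floor)
    return (float(y[inside].max()) - med) / noise


# ---------------------------------------------------------------------------
# Global-profiling statistics
# ---------------------------------------------------------------------------


def median_center(matrix: pd.DataFrame) -> pd.DataFrame:
    """Subtract each sample's (column's) median, ignoring missing values."""
    return matrix - matrix.median(axis=0, skipna=True)


def pathway_zscore(
    matrix: pd.DataFrame, pathways: dict[str, set[str]]
) -> pd.DataFrame:
    """Per-sample mean z-score of each pathway's member proteins.

    Each protein is z-scored across samples (sample standard deviation,
    pairwise deletion of missing values); a zero-variance protein
    contributes 0 everywhere, with a warning.  Rows are pathways, columns
    samples.  Apply :func:`median_center` beforehand when comparing samples
    with different loading.
    """
    mu = matrix.mean(axis=1, skipna=True)
    sd = matrix.std(axis=1, ddof=1, skipna=True)
    flat = sd.fillna(0) == 0
    if flat.any():
        _warnings.warn(
            f"{int(flat.sum())} zero-variance protein(s) contribute z = 0",
            stacklevel=2,
        )
    z = matrix.sub(mu, axis=0).div(sd.where(~flat, np.inf), axis=0)
    z = z.where(~z.isna(), np.nan)
    scores = {}
    for name, members in pathways.items():
        present = [p for p in members if p in z.index]
        if not present:
            raise ValueError(f"pathway {name!r} has no proteins in the matrix")
        scores[name] = z.loc[present].mean(axis=0, skipna=True)
    return pd.DataFrame(scores).T


def dep_filter(
    matrix: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    fc_threshold: float = 2.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Differentially expressed proteins between two sample groups.

    Per protein: two-sided Wilcoxon rank-sum (Mann-Whitney) test on the
    log2 intensities plus the mean log2 fold change (group A minus group B);
    Benjamini-Hochberg adjustment across all tested proteins.  A protein is
    ``significant`` iff |log2 FC| >= log2(fc_threshold) AND adjusted
    p <= alpha.  Requires >= 3 samples per group for the rank test.
    """
    if len(group_a) < 3 or len(group_b) < 3:
        raise ValueError("rank-sum test requires >= 3 samples per group")
    missing = [s for s in (*group_a, *group_b) if s not in matrix.columns]
    if missing:
        raise ValueError(f"samples not in matrix: {missing}")
    a = matrix[group_a]
    b = matrix[group_b]
    log2fc = a.mean(axis=1, skipna=True) - b.mean(axis=1, skipna=True)
    pvals = []
    for prot in matrix.index:
        xa = a.loc[prot].dropna().to_numpy()
        xb = b.loc[prot].dropna().to_numpy()
        if len(xa) < 3 or len(xb) < 3 or (np.ptp(np.concatenate([xa, xb])) == 0):
            pvals.append(1.0)
            continue
        pvals.append(float(stats.mannwhitneyu(xa, xb, alternative="two-sided").pvalue))
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    lfc_gate = np.log2(fc_threshold)
    out = pd.DataFrame(
        {
            "log2_fc": log2fc,
            "p_value": pvals,
            "adj_p_value": qvals,
        },
        index=matrix.index,
    )
    out["significant"] = (out["log2_fc"].abs() >= lfc_gate) & (
        out["adj_p_value"] <= alpha
    )
    return out
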