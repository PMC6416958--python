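"""DAPI-based DNA content analysis and genome duplication rates.

Integrated nuclear DAPI intensity is proportional to DNA content.  Within
each replicate the G1 and G2 peaks of the intensity histogram are located by
kernel-density fitting and intensities are mapped linearly so that G1 -> 1.0
and G2 -> 2.0 ("G1 equivalents"); this absorbs any staining/exposure gain and
lets replicates be pooled.  The cumulative genome fraction replicated at the
end of each S-phase substage is then read off as a high quantile of the
normalized content of cells staged into that substage, giving the percent of
the genome replicated per substage and, combined with measured substage
durations, the genome duplication rate in % per hour.

The cell line is tetraploid; "G1 equivalents" are relative to its own G1
peak and no absolute genome size is used anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.signal import argrelextrema

__all__ = [
    "G1G2Fit",
    "PeakFitError",
    "fit_g1_g2",
    "normalize_content",
    "normalize_records",
    "SubstageGenomeFractions",
    "genome_fractions",
    "duplication_rate",
    "binned_pattern_frequencies",
]

_SUBSTAGES = ("early", "mid", "late")


class PeakFitError(ValueError):
    """G1/G2 peak fitting failed; carries diagnostic KDE data."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclass
class G1G2Fit:
    """Result of the G1/G2 density fit with diagnostics."""

    g1: float
    g2: float
    grid: np.ndarray = field(repr=False, default=None)
    density: np.ndarray = field(repr=False, default=None)
    modes: np.ndarray = field(repr=False, default=None)

    @property
    def ratio(self) -> float:
        return self.g2 / self.g1


def fit_g1_g2(intensities, ratio_band: tuple[float, float] = (1.7, 2.3),
              grid_points: int = 512) -> G1G2Fit:
    """Locate the G1 and G2 peaks of an integrated-DAPI distribution.

    A Gaussian KDE (Silverman bandwidth) is fit on log-intensities and
    evaluated on a 512-point grid; local maxima are the candidate modes.
    Among all mode pairs whose location ratio falls in `ratio_band` (around
    the expected G2/G1 = 2), the pair with the greatest summed density is
    returned as (G1, G2).  Fewer than two qualifying modes, or none in the
    band, raise :class:`PeakFitError` carrying the KDE for diagnostics.

    At least ~100 cells spanning both peaks are recommended.
    """
    x = np.asarray(intensities, dtype=float).ravel()
    x = x[np.isfinite(x) & (x > 0)]
    if x.size < 10:
        raise PeakFitError(f"too few positive intensities ({x.size}) for a density fit")
    logx = np.log(x)
    kde = stats.gaussian_kde(logx, bw_method="silverman")
    bw = np.sqrt(kde.covariance[0, 0])
    grid = np.linspace(logx.min() - 3 * bw, logx.max() + 3 * bw, grid_points)
    dens = kde(grid)
    peaks = argrelextrema(dens, np.greater)[0]
    diag = {"grid": np.exp(grid), "density": dens, "modes": np.exp(grid[peaks])}
    if peaks.size < 2:
        raise PeakFitError("fewer than two density modes; cannot identify G1 and G2",
                           diag)
    best, best_score = None, -np.inf
    for i in range(peaks.size):
        for j in range(i + 1, peaks.size):
            r = np.exp(grid[peaks[j]] - grid[peaks[i]])
            if ratio_band[0] <= r <= ratio_band[1]:
                score = dens[peaks[i]] + dens[peaks[j]]
                if score > best_score:
                    best, best_score = (peaks[i], peaks[j]), score
    if best is None:
        raise PeakFitError(
            f"no mode pair with location ratio in {ratio_band}; "
            f"modes at {np.exp(grid[peaks])}", diag)
    g1, g2 = float(np.exp(grid[best[0]])), float(np.exp(grid[best[1]]))
    return G1G2Fit(g1=g1, g2=g2, grid=np.exp(grid), density=dens,
                   modes=np.exp(grid[peaks]))


def normalize_content(intensity, g1: float, g2: float):
    """Map integrated DAPI linearly to G1 equivalents: g1 -> 1.0, g2 -> 2.0."""
    if not g2 > g1 > 0:
        raise ValueError(f"need g2 > g1 > 0, got g1={g1}, g2={g2}")
    intensity = np.asarray(intensity, dtype=float)
    out = 1.0 + (intensity - g1) / (g2 - g1)
    return float(out) if out.ndim == 0 else out


def normalize_records(table: pd.DataFrame, intensity_col: str = "dapi_integrated",
                      replicate_col: str = "replicate",
                      sanity_band: tuple[float, float] = (0.8, 2.3)) -> pd.DataFrame:
    """Fit G1/G2 per replicate, normalize, and pool.

    Each replicate is normalized independently against its own G1/G2 peaks
    (absorbing replicate-specific gain), then pooled.  Adds columns
    ``content`` (G1 equivalents) and ``content_outlier`` (outside the sanity
    band, flagged rather than dropped).
    """
    out = table.copy()
    out["content"] = np.nan
    for rep, grp in table.groupby(replicate_col):
        fit = fit_g1_g2(grp[intensity_col])
        out.loc[grp.index, "content"] = normalize_content(
            grp[intensity_col].to_numpy(), fit.g1, fit.g2)
    out["content_outlier"] = (out["content"] < sanity_band[0]) | (out["content"] > sanity_band[1])
    return out


@dataclass
class SubstageGenomeFractions:
    """Percent of the genome replicated in each substage, with boundaries."""

    early: float
    mid: float
    late: float
    boundaries: tuple[float, float]  # content at end of early and of mid S
    q: float
    n: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {"early": self.early, "mid": self.mid, "late": self.late}

    @property
    def total(self) -> float:
        return self.early + self.mid + self.late


def genome_fractions(records: pd.DataFrame, q: float = 0.95,
                     pattern_col: str = "pattern",
                     content_col: str = "content") -> SubstageGenomeFractions:
    """Percent of genome replicated per substage from staged, normalized cells.

    The content reached by the end of a substage is estimated as the `q`
    quantile (default 0.95) of the normalized content of cells staged into
    it — a robust surrogate for the maximal content, since the literal
    maximum is an extreme-value statistic with unbounded upward bias under
    intensity noise (q=1.0 recovers the literal maximum).  Then::

        fraction(early) = (boundary(early) - 1) * 100
        fraction(mid)   = (boundary(mid) - boundary(early)) * 100
        fraction(late)  = (2.0 - boundary(mid)) * 100

    so the three fractions sum to 100 exactly.  Empty substages and
    non-monotone boundaries raise ``ValueError`` with diagnostics.
    """
    if not 0 < q <= 1:
        raise ValueError("quantile q must lie in (0, 1]")
    bounds, n = {}, {}
    for sub in _SUBSTAGES:
        vals = records.loc[records[pattern_col] == sub, content_col].dropna()
        if vals.empty:
            raise ValueError(f"no cells staged as {sub!r}; cannot place its boundary")
        bounds[sub] = float(np.quantile(vals, q))
        n[sub] = int(vals.size)
    b_e, b_m = bounds["early"], bounds["mid"]
    if not (1.0 <= b_e <= b_m <= 2.0 + 1e-9):
        raise ValueError(
            f"non-monotone substage boundaries: early={b_e:.3f}, mid={b_m:.3f} "
            "(check staging or noise level)")
    return SubstageGenomeFractions(
        early=(b_e - 1.0) * 100.0, mid=(b_m - b_e) * 100.0, late=(2.0 - b_m) * 100.0,
        boundaries=(b_e, b_m), q=q, n=n)


def duplication_rate(fractions: SubstageGenomeFractions,
                     durations_h: dict[str, float]) -> dict[str, float]:
    """Genome duplication rate per substage: percent of genome per hour.

    `durations_h` maps substage name to its measured duration in hours (the
    live-cell frame-counting estimates).
    """
    rates = {}
    for sub, frac in fractions.as_dict().items():
        d = durations_h.get(sub)
        if d is None:
            raise ValueError(f"no duration for substage {sub!r}")
        if d <= 0:
            raise ValueError(f"nonpositive duration for substage {sub!r}")
        rates[sub] = frac / d
    return rates


def binned_pattern_frequencies(records: pd.DataFrame, n_bins: int = 18,
                               pattern_col: str = "pattern",
                               content_col: str = "content") -> pd.DataFrame:
    """Relative pattern frequencies across DNA-content bins from G1 to G2.

    The content axis [1.0, 2.0] is partitioned into `n_bins` equal-width
    bins; for each bin the relative frequency of every pattern label among
    cells falling in that bin is reported (rows sum to 1 for nonempty bins;
    empty bins are emitted as zero rows with ``n = 0``).  This is the
    staging-independent control: it shows where each visually assigned
    replication pattern sits on the DNA-content axis.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    edges = np.linspace(1.0, 2.0, n_bins + 1)
    sub = records.dropna(subset=[content_col])
    idx = np.clip(np.digitize(sub[content_col], edges) - 1, 0, n_bins - 1)
    # cells outside [1, 2] (G1/G2 noise) are clipped into the terminal bins
    patterns = sorted(sub[pattern_col].unique())
    counts = pd.crosstab(idx, sub[pattern_col]).reindex(
        index=range(n_bins), columns=patterns, fill_value=0)
    n_per_bin = counts.sum(axis=1)
    freq = counts.div(n_per_bin.replace(0, np.nan), axis=0).fillna(0.0)
    freq.insert(0, "bin_low", edges[:-1])
    freq.insert(1, "bin_high", edges[1:])
    freq["n"] = n_per_bin.to_numpy()
    freq.index.name = "bin"
    return freq
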