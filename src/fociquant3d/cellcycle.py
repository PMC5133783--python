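"""Cell-cycle analysis: DNA-content phase gating, colcemid G0/1-depletion
kinetics and division-interval statistics.

DNA-content samples are per-event fluorescence lists (propidium-iodide style,
arbitrary units).  Phase fractions are obtained with peak-anchored gates: the
2N peak is located on a kernel-smoothed density, the G0/1 and G2/M gates are
placed at ±2.5 CV-widths around 2N and 4N, and S-phase events are counted in
between.  Because an S-phase distribution that is uniform in DNA content
leaks into both gates, the S density is estimated from the unambiguous
inter-gate region and its expected spill-in is subtracted from the G0/1 and
G2/M counts (see docs/methods.md).

Colcemid traps cycling cells in M, so the G0/1 fraction decays over exposure
time; the residual plateau of an exponential decay-to-plateau fit
``f(t) = r + (f0 - r) exp(-t/tau)`` estimates the non-cycling subpopulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.optimize import curve_fit
from scipy.signal import find_peaks

from .stats import StatTestResult, two_sample_t


@dataclass
class DNAContentSample:
    """Per-event DNA fluorescence values with sample metadata."""

    values: np.ndarray
    genotype: str = ""
    colcemid_h: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size and np.any(self.values <= 0):
            raise ValueError("DNA content values must be strictly positive")

    @property
    def n_events(self) -> int:
        return self.values.size


@dataclass
class PhaseFractions:
    f_g01: float
    f_s: float
    f_g2m: float
    mu: float
    cv: float
    gates: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for f in (self.f_g01, self.f_s, self.f_g2m):
            if f < 0:
                raise ValueError("phase fractions must be non-negative")
        if self.f_g01 + self.f_s + self.f_g2m > 1.0 + 1e-9:
            raise ValueError("phase fractions must sum to <= 1")


@dataclass
class DivisionTracks:
    """Division-time tracks for one cell line.

    ``table`` has one row per completed cell cycle with columns
    ``lineage_id``, ``generation`` (1-based), ``division_time_h`` (cumulative
    clock time of the division ending the interval) and ``interval_h``.
    """

    line: str
    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"lineage_id", "generation", "division_time_h", "interval_h"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"tracks table missing columns {sorted(missing)}")
        if (self.table["interval_h"] <= 0).any():
            raise ValueError("division intervals must be positive")
        for _, grp in self.table.groupby("lineage_id"):
            t = grp.sort_values("generation")["division_time_h"].to_numpy()
            if np.any(np.diff(t) <= 0):
                raise ValueError("division times must strictly increase per lineage")

    @property
    def intervals(self) -> np.ndarray:
        return self.table["interval_h"].to_numpy()


def _smoothed_density(values: np.ndarray, n_bins: int = 256):
    hi = float(values.max()) * 1.02
    counts, edges = np.histogram(values, bins=n_bins, range=(0.0, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    density = gaussian_filter1d(counts.astype(float), sigma=2.0)
    return centers, density, edges[1] - edges[0]


def _locate_2n_peak(centers, density) -> float:
    peaks, props = find_peaks(density, prominence=0.05 * density.max())
    if peaks.size == 0:
        raise ValueError("no detectable DNA-content peak")
    pos = centers[peaks]
    prom = props["prominences"]
    # Prefer a (2N, 4N) peak pair with position ratio ~2.
    for i in np.argsort(pos):
        for j in np.argsort(pos):
            if pos[j] > pos[i] and 1.8 <= pos[j] / pos[i] <= 2.2:
                return float(pos[i])
    return float(pos[np.argmax(prom)])


def _estimate_cv(centers, density, bin_width, mu) -> float:
    """CV of the 2N peak from its FWHM, deconvolving the histogram smoothing."""
    idx = int(np.argmin(np.abs(centers - mu)))
    half = density[idx] / 2.0
    lo = idx
    while lo > 0 and density[lo] > half:
        lo -= 1
    hi = idx
    while hi < density.size - 1 and density[hi] > half:
        hi += 1
    fwhm = (hi - lo) * bin_width
    sigma_obs = fwhm / 2.3548
    smooth_sigma = 2.0 * bin_width
    sigma = math.sqrt(max(sigma_obs**2 - smooth_sigma**2, (0.01 * mu) ** 2))
    return float(np.clip(sigma / mu, 0.01, 0.12))


def phase_fractions(
    sample: DNAContentSample,
    mu: float | None = None,
    cv: float | None = None,
    gate_width_cvs: float = 2.5,
    s_correction: bool = True,
) -> PhaseFractions:
    """Gate a DNA-content sample into G0/1, S and G2/M fractions.

    Parameters
    ----------
    mu, cv
        Position and coefficient of variation of the 2N peak.  When omitted
        they are estimated from the sample itself; pass values from a
        reference sample (e.g. an untreated time point) when the 2N peak may
        be depleted.
    gate_width_cvs
        Gate half-width in units of cv·(gate center), default 2.5.
    s_correction
        Subtract the expected S-phase spill-in from the G0/1 and G2/M gates
        (S density estimated from the inter-gate region).
    """
    v = sample.values
    if v.size < 500:
        raise ValueError("need >= 500 events for phase gating")
    centers, density, bw = _smoothed_density(v)
    if mu is None:
        mu = _locate_2n_peak(centers, density)
    if cv is None:
        cv = _estimate_cv(centers, density, bw, mu)
    w = gate_width_cvs * cv
    g1_lo, g1_hi = mu * (1 - w), mu * (1 + w)
    g2_lo, g2_hi = 2 * mu * (1 - w), 2 * mu * (1 + w)
    if g1_hi >= g2_lo:
        raise ValueError(
            f"G0/1 and G2/M gates intersect (cv={cv:.3f}); narrow gate_width_cvs"
        )
    n = v.size
    n_g1 = int(np.count_nonzero((v >= g1_lo) & (v <= g1_hi)))
    n_g2 = int(np.count_nonzero((v >= g2_lo) & (v <= g2_hi)))
    n_mid = int(np.count_nonzero((v > g1_hi) & (v < g2_lo)))
    if s_correction:
        rho = n_mid / (g2_lo - g1_hi)  # events per DNA-content unit
        f_s = rho * mu / n  # S support spans (mu, 2 mu)
        spill_g1 = rho * (g1_hi - mu)
        spill_g2 = rho * (2 * mu - g2_lo)
        f_g1 = max(n_g1 - spill_g1, 0.0) / n
        f_g2 = max(n_g2 - spill_g2, 0.0) / n
    else:
        f_s = n_mid / n
        f_g1 = n_g1 / n
        f_g2 = n_g2 / n
    total = f_g1 + f_s + f_g2
    if total > 1.0:  # guard against correction overshoot
        f_g1, f_s, f_g2 = (f / total for f in (f_g1, f_s, f_g2))
    return PhaseFractions(
        f_g01=f_g1, f_s=f_s, f_g2m=f_g2, mu=float(mu), cv=float(cv),
        gates={"g01": (g1_lo, g1_hi), "g2m": (g2_lo, g2_hi)},
    )


@dataclass
class ColcemidFit:
    table: pd.DataFrame  # columns time_h, f_g01
    residual_fraction: float
    tau_h: float
    f0: float


def colcemid_depletion(
    series: Sequence[DNAContentSample],
    times_h: Sequence[float] | None = None,
    **gate_kwargs,
) -> ColcemidFit:
    """G0/1 fraction over colcemid exposure and the fitted residual plateau.

    The 2N peak position and CV are anchored on the t=0 sample so that late
    time points with a depleted 2N peak are still gated consistently.  The
    plateau of ``f(t) = r + (f0 - r) exp(-t/tau)`` estimates the non-cycling
    fraction.
    """
    samples = list(series)
    if times_h is None:
        times_h = [s.colcemid_h for s in samples]
    t = np.asarray(times_h, dtype=float)
    if t.size != len(samples):
        raise ValueError("times_h length must match series")
    if t.size < 3 or t.min() != 0.0:
        raise ValueError("need >= 3 time points including t=0")
    order = np.argsort(t)
    t = t[order]
    samples = [samples[i] for i in order]
    pf0 = phase_fractions(samples[0], **gate_kwargs)
    f = np.array(
        [pf0.f_g01]
        + [
            phase_fractions(s, mu=pf0.mu, cv=pf0.cv, **gate_kwargs).f_g01
            for s in samples[1:]
        ]
    )
    table = pd.DataFrame({"time_h": t, "f_g01": f})
    f0 = float(f[0])
    if float(np.ptp(f)) < 0.02:  # flat series: tau unidentifiable
        return ColcemidFit(table, residual_fraction=float(f.mean()),
                           tau_h=math.inf, f0=f0)

    def model(tt, r, a, tau):
        return r + a * np.exp(-tt / tau)

    p0 = (float(f.min()), max(f0 - float(f.min()), 1e-3), max(t[1], 1.0))
    popt, _ = curve_fit(
        model, t, f, p0=p0,
        bounds=([0.0, 0.0, 1e-2], [1.0, 1.0, 1e4]), maxfev=10000,
    )
    r, a, tau = popt
    return ColcemidFit(table, residual_fraction=float(np.clip(r, 0.0, 1.0)),
                       tau_h=float(tau), f0=f0)


@dataclass
class DivisionStats:
    mean_a: float
    sem_a: float
    mean_b: float
    sem_b: float
    fold_change: float
    test: StatTestResult


def _intervals(tracks) -> np.ndarray:
    if isinstance(tracks, DivisionTracks):
        return tracks.intervals
    return np.asarray(tracks, dtype=float)


def division_stats(tracks_a, tracks_b) -> DivisionStats:
    """Mean ± SEM division interval per line, fold change B/A, and the
    two-tailed unpaired Student t-test on the pooled intervals."""
    a = _intervals(tracks_a)
    b = _intervals(tracks_b)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 intervals per line")
    test = two_sample_t(b, a, tails=2, paired=False)
    return DivisionStats(
        mean_a=float(a.mean()), sem_a=float(a.std(ddof=1) / math.sqrt(a.size)),
        mean_b=float(b.mean()), sem_b=float(b.std(ddof=1) / math.sqrt(b.size)),
        fold_change=float(b.mean() / a.mean()),
        test=test,
    )


def align_generations(
    tracks: DivisionTracks | pd.DataFrame,
    anchor_generation: int = 3,
    lineage_anchors: Mapping | None = None,
) -> pd.DataFrame:
    """Re-index generations so a shared anchor event coincides across lineages.

    ``lineage_anchors`` maps lineage_id to the generation during which the
    anchor event (e.g. a medium refresh) occurred in that lineage; each
    lineage is shifted so that its anchor generation is renumbered
    ``anchor_generation``.  Lineages without an entry are left unshifted, and
    missing generations remain as gaps (no imputation).
    """
    df = tracks.table if isinstance(tracks, DivisionTracks) else tracks
    out = df.copy()
    if lineage_anchors is None:
        out["aligned_generation"] = out["generation"]
        return out
    shift = out["lineage_id"].map(
        lambda lid: anchor_generation - lineage_anchors.get(lid, anchor_generation)
    )
    out["aligned_generation"] = out["generation"] + shift
    return out


def per_generation_means(aligned: pd.DataFrame) -> pd.DataFrame:
    """Mean ± SEM interval per aligned generation."""
    g = aligned.groupby("aligned_generation")["interval_h"]
    res = g.agg(["mean", "sem", "count"]).reset_index()
    return res.rename(columns={"mean": "mean_h", "sem": "sem_h", "count": "n"})
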