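"""Gaussian null model of random reporter-ion ratio variation.

Pipeline, per contrast and per experiment: natural-log ratios of two
channel areas are histogrammed on [−1, +1] in 200 bins, the counts are
smoothed with a Savitzky–Golay filter, a Gaussian A·exp(−(x−μ)²/(2σ²)) is
least-squares fitted to the smoothed counts, and the fitted σ quantifies
technical ratio variation. Peptides whose ln-ratio deviates from the
center by at least k·σ (k = 2.5 by default, i.e. 98.8% two-sided
confidence) are called significantly different from random variation;
two-sided Gaussian tail p-values are attached to every peptide.

Observations falling outside the histogram range do not enter the fit but
are still scored against the fitted null, so extreme fold-changes remain
callable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal, stats
from scipy.optimize import curve_fit

from .errors import ConfigurationError, FitError, ValidationError
from .quantio import ChannelContrast

__all__ = [
    "HistogramSpec",
    "SmootherSpec",
    "CallingConfig",
    "GaussianNull",
    "compute_ln_ratios",
    "build_histogram",
    "savgol_smooth",
    "fit_gaussian",
    "fit_null",
    "peptide_pvalue",
    "call_significant",
]


@dataclass(frozen=True)
class HistogramSpec:
    """Histogram of ln-ratios: 200 equal bins on [−1, +1] by default."""

    lower: float = -1.0
    upper: float = 1.0
    n_bins: int = 200

    def __post_init__(self) -> None:
        if self.upper <= self.lower:
            raise ConfigurationError(
                f"histogram upper ({self.upper}) must exceed lower ({self.lower})"
            )
        if self.n_bins < 10:
            raise ConfigurationError(f"n_bins must be >= 10, got {self.n_bins}")

    @property
    def bin_width(self) -> float:
        return (self.upper - self.lower) / self.n_bins


@dataclass(frozen=True)
class SmootherSpec:
    """Savitzky–Golay smoothing parameters (window 11, cubic by default)."""

    window: int = 11
    polyorder: int = 3

    def __post_init__(self) -> None:
        if self.window % 2 == 0 or self.window < 3:
            raise ConfigurationError(f"window must be an odd count >= 3, got {self.window}")
        if not 0 <= self.polyorder < self.window:
            raise ConfigurationError(
                f"polyorder must satisfy 0 <= polyorder < window, got {self.polyorder}"
            )


@dataclass(frozen=True)
class CallingConfig:
    """Significance rule: |ln ratio − center| ≥ k·σ, boundary inclusive."""

    k: float = 2.5
    center_policy: str = "fitted_mu"  # or "zero"

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ConfigurationError(f"k must be positive, got {self.k}")
        if self.center_policy not in ("fitted_mu", "zero"):
            raise ConfigurationError(
                f"center_policy must be 'fitted_mu' or 'zero', got {self.center_policy!r}"
            )


@dataclass(frozen=True)
class GaussianNull:
    """Fitted null of ln-ratio technical variation for one contrast."""

    mu: float
    sigma: float
    amplitude: float
    rss: float
    n_in_range: int
    n_out_of_range: int

    def center(self, cfg: CallingConfig = CallingConfig()) -> float:
        return self.mu if cfg.center_policy == "fitted_mu" else 0.0


def compute_ln_ratios(
    records: pd.DataFrame, contrast: ChannelContrast
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Natural-log reporter-ion ratios for one contrast.

    Returns (observations, exclusions). Observations carry
    ``experiment_id, protein_accession, peptide_sequence, contrast,
    ln_ratio``; rows with a zero (or negative) area in either channel are
    excluded with a reason rather than producing non-finite ratios.
    Contrasts not involving the reference channel are computed directly
    from the two areas, which equals the ratio of reference-based ratios.
    """
    num = records[f"area_{contrast.numerator_channel}"].to_numpy(float)
    den = records[f"area_{contrast.denominator_channel}"].to_numpy(float)
    bad_num = num <= 0
    bad_den = den <= 0
    ok = ~(bad_num | bad_den)

    obs = pd.DataFrame(
        {
            "experiment_id": records.loc[ok, "experiment_id"].to_numpy(),
            "protein_accession": records.loc[ok, "protein_accession"].to_numpy(),
            "peptide_sequence": records.loc[ok, "peptide_sequence"].to_numpy(),
            "contrast": contrast.name,
            "ln_ratio": np.log(num[ok] / den[ok]),
        }
    )

    reasons = []
    for i in np.flatnonzero(~ok):
        parts = []
        if bad_num[i]:
            parts.append("nonpositive numerator")
        if bad_den[i]:
            parts.append("nonpositive denominator")
        reasons.append(
            {
                "row": int(i),
                "experiment_id": records.iloc[i]["experiment_id"],
                "protein_accession": records.iloc[i]["protein_accession"],
                "peptide_sequence": records.iloc[i]["peptide_sequence"],
                "contrast": contrast.name,
                "reason": " and ".join(parts),
            }
        )
    exclusions = pd.DataFrame(
        reasons,
        columns=["row", "experiment_id", "protein_accession", "peptide_sequence", "contrast", "reason"],
    )
    return obs, exclusions


def build_histogram(
    values, spec: HistogramSpec = HistogramSpec()
) -> tuple[np.ndarray, np.ndarray, int]:
    """Histogram ln-ratios on the spec's range.

    Bins are half-open [edge_i, edge_{i+1}) with the final bin closed (the
    numpy convention). Returns (bin_centers, counts, n_out_of_range);
    sum(counts) + n_out_of_range equals the number of values.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValidationError("cannot build a null-model histogram from zero ln-ratios")
    edges = np.linspace(spec.lower, spec.upper, spec.n_bins + 1)
    counts, _ = np.histogram(x, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    n_out = int(x.size - counts.sum())
    return centers, counts.astype(float), n_out


def savgol_smooth(counts, spec: SmootherSpec = SmootherSpec()) -> np.ndarray:
    """Savitzky–Golay smoothing with truncated-window edge handling.

    Interior points are the standard least-squares polynomial convolution
    (degree ``polyorder``, window ``window``). At each edge point the
    polynomial is re-fitted on the window truncated to the signal (degree
    capped at the number of points minus one) and evaluated in place, so a
    polynomial signal of degree <= polyorder is reproduced exactly
    everywhere as long as polyorder <= window//2.
    """
    y = np.asarray(counts, dtype=float)
    if y.ndim != 1:
        raise ConfigurationError("savgol_smooth expects a 1-D signal")
    n = y.size
    if n < spec.window:
        raise ValidationError(f"signal length {n} shorter than window {spec.window}")
    out = signal.savgol_filter(y, spec.window, spec.polyorder, mode="interp")
    half = spec.window // 2
    for i in list(range(half)) + list(range(n - half, n)):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        xs = np.arange(lo, hi, dtype=float) - i
        deg = min(spec.polyorder, hi - lo - 1)
        beta = np.polynomial.polynomial.polyfit(xs, y[lo:hi], deg)
        out[i] = beta[0]  # polynomial evaluated at the edge position (x = 0)
    return out


def _gauss(x, amplitude, mu, sigma):
    return amplitude * np.exp(-((x - mu) ** 2) / (2.0 * sigma**2))


def fit_gaussian(
    bin_centers,
    smoothed_counts,
    *,
    n_in_range: int | None = None,
    n_out_of_range: int = 0,
) -> GaussianNull:
    """Least-squares Gaussian fit to smoothed histogram counts.

    Initialised from the moment estimates of the (non-negative part of
    the) smoothed counts; if the free-center fit fails to converge, a
    zero-centered two-parameter fit is retried. Degenerate inputs (fewer
    than 5 positive bins, or a flat signal) raise :class:`FitError`.
    """
    x = np.asarray(bin_centers, dtype=float)
    y = np.asarray(smoothed_counts, dtype=float)
    if x.shape != y.shape:
        raise ConfigurationError("bin_centers and smoothed_counts must have equal length")
    if np.count_nonzero(y > 0) < 5:
        raise FitError(
            f"cannot fit a Gaussian: only {np.count_nonzero(y > 0)} positive bins (need >= 5)"
        )
    if np.ptp(y) == 0:
        raise FitError("cannot fit a Gaussian: all smoothed counts are equal")

    w = np.clip(y, 0.0, None)
    mu0 = float(np.average(x, weights=w))
    var0 = float(np.average((x - mu0) ** 2, weights=w))
    bin_width = float(np.median(np.diff(x))) if x.size > 1 else 1.0
    sigma0 = max(np.sqrt(var0), bin_width)
    a0 = float(y.max())

    try:
        popt, _ = curve_fit(_gauss, x, y, p0=[a0, mu0, sigma0], maxfev=20000)
        amplitude, mu, sigma = popt
    except RuntimeError:
        try:  # fall back to a zero-centered two-parameter fit
            popt, _ = curve_fit(
                lambda xx, a, s: _gauss(xx, a, 0.0, s), x, y, p0=[a0, sigma0], maxfev=20000
            )
            amplitude, sigma = popt
            mu = 0.0
        except RuntimeError as exc:
            raise FitError(f"Gaussian fit did not converge: {exc}") from exc
    sigma = abs(float(sigma))
    if sigma == 0.0 or not np.isfinite(sigma):
        raise FitError(f"Gaussian fit produced a degenerate sigma ({sigma})")
    rss = float(np.sum((y - _gauss(x, amplitude, mu, sigma)) ** 2))
    if n_in_range is None:
        n_in_range = int(round(float(np.sum(np.clip(y, 0, None)))))
    return GaussianNull(
        mu=float(mu),
        sigma=sigma,
        amplitude=abs(float(amplitude)),
        rss=rss,
        n_in_range=int(n_in_range),
        n_out_of_range=int(n_out_of_range),
    )


def fit_null(
    values,
    hist_spec: HistogramSpec = HistogramSpec(),
    smoother: SmootherSpec = SmootherSpec(),
) -> GaussianNull:
    """Histogram → smooth → Gaussian fit, the full null-model procedure."""
    centers, counts, n_out = build_histogram(values, hist_spec)
    smoothed = savgol_smooth(counts, smoother)
    return fit_gaussian(
        centers, smoothed, n_in_range=int(counts.sum()), n_out_of_range=n_out
    )


def peptide_pvalue(ln_ratio, null: GaussianNull, cfg: CallingConfig = CallingConfig()):
    """Two-sided Gaussian tail probability 2·(1 − Φ(|x − center|/σ)).

    Accepts a scalar or array of ln-ratios; monotone decreasing in the
    deviation from the center; equal to 1 at the center, never 0.
    """
    x = np.asarray(ln_ratio, dtype=float)
    z = np.abs(x - null.center(cfg)) / null.sigma
    p = np.clip(2.0 * stats.norm.sf(z), np.finfo(float).tiny, 1.0)
    return float(p) if np.isscalar(ln_ratio) or x.ndim == 0 else p


def call_significant(ln_ratio, null: GaussianNull, cfg: CallingConfig = CallingConfig()):
    """k·σ calling rule: (significant, direction).

    Significant iff |ln_ratio − center| >= k·σ (boundary inclusive);
    direction is 'up'/'down' by the sign of the deviation, 'none' at
    exactly zero deviation. Applies equally to observations outside the
    histogram range. Vectorised over arrays.
    """
    x = np.asarray(ln_ratio, dtype=float)
    dev = x - null.center(cfg)
    sig = np.abs(dev) >= cfg.k * null.sigma
    direction = np.where(dev > 0, "up", np.where(dev < 0, "down", "none"))
    if np.isscalar(ln_ratio) or x.ndim == 0:
        return bool(sig), str(direction)
    return sig, direction


def plot_null_fit(null: GaussianNull, bin_centers, counts, smoothed, path) -> None:
    """Diagnostic plot: raw histogram, smoothed counts and the fitted curve."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = np.asarray(bin_centers, float)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar(x, counts, width=np.median(np.diff(x)), alpha=0.4, label="ln-ratio histogram")
    ax.plot(x, smoothed, lw=1.5, label="Savitzky–Golay smoothed")
    ax.plot(x, _gauss(x, null.amplitude, null.mu, null.sigma), lw=1.5, label="Gaussian fit")
    ax.axvline(null.mu - 2.5 * null.sigma, ls="--", c="grey")
    ax.axvline(null.mu + 2.5 * null.sigma, ls="--", c="grey", label="±2.5σ")
    ax.set_xlabel("ln(reporter-ion ratio)")
    ax.set_ylabel("peptides per bin")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
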