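"""Anatomical summary statistics for retinotopic vertex tables.

Covers the four measurements made on each participant's delineated visual
cortex: (1) an exponential fit a·e^(−bx) to the binned eccentricity
distribution, whose area ratio between the delineated band and the full
support gives the retinotopy coverage fraction; (2) a histogram Gaussian
fit to the thickness distribution; (3) surface area as the sum of vertex
areas; (4) paired contrasts of thickness across folding class (sulcus vs
gyrus) and eccentricity zone (parafovea vs perifovea, boundary 2.0 deg).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.optimize import curve_fit

__all__ = [
    "ExponentialFit",
    "GaussianFit",
    "ContrastResult",
    "fit_exponential",
    "coverage_fraction",
    "fit_gaussian",
    "surface_area",
    "folding_eccentricity_contrast",
]

PARAFOVEA_BOUNDARY = 2.0  # deg


class FitError(RuntimeError):
    """Degenerate input for a histogram fit."""


@dataclass
class ExponentialFit:
    a: float  # percent of vertices per bin at x = 0
    b: float  # per-degree decay
    r2: float
    coverage_fraction: float
    bin_centers: np.ndarray | None = None
    bin_percent: np.ndarray | None = None  # sums to 100 over the bins

    def __post_init__(self):
        if self.b <= 0:
            raise FitError("fitted decay rate must be > 0")


@dataclass
class GaussianFit:
    mean: float  # mm
    sd: float
    r2: float

    def __post_init__(self):
        if self.sd <= 0:
            raise FitError("fitted SD must be > 0")


@dataclass
class ContrastResult:
    """Paired-t contrast of per-participant cell means (mm)."""

    name: str
    cell_means: dict[str, float]
    T: float
    p: float
    n: int


def _r2(y, yhat):
    ss_res = float(((y - yhat) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0


def fit_exponential(eccentricities, n_bins=30, weights=None,
                    coverage_range=(0.25, 7.2)):
    """Least-squares fit of a·e^(−bx) to the binned eccentricity histogram.

    Values are binned into ``n_bins`` equal-width bins over the observed
    range; counts become percentage of vertices per bin (summing to 100),
    and the curve is fitted on bin centers, unweighted, with log-linear
    initialization and nonlinear refinement.  ``weights`` optionally weight
    each vertex's histogram contribution (e.g. by vertex area).
    """
    x = np.asarray(eccentricities, dtype=float)
    if x.size < 3:
        raise FitError("need at least 3 eccentricity values")
    counts, edges = np.histogram(x, bins=n_bins, weights=weights)
    total = counts.sum()
    nonempty = counts > 0
    if nonempty.sum() < 3 or total <= 0:
        raise FitError("eccentricity histogram has fewer than 3 nonempty bins")
    centers = 0.5 * (edges[:-1] + edges[1:])
    pct = counts / total * 100.0

    xb, yb = centers[nonempty], pct[nonempty]
    slope, intercept = np.polyfit(xb, np.log(yb), 1)
    b0 = max(-slope, 1e-3)
    a0 = float(np.exp(intercept))
    try:
        (a, b), _ = curve_fit(
            lambda t, a, b: a * np.exp(-b * t),
            centers, pct, p0=(a0, b0),
            bounds=((0, 1e-9), (np.inf, np.inf)), maxfev=10000,
        )
    except RuntimeError as exc:  # pragma: no cover - optimizer failure
        raise FitError("exponential fit did not converge") from exc
    yhat = a * np.exp(-b * centers)
    return ExponentialFit(
        float(a), float(b), _r2(pct, yhat),
        coverage_fraction(float(b), *coverage_range),
        bin_centers=centers, bin_percent=pct,
    )


def coverage_fraction(b, e_min=0.25, e_max=7.2):
    """Area under a·e^(−bx) on [e_min, e_max] relative to [0, inf).

    Closed form exp(−b·e_min) − exp(−b·e_max); independent of a.
    """
    if b <= 0:
        raise ValueError("decay rate b must be > 0")
    return float(np.exp(-b * e_min) - np.exp(-b * e_max))


def fit_gaussian(values, n_bins=30):
    """Histogram-based least-squares Gaussian fit (mirrors the thickness
    distribution plot): A·exp(−(x−mu)²/2s²) on 30 bin centers, moments as
    initialization and as fallback when the nonlinear fit fails.
    """
    x = np.asarray(values, dtype=float)
    if np.unique(x).size < 3:
        raise FitError("need at least 3 distinct values")
    if np.std(x) <= 0:
        raise FitError("zero variance")
    counts, edges = np.histogram(x, bins=n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    pct = counts / counts.sum() * 100.0
    m0, s0 = float(x.mean()), float(x.std())
    span = float(x.max() - x.min())
    try:
        (amp, mu, sd), _ = curve_fit(
            lambda t, amp, mu, sd: amp * np.exp(-((t - mu) ** 2) / (2 * sd**2)),
            centers, pct, p0=(pct.max(), m0, s0), maxfev=10000,
            bounds=((0, x.min(), 1e-6 * span), (np.inf, x.max(), 10 * span)),
        )
        sd = abs(float(sd))
        yhat = amp * np.exp(-((centers - mu) ** 2) / (2 * sd**2))
        return GaussianFit(float(mu), sd, _r2(pct, yhat))
    except RuntimeError:
        yhat = pct.max() * np.exp(-((centers - m0) ** 2) / (2 * s0**2))
        return GaussianFit(m0, s0, _r2(pct, yhat))


def surface_area(vertices, participant, area):
    """Sum of vertex areas (mm²) for one participant/area."""
    sel = vertices[
        (vertices["participant_id"] == participant)
        & (vertices["area"] == area)
    ]
    if sel.empty:
        raise LookupError(f"no vertices for {participant}/{area}")
    return float(sel["vertex_area"].sum())


_CONTRASTS = {
    # name: ((class or zone fixed), (varying pair high, low))
    "gyrus_minus_sulcus_parafovea": ("parafovea", ("gyrus", "sulcus")),
    "gyrus_minus_sulcus_perifovea": ("perifovea", ("gyrus", "sulcus")),
    "perifovea_minus_parafovea_sulcus": ("sulcus", ("perifovea", "parafovea")),
    "perifovea_minus_parafovea_gyrus": ("gyrus", ("perifovea", "parafovea")),
}


def folding_eccentricity_contrast(vertices, boundary=PARAFOVEA_BOUNDARY,
                                  area=None):
    """Paired t-tests of thickness across folding class and eccentricity zone.

    Per participant, the mean thickness of each of the four cells
    (sulcus/gyrus × parafovea/perifovea) is computed; each of the four
    contrasts (gyri−sulci within each zone, perifovea−parafovea within each
    class) is a two-tailed paired t-test across participants.  Participants
    with an empty cell are excluded with a warning.  Pass ``area`` to
    restrict to one visual area; returns a dict name -> ContrastResult.
    """
    df = vertices if area is None else vertices[vertices["area"] == area]
    if df.empty:
        raise LookupError("no vertices selected for the contrast")
    zone = np.where(
        df["eccentricity"].to_numpy() < boundary, "parafovea", "perifovea"
    )
    cells = (
        df.assign(zone=zone)
        .groupby(["participant_id", "folding_class", "zone"], observed=True)[
            "thickness"
        ]
        .mean()
        .unstack(["folding_class", "zone"])
    )
    complete = cells.dropna()
    dropped = len(cells) - len(complete)
    if dropped:
        warnings.warn(
            f"{dropped} participant(s) excluded from contrasts (empty cell)"
        )
    if len(complete) < 2:
        raise FitError("need at least 2 participants with all four cells")

    out = {}
    grand = complete.mean()
    cell_means = {
        f"{fold}_{zn}": float(grand[(fold, zn)])
        for fold in ("sulcus", "gyrus")
        for zn in ("parafovea", "perifovea")
    }
    for name, (fixed, (hi, lo)) in _CONTRASTS.items():
        if fixed in ("parafovea", "perifovea"):
            a = complete[(hi, fixed)]
            b = complete[(lo, fixed)]
        else:
            a = complete[(fixed, hi)]
            b = complete[(fixed, lo)]
        t, p = stats.ttest_rel(a, b)
        out[name] = ContrastResult(
            name, cell_means, float(t), float(p), len(complete)
        )
    return out
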