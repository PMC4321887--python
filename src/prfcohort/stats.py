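"""Statistical engine: permutation Spearman correlation with max-statistic
familywise-error (FWE) control, intra/inter-individual variance
decomposition by group-mean centering, data-grid binning, and the two
analysis patterns of the pipeline:

* fixed-eccentricity analysis — the 20-participant × 6-position table at
  4.7 deg relating tuning width, discrimination threshold, thickness and
  surface area;
* eccentricity-resolved analysis — per-participant (or per-thickness-bin)
  linear fits of a value against eccentricity, with slope/intercept
  correlations against anatomy and per-eccentricity-bin correlations.

Permutation p-values are two-sided on |rho| with the add-one estimator
(1 + #{|rho_perm| >= |rho_obs|}) / (1 + n_perm); families are corrected
single-step by the permutation distribution of the familywise max |rho|.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "CorrelationResult",
    "LinearFit",
    "DataGrid",
    "spearman_rho",
    "permutation_pvalue",
    "fwe_correct",
    "center_by_group",
    "fixed_eccentricity_analysis",
    "build_grid",
    "eccentricity_resolved_analysis",
    "FixedEccentricityResult",
    "EccentricityResolvedResult",
]

EXHAUSTIVE_LIMIT = 40320  # 8! — enumerate all permutations up to here
_EPS = 1e-12  # |rho| comparisons are float-tolerant


@dataclass
class CorrelationResult:
    family: str
    pair: str
    rho: float
    p_raw: float
    p_fwe: float
    n: int


@dataclass
class LinearFit:
    slope: float
    intercept: float
    r2: float
    n: int


def _normed_ranks(x):
    """Average ranks, centered and scaled to unit norm."""
    r = rankdata(np.asarray(x, dtype=float))
    r = r - r.mean()
    nrm = np.sqrt(r @ r)
    if nrm <= 0:
        raise ValueError("zero rank variance: correlation undefined")
    return r / nrm


def spearman_rho(x, y):
    """Spearman rank correlation with average ranks for ties."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need n >= 3")
    return float(_normed_ranks(x) @ _normed_ranks(y))


def permutation_pvalue(x, y, n_perm=10000, rng=None, exhaustive_if_small=True):
    """Two-sided permutation p-value for the Spearman correlation.

    Exhaustive enumeration of all n! relabellings when n! <= 40,320 and
    ``exhaustive_if_small``; otherwise ``n_perm`` Monte-Carlo draws with the
    add-one estimator.  Returns ``(rho, p)``.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    if n < 4:
        raise ValueError("need n >= 4 for a permutation test")
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a very coarse p-value")
    rx, ry = _normed_ranks(x), _normed_ranks(y)
    rho = float(rx @ ry)
    if exhaustive_if_small and math.factorial(n) <= EXHAUSTIVE_LIMIT:
        perms = np.array(list(itertools.permutations(range(n))))
        null = ry[perms] @ rx
        p = float(np.mean(np.abs(null) >= abs(rho) - _EPS))
    else:
        rng = np.random.default_rng(rng)
        idx = np.argsort(rng.random((n_perm, n)), axis=1)
        null = ry[idx] @ rx
        p = (1 + int(np.sum(np.abs(null) >= abs(rho) - _EPS))) / (1 + n_perm)
    return rho, p


def fwe_correct(pairs, n_perm=10000, rng=None, family_id="family"):
    """Single-step max-statistic FWE correction over a family of pairs.

    ``pairs`` is a list of ``(name, x, y)``.  When all members share n, one
    relabelling per permutation is applied to every member and the familywise
    max |rho| recorded; with heterogeneous n each member gets its own
    permutations and the max is taken across members per draw (conservative,
    documented).  p_fwe is the add-one rank of each observed |rho| in the
    max-null; p_fwe >= p_raw is enforced.
    """
    if not pairs:
        raise ValueError("empty family")
    rng = np.random.default_rng(rng)
    prepared = []
    for name, x, y in pairs:
        x, y = np.asarray(x, float), np.asarray(y, float)
        if len(x) < 4:
            raise ValueError(f"member {name}: need n >= 4")
        prepared.append((name, _normed_ranks(x), _normed_ranks(y), len(x)))

    ns = {n for *_, n in prepared}
    nulls = np.empty((len(prepared), n_perm))
    if len(ns) == 1:
        n = ns.pop()
        idx = np.argsort(rng.random((n_perm, n)), axis=1)
        for i, (_, rx, ry, _) in enumerate(prepared):
            nulls[i] = ry[idx] @ rx
    else:
        for i, (_, rx, ry, n) in enumerate(prepared):
            idx = np.argsort(rng.random((n_perm, n)), axis=1)
            nulls[i] = ry[idx] @ rx
    max_null = np.abs(nulls).max(axis=0)

    out = []
    for i, (name, rx, ry, n) in enumerate(prepared):
        rho = float(rx @ ry)
        p_raw = (1 + int(np.sum(np.abs(nulls[i]) >= abs(rho) - _EPS))) / (
            1 + n_perm
        )
        p_fwe = (1 + int(np.sum(max_null >= abs(rho) - _EPS))) / (1 + n_perm)
        out.append(
            CorrelationResult(family_id, name, rho, p_raw, max(p_fwe, p_raw), n)
        )
    return out


def center_by_group(values, group_labels):
    """Subtract each group's mean; output group means are exactly zero.

    Subtracting participant means factors out inter-individual variability
    (leaving the intra-individual component); subtracting position means
    factors out intra-individual variability.
    """
    v = np.asarray(values, dtype=float)
    s = pd.Series(v)
    return (s - s.groupby(list(group_labels)).transform("mean")).to_numpy()


def _nearest_angle(angles, targets):
    d = np.abs((np.asarray(angles)[:, None] - np.asarray(targets)[None, :]
                + 180) % 360 - 180)
    return np.asarray(targets)[np.argmin(d, axis=1)]


@dataclass
class FixedEccentricityResult:
    table: pd.DataFrame  # participant x position rows
    results: list[CorrelationResult]
    n_excluded: int

    def by_pair(self):
        return {r.pair: r for r in self.results}


def fixed_eccentricity_analysis(
    vertices,
    threshold_maps,
    surface_areas,
    area="V1",
    value_col="true_sigma",
    ecc=4.7,
    tol=0.5,
    n_perm=10000,
    rng=None,
):
    """Correlations among width, threshold and anatomy at one eccentricity.

    Builds the participants × ring-positions table (20 × 6 = 120 rows at the
    defaults): per cell, ``value_col`` (tuning width) and thickness averaged
    over the vertices of ``area`` within ``ecc ± tol`` whose polar angle is
    nearest that position, the staircase threshold at the position, and the
    participant's surface area.  Computes the pairwise correlations plus the
    intra-individual (participant means subtracted) and inter-individual
    (position means subtracted) variants, FWE-corrected within three
    families: width~threshold, width~anatomy, threshold~anatomy.

    ``threshold_maps``: dict participant -> ThresholdMap;
    ``surface_areas``: dict participant -> mm².  Cells without vertices are
    excluded listwise with a report in ``n_excluded``.
    """
    rng = np.random.default_rng(rng)
    ring = sorted(
        a for e, a in _ring_positions(threshold_maps) if e == ecc
    )
    if len(ring) < 2:
        raise ValueError(f"need ring positions at {ecc} deg in threshold maps")

    sel = vertices[
        (vertices["area"] == area)
        & (np.abs(vertices["eccentricity"] - ecc) <= tol)
    ].copy()
    sel["position_angle"] = _nearest_angle(
        sel["polar_angle"].to_numpy(), ring
    )
    cells = (
        sel.groupby(["participant_id", "position_angle"], observed=True)
        .agg(width=(value_col, "mean"), thickness=("thickness", "mean"))
        .reset_index()
    )
    rows = []
    n_expected = 0
    for pid, tmap in threshold_maps.items():
        for ang in ring:
            n_expected += 1
            cell = cells[
                (cells["participant_id"] == pid)
                & (cells["position_angle"] == ang)
            ]
            if cell.empty:
                continue
            rows.append(
                {
                    "participant_id": pid,
                    "position_angle": ang,
                    "width": float(cell["width"].iloc[0]),
                    "thickness": float(cell["thickness"].iloc[0]),
                    "threshold": tmap.threshold_at(ecc, ang),
                    "surface_area": float(surface_areas[pid]),
                }
            )
    table = pd.DataFrame(rows)
    n_excluded = n_expected - len(table)
    if n_excluded:
        warnings.warn(f"{n_excluded} participant×position cells excluded")
    if len(table) < 8:
        raise ValueError("too few populated cells for the analysis")

    pid_l = table["participant_id"]
    pos_l = table["position_angle"]

    def intra(col):  # participant means out -> intra-individual component
        return center_by_group(table[col], pid_l)

    def inter(col):  # position means out -> inter-individual component
        return center_by_group(table[col], pos_l)

    w, thr = table["width"], table["threshold"]
    t, s = table["thickness"], table["surface_area"]
    families = {
        "width_vs_threshold": [
            ("width~threshold", w, thr),
            ("width~threshold_intra", intra("width"), intra("threshold")),
            ("width~threshold_inter", inter("width"), inter("threshold")),
        ],
        "width_vs_anatomy": [
            ("width~thickness", w, t),
            ("width~thickness_intra", intra("width"), intra("thickness")),
            ("width~thickness_inter", inter("width"), inter("thickness")),
            ("width~area", w, s),
        ],
        "threshold_vs_anatomy": [
            ("threshold~thickness", thr, t),
            ("threshold~thickness_intra",
             intra("threshold"), intra("thickness")),
            ("threshold~thickness_inter",
             inter("threshold"), inter("thickness")),
            ("threshold~area", thr, s),
        ],
    }
    results = []
    for fam, members in families.items():
        results.extend(fwe_correct(members, n_perm, rng, family_id=fam))
    return FixedEccentricityResult(table, results, n_excluded)


def _ring_positions(threshold_maps):
    tmap = next(iter(threshold_maps.values()))
    return [
        (float(e), float(a))
        for e, a in zip(
            tmap.table["eccentricity"], tmap.table["polar_angle"]
        )
        if e > 0
    ]


@dataclass
class DataGrid:
    """Binned value × eccentricity × (participant | thickness-bin) grid."""

    value_label: str
    axis2_kind: str  # "participant" or "thickness"
    ecc_edges: np.ndarray
    means: pd.DataFrame  # rows: axis2 labels, cols: ecc bin centers
    counts: pd.DataFrame

    @property
    def ecc_centers(self):
        return 0.5 * (self.ecc_edges[:-1] + self.ecc_edges[1:])


def build_grid(
    vertices,
    value_col,
    axis2="participant",
    n_ecc_bins=10,
    thickness_bin_width=0.1,
    ecc_range=None,
    area=None,
):
    """Average ``value_col`` over cells of eccentricity × second axis.

    axis2="participant" groups vertices by participant; axis2="thickness"
    groups them into 0.1 mm thickness bins.  Eccentricity bins are
    equal-width (10 by default) over ``ecc_range`` or the observed range.
    """
    df = vertices if area is None else vertices[vertices["area"] == area]
    if df.empty:
        raise ValueError("empty vertex selection")
    ecc = df["eccentricity"].to_numpy()
    lo, hi = ecc_range if ecc_range else (ecc.min(), ecc.max())
    edges = np.linspace(lo, hi, n_ecc_bins + 1)
    ecc_bin = pd.cut(df["eccentricity"], edges, include_lowest=True)

    if axis2 == "participant":
        key = df["participant_id"]
    elif axis2 == "thickness":
        t = df["thickness"].to_numpy()
        t_edges = np.arange(
            np.floor(t.min() / thickness_bin_width) * thickness_bin_width,
            t.max() + thickness_bin_width,
            thickness_bin_width,
        )
        centers_t = np.round(0.5 * (t_edges[:-1] + t_edges[1:]), 6)
        key = pd.cut(
            df["thickness"], t_edges, labels=centers_t,
            include_lowest=True,
        ).astype(float)
    else:
        raise ValueError("axis2 must be 'participant' or 'thickness'")

    grouped = df.groupby([key, ecc_bin], observed=False)[value_col]
    means = grouped.mean().unstack()
    counts = grouped.count().unstack().fillna(0).astype(int)
    if counts.to_numpy().sum() == 0:
        raise ValueError("empty grid")
    centers = 0.5 * (edges[:-1] + edges[1:])
    means.columns = centers
    counts.columns = centers
    means.index.name = axis2
    counts.index.name = axis2
    return DataGrid(value_col, axis2, edges, means, counts)


@dataclass
class EccentricityResolvedResult:
    fits: dict  # axis2 label -> LinearFit
    results: list[CorrelationResult]
    skipped: list = field(default_factory=list)

    def by_pair(self):
        return {r.pair: r for r in self.results}


def eccentricity_resolved_analysis(
    grid: DataGrid,
    anatomy_values=None,
    n_perm=10000,
    rng=None,
    min_bins=3,
    min_axis2=5,
):
    """Linear fits of value against eccentricity, related to anatomy.

    Per grid row (one participant, or one thickness bin) with at least
    ``min_bins`` populated eccentricity bins, fit value ~ eccentricity by
    least squares.  Slopes, intercepts, and goodness of fit are correlated
    against ``anatomy_values`` (dict row-label -> value, e.g. surface area;
    for a thickness grid the bin thickness itself is used when omitted),
    FWE-corrected as one family.  A second family correlates the cell value
    against anatomy within each eccentricity bin.  The goodness-of-fit
    member mirrors the negative-control pattern: it is reported alongside,
    not a planted effect.
    """
    rng = np.random.default_rng(rng)
    if anatomy_values is None:
        if grid.axis2_kind != "thickness":
            raise ValueError(
                "anatomy_values required for a participant grid"
            )
        anatomy_values = {lab: float(lab) for lab in grid.means.index}

    fits, skipped = {}, []
    for lab in grid.means.index:
        row = grid.means.loc[lab]
        cnt = grid.counts.loc[lab]
        mask = (cnt.to_numpy() > 0) & row.notna().to_numpy()
        if mask.sum() < min_bins:
            skipped.append(lab)
            continue
        xb = row.index.to_numpy(dtype=float)[mask]
        yb = row.to_numpy(dtype=float)[mask]
        slope, intercept = np.polyfit(xb, yb, 1)
        yhat = slope * xb + intercept
        ss_tot = float(((yb - yb.mean()) ** 2).sum())
        r2 = 1.0 - float(((yb - yhat) ** 2).sum()) / ss_tot if ss_tot else 0.0
        fits[lab] = LinearFit(float(slope), float(intercept), r2, int(mask.sum()))
    if skipped:
        warnings.warn(f"{len(skipped)} grid row(s) skipped (<{min_bins} bins)")
    labs = [lab for lab in fits if lab in anatomy_values]
    if len(labs) < 4:
        raise ValueError("too few fitted rows for slope/intercept analysis")
    anat = np.array([anatomy_values[lab] for lab in labs])
    members = [
        ("slope~anatomy", np.array([fits[lab].slope for lab in labs]), anat),
        ("intercept~anatomy",
         np.array([fits[lab].intercept for lab in labs]), anat),
        ("gof~anatomy", np.array([fits[lab].r2 for lab in labs]), anat),
    ]
    results = fwe_correct(members, n_perm, rng, family_id="slope_intercept")

    bin_members = []
    for c in grid.means.columns:
        col = grid.means[c]
        mask = (grid.counts[c].to_numpy() > 0) & col.notna().to_numpy()
        sel_labs = [
            lab for lab, m in zip(grid.means.index, mask)
            if m and lab in anatomy_values
        ]
        if len(sel_labs) < min_axis2:
            continue
        vals = col.loc[sel_labs].to_numpy(dtype=float)
        an = np.array([anatomy_values[lab] for lab in sel_labs])
        bin_members.append((f"value~anatomy@{c:.2f}", vals, an))
    if bin_members:
        results.extend(
            fwe_correct(bin_members, n_perm, rng, family_id="per_ecc_bin")
        )
    return EccentricityResolvedResult(fits, results, skipped)


def correlation_table(results) -> pd.DataFrame:
    """Long-format TSV-ready table of CorrelationResults."""
    return pd.DataFrame(
        [
            {
                "family": r.family,
                "pair": r.pair,
                "rho": r.rho,
                "p_raw": r.p_raw,
                "p_fwe": r.p_fwe,
                "n": r.n,
            }
            for r in results
        ]
    )
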