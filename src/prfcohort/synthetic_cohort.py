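"""Seeded synthetic cohorts of visual cortical anatomy, tuning, and perception.

The generator emulates a cohort of human observers in whom three kinds of
measurement are linked at the level of single cortical surface locations
(vertices) in early visual cortex (V1/V2):

* anatomy — per-vertex cortical thickness and vertex surface area, with
  sulcus<gyrus and parafovea<perifovea thickness gradients and an
  inter-individual spread in total surface area that is correlated between
  V1 and V2;
* neural tuning — a ground-truth population tuning width (pRF sigma) per
  vertex, generated from a linear model in eccentricity with planted
  positive thickness and negative surface-area effects;
* perception — psychometric observers at 13 visual-field positions whose
  position-discrimination thresholds inherit the same anatomical effects.

Vertex eccentricities follow a truncated exponential density (cortical
magnification); polar angles are uniform within each hemifield.  Everything
is deterministic given ``CohortConfig.seed``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .psychophysics import PsychometricObserver, threshold_positions

__all__ = [
    "CohortConfig",
    "ParticipantAnatomy",
    "Cohort",
    "generate_cohort",
    "sample_eccentricities",
    "assign_thickness",
    "write_vertex_table",
    "read_vertex_table",
    "write_anatomy_json",
    "VERTEX_COLUMNS",
]

#: Documented header of the vertex-table TSV (user-supplied tables must carry
#: at least the first nine columns; ``true_sigma`` is generator-only and
#: fitted columns are appended downstream).
VERTEX_COLUMNS = [
    "participant_id",
    "area",
    "hemisphere",
    "vertex_id",
    "eccentricity",
    "polar_angle",
    "thickness",
    "folding_class",
    "vertex_area",
    "true_sigma",
]

SIGMA_FLOOR = 0.05  # deg; keeps the generative tuning model physical
THICKNESS_FLOOR = 0.5  # mm
THRESHOLD_FLOOR = 0.02  # deg


@dataclass(frozen=True)
class CohortConfig:
    """Generative parameters of a synthetic cohort.

    Defaults are calibrated to the published cohort scale: 20 participants,
    V1+V2, eccentricity 0.25–7.2 deg with exponential decay rate 0.26/deg
    (retinotopy coverage fraction 78.3%), thickness 2.25 ± 0.40 mm spanning
    roughly 1–4 mm, 0.3 mm sulcus→gyrus and parafovea→perifovea increments,
    surface areas with ~1.5× min–max spread over 20 participants correlated
    0.6 between V1 and V2, and tuning width 0.19 + 0.15·eccentricity deg
    (≈ 0.6 ± 0.33 deg marginally) with a +0.3 deg/mm thickness effect and
    negative surface-area effects on both intercept and slope.
    """

    n_participants: int = 20
    areas: tuple[str, ...] = ("V1", "V2")
    n_vertices: int = 2000  # per participant and area
    ecc_range: tuple[float, float] = (0.25, 7.2)
    magnification_decay_b: float = 0.26  # per degree

    # thickness model (mm)
    thickness_mean: float = 2.25
    thickness_sd: float = 0.40  # marginal SD; residual SD derived from it
    thickness_gyrus_delta: float = 0.30
    thickness_perifovea_delta: float = 0.30
    thickness_participant_sd: float = 0.06
    thickness_polar_sd: float = 0.12  # amplitude of per-participant harmonic
    parafovea_boundary: float = 2.0  # deg

    # surface area model (mm^2)
    area_mean: dict[str, float] = field(
        default_factory=lambda: {"V1": 2770.0, "V2": 2270.0}
    )
    area_cv: float = 0.105  # lognormal coefficient of variation
    v1v2_area_correlation: float = 0.6

    # tuning-width model (deg)
    sigma_intercept: float = 0.19
    sigma_slope: float = 0.15  # deg per deg eccentricity
    beta_thickness: float = 0.30  # deg per mm
    beta_area: float = -1.0e-4  # deg per mm^2
    area_slope_coupling: float = 0.45  # relative slope change per rel. area
    slope_rel_sd: float = 0.03  # shared magnification noise (lognormal)
    sigma_noise_sd: float = 0.08

    # discrimination-threshold model (deg)
    threshold_intercept: float = 0.08
    threshold_slope: float = 0.05  # deg per deg eccentricity
    threshold_beta_thickness: float = 0.30  # deg per mm
    threshold_beta_area: float = -1.5e-4  # deg per mm^2
    threshold_noise_rel_sd: float = 0.05  # multiplicative lognormal noise

    # psychometric observer shape
    observer_beta: float = 3.5
    observer_lapse: float = 0.02

    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ValueError("n_participants must be >= 2")
        if self.n_vertices < 1:
            raise ValueError("n_vertices must be >= 1")
        lo, hi = self.ecc_range
        if not (0 < lo < hi):
            raise ValueError("ecc_range must satisfy 0 < lo < hi")
        if self.magnification_decay_b <= 0:
            raise ValueError("magnification_decay_b must be > 0")
        for name in (
            "thickness_sd",
            "thickness_participant_sd",
            "thickness_polar_sd",
            "area_cv",
            "slope_rel_sd",
            "sigma_noise_sd",
            "threshold_noise_rel_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not all(a in self.area_mean for a in self.areas):
            raise ValueError("area_mean must cover every configured area")
        if not -1.0 <= self.v1v2_area_correlation <= 1.0:
            raise ValueError("v1v2_area_correlation must be in [-1, 1]")

    def residual_thickness_sd(self) -> float:
        """Vertex-level residual SD implied by the configured marginal SD.

        The marginal thickness variance decomposes into participant offsets,
        the polar harmonic (variance A^2/2 with A ~ N(0, polar_sd)), the two
        centered binary gradients, and a residual; the residual absorbs
        whatever the structure terms leave of ``thickness_sd**2``.
        """
        p_peri = self._perifovea_fraction()
        structure = (
            self.thickness_participant_sd**2
            + 0.5 * self.thickness_polar_sd**2
            + 0.25 * self.thickness_gyrus_delta**2
            + p_peri * (1 - p_peri) * self.thickness_perifovea_delta**2
        )
        resid = self.thickness_sd**2 - structure
        if resid <= 0:
            raise ValueError(
                "thickness_sd too small for the configured structure terms"
            )
        return float(np.sqrt(resid))

    def _perifovea_fraction(self) -> float:
        b = self.magnification_decay_b
        lo, hi = self.ecc_range
        bound = min(max(self.parafovea_boundary, lo), hi)
        total = np.exp(-b * lo) - np.exp(-b * hi)
        peri = np.exp(-b * bound) - np.exp(-b * hi)
        return float(peri / total)


@dataclass(frozen=True)
class ParticipantAnatomy:
    """Per-participant anatomical summary: surface area and mean thickness."""

    participant_id: str
    surface_area: dict[str, float]  # mm^2 per area
    mean_thickness: dict[str, float]  # mm per area


@dataclass
class Cohort:
    """A generated cohort: vertex table, anatomy summaries, observers."""

    vertices: pd.DataFrame
    anatomy: list[ParticipantAnatomy]
    observers: dict[str, list[PsychometricObserver]]
    config: CohortConfig

    def participant_ids(self) -> list[str]:
        return [a.participant_id for a in self.anatomy]


def sample_eccentricities(n, b, ecc_range=(0.25, 7.2), rng=None):
    """Draw eccentricities from the truncated exponential density a·e^(−bx).

    Inverse-CDF sampling on [lo, hi]; the empirical histogram converges to
    the exponential law that the anatomy module fits back.
    """
    if b <= 0:
        raise ValueError("decay rate b must be > 0")
    lo, hi = ecc_range
    if not 0 < lo < hi:
        raise ValueError("ecc_range must satisfy 0 < lo < hi")
    rng = np.random.default_rng(rng)
    u = rng.random(int(n))
    c_lo, c_hi = np.exp(-b * lo), np.exp(-b * hi)
    return -np.log(c_lo - u * (c_lo - c_hi)) / b


def assign_thickness(vertices, config, rng=None):
    """Sample per-vertex cortical thickness (mm) for a single participant.

    Requires ``eccentricity``, ``polar_angle`` and ``folding_class`` columns.
    The marginal distribution is Gaussian at the configured mean/SD; gyri
    exceed sulci by ``thickness_gyrus_delta`` and perifovea exceeds parafovea
    by ``thickness_perifovea_delta`` in expectation.  Structure terms are
    centered so the marginal mean stays at ``thickness_mean``.  Values are
    clipped below at 0.5 mm.
    """
    rng = np.random.default_rng(rng)
    cfg = config
    n = len(vertices)
    gyrus = (vertices["folding_class"].to_numpy() == "gyrus").astype(float)
    peri = (
        vertices["eccentricity"].to_numpy() >= cfg.parafovea_boundary
    ).astype(float)
    p_peri = cfg._perifovea_fraction()

    offset = rng.normal(0.0, cfg.thickness_participant_sd)
    amp = rng.normal(0.0, cfg.thickness_polar_sd)
    phase = rng.uniform(0.0, 2 * np.pi)
    theta = np.deg2rad(vertices["polar_angle"].to_numpy())

    t = (
        cfg.thickness_mean
        + offset
        + amp * np.cos(theta - phase)
        + cfg.thickness_gyrus_delta * (gyrus - 0.5)
        + cfg.thickness_perifovea_delta * (peri - p_peri)
        + rng.normal(0.0, cfg.residual_thickness_sd(), n)
    )
    return np.maximum(t, THICKNESS_FLOOR)


def _sample_surface_areas(config, rng):
    """Correlated lognormal surface areas, one row per participant.

    V1 and V2 (and any further areas) share a Gaussian copula with pairwise
    correlation ``v1v2_area_correlation`` on the log scale.
    """
    k = len(config.areas)
    log_sd = np.sqrt(np.log1p(config.area_cv**2))
    corr = np.full((k, k), config.v1v2_area_correlation)
    np.fill_diagonal(corr, 1.0)
    z = rng.multivariate_normal(np.zeros(k), corr, size=config.n_participants)
    means = np.array([config.area_mean[a] for a in config.areas])
    # lognormal with exact mean `means` and CV `area_cv`
    mu = np.log(means) - 0.5 * log_sd**2
    return np.exp(mu + log_sd * z)  # (n_participants, k)


def _position_mean_thickness(vertices_v1, config):
    """Mean thickness near each of the 13 threshold positions (area V1).

    Vertices within ±0.5 deg of a ring eccentricity are pooled by nearest
    polar angle; the central position pools vertices below 0.5 deg.  Falls
    back to the participant mean when a position has no vertices.
    """
    ecc = vertices_v1["eccentricity"].to_numpy()
    ang = vertices_v1["polar_angle"].to_numpy()
    thick = vertices_v1["thickness"].to_numpy()
    out = []
    for pos_ecc, pos_ang in threshold_positions():
        if pos_ecc == 0.0:
            sel = ecc < 0.5
        else:
            ring = np.abs(ecc - pos_ecc) <= 0.5
            ring_angles = np.array(
                [a for e, a in threshold_positions() if e == pos_ecc]
            )
            d = np.abs((ang[:, None] - ring_angles[None, :] + 180) % 360 - 180)
            nearest = ring_angles[np.argmin(d, axis=1)]
            sel = ring & (nearest == pos_ang)
        out.append(thick[sel].mean() if sel.any() else thick.mean())
    return np.array(out)


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate a full synthetic cohort from ``config``.

    Deterministic given ``config.seed``.  Ground-truth tuning width per
    vertex follows

        sigma = intercept·(1 + c·dS) + slope·(1 + c·dS)·e
                + beta_thickness·(t − t_mean) + beta_area·(S − S_mean) + noise

    with dS = −(S − S_mean)/S_mean and c = ``area_slope_coupling``, truncated
    below at 0.05 deg; observers' true thresholds follow the analogous model
    with the participant's position-local mean thickness.
    """
    cfg = config
    root = np.random.SeedSequence(cfg.seed)
    ss_area, ss_vertices, ss_obs = root.spawn(3)
    rng_area = np.random.default_rng(ss_area)

    areas_matrix = _sample_surface_areas(cfg, rng_area)
    # participant-level magnification scalar: residual steepness of the
    # eccentricity dependence shared by tuning width and threshold
    eta = rng_area.normal(0.0, cfg.slope_rel_sd, cfg.n_participants)
    pids = [f"P{i + 1:02d}" for i in range(cfg.n_participants)]

    vertex_rngs = [
        np.random.default_rng(s) for s in ss_vertices.spawn(cfg.n_participants)
    ]
    obs_rngs = [
        np.random.default_rng(s) for s in ss_obs.spawn(cfg.n_participants)
    ]

    frames = []
    anatomy: list[ParticipantAnatomy] = []
    observers: dict[str, list[PsychometricObserver]] = {}

    for i, pid in enumerate(pids):
        rng = vertex_rngs[i]
        per_area = {}
        mean_thick = {}
        for j, area in enumerate(cfg.areas):
            s_total = areas_matrix[i, j]
            n = cfg.n_vertices
            ecc = sample_eccentricities(
                n, cfg.magnification_decay_b, cfg.ecc_range, rng
            )
            polar = rng.uniform(0.0, 360.0, n)
            hemi = np.where(np.cos(np.deg2rad(polar)) >= 0, "left", "right")
            folding = np.where(rng.random(n) < 0.5, "sulcus", "gyrus")
            # vertex areas: random positive weights summing exactly to s_total
            w = rng.gamma(4.0, 1.0, n)
            va = s_total * (w / w.sum())
            df = pd.DataFrame(
                {
                    "participant_id": pid,
                    "area": area,
                    "hemisphere": hemi,
                    "vertex_id": np.arange(n),
                    "eccentricity": ecc,
                    "polar_angle": polar,
                    "folding_class": folding,
                    "vertex_area": va,
                }
            )
            df["thickness"] = assign_thickness(df, cfg, rng)

            s_mean = cfg.area_mean[area]
            rel = (s_total - s_mean) / s_mean
            slope_i = (
                cfg.sigma_slope
                * (1 - cfg.area_slope_coupling * rel)
                * np.exp(eta[i])
            )
            inter_i = cfg.sigma_intercept * (
                1 - cfg.area_slope_coupling * rel
            )
            sigma = (
                inter_i
                + slope_i * ecc
                + cfg.beta_thickness * (df["thickness"] - cfg.thickness_mean)
                + cfg.beta_area * (s_total - s_mean)
                + rng.normal(0.0, cfg.sigma_noise_sd, n)
            )
            df["true_sigma"] = np.maximum(sigma, SIGMA_FLOOR)
            frames.append(df)
            per_area[area] = float(s_total)
            mean_thick[area] = float(df["thickness"].mean())
        anatomy.append(ParticipantAnatomy(pid, per_area, mean_thick))

    vertices = pd.concat(frames, ignore_index=True)[VERTEX_COLUMNS]

    # psychometric observers inherit the anatomy effects (area "V1" = first)
    ref_area = cfg.areas[0]
    s_ref_mean = cfg.area_mean[ref_area]
    for i, pid in enumerate(pids):
        rng = obs_rngs[i]
        v1 = vertices[
            (vertices["participant_id"] == pid) & (vertices["area"] == ref_area)
        ]
        pos_thick = _position_mean_thickness(v1, cfg)
        s_total = anatomy[i].surface_area[ref_area]
        rel = (s_total - s_ref_mean) / s_ref_mean
        slope_i = (
            cfg.threshold_slope
            * (1 - cfg.area_slope_coupling * rel)
            * np.exp(eta[i])
        )
        inter_i = cfg.threshold_intercept * (
            1 - cfg.area_slope_coupling * rel
        )
        obs_list = []
        for k, (pos_ecc, pos_ang) in enumerate(threshold_positions()):
            alpha = (
                inter_i
                + slope_i * pos_ecc
                + cfg.threshold_beta_thickness
                * (pos_thick[k] - cfg.thickness_mean)
                + cfg.threshold_beta_area * (s_total - s_ref_mean)
            )
            alpha *= np.exp(rng.normal(0.0, cfg.threshold_noise_rel_sd))
            obs_list.append(
                PsychometricObserver(
                    position=(pos_ecc, pos_ang),
                    alpha=max(float(alpha), THRESHOLD_FLOOR),
                    beta=cfg.observer_beta,
                    lapse=cfg.observer_lapse,
                )
            )
        observers[pid] = obs_list

    return Cohort(vertices, anatomy, observers, cfg)


# ---------------------------------------------------------------------------
# I/O: TSV for vertex tables, JSON for anatomy + provenance
# ---------------------------------------------------------------------------

def write_vertex_table(vertices: pd.DataFrame, path) -> None:
    vertices.to_csv(path, sep="\t", index=False)


def read_vertex_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in VERTEX_COLUMNS[:9] if c not in df.columns]
    if missing:
        raise ValueError(f"vertex table missing columns: {missing}")
    return df


def write_anatomy_json(anatomy, config, path) -> None:
    payload = {
        "config": dataclasses.asdict(config),
        "participants": [dataclasses.asdict(a) for a in anatomy],
    }
    Path(path).write_text(json.dumps(payload, indent=2))
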