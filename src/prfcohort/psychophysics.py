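"""2AFC position-discrimination observers, adaptive staircases, projection.

An observer at one visual-field position answers a two-alternative
forced-choice position-discrimination trial with probability

    P(correct | delta) = gamma + (1 - gamma - lambda) * W(delta; alpha, beta)

where W is the Weibull CDF, gamma = 0.5 (chance), lambda a small lapse rate.
The stimulus offset delta is driven by a transformed 2-down-1-up staircase
(two consecutive correct responses make the task harder, one error makes it
easier), which converges on the level where P(correct) = sqrt(0.5) ~ 70.7%.
Thresholds measured at the 13 standard positions (eccentricities 0, 4.7,
6.7 deg; polar angles 45, 90, 135, 225, 270, 315 deg) form a ThresholdMap
that can be projected onto a retinotopic vertex table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "PsychometricObserver",
    "StaircaseConfig",
    "StaircaseResult",
    "ThresholdMap",
    "threshold_positions",
    "psychometric_prob",
    "convergence_point",
    "run_staircase",
    "measure_thresholds",
    "project_to_cortex",
]

#: Targeted proportion correct of the 2-down-1-up rule.
TWO_DOWN_ONE_UP_TARGET = np.sqrt(0.5)

#: Vertices closer to fixation than this are matched to the central position.
CENTRAL_MATCH_ECC = 0.5

_RING_ANGLES = (45.0, 90.0, 135.0, 225.0, 270.0, 315.0)


def threshold_positions():
    """The 13 measured positions: center plus two rings of six angles."""
    pos = [(0.0, 0.0)]
    for ecc in (4.7, 6.7):
        pos.extend((ecc, ang) for ang in _RING_ANGLES)
    return pos


@dataclass(frozen=True)
class PsychometricObserver:
    """Weibull 2AFC observer at one visual-field position.

    ``beta=inf`` gives a step-function observer (deterministically correct
    at delta >= alpha), useful as the noiseless limit.
    """

    position: tuple[float, float]  # (eccentricity deg, polar angle deg)
    alpha: float  # deg; Weibull scale (threshold parameter)
    beta: float = 3.5  # psychometric slope
    gamma: float = 0.5  # 2AFC guess rate
    lapse: float = 0.02

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if not 0 <= self.lapse <= 0.1:
            raise ValueError("lapse must be in [0, 0.1]")


def psychometric_prob(observer: PsychometricObserver, delta):
    """P(correct) at offset ``delta`` (deg); nondecreasing in delta."""
    delta = np.asarray(delta, dtype=float)
    if np.any(delta < 0):
        raise ValueError("delta must be >= 0")
    obs = observer
    if np.isinf(obs.beta):
        w = (delta >= obs.alpha).astype(float)
    else:
        w = 1.0 - np.exp(-((delta / obs.alpha) ** obs.beta))
    p = obs.gamma + (1.0 - obs.gamma - obs.lapse) * w
    return p if p.ndim else float(p)


def convergence_point(observer, target=TWO_DOWN_ONE_UP_TARGET):
    """Offset where P(correct) = ``target`` (the staircase's fixed point)."""
    lo, hi = observer.alpha * 1e-4, observer.alpha * 1e4
    return brentq(
        lambda d: psychometric_prob(observer, d) - target, lo, hi, xtol=1e-12
    )


@dataclass(frozen=True)
class StaircaseConfig:
    """Transformed 2-down-1-up staircase with annealing multiplicative steps.

    ``start_delta=None`` starts at 4x the observer's alpha (simulation
    convention).  The step factor starts at ``step_factor`` and shrinks by
    ×0.75 at each early reversal until it reaches ``min_step_factor``.
    The threshold is the geometric mean of the last ``n_reversals_avg`` of
    ``n_reversals_stop`` reversal deltas.
    """

    start_delta: float | None = None
    step_factor: float = 2.0
    min_step_factor: float = 1.10
    n_reversals_stop: int = 16
    n_reversals_avg: int = 8
    rule: str = "2-down-1-up"
    max_trials: int = 600
    anneal_rate: float = 0.75

    def __post_init__(self) -> None:
        if self.start_delta is not None and self.start_delta <= 0:
            raise ValueError("start_delta must be > 0")
        if self.step_factor <= 1 or self.min_step_factor <= 1:
            raise ValueError("step factors must be > 1")
        if self.n_reversals_avg > self.n_reversals_stop:
            raise ValueError("n_reversals_avg must be <= n_reversals_stop")
        if self.rule != "2-down-1-up":
            raise ValueError("only the 2-down-1-up rule is implemented")


@dataclass
class StaircaseResult:
    delta_sequence: np.ndarray  # deg, one per trial
    response_sequence: np.ndarray  # bool, correct per trial
    reversal_indices: np.ndarray
    threshold: float  # deg
    truncated: bool = False


def run_staircase(observer, config=StaircaseConfig(), rng=None):
    """Run one adaptive track on ``observer``; seeded and reproducible.

    Two consecutive correct responses divide delta by the current step
    factor; any error multiplies by it.  Direction changes are reversals;
    after each early reversal the factor anneals toward its floor so the
    track settles near the 70.7%-correct level.
    """
    rng = np.random.default_rng(rng)
    cfg = config
    delta = cfg.start_delta if cfg.start_delta else 4.0 * observer.alpha

    deltas, responses = [], []
    reversals: list[int] = []
    factor = cfg.step_factor
    streak = 0
    direction = 0  # -1 down, +1 up
    for _ in range(cfg.max_trials):
        deltas.append(delta)
        correct = rng.random() < psychometric_prob(observer, delta)
        responses.append(correct)
        move = 0
        if correct:
            streak += 1
            if streak == 2:
                move, streak = -1, 0
        else:
            move, streak = +1, 0
        if move:
            if direction and move != direction:
                reversals.append(len(deltas) - 1)
                factor = max(cfg.min_step_factor, factor * cfg.anneal_rate)
                if len(reversals) >= cfg.n_reversals_stop:
                    delta = delta * factor if move > 0 else delta / factor
                    break
            direction = move
            delta = delta * factor if move > 0 else delta / factor

    truncated = len(reversals) < cfg.n_reversals_stop
    deltas = np.asarray(deltas)
    rev = np.asarray(reversals, dtype=int)
    tail = rev[-cfg.n_reversals_avg:] if rev.size else np.array([], dtype=int)
    if tail.size:
        threshold = float(np.exp(np.mean(np.log(deltas[tail]))))
    else:  # pathological: no reversal before the trial cap
        threshold = float(deltas[-1])
    return StaircaseResult(
        deltas, np.asarray(responses, dtype=bool), rev, threshold, truncated
    )


@dataclass
class ThresholdMap:
    """Discrimination thresholds at the 13 standard positions."""

    participant_id: str
    table: pd.DataFrame  # columns: eccentricity, polar_angle, threshold
    paradigm: str = "spatial"

    def threshold_at(self, ecc, angle):
        t = self.table
        row = t[(t["eccentricity"] == ecc) & (t["polar_angle"] == angle)]
        if row.empty:
            raise KeyError(f"no threshold measured at ({ecc}, {angle})")
        return float(row["threshold"].iloc[0])


def measure_thresholds(
    observer_set,
    config=StaircaseConfig(),
    rng=None,
    participant_id="P00",
    paradigm="spatial",
    return_tracks=False,
    n_tracks=3,
):
    """Independent staircases per position -> ThresholdMap.

    ``observer_set`` must cover all 13 standard positions.  Each position
    is measured with ``n_tracks`` independent tracks whose thresholds are
    combined by geometric mean (emulating repeated runs of the same
    experiment); the per-position experiments are mutually independent.
    ``paradigm`` is provenance only (spatial vs temporal forced choice).
    """
    rng = np.random.default_rng(rng)
    by_pos = {obs.position: obs for obs in observer_set}
    missing = [p for p in threshold_positions() if p not in by_pos]
    if missing:
        raise ValueError(f"observer set missing positions: {missing}")
    if paradigm not in ("spatial", "temporal"):
        raise ValueError("paradigm must be 'spatial' or 'temporal'")

    rows, tracks = [], {}
    for pos in threshold_positions():
        runs = [run_staircase(by_pos[pos], config, rng)
                for _ in range(n_tracks)]
        rows.append(
            {
                "eccentricity": pos[0],
                "polar_angle": pos[1],
                "threshold": float(
                    np.exp(np.mean([np.log(r.threshold) for r in runs]))
                ),
                "truncated": any(r.truncated for r in runs),
            }
        )
        tracks[pos] = runs[0]
    tmap = ThresholdMap(participant_id, pd.DataFrame(rows), paradigm)
    return (tmap, tracks) if return_tracks else tmap


def _logpolar_xy(ecc, angle_deg):
    r = np.log1p(np.asarray(ecc, dtype=float))
    th = np.deg2rad(np.asarray(angle_deg, dtype=float))
    return r * np.cos(th), r * np.sin(th)


def project_to_cortex(threshold_map, vertices):
    """Assign each vertex the threshold of its nearest measured position.

    Distance is Euclidean in the log-polar embedding
    (log(1+e)·cos(theta), log(1+e)·sin(theta)), which compresses peripheral
    space the way cortical magnification does.  Vertices with eccentricity
    below 0.5 deg are matched to the central position and flagged so that
    downstream binning can collapse them into a single data point.

    Returns a DataFrame (aligned to ``vertices``) with columns
    ``threshold``, ``position_eccentricity``, ``position_angle``,
    ``central``.
    """
    t = threshold_map.table
    if t.empty:
        raise ValueError("empty threshold map")
    ecc = vertices["eccentricity"].to_numpy()
    ang = vertices["polar_angle"].to_numpy()
    vx, vy = _logpolar_xy(ecc, ang)

    periph = t[t["eccentricity"] > 0].reset_index(drop=True)
    px, py = _logpolar_xy(
        periph["eccentricity"].to_numpy(), periph["polar_angle"].to_numpy()
    )
    d2 = (vx[:, None] - px[None, :]) ** 2 + (vy[:, None] - py[None, :]) ** 2
    nearest = np.argmin(d2, axis=1)

    central = ecc < CENTRAL_MATCH_ECC
    thr = periph["threshold"].to_numpy()[nearest]
    pos_e = periph["eccentricity"].to_numpy()[nearest]
    pos_a = periph["polar_angle"].to_numpy()[nearest]

    c_row = t[t["eccentricity"] == 0]
    if not c_row.empty:
        thr = np.where(central, float(c_row["threshold"].iloc[0]), thr)
        pos_e = np.where(central, 0.0, pos_e)
        pos_a = np.where(central, 0.0, pos_a)

    return pd.DataFrame(
        {
            "threshold": thr,
            "position_eccentricity": pos_e,
            "position_angle": pos_a,
            "central": central,
        },
        index=vertices.index,
    )


def write_threshold_map(tmap: ThresholdMap, path) -> None:
    out = tmap.table.copy()
    out.insert(0, "participant_id", tmap.participant_id)
    out.insert(1, "paradigm", tmap.paradigm)
    out.to_csv(path, sep="\t", index=False)


def write_tracks(tracks, path) -> None:
    """Per-trial audit TSV for a dict of position -> StaircaseResult."""
    rows = []
    for (ecc, ang), res in tracks.items():
        for i, (d, r) in enumerate(
            zip(res.delta_sequence, res.response_sequence)
        ):
            rows.append(
                {
                    "eccentricity": ecc,
                    "polar_angle": ang,
                    "trial": i,
                    "delta": d,
                    "correct": bool(r),
                    "reversal": i in set(res.reversal_indices.tolist()),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
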