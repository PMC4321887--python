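"""Seeded parameter-recovery and calibration studies.

Each function runs one self-contained simulation experiment at the
package's study conditions and returns plain-float summaries: pRF
parameter recovery, staircase convergence, exponential-coverage checks,
permutation-test calibration, end-to-end sign recovery of the planted
anatomy effects, and soft calibration of the default cohort against the
published scale.  These are the computations behind
``scripts/acceptance.py``; sizes are arguments so tests can scale down.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import integrate
from scipy.stats import kstest

from . import stats as st
from .anatomy import (
    coverage_fraction,
    fit_exponential,
    folding_eccentricity_contrast,
)
from .prf import HRFParams, PRFFitter, PRFParams, make_bar_stimulus, \
    predict_bold, simulate_bold
from .psychophysics import (
    PsychometricObserver,
    StaircaseConfig,
    convergence_point,
    measure_thresholds,
    run_staircase,
)
from .synthetic_cohort import CohortConfig, generate_cohort, \
    sample_eccentricities

HEADLINE_SIGNS = {
    "width~threshold": +1,
    "width~thickness": +1,
    "width~area": -1,
    "threshold~thickness": +1,
    "threshold~area": -1,
}
VARIANT_OF = {
    "width~threshold_intra": "width~threshold",
    "width~threshold_inter": "width~threshold",
    "width~thickness_intra": "width~thickness",
    "width~thickness_inter": "width~thickness",
    "threshold~thickness_intra": "threshold~thickness",
    "threshold~thickness_inter": "threshold~thickness",
}


def _sub_seeds(seed, k):
    return [
        int(s & 0x7FFFFFFF)
        for s in np.random.SeedSequence(seed).generate_state(k, np.uint64)
    ]


def _random_prfs(rng, n, ecc_max=6.5, sigma_range=(0.2, 2.0)):
    ecc = rng.uniform(0.3, ecc_max, n)
    ang = rng.uniform(0, 2 * np.pi, n)
    sig = np.exp(rng.uniform(*np.log(sigma_range), n))
    return [
        PRFParams(e * np.cos(a), e * np.sin(a), s)
        for e, a, s in zip(ecc, ang, sig)
    ]


def prf_recovery(n_voxels=200, seed=0, snr=1.0):
    """Noiseless and SNR-matched 2D-Gaussian recovery over random pRFs.

    Returns max relative sigma error (noiseless) and median relative sigma
    error at amplitude/noise_sd = ``snr``.
    """
    rng = np.random.default_rng(seed)
    stim = make_bar_stimulus()
    fitter = PRFFitter(stim)
    prfs = _random_prfs(rng, n_voxels)
    err0, errn = [], []
    for prf in prfs:
        clean = predict_bold(prf, stim)
        err0.append(abs(fitter.fit(clean).sigma - prf.sigma) / prf.sigma)
        noisy = simulate_bold(
            prf, stim, noise_sd=prf.amplitude / snr, rng=rng
        )
        errn.append(abs(fitter.fit(noisy).sigma - prf.sigma) / prf.sigma)
    return {
        "max_rel_err_noiseless": float(np.max(err0)),
        "median_rel_err_snr1": float(np.median(errn)),
        "n": n_voxels,
    }


def prf_noise_independence(n_voxels=200, seed=0, noise_range=(0.5, 2.0)):
    """|Spearman rho| between fitted sigma and randomized noise level."""
    rng = np.random.default_rng(seed)
    stim = make_bar_stimulus()
    fitter = PRFFitter(stim)
    prfs = _random_prfs(rng, n_voxels)
    noise = np.exp(rng.uniform(*np.log(noise_range), n_voxels))
    fitted = [
        fitter.fit(simulate_bold(p, stim, noise_sd=ns, rng=rng)).sigma
        for p, ns in zip(prfs, noise)
    ]
    resid = np.log(fitted) - np.log([p.sigma for p in prfs])
    return {
        "rho_sigma_vs_noise": st.spearman_rho(fitted, noise),
        "rho_sigma_error_vs_noise": st.spearman_rho(resid, noise),
        "n": n_voxels,
    }


def staircase_fixed_point(n_runs=500, alphas=(0.1, 0.3, 0.6), seed=0):
    """Mean staircase threshold vs the 70.7%-correct fixed point.

    The fixed point is solved numerically from the psychometric function;
    bias is |mean threshold − fixed point| / fixed point per observer.
    """
    out, biases = {}, []
    for alpha, s in zip(alphas, _sub_seeds(seed, len(alphas))):
        obs = PsychometricObserver((4.7, 90.0), alpha=alpha)
        fp = convergence_point(obs)
        rng = np.random.default_rng(s)
        thr = [
            run_staircase(obs, StaircaseConfig(), rng).threshold
            for _ in range(n_runs)
        ]
        bias = abs(float(np.mean(thr)) - fp) / fp
        out[alpha] = {"fixed_point": fp, "mean_threshold": float(np.mean(thr)),
                      "rel_bias": bias}
        biases.append(bias)
    return {"max_rel_bias": float(np.max(biases)), "per_alpha": out,
            "n": n_runs}


def coverage_and_b_recovery(seed=0, n=50_000, b_true=0.35,
                            b_grid=np.linspace(0.05, 2.0, 40)):
    """Closed-form coverage vs quadrature, and decay-rate round trip."""
    errs = []
    for b in b_grid:
        num, _ = integrate.quad(lambda x: np.exp(-b * x), 0.25, 7.2)
        den, _ = integrate.quad(lambda x: np.exp(-b * x), 0.0, np.inf)
        errs.append(abs(coverage_fraction(b) - num / den))
    ecc = sample_eccentricities(n, b_true, rng=np.random.default_rng(seed))
    fit = fit_exponential(ecc)
    return {
        "coverage_max_abs_err": float(np.max(errs)),
        "b_recovery_rel_err": abs(fit.b - b_true) / b_true,
        "n": n,
    }


def permutation_type1(n_sims=2000, n=20, n_perm=199, alpha=0.05, seed=0):
    """Rejection rate of the permutation Spearman test under independence."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_sims):
        x, y = rng.normal(size=n), rng.normal(size=n)
        _, p = st.permutation_pvalue(x, y, n_perm=n_perm, rng=rng)
        hits += p <= alpha
    return {"type1_rate": hits / n_sims, "n": n_sims}


def exhaustive_vs_sampled(n_datasets=20, n=6, n_perm=2000, seed=0):
    """Monte-Carlo p vs exhaustive p at n=6 (same data, both routes)."""
    rng = np.random.default_rng(seed)
    diffs, ok = [], True
    for _ in range(n_datasets):
        x, y = rng.normal(size=n), rng.normal(size=n)
        _, p_ex = st.permutation_pvalue(x, y, exhaustive_if_small=True)
        _, p_mc = st.permutation_pvalue(
            x, y, n_perm=n_perm, rng=rng, exhaustive_if_small=False
        )
        diffs.append(abs(p_mc - p_ex))
        se = np.sqrt(p_ex * (1 - p_ex) / n_perm)
        ok &= abs(p_mc - p_ex) <= 4 * se + 2 / n_perm
    return {"max_abs_diff": float(np.max(diffs)), "all_within_ci": bool(ok),
            "n": n_datasets}


def fwe_null_rate(n_sims=1000, family_size=6, n=20, n_perm=199, alpha=0.05,
                  seed=0):
    """Familywise error rate under a global-null family."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_sims):
        pairs = [
            (f"m{i}", rng.normal(size=n), rng.normal(size=n))
            for i in range(family_size)
        ]
        res = st.fwe_correct(pairs, n_perm=n_perm, rng=rng)
        hits += any(r.p_fwe <= alpha for r in res)
    return {"fwe_rate": hits / n_sims, "n": n_sims}


def _one_cohort_fixed_ecc(seed, n_perm=999, n_vertices=2000):
    cfg = CohortConfig(areas=("V1",), n_vertices=n_vertices, seed=seed)
    cohort = generate_cohort(cfg)
    ss = np.random.SeedSequence(seed ^ 0x5EED).spawn(
        cfg.n_participants + 1
    )
    maps = {
        pid: measure_thresholds(
            cohort.observers[pid], StaircaseConfig(),
            np.random.default_rng(s), participant_id=pid,
        )
        for pid, s in zip(cohort.participant_ids(), ss[:-1])
    }
    areas_by_pid = {
        a.participant_id: a.surface_area["V1"] for a in cohort.anatomy
    }
    return cohort, st.fixed_eccentricity_analysis(
        cohort.vertices, maps, areas_by_pid, area="V1",
        value_col="true_sigma", n_perm=n_perm,
        rng=np.random.default_rng(ss[-1]),
    )


def sign_recovery(n_cohorts=100, seed=0, n_perm=999, n_vertices=2000,
                  alpha=0.05):
    """End-to-end recovery of the planted association signs at 4.7 deg.

    Per seeded cohort, all five headline associations (width↔threshold +,
    width↔thickness +, width↔area −, threshold↔thickness +,
    threshold↔area −) must be sign-correct with FWE-corrected p below
    ``alpha``; the intra/inter variants must sign-match their totals.
    """
    ok_all, ok_var, n_rows = 0, 0, []
    for s in _sub_seeds(seed, n_cohorts):
        _, res = _one_cohort_fixed_ecc(s, n_perm, n_vertices)
        by = res.by_pair()
        heads = all(
            np.sign(by[pair].rho) == sgn and by[pair].p_fwe <= alpha
            for pair, sgn in HEADLINE_SIGNS.items()
        )
        variants = all(
            np.sign(by[v].rho) == np.sign(by[t].rho)
            for v, t in VARIANT_OF.items()
        )
        ok_all += heads
        ok_var += variants
        n_rows.append(len(res.table))
    return {
        "frac_all_signs_significant": ok_all / n_cohorts,
        "frac_variants_sign_match": ok_var / n_cohorts,
        "median_table_rows": float(np.median(n_rows)),
        "n": n_cohorts,
    }


def ecc_resolved_recovery(n_cohorts=50, seed=0, n_perm=999, n_vertices=2000,
                          alpha=0.05):
    """Slope/intercept–area recovery and per-bin thickness correlations.

    With the generator tying the width-vs-eccentricity slope to surface
    area, both the slope and the intercept of per-participant linear fits
    should correlate negatively with area; per-eccentricity-bin width↔
    thickness correlations (thickness-axis grid) should be positive; the
    goodness of fit should carry no systematic area correlation.
    """
    slope_ok = inter_ok = 0
    gof_sig = 0
    gof_rhos, bin_pos, bin_tot = [], 0, 0
    for s in _sub_seeds(seed, n_cohorts):
        cfg = CohortConfig(areas=("V1",), n_vertices=n_vertices, seed=s)
        cohort = generate_cohort(cfg)
        areas_by_pid = {
            a.participant_id: a.surface_area["V1"] for a in cohort.anatomy
        }
        rng = np.random.default_rng(s ^ 0x0DD5)
        g_p = st.build_grid(cohort.vertices, "true_sigma",
                            axis2="participant", area="V1")
        r_p = st.eccentricity_resolved_analysis(
            g_p, areas_by_pid, n_perm=n_perm, rng=rng
        ).by_pair()
        slope_ok += (r_p["slope~anatomy"].rho < 0
                     and r_p["slope~anatomy"].p_fwe <= alpha)
        inter_ok += (r_p["intercept~anatomy"].rho < 0
                     and r_p["intercept~anatomy"].p_fwe <= alpha)
        gof_rhos.append(r_p["gof~anatomy"].rho)
        gof_sig += r_p["gof~anatomy"].p_fwe <= alpha

        g_t = st.build_grid(cohort.vertices, "true_sigma",
                            axis2="thickness", area="V1")
        r_t = st.eccentricity_resolved_analysis(g_t, n_perm=n_perm, rng=rng)
        for r in r_t.results:
            if r.family == "per_ecc_bin":
                bin_tot += 1
                bin_pos += r.rho > 0
    return {
        "frac_slope_negative_significant": slope_ok / n_cohorts,
        "frac_intercept_negative_significant": inter_ok / n_cohorts,
        "frac_bin_thickness_positive": bin_pos / max(bin_tot, 1),
        "frac_gof_significant": gof_sig / n_cohorts,
        "mean_gof_rho": float(np.mean(gof_rhos)),
        "n": n_cohorts,
    }


def anatomy_contrast_power(seed=0, n_null=200, null_vertices=150):
    """Planted 0.3 mm deltas detected at n=20; null deltas give uniform p.

    The planted check uses the default cohort; the null check repeats the
    gyrus−sulcus parafovea contrast over cohorts generated with both deltas
    zero and KS-tests the p-values against U(0,1).
    """
    cohort = generate_cohort(
        CohortConfig(areas=("V1",), n_vertices=1000, seed=seed)
    )
    planted = folding_eccentricity_contrast(cohort.vertices, area="V1")
    min_T = min(c.T for c in planted.values())
    max_p = max(c.p for c in planted.values())

    null_cfg = dataclasses.replace(
        CohortConfig(areas=("V1",), n_vertices=null_vertices),
        thickness_gyrus_delta=0.0, thickness_perifovea_delta=0.0,
    )
    pvals = []
    for s in _sub_seeds(seed + 1, n_null):
        c = generate_cohort(dataclasses.replace(null_cfg, seed=s))
        res = folding_eccentricity_contrast(c.vertices, area="V1")
        pvals.append(res["gyrus_minus_sulcus_parafovea"].p)
    ks = kstest(pvals, "uniform")
    return {
        "planted_min_T": float(min_T),
        "planted_max_p": float(max_p),
        "null_p_ks_pvalue": float(ks.pvalue),
        "n": 20,
    }


def cohort_calibration(seed=0, n_fit_voxels=120, snr=1.0):
    """Soft calibration of the default cohort against the published scale.

    Reports (does not assert): the fitted-sigma distribution of a random
    voxel subsample refit at the default SNR, per-participant retinotopy
    coverage fractions, and the span of the thickness distribution.
    """
    cohort = generate_cohort(CohortConfig(seed=seed))
    v1 = cohort.vertices[cohort.vertices["area"] == "V1"]
    rng = np.random.default_rng(seed + 1)
    stim = make_bar_stimulus()
    fitter = PRFFitter(stim)
    idx = rng.choice(
        v1.index[v1["eccentricity"] <= 6.5].to_numpy(), n_fit_voxels,
        replace=False,
    )
    fitted = []
    for i in idx:
        row = v1.loc[i]
        th = np.deg2rad(row["polar_angle"])
        prf = PRFParams(
            row["eccentricity"] * np.cos(th),
            row["eccentricity"] * np.sin(th),
            max(row["true_sigma"], 0.05),
        )
        series = simulate_bold(prf, stim, noise_sd=prf.amplitude / snr,
                               rng=rng)
        fitted.append(fitter.fit(series).sigma)
    coverages = [
        fit_exponential(
            v1[v1["participant_id"] == pid]["eccentricity"]
        ).coverage_fraction
        for pid in cohort.participant_ids()
    ]
    thick = cohort.vertices["thickness"]
    return {
        "fitted_sigma_mean": float(np.mean(fitted)),
        "fitted_sigma_sd": float(np.std(fitted)),
        "coverage_fraction_mean": float(np.mean(coverages)),
        "thickness_p005": float(thick.quantile(0.005)),
        "thickness_p995": float(thick.quantile(0.995)),
        "n": len(fitted),
    }
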