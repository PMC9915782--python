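"""Monte-Carlo calibration studies for the MR estimators.

These routines re-run the full pipeline — simulate a study, estimate LD
from the reference panel, screen instruments, fit — many times with
known truth, and summarize recovery, CI coverage, type-I error, Egger
pleiotropy detection, and the behaviour of the KS multiplicity screen.
They are what the package's own validation (and anyone auditing it)
runs; every number is computed at call time from the given seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .estimators import EGGER, gls_egger, gls_ivw, select_model
from .instruments import SelectionConfig, clump
from .ld import compute_ld
from .scan import ks_uniform
from .simulate import (
    AR1,
    Independent,
    NoPleiotropy,
    Pleiotropy,
    SimConfig,
    simulate,
    simulate_grid,
)


@dataclass
class RecoveryStudy:
    """Per-rep IVW and Egger summaries of a repeated-simulation study."""

    slopes: np.ndarray
    slope_ses: np.ndarray
    covered: np.ndarray  # 95% CI contains the true slope
    rejected: np.ndarray  # two-sided p < 0.05
    egger_intercepts: np.ndarray
    egger_selected: np.ndarray  # Rucker/Bowden verdict per rep
    n_instruments: np.ndarray
    true_slope: float

    @property
    def mean_slope(self) -> float:
        return float(self.slopes.mean())

    @property
    def mc_se(self) -> float:
        return float(self.slopes.std(ddof=1) / np.sqrt(self.slopes.size))

    @property
    def coverage(self) -> float:
        return float(self.covered.mean())

    @property
    def rejection_rate(self) -> float:
        return float(self.rejected.mean())

    @property
    def intercept_mean(self) -> float:
        return float(self.egger_intercepts.mean())

    @property
    def intercept_mc_se(self) -> float:
        return float(
            self.egger_intercepts.std(ddof=1) / np.sqrt(self.egger_intercepts.size)
        )

    @property
    def egger_selection_rate(self) -> float:
        return float(self.egger_selected.mean())


def screened_fit(study, selection: SelectionConfig = SelectionConfig(),
                 use_panel_ld: bool = True):
    """F/MAF screen + clump + GLS-IVW and GLS-Egger for one simulated study.

    LD comes from the study's reference panel (conditioned to PD) unless
    ``use_panel_ld`` is false, in which case the generative truth is used.
    Returns ``(fit_ivw, fit_egger)``; Egger is None below 3 instruments.
    """
    bx = np.array([r.beta for r in study.exposure_stats])
    sx = np.array([r.se for r in study.exposure_stats])
    by = np.array([r.beta for r in study.outcome_stats])
    sy = np.array([r.se for r in study.outcome_stats])
    ids = np.array([r.variant_id for r in study.exposure_stats])
    pvals = np.array([r.pval for r in study.exposure_stats])
    mafs = np.minimum(study.truth.mafs, 1 - study.truth.mafs)

    keep = ((bx / sx) ** 2 > selection.f_min) & (mafs >= selection.maf_min)
    if not keep.any():
        raise ValueError("no instruments pass the strength/frequency screens")
    if use_panel_ld:
        ld = compute_ld(study.panel, list(ids[keep]))
    else:
        ld = study.truth.ld.subset(list(ids[keep]))
    retained = clump(dict(zip(ids[keep], pvals[keep])), ld, selection)
    order = [list(ids).index(v) for v in retained]
    bxs, bys, sys_ = bx[order], by[order], sy[order]
    ld_sub = ld.subset(retained)

    fit_ivw = gls_ivw(bxs, bys, sys_, ld_sub, instrument_ids=tuple(retained))
    fit_egger = (
        gls_egger(bxs, bys, sys_, ld_sub, instrument_ids=tuple(retained))
        if len(retained) >= 3
        else None
    )
    return fit_ivw, fit_egger


def ivw_recovery_study(
    true_slope: float,
    reps: int,
    seed: int,
    k: int = 50,
    rho: float = 0.5,
    n_gwas: int = 50000,
    n_panel: int = 2000,
    pleiotropy: Pleiotropy = NoPleiotropy(),
    alpha_sel: float = 0.05,
) -> RecoveryStudy:
    """Repeatedly simulate, screen, and fit; collect estimator summaries.

    The design follows the package's reference study conditions:
    ``k`` AR(1)-correlated instruments (lag-1 correlation ``rho``),
    exposure and outcome GWAS of ``n_gwas`` subjects, LD estimated from
    an ``n_panel``-subject reference panel.
    """
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s) for s in ss.generate_state(reps) >> 1]
    slopes = np.empty(reps)
    ses = np.empty(reps)
    covered = np.zeros(reps, dtype=bool)
    rejected = np.zeros(reps, dtype=bool)
    intercepts = np.full(reps, np.nan)
    egger_sel = np.zeros(reps, dtype=bool)
    n_used = np.empty(reps, dtype=int)
    for i in range(reps):
        cfg = SimConfig(
            k_variants=k,
            seed=child_seeds[i],
            n_panel=n_panel,
            n_exposure_gwas=n_gwas,
            n_outcome_gwas=n_gwas,
            ld_structure=AR1(rho) if rho else Independent(),
            true_slope=true_slope,
            pleiotropy=pleiotropy,
        )
        study = simulate(cfg)
        fit_ivw, fit_egger = screened_fit(study)
        slopes[i] = fit_ivw.slope
        ses[i] = fit_ivw.slope_se
        covered[i] = fit_ivw.ci_low <= true_slope <= fit_ivw.ci_high
        rejected[i] = fit_ivw.pval < 0.05
        n_used[i] = fit_ivw.n_instruments_used
        if fit_egger is not None:
            intercepts[i] = fit_egger.intercept
            egger_sel[i] = select_model(fit_ivw, fit_egger, alpha_sel) == EGGER
    return RecoveryStudy(
        slopes=slopes,
        slope_ses=ses,
        covered=covered,
        rejected=rejected,
        egger_intercepts=intercepts,
        egger_selected=egger_sel,
        n_instruments=n_used,
        true_slope=true_slope,
    )


def ks_screen_study(
    reps: int,
    seed: int,
    n_outcomes: int = 20,
    n_signal: int = 0,
    signal_slope: float = 0.3,
    k: int = 20,
    n_gwas: int = 50000,
) -> np.ndarray:
    """KS p-value of each of ``reps`` scans of one exposure vs many outcomes.

    Each scan simulates ``n_outcomes`` outcome GWAS sharing one exposure;
    the first ``n_signal`` outcomes carry a true causal slope, the rest
    are null. Per-pair IVW p-values (true-LD GLS on all variants) are
    screened for uniformity; the array of per-scan KS p-values is
    returned.
    """
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s) for s in ss.generate_state(reps) >> 1]
    slopes = [signal_slope] * n_signal + [0.0] * (n_outcomes - n_signal)
    ks_ps = np.empty(reps)
    for i in range(reps):
        grid = simulate_grid(
            SimConfig(k_variants=k, seed=child_seeds[i], n_panel=2,
                      n_exposure_gwas=n_gwas, n_outcome_gwas=n_gwas),
            outcome_slopes=slopes,
        )
        bx = np.array([r.beta for r in grid.exposure_stats])
        pvals = []
        for recs in grid.outcome_stats:
            by = np.array([r.beta for r in recs])
            sy = np.array([r.se for r in recs])
            pvals.append(gls_ivw(bx, by, sy, grid.truth.ld).pval)
        ks_ps[i] = ks_uniform(pvals)[1]
    return ks_ps
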