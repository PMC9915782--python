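"""Phenome-wide MR scanning with multiplicity screening.

Runs the per-pair pipeline over an exposure x outcome grid, flags rows at
the primary (0.05) and multiplicity-corrected alpha levels, and screens
each exposure's p-value set against the standard uniform with a
Kolmogorov-Smirnov test: under a global null the MR p-values are U(0,1),
so an exposure whose p-values pass the KS screen is unlikely to owe its
hits to multiple testing alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import DiagnosticsConfig
from .harmonize import SummaryStatRecord
from .instruments import SelectionConfig
from .ld import GenotypePanel, LDMatrix
from .pipeline import run_pair


@dataclass(frozen=True)
class ThresholdConfig:
    """Significance and screening thresholds for a scan.

    ``alpha_corrected`` defaults to 1.25e-2, the multiplicity-corrected
    level quoted for 20 non-cardiac traits in the source setting (note
    0.05/20 would be 2.5e-3; the quoted value is kept configurable for
    exactly that reason).
    """

    alpha_primary: float = 0.05
    alpha_corrected: float = 1.25e-2
    ks_alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha_corrected <= self.alpha_primary <= 1.0:
            raise ValueError("need 0 < alpha_corrected <= alpha_primary <= 1")
        if not 0.0 < self.ks_alpha < 1.0:
            raise ValueError("ks_alpha must lie in (0, 1)")


@dataclass
class TraitSource:
    """One GWAS in a scan: an id, its records, and presentation flags."""

    trait_id: str
    records: list[SummaryStatRecord]
    binary: bool = False
    group: str | None = None


@dataclass
class ScanResult:
    """Grid of per-pair MR results with multiplicity flags and KS screen."""

    table: pd.DataFrame
    ks: pd.DataFrame  # per exposure: D, pval, n_pvals
    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig)

    def to_files(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(out_dir / "scan.tsv", sep="\t", index=False,
                          float_format="%.17g")
        self.ks.to_csv(out_dir / "ks.tsv", sep="\t", index=False,
                       float_format="%.17g")
        payload = {
            "thresholds": {
                "alpha_primary": self.thresholds.alpha_primary,
                "alpha_corrected": self.thresholds.alpha_corrected,
                "ks_alpha": self.thresholds.ks_alpha,
            },
            "rows": json.loads(self.table.to_json(orient="records")),
            "ks": json.loads(self.ks.to_json(orient="records")),
        }
        (out_dir / "scan.json").write_text(json.dumps(payload, indent=1))


def ks_uniform(pvals: Sequence[float]) -> tuple[float, float]:
    """One-sample two-sided KS statistic of p-values against U(0,1).

    Exact p-value for n <= 35, asymptotic otherwise. Empty input is a
    hard error; values must lie in (0, 1].
    """
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        raise ValueError("ks_uniform requires a nonempty p-value collection")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    method = "exact" if p.size <= 35 else "asymp"
    res = stats.kstest(p, stats.uniform.cdf, method=method)
    return float(res.statistic), float(res.pvalue)


def run_scan(
    exposures: Iterable[TraitSource],
    outcomes: Iterable[TraitSource],
    panel: GenotypePanel | LDMatrix,
    selection: SelectionConfig = SelectionConfig(),
    diag_cfg: DiagnosticsConfig = DiagnosticsConfig(),
    thresholds: ThresholdConfig = ThresholdConfig(),
    palindromic_eaf_window: float = 0.08,
    alpha_sel: float = 0.05,
) -> ScanResult:
    """One MR run per exposure/outcome pair with failure isolation.

    Failed pairs (for example, no surviving instruments) are kept as
    rows with ``status='failed'`` and a reason, and the scan continues;
    only a scan in which every pair fails raises. Rows are emitted in
    deterministic order (exposures outer, outcomes inner, input order).
    """
    exposures = list(exposures)
    outcomes = list(outcomes)
    if not exposures or not outcomes:
        raise ValueError("need at least one exposure and one outcome")

    rows = []
    n_ok = 0
    for exp in exposures:
        for out in outcomes:
            row = {
                "exposure_id": exp.trait_id,
                "outcome_id": out.trait_id,
                "exposure_group": exp.group,
                "status": "ok",
                "reason": None,
                "method": None,
                "slope": np.nan,
                "slope_se": np.nan,
                "ci_low": np.nan,
                "ci_high": np.nan,
                "pval": np.nan,
                "intercept": np.nan,
                "intercept_p": np.nan,
                "q_ivw": np.nan,
                "q_egger": np.nan,
                "n_instruments": 0,
                "or_ci_text": None,
                "significant_primary": False,
                "significant_corrected": False,
            }
            try:
                res = run_pair(
                    exp.records,
                    out.records,
                    panel,
                    selection=selection,
                    diag_cfg=diag_cfg,
                    palindromic_eaf_window=palindromic_eaf_window,
                    alpha_sel=alpha_sel,
                    binary_outcome=out.binary,
                )
            except (ValueError, KeyError) as err:
                row["status"] = "failed"
                row["reason"] = str(err)
                rows.append(row)
                continue
            sel = res.selected_fit
            row.update(
                method=res.selected_method,
                slope=sel.slope,
                slope_se=sel.slope_se,
                ci_low=sel.ci_low,
                ci_high=sel.ci_high,
                pval=sel.pval,
                q_ivw=res.fit_ivw.q_stat,
                q_egger=res.fit_egger.q_stat if res.fit_egger else np.nan,
                n_instruments=sel.n_instruments_used,
                or_ci_text=res.or_ci_text,
                significant_primary=bool(sel.pval < thresholds.alpha_primary),
                significant_corrected=bool(sel.pval < thresholds.alpha_corrected),
            )
            if res.fit_egger is not None and res.selected_method == "Egger":
                row["intercept"] = res.fit_egger.intercept
                row["intercept_p"] = res.fit_egger.intercept_p
            n_ok += 1
            rows.append(row)

    if n_ok == 0:
        raise ValueError("all exposure/outcome pairs failed")

    table = pd.DataFrame(rows)
    ks_rows = []
    for exp in exposures:
        sub = table[(table.exposure_id == exp.trait_id) & (table.status == "ok")]
        if len(sub) == 0:
            ks_rows.append(
                {"exposure_id": exp.trait_id, "D": np.nan, "pval": np.nan, "n_pvals": 0}
            )
            continue
        d, p = ks_uniform(sub.pval.to_numpy())
        ks_rows.append(
            {"exposure_id": exp.trait_id, "D": d, "pval": p, "n_pvals": len(sub)}
        )
    ks = pd.DataFrame(ks_rows)
    return ScanResult(table=table, ks=ks, thresholds=thresholds)


def pooled_ks(scan: ScanResult) -> tuple[float, float]:
    """KS uniformity screen pooled over every successful row of a scan."""
    ok = scan.table[scan.table.status == "ok"]
    return ks_uniform(ok.pval.to_numpy())


def count_significant(
    scan: ScanResult,
    group_by: Mapping[str, str] | None = None,
    corrected: bool = False,
) -> pd.Series:
    """Per-group counts of significant rows.

    ``group_by`` maps exposure ids to group labels (for example cardiac
    chamber); by default each exposure's own ``exposure_group`` (or its
    id) is used. An exposure without a label is a hard error.
    """
    flag = "significant_corrected" if corrected else "significant_primary"
    tbl = scan.table
    if group_by is not None:
        unknown = sorted(set(tbl.exposure_id) - set(group_by))
        if unknown:
            raise KeyError(f"unknown group label for exposures: {unknown}")
        labels = tbl.exposure_id.map(group_by)
    else:
        labels = tbl.exposure_group.fillna(tbl.exposure_id)
    return tbl.groupby(labels, sort=True)[flag].sum().astype(int)


def heat_grid(scan: ScanResult, truncate_at: float = 8.0) -> pd.DataFrame:
    """Sign x -log10(p) grid (exposures as rows), truncated for display."""
    ok = scan.table[scan.table.status == "ok"].copy()
    ok["cell"] = np.sign(ok.slope) * np.minimum(
        -np.log10(np.maximum(ok.pval, 1e-300)), truncate_at
    )
    return ok.pivot(index="exposure_id", columns="outcome_id", values="cell")
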