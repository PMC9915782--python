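"""End-to-end MR for one exposure/outcome pair.

Chains harmonization, instrument selection, LD estimation, the GLS
estimators with diagnostics, and Rucker/Bowden model selection into a
single call that mirrors how the package is used in practice.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .estimators import (
    EGGER,
    IVW,
    DiagnosticsConfig,
    MRFit,
    diagnostics,
    format_or_ci,
    gls_egger,
    select_model,
    to_odds_ratio,
)
from .harmonize import HarmonizeResult, SummaryStatRecord, harmonize
from .instruments import SelectionConfig, select_instruments
from .ld import GenotypePanel, LDMatrix, compute_ld


class NoInstrumentsError(ValueError):
    """No instrument survives harmonization and selection."""


@dataclass
class PairResult:
    """Both fits, the selection verdict, and the selection report for a pair."""

    fit_ivw: MRFit
    fit_egger: MRFit | None
    selected_method: str
    harmonization: HarmonizeResult
    retained_ids: list[str]
    or_ci_text: str | None = None

    @property
    def selected_fit(self) -> MRFit:
        if self.selected_method == EGGER and self.fit_egger is not None:
            return self.fit_egger
        return self.fit_ivw

    def to_dict(self) -> dict:
        sel = self.selected_fit
        d = {
            "selected_method": self.selected_method,
            "ivw": self.fit_ivw.to_dict(),
            "egger": self.fit_egger.to_dict() if self.fit_egger else None,
            "drop_counts": self.harmonization.drop_counts,
            "retained_ids": list(self.retained_ids),
            "slope": sel.slope,
            "slope_se": sel.slope_se,
            "pval": sel.pval,
        }
        if self.or_ci_text is not None:
            d["or_ci_text"] = self.or_ci_text
            d["odds_ratio"] = to_odds_ratio(sel.slope, sel.slope_se)
        return d


def run_pair(
    exposure: Iterable[SummaryStatRecord],
    outcome: Iterable[SummaryStatRecord],
    panel: GenotypePanel | LDMatrix,
    selection: SelectionConfig = SelectionConfig(),
    diag_cfg: DiagnosticsConfig = DiagnosticsConfig(),
    palindromic_eaf_window: float = 0.08,
    alpha_sel: float = 0.05,
    binary_outcome: bool = False,
) -> PairResult:
    """Full LD-aware MR of one exposure against one outcome.

    ``panel`` may be a reference :class:`GenotypePanel` (LD is estimated
    from it) or a precomputed :class:`LDMatrix`. Diagnostics are run
    under the IVW model; both estimators are then fit on the cleaned
    instrument set so the Rucker/Bowden selection compares like with
    like. Raises :class:`NoInstrumentsError` when nothing survives.
    """
    harm = harmonize(exposure, outcome, palindromic_eaf_window)
    if not harm.instruments:
        raise NoInstrumentsError("no shared variants after harmonization")

    if isinstance(panel, LDMatrix):
        ld_all = panel
        panel_freq = None
    else:
        avail = set(panel.variant_ids)
        harm.instruments = [h for h in harm.instruments if h.variant_id in avail]
        if not harm.instruments:
            raise NoInstrumentsError("no harmonized variants present in the panel")
        ld_all = compute_ld(panel, [h.variant_id for h in harm.instruments])
        panel_freq = panel.frequencies()

    retained, _report = select_instruments(
        harm.instruments, ld_all, selection, panel_freq
    )
    if not retained:
        raise NoInstrumentsError("no instruments pass the F/MAF screens")

    by_id = {h.variant_id: h for h in harm.instruments}
    bx = np.array([by_id[v].beta_exp for v in retained])
    by = np.array([by_id[v].beta_out for v in retained])
    sy = np.array([by_id[v].se_out for v in retained])
    ld = ld_all.subset(retained)

    fit_ivw = diagnostics(
        bx, by, sy, ld, model=IVW, cfg=diag_cfg, instrument_ids=tuple(retained)
    )
    used = list(fit_ivw.instrument_ids)
    if len(used) < len(retained):
        keep = [v in set(used) for v in retained]
        bx, by, sy = bx[keep], by[keep], sy[keep]
        ld = ld.subset(used)

    fit_egger = (
        gls_egger(bx, by, sy, ld, instrument_ids=tuple(used))
        if len(used) >= 3
        else None
    )
    method = select_model(fit_ivw, fit_egger, alpha_sel)
    result = PairResult(
        fit_ivw=fit_ivw,
        fit_egger=fit_egger,
        selected_method=method,
        harmonization=harm,
        retained_ids=list(fit_ivw.instrument_ids),
    )
    if binary_outcome:
        sel = result.selected_fit
        result.or_ci_text = format_or_ci(sel.slope, sel.slope_se)
    return result
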