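"""Instrument selection: strength and frequency screens, greedy LD clumping.

Instruments are kept when the single-variant F-statistic (squared z-score)
exceeds ``f_min`` and the minor allele frequency is at least ``maf_min``,
then thinned greedily by exposure p-value so that every retained pair of
variants has squared LD correlation at most ``r2_max``. Residual
correlation among the retained instruments (up to ``r2_max``) is later
absorbed by the GLS covariance rather than removed here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .harmonize import HarmonizedInstrument
from .ld import LDMatrix


@dataclass(frozen=True)
class SelectionConfig:
    f_min: float = 24.0
    maf_min: float = 0.01
    r2_max: float = 0.30

    def __post_init__(self) -> None:
        if not self.f_min > 0:
            raise ValueError("f_min must be positive")
        if not 0.0 < self.maf_min < 0.5:
            raise ValueError("maf_min must lie in (0, 0.5)")
        if not 0.0 < self.r2_max <= 1.0:
            raise ValueError("r2_max must lie in (0, 1]")


def f_statistic(beta, se):
    """Single-variant instrument-strength F-statistic, (beta/se)^2."""
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("se must be positive")
    out = (beta / se) ** 2
    return float(out) if out.ndim == 0 else out


def maf(eaf):
    """Minor allele frequency, min(eaf, 1 - eaf)."""
    eaf = np.asarray(eaf, dtype=float)
    if np.any((eaf <= 0) | (eaf >= 1)):
        raise ValueError("eaf must lie in (0, 1)")
    out = np.minimum(eaf, 1.0 - eaf)
    return float(out) if out.ndim == 0 else out


def clump(
    pvals: Mapping[str, float],
    ld: LDMatrix,
    cfg: SelectionConfig = SelectionConfig(),
) -> list[str]:
    """Greedy LD clumping of candidates keyed by exposure p-value.

    Repeatedly retain the remaining candidate with the smallest p-value
    (ties broken lexicographically by variant id) and discard every
    remaining candidate whose squared correlation with it exceeds
    ``cfg.r2_max``. The retained list is returned in retention order;
    every retained pair satisfies r^2 <= r2_max.
    """
    if not pvals:
        raise ValueError("no instruments: empty candidate set")
    idx = ld.indices(list(pvals))  # validates presence
    pos = dict(zip(pvals, idx))
    remaining = sorted(pvals, key=lambda v: (pvals[v], v))
    retained: list[str] = []
    while remaining:
        lead = remaining.pop(0)
        retained.append(lead)
        i = pos[lead]
        remaining = [v for v in remaining if ld.r[i, pos[v]] ** 2 <= cfg.r2_max]
    return retained


def select_instruments(
    instruments: Sequence[HarmonizedInstrument],
    ld: LDMatrix,
    cfg: SelectionConfig = SelectionConfig(),
    panel_freq: Mapping[str, float] | None = None,
) -> tuple[list[str], pd.DataFrame]:
    """Apply the F, MAF and clumping screens to harmonized instruments.

    MAF is assessed on the exposure effect-allele frequency, falling back
    to the reference-panel frequency when the GWAS one is missing; a
    variant with neither is removed. Returns the retained ids (clump
    order) and a per-variant report with columns variant_id, F, MAF,
    status and removed_by.
    """
    rows = []
    candidates: dict[str, float] = {}
    for h in instruments:
        F = f_statistic(h.beta_exp, h.se_exp)
        eaf = h.eaf if h.eaf is not None else (panel_freq or {}).get(h.variant_id)
        m = maf(eaf) if eaf is not None else None
        removed_by = None
        if F <= cfg.f_min:
            removed_by = "f_min"
        elif m is None:
            removed_by = "missing_eaf"
        elif m < cfg.maf_min:
            removed_by = "maf_min"
        rows.append(
            {"variant_id": h.variant_id, "F": F, "MAF": m, "removed_by": removed_by}
        )
        if removed_by is None:
            candidates[h.variant_id] = h.pval_exp

    retained = clump(candidates, ld, cfg) if candidates else []
    retained_set = set(retained)
    for row in rows:
        if row["removed_by"] is None and row["variant_id"] not in retained_set:
            row["removed_by"] = "clump"
        row["status"] = "retained" if row["variant_id"] in retained_set else "removed"
    report = pd.DataFrame(rows, columns=["variant_id", "F", "MAF", "status", "removed_by"])
    return retained, report
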