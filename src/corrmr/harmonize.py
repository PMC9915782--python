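"""Reading GWAS summary statistics and two-sample allele harmonization.

Two-sample Mendelian randomization combines per-variant effect estimates
from an exposure GWAS and an outcome GWAS. Before any estimation the two
sets of records must refer to the same effect allele per variant: this
module reads tab/whitespace-delimited summary-statistic files and aligns
outcome records to the exposure's effect allele, handling allele swaps,
strand complements, and ambiguous palindromic (A/T, G/C) variants.
"""

from __future__ import annotations

import gzip
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy.stats import norm

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
#: allele pairs that are their own strand complement
PALINDROMIC_PAIRS = frozenset({("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")})

#: standard column names; a column_map may rename any of them to the
#: header actually present in the file
STANDARD_COLUMNS = (
    "variant_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
)
MANDATORY_COLUMNS = ("variant_id", "effect_allele", "other_allele", "beta", "se")


@dataclass(frozen=True)
class SummaryStatRecord:
    """One variant's association estimate in one GWAS.

    ``beta`` is the per-allele effect of ``effect_allele`` (log-odds for
    binary traits); ``eaf`` its frequency. ``se`` must be positive.
    """

    variant_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    chrom: str | None = None
    pos: int | None = None
    eaf: float | None = None
    pval: float | None = None
    n: int | None = None

    def __post_init__(self) -> None:
        if self.effect_allele not in VALID_ALLELES:
            raise ValueError(f"invalid effect allele {self.effect_allele!r}")
        if self.other_allele not in VALID_ALLELES:
            raise ValueError(f"invalid other allele {self.other_allele!r}")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.variant_id}: effect and other allele are equal")
        if not self.se > 0:
            raise ValueError(f"{self.variant_id}: se must be positive, got {self.se}")
        if self.eaf is not None and not 0.0 < self.eaf < 1.0:
            raise ValueError(f"{self.variant_id}: eaf must lie in (0,1), got {self.eaf}")
        if self.pval is not None and not 0.0 < self.pval <= 1.0:
            raise ValueError(f"{self.variant_id}: pval must lie in (0,1], got {self.pval}")

    @property
    def zscore(self) -> float:
        return self.beta / self.se

    @property
    def palindromic(self) -> bool:
        return (self.effect_allele, self.other_allele) in PALINDROMIC_PAIRS


@dataclass(frozen=True)
class HarmonizedInstrument:
    """An exposure/outcome-aligned variant sharing one effect allele.

    ``flipped`` records whether the raw outcome beta sign and frequency
    were inverted to reach the exposure's allele orientation.
    """

    variant_id: str
    effect_allele: str
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float
    eaf: float | None
    flipped: bool
    palindromic: bool

    @property
    def pval_exp(self) -> float:
        """Two-sided normal p-value of the exposure association."""
        return float(2.0 * norm.sf(abs(self.beta_exp / self.se_exp)))


@dataclass
class ReadResult:
    """Parsed summary statistics plus a count of skipped malformed rows."""

    records: list[SummaryStatRecord]
    n_skipped: int = 0

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class HarmonizeResult:
    """Harmonized instruments plus drop counts keyed by reason."""

    instruments: list[HarmonizedInstrument]
    drop_counts: dict[str, int] = field(default_factory=dict)

    def __iter__(self):
        return iter(self.instruments)

    def __len__(self) -> int:
        return len(self.instruments)


def _to_float(value) -> float | None:
    try:
        x = float(value)
    except (TypeError, ValueError):
        return None
    if math.isnan(x):
        return None
    return x


def read_sumstats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> ReadResult:
    """Read a whitespace/tab-delimited GWAS summary-statistics file.

    Parameters
    ----------
    path
        Text file (gzip transparently supported) with a header row.
    column_map
        Optional mapping from the standard names (``variant_id``, ``chrom``,
        ``pos``, ``effect_allele``, ``other_allele``, ``eaf``, ``beta``,
        ``se``, ``pval``, ``n``) to the header names actually present.

    Rows with non-numeric (or non-positive-``se``) effect estimates are
    skipped and counted; alleles are uppercased. A missing mandatory
    column raises ``ValueError`` naming it.
    """
    path = Path(path)
    colmap = dict.fromkeys(STANDARD_COLUMNS)
    for std in STANDARD_COLUMNS:
        colmap[std] = (column_map or {}).get(std, std)

    df = pd.read_csv(path, sep=r"\s+", dtype=str, compression="infer")
    for std in MANDATORY_COLUMNS:
        if colmap[std] not in df.columns:
            raise ValueError(
                f"{path}: mandatory column {colmap[std]!r} (for {std!r}) not found"
            )

    records: list[SummaryStatRecord] = []
    n_skipped = 0
    n_pval_inconsistent = 0
    for row in df.itertuples(index=False):
        row = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        get = lambda std: row.get(colmap[std]) if colmap[std] in row else None  # noqa: E731
        beta = _to_float(get("beta"))
        se = _to_float(get("se"))
        ea = str(get("effect_allele")).upper()
        oa = str(get("other_allele")).upper()
        if (
            beta is None
            or se is None
            or se <= 0
            or ea not in VALID_ALLELES
            or oa not in VALID_ALLELES
            or ea == oa
        ):
            n_skipped += 1
            continue
        eaf = _to_float(get("eaf"))
        if eaf is not None and not 0.0 < eaf < 1.0:
            eaf = None
        pval = _to_float(get("pval"))
        if pval is not None and not 0.0 < pval <= 1.0:
            pval = None
        n_val = _to_float(get("n"))
        pos = _to_float(get("pos"))
        chrom = get("chrom")
        records.append(
            SummaryStatRecord(
                variant_id=str(get("variant_id")),
                chrom=None if chrom is None or pd.isna(chrom) else str(chrom),
                pos=None if pos is None else int(pos),
                effect_allele=ea,
                other_allele=oa,
                eaf=eaf,
                beta=beta,
                se=se,
                pval=pval,
                n=None if n_val is None else int(n_val),
            )
        )
        # loose consistency screen: reported p vs two-sided normal from z
        if pval is not None and pval > 1e-300:
            expected = 2.0 * norm.sf(abs(beta / se))
            if expected > 1e-300:
                if abs(math.log10(pval) - math.log10(expected)) > 1.0:
                    n_pval_inconsistent += 1

    if n_skipped:
        logger.warning("%s: skipped %d malformed rows", path, n_skipped)
    if n_pval_inconsistent:
        logger.warning(
            "%s: %d rows have p-values loosely inconsistent with beta/se",
            path,
            n_pval_inconsistent,
        )
    return ReadResult(records=records, n_skipped=n_skipped)


def _index_by_id(records: Iterable[SummaryStatRecord], label: str):
    out: dict[str, SummaryStatRecord] = {}
    for rec in records:
        if rec.variant_id in out:
            raise ValueError(f"duplicate variant_id {rec.variant_id!r} in {label} input")
        out[rec.variant_id] = rec
    return out


def harmonize(
    exposure: Iterable[SummaryStatRecord],
    outcome: Iterable[SummaryStatRecord],
    palindromic_eaf_window: float = 0.08,
) -> HarmonizeResult:
    """Align outcome records to the exposure's effect allele per variant.

    Only variants present in both inputs are considered. Alleles are
    matched directly, after orientation swap (outcome beta negated, eaf
    reflected), or after strand complementation. Palindromic variants
    (A/T, G/C) are kept only when both effect-allele frequencies lie
    outside ``0.5 +/- palindromic_eaf_window`` and fall on the same side
    of 0.5; otherwise they are dropped as strand-ambiguous. Dropped
    variants are tallied by reason in ``drop_counts``.
    """
    exp_by_id = _index_by_id(exposure, "exposure")
    out_by_id = _index_by_id(outcome, "outcome")

    instruments: list[HarmonizedInstrument] = []
    drops = {
        "palindromic_ambiguous": 0,
        "palindromic_missing_eaf": 0,
        "incompatible_alleles": 0,
    }
    w = palindromic_eaf_window

    for vid, e in exp_by_id.items():
        o = out_by_id.get(vid)
        if o is None:
            continue
        ea, oa = e.effect_allele, e.other_allele
        o_pair = (o.effect_allele, o.other_allele)

        if e.palindromic:
            if o_pair not in ((ea, oa), (oa, ea)):
                drops["incompatible_alleles"] += 1
                continue
            if e.eaf is None or o.eaf is None:
                drops["palindromic_missing_eaf"] += 1
                continue
            if o_pair == (ea, oa):
                beta_out, eaf_out, flipped = o.beta, o.eaf, False
            else:
                beta_out, eaf_out, flipped = -o.beta, 1.0 - o.eaf, True
            near_half = abs(e.eaf - 0.5) <= w or abs(eaf_out - 0.5) <= w
            same_side = (e.eaf - 0.5) * (eaf_out - 0.5) > 0
            if near_half or not same_side:
                drops["palindromic_ambiguous"] += 1
                continue
            palindromic = True
        else:
            comp_pair = (COMPLEMENT[ea], COMPLEMENT[oa])
            if o_pair == (ea, oa) or o_pair == comp_pair:
                beta_out, flipped = o.beta, False
                eaf_out = o.eaf
            elif o_pair == (oa, ea) or o_pair == (comp_pair[1], comp_pair[0]):
                beta_out, flipped = -o.beta, True
                eaf_out = None if o.eaf is None else 1.0 - o.eaf
            else:
                drops["incompatible_alleles"] += 1
                continue
            palindromic = False

        instruments.append(
            HarmonizedInstrument(
                variant_id=vid,
                effect_allele=ea,
                beta_exp=e.beta,
                se_exp=e.se,
                beta_out=beta_out,
                se_out=o.se,
                eaf=e.eaf if e.eaf is not None else eaf_out,
                flipped=flipped,
                palindromic=palindromic,
            )
        )

    return HarmonizeResult(instruments=instruments, drop_counts=drops)


def write_harmonized(result: HarmonizeResult, path: str | Path) -> None:
    """Write the harmonized table as TSV with a JSON sidecar of drop counts."""
    path = Path(path)
    df = pd.DataFrame(
        [
            {
                "variant_id": h.variant_id,
                "effect_allele": h.effect_allele,
                "beta_exp": h.beta_exp,
                "se_exp": h.se_exp,
                "beta_out": h.beta_out,
                "se_out": h.se_out,
                "eaf": h.eaf,
                "flipped": h.flipped,
                "palindromic": h.palindromic,
            }
            for h in result.instruments
        ]
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")
    sidecar = path.with_suffix(path.suffix + ".drops.json")
    sidecar.write_text(json.dumps(result.drop_counts, indent=2, sort_keys=True))


def write_sumstats(records: Sequence[SummaryStatRecord], path: str | Path) -> None:
    """Write records in the standard summary-statistics layout (TSV)."""
    path = Path(path)
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        fh.write("\t".join(STANDARD_COLUMNS) + "\n")
        for r in records:
            fh.write(
                "\t".join(
                    [
                        r.variant_id,
                        r.chrom if r.chrom is not None else "NA",
                        str(r.pos) if r.pos is not None else "NA",
                        r.effect_allele,
                        r.other_allele,
                        "NA" if r.eaf is None else format(r.eaf, ".17g"),
                        format(r.beta, ".17g"),
                        format(r.se, ".17g"),
                        "NA" if r.pval is None else format(r.pval, ".17g"),
                        "NA" if r.n is None else str(r.n),
                    ]
                )
                + "\n"
            )
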