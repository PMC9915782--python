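"""Synthetic GWAS summary statistics and reference panels with known truth.

The generator emulates the two-sample aggregate-data setting: a reference
panel of individual-level dosages carrying a chosen LD structure, plus
exposure and outcome summary statistics produced directly at the summary
level as (true marginal effect) + (correlated sampling noise) with
analytic standard errors for the stated GWAS sample sizes. The causal
model is linear: outcome marginal effects equal ``true_slope`` times the
exposure effects plus an optional per-variant horizontal-pleiotropy term.

Binary correlations between genotypes cannot exceed Frechet bounds set by
their allele frequencies, so correlated structures are built directly on
the allele scale: an AR(1) chain uses a stationary binary Markov chain
whose lag-l correlation is exactly rho**l, and exchangeable blocks use a
shared-ancestor copy construction with pairwise correlation exactly rho
(one allele frequency per block). This mirrors real LD, where strongly
correlated variants necessarily have similar allele frequencies.

Effect alleles are emitted oriented to the exposure-increasing direction
(exposure effects are half-normal), giving "directional" pleiotropy a
well-defined sign under the Egger intercept.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .harmonize import SummaryStatRecord, write_sumstats
from .ld import GenotypePanel, LDMatrix

#: non-palindromic allele pairs used for simulated variants
_ALLELE_PAIRS = (("A", "G"), ("G", "A"), ("C", "T"), ("T", "C"), ("A", "C"), ("G", "T"))

MIN_PVAL = 1e-300


@dataclass(frozen=True)
class Independent:
    """No LD: all variants mutually uncorrelated."""


@dataclass(frozen=True)
class AR1:
    """Autoregressive LD: corr(i, j) = rho ** |i - j| on the allele scale."""

    rho: float

    def __post_init__(self) -> None:
        if not abs(self.rho) < 1:
            raise ValueError("AR1 rho must satisfy |rho| < 1")


@dataclass(frozen=True)
class Blocks:
    """Exchangeable LD blocks: corr = rho within blocks of ``size`` variants."""

    size: int
    rho: float

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError("block size must be >= 1")
        if not 0.0 <= self.rho < 1:
            raise ValueError("block rho must lie in [0, 1)")


@dataclass(frozen=True)
class NoPleiotropy:
    pass


@dataclass(frozen=True)
class Balanced:
    """Horizontal pleiotropy with zero mean (InSIDE-satisfying noise)."""

    sd: float


@dataclass(frozen=True)
class Directional:
    """Horizontal pleiotropy with nonzero mean: biases IVW, targets Egger."""

    mean: float
    sd: float


LDStructure = Independent | AR1 | Blocks
Pleiotropy = NoPleiotropy | Balanced | Directional


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters for one simulated two-sample MR dataset.

    Defaults emulate the scale of the source setting: an exposure GWAS of
    ~36.5k subjects, an outcome GWAS of ~60k (cases+controls handled via
    ``case_fraction`` on the log-odds scale when ``outcome_binary``), and
    a 5,000-subject reference panel. ``variant_effect_sd`` (per-allele
    effect on a unit-variance exposure) defaults to 0.1, the strength of
    genome-wide-significant instruments at these sample sizes.
    """

    k_variants: int
    seed: int
    n_panel: int = 5000
    n_exposure_gwas: int = 36548
    n_outcome_gwas: int = 60620
    maf_range: tuple[float, float] = (0.1, 0.4)
    ld_structure: LDStructure = Independent()
    true_slope: float = 0.0
    pleiotropy: Pleiotropy = NoPleiotropy()
    variant_effect_sd: float = 0.1
    outcome_binary: bool = False
    case_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.k_variants < 1:
            raise ValueError("k_variants must be >= 1")
        lo, hi = self.maf_range
        if not 0.0 < lo < hi < 0.5:
            raise ValueError("maf_range must satisfy 0 < low < high < 0.5")
        if self.variant_effect_sd <= 0:
            raise ValueError("variant_effect_sd must be positive")
        if self.outcome_binary and not 0.0 < self.case_fraction < 1.0:
            raise ValueError("case_fraction must lie in (0, 1)")
        for n, name in (
            (self.n_panel, "n_panel"),
            (self.n_exposure_gwas, "n_exposure_gwas"),
            (self.n_outcome_gwas, "n_outcome_gwas"),
        ):
            if n < 2:
                raise ValueError(f"{name} must be >= 2")


@dataclass
class Truth:
    """Generative quantities carried alongside the outputs for recovery tests."""

    true_slope: float
    beta_exp: np.ndarray
    pleiotropy: np.ndarray
    mafs: np.ndarray
    ld: LDMatrix
    se_exp: np.ndarray
    se_out: np.ndarray


@dataclass
class SimulatedStudy:
    panel: GenotypePanel
    exposure_stats: list[SummaryStatRecord]
    outcome_stats: list[SummaryStatRecord]
    truth: Truth
    config: SimConfig = field(repr=False, default=None)


def _max_binary_corr(p: float, q: float) -> float:
    """Frechet upper bound on corr of Bernoulli(p), Bernoulli(q)."""
    s = np.sqrt(p * (1 - p) * q * (1 - q))
    upper = min(p, q) - p * q
    return upper / s


def _draw_mafs(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    lo, hi = cfg.maf_range
    k = cfg.k_variants
    ld = cfg.ld_structure
    if isinstance(ld, Independent):
        return rng.uniform(lo, hi, size=k)
    if isinstance(ld, Blocks):
        n_blocks = -(-k // ld.size)
        block_mafs = rng.uniform(lo, hi, size=n_blocks)
        return np.repeat(block_mafs, ld.size)[:k]
    # AR1: constrained random walk so each adjacent pair admits corr rho
    rho = abs(ld.rho)
    grid = np.linspace(lo, hi, 256)
    mafs = np.empty(k)
    mafs[0] = rng.uniform(lo, hi)
    margin = 1.02  # keep a little slack from the Frechet boundary
    for j in range(1, k):
        p = mafs[j - 1]
        feasible = grid[
            np.array([_max_binary_corr(p, q) >= margin * rho for q in grid])
        ]
        if feasible.size == 0:
            raise ValueError(
                f"maf_range {cfg.maf_range} cannot support adjacent allele "
                f"correlation {ld.rho}"
            )
        mafs[j] = rng.choice(feasible)
    return mafs


def _true_ld(cfg: SimConfig) -> np.ndarray:
    k = cfg.k_variants
    ld = cfg.ld_structure
    if isinstance(ld, Independent):
        return np.eye(k)
    if isinstance(ld, AR1):
        lags = np.abs(np.subtract.outer(np.arange(k), np.arange(k)))
        return np.sign(ld.rho) ** lags * abs(ld.rho) ** lags
    block_of = np.repeat(np.arange(-(-k // ld.size)), ld.size)[:k]
    same = block_of[:, None] == block_of[None, :]
    r = np.where(same, ld.rho, 0.0)
    np.fill_diagonal(r, 1.0)
    return r


def _haplotypes(
    cfg: SimConfig, mafs: np.ndarray, n_hap: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw n_hap haplotypes whose allele correlations match the structure."""
    k = cfg.k_variants
    ld = cfg.ld_structure
    if isinstance(ld, Independent):
        return (rng.random((n_hap, k)) < mafs).astype(np.int8)
    if isinstance(ld, Blocks):
        a = np.sqrt(ld.rho)
        block_of = np.repeat(np.arange(-(-k // ld.size)), ld.size)[:k]
        # one maf per block: the first variant of each block carries it
        first_of_block = np.searchsorted(block_of, np.arange(block_of.max() + 1))
        ancestors = rng.random((n_hap, block_of.max() + 1)) < mafs[first_of_block]
        fresh = rng.random((n_hap, k)) < mafs
        copy = rng.random((n_hap, k)) < a
        return np.where(copy, ancestors[:, block_of], fresh).astype(np.int8)
    # AR1 stationary binary Markov chain; lag correlations telescope to rho**lag
    rho = ld.rho
    hap = np.empty((n_hap, k), dtype=np.int8)
    hap[:, 0] = rng.random(n_hap) < mafs[0]
    for j in range(1, k):
        p_prev, p_cur = mafs[j - 1], mafs[j]
        s = np.sqrt(p_prev * (1 - p_prev) * p_cur * (1 - p_cur))
        p11 = p_prev * p_cur + rho * s
        p_given1 = p11 / p_prev
        p_given0 = (p_cur - p11) / (1 - p_prev)
        if not (0 <= p_given0 <= 1 and 0 <= p_given1 <= 1):
            raise ValueError("infeasible adjacent correlation in AR1 chain")
        prob = np.where(hap[:, j - 1] == 1, p_given1, p_given0)
        hap[:, j] = rng.random(n_hap) < prob
    return hap


def _make_records(variant_ids, mafs, betas, ses, n) -> list[SummaryStatRecord]:
    out = []
    for i, vid in enumerate(variant_ids):
        z = betas[i] / ses[i]
        p = max(MIN_PVAL, float(2.0 * norm.sf(abs(z))))
        ea, oa = _ALLELE_PAIRS[i % len(_ALLELE_PAIRS)]
        out.append(
            SummaryStatRecord(
                variant_id=vid,
                chrom="1",
                pos=(i + 1) * 100000,
                effect_allele=ea,
                other_allele=oa,
                eaf=float(mafs[i]),
                beta=float(betas[i]),
                se=float(ses[i]),
                pval=p,
                n=n,
            )
        )
    return out


def simulate(cfg: SimConfig) -> SimulatedStudy:
    """Generate a reference panel and two-sample summary statistics.

    Summary-level model: exposure marginal effects beta_x are half-normal
    with scale ``variant_effect_sd`` (effect allele = exposure-increasing
    allele); outcome effects are ``true_slope * beta_x`` plus the
    pleiotropy term; observed betas add multivariate normal noise with
    covariance diag(se) R diag(se), R the true allele correlation, as the
    estimates of correlated variants from one GWAS sample are themselves
    correlated. Standard errors follow se = 1/sqrt(n * 2 p (1-p)) for a
    unit-variance trait, and 1/sqrt(n * cf (1-cf) * 2 p (1-p)) on the
    log-odds scale for a binary outcome with case fraction cf. Fully
    reproducible from ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    k = cfg.k_variants
    mafs = _draw_mafs(cfg, rng)
    r_true = _true_ld(cfg)

    # reference panel: two independent haplotypes per sample
    hap = _haplotypes(cfg, mafs, 2 * cfg.n_panel, rng)
    dosages = (hap[: cfg.n_panel] + hap[cfg.n_panel :]).astype(float)
    panel = GenotypePanel(
        variant_ids=[f"rs{i + 1:05d}" for i in range(k)],
        dosages=dosages,
        sample_ids=[f"S{i + 1}" for i in range(cfg.n_panel)],
    )

    beta_exp = np.abs(rng.normal(0.0, cfg.variant_effect_sd, size=k))
    plei = cfg.pleiotropy
    if isinstance(plei, NoPleiotropy):
        alpha = np.zeros(k)
    elif isinstance(plei, Balanced):
        alpha = rng.normal(0.0, plei.sd, size=k)
    else:
        alpha = rng.normal(plei.mean, plei.sd, size=k)
    beta_out_true = cfg.true_slope * beta_exp + alpha

    var_g = 2.0 * mafs * (1.0 - mafs)
    se_exp = 1.0 / np.sqrt(cfg.n_exposure_gwas * var_g)
    if cfg.outcome_binary:
        cf = cfg.case_fraction
        se_out = 1.0 / np.sqrt(cfg.n_outcome_gwas * cf * (1.0 - cf) * var_g)
    else:
        se_out = 1.0 / np.sqrt(cfg.n_outcome_gwas * var_g)

    L = np.linalg.cholesky(r_true + 1e-12 * np.eye(k))
    bx_hat = beta_exp + se_exp * (L @ rng.standard_normal(k))
    by_hat = beta_out_true + se_out * (L @ rng.standard_normal(k))

    def records(betas, ses, n):
        return _make_records(panel.variant_ids, mafs, betas, ses, n)

    truth = Truth(
        true_slope=cfg.true_slope,
        beta_exp=beta_exp,
        pleiotropy=alpha,
        mafs=mafs,
        ld=LDMatrix(list(panel.variant_ids), r_true),
        se_exp=se_exp,
        se_out=se_out,
    )
    return SimulatedStudy(
        panel=panel,
        exposure_stats=records(bx_hat, se_exp, cfg.n_exposure_gwas),
        outcome_stats=records(by_hat, se_out, cfg.n_outcome_gwas),
        truth=truth,
        config=cfg,
    )


@dataclass
class SimulatedGrid:
    """One exposure against several outcomes sharing the genetic truth."""

    panel: GenotypePanel
    exposure_stats: list[SummaryStatRecord]
    outcome_stats: list[list[SummaryStatRecord]]
    outcome_slopes: list[float]
    truth: Truth


def simulate_grid(cfg: SimConfig, outcome_slopes: Sequence[float]) -> SimulatedGrid:
    """Simulate one exposure GWAS and independent outcome GWAS per slope.

    All outcomes share the exposure's variants, LD and per-variant
    effects; outcome j has causal slope ``outcome_slopes[j]``, its own
    pleiotropy draw per ``cfg.pleiotropy``, and independent sampling
    noise (child seed [cfg.seed, j]). This is the generative layout of a
    phenome-wide scan of one trait against many outcomes.
    """
    base = simulate(cfg)
    truth = base.truth
    k = cfg.k_variants
    L = np.linalg.cholesky(truth.ld.r + 1e-12 * np.eye(k))
    plei = cfg.pleiotropy
    outcome_stats = []
    for j, slope in enumerate(outcome_slopes):
        rng = np.random.default_rng([cfg.seed, j])
        if isinstance(plei, NoPleiotropy):
            alpha = np.zeros(k)
        elif isinstance(plei, Balanced):
            alpha = rng.normal(0.0, plei.sd, size=k)
        else:
            alpha = rng.normal(plei.mean, plei.sd, size=k)
        by_true = slope * truth.beta_exp + alpha
        by_hat = by_true + truth.se_out * (L @ rng.standard_normal(k))
        outcome_stats.append(
            _make_records(
                base.panel.variant_ids, truth.mafs, by_hat, truth.se_out,
                cfg.n_outcome_gwas,
            )
        )
    return SimulatedGrid(
        panel=base.panel,
        exposure_stats=base.exposure_stats,
        outcome_stats=outcome_stats,
        outcome_slopes=list(outcome_slopes),
        truth=truth,
    )


def write_fixture(study: SimulatedStudy, out_dir: str | Path) -> dict[str, Path]:
    """Write a study as pipeline-ready files plus a truth JSON.

    Emits ``exposure.tsv`` / ``outcome.tsv`` in the standard
    summary-statistics layout, ``panel.tsv`` as a dosage table, and
    ``truth.json``; the files round-trip losslessly through the readers.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "exposure": out_dir / "exposure.tsv",
        "outcome": out_dir / "outcome.tsv",
        "panel": out_dir / "panel.tsv",
        "truth": out_dir / "truth.json",
    }
    write_sumstats(study.exposure_stats, paths["exposure"])
    write_sumstats(study.outcome_stats, paths["outcome"])

    with open(paths["panel"], "w") as fh:
        fh.write("sample_id\t" + "\t".join(study.panel.variant_ids) + "\n")
        sample_ids = study.panel.sample_ids or [
            f"S{i + 1}" for i in range(study.panel.sample_count)
        ]
        for sid, row in zip(sample_ids, study.panel.dosages):
            fh.write(sid + "\t" + "\t".join(format(x, ".17g") for x in row) + "\n")

    truth = study.truth
    paths["truth"].write_text(
        json.dumps(
            {
                "true_slope": truth.true_slope,
                "beta_exp": truth.beta_exp.tolist(),
                "pleiotropy": truth.pleiotropy.tolist(),
                "mafs": truth.mafs.tolist(),
                "se_exp": truth.se_exp.tolist(),
                "se_out": truth.se_out.tolist(),
                "ld_variant_ids": truth.ld.variant_ids,
                "ld_r": truth.ld.r.tolist(),
            },
            indent=1,
        )
    )
    return paths
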