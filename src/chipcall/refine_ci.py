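"""Prediction refinement, cohort filtering, and Bayesian credible intervals.

Three post-classification stages:

1. **Rescue rules** catch likely mis-predictions.  A non-CHIP prediction is
   flagged as putative CHIP when the variant is a previously reported CHIP
   mutation and at least two callers found it here.  CHIP-sized clones
   rarely exceed 30% VAF, so higher-VAF predictions revert to germline —
   unless the variant sits in one of the five genes where germline variants
   are essentially absent (DNMT3A, ASXL1, TET2, PPM1D, JAK2), in which case
   it is held for review instead.

2. **Cohort filters** remove, in order: variants common in any of four
   germline-frequency databases (MAF >= 0.3%), low-confidence (single
   caller) variants in low-complexity regions, and variants recurring in
   >= 8% of subjects (systematic artifacts); survivors must then reach 2%
   VAF and appear in the somatic-cancer catalogue, with an optional
   driver-mutation restriction.  Per-rule removal tallies are reported and
   conserve counts.

3. **Credible intervals** come from a hierarchical two-component mixture:
   at each site, the observed alt count k of n reads arises either from the
   background error process, k ~ BetaBinomial(n, alpha, beta) with the Beta
   fitted per site (falling back to gene, then global) from a reference
   panel of young healthy subjects, or from a true clone, k ~ Binomial(n,
   theta) with theta ~ Beta(a0, b0) truncated to (0.005, 0.5).  The prior
   clone probability pi is the CHIP incidence observed in the panel.  The
   posterior clone probability and the 2.5/97.5% quantiles of theta's
   truncated conjugate posterior are attached to each CHIP prediction.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import betaln, gammaln

from .feature_annot import ResourceTables
from .meta_caller import MergedCall
from .variant_model import VariantKey, VariantType

__all__ = [
    "RefinementConfig",
    "CohortFilterConfig",
    "RefineFlag",
    "Prediction",
    "BackgroundModel",
    "rescue_rules",
    "cohort_filter",
    "fit_background",
    "chip_posterior",
    "chip_log_odds",
]


@dataclass(frozen=True)
class RefinementConfig:
    """Rescue-rule thresholds."""

    vaf_germline_default: float = 0.30
    rescue_min_callers: int = 2
    privileged_genes: frozenset[str] = frozenset(
        {"DNMT3A", "ASXL1", "TET2", "PPM1D", "JAK2"}
    )

    def __post_init__(self) -> None:
        if not 0 < self.vaf_germline_default <= 1:
            raise ValueError("vaf_germline_default must be in (0, 1]")


@dataclass(frozen=True)
class CohortFilterConfig:
    """Cohort-level filter thresholds."""

    max_germline_maf: float = 0.003
    max_subject_fraction: float = 0.08
    min_vaf: float = 0.02
    require_catalogue: bool = True
    driver_restrict: bool = False

    def __post_init__(self) -> None:
        for v in (self.max_germline_maf, self.max_subject_fraction, self.min_vaf):
            if not 0 < v < 1:
                raise ValueError("filter fractions must be in (0, 1)")


class RefineFlag(str, enum.Enum):
    NONE = "none"
    PUTATIVE_CHIP_RESCUED = "putative_chip_rescued"
    PUTATIVE_CHIP_VAF_REVIEW = "putative_chip_vaf_review"
    GERMLINE_BY_VAF = "germline_by_vaf"


@dataclass(frozen=True)
class Prediction:
    """A classified variant with refinement and credible-interval fields."""

    label: str
    prob_chip: float
    prob_germline: float
    prob_artifact: float
    refined_flag: RefineFlag = RefineFlag.NONE
    posterior_chip: float | None = None
    ci95: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        total = self.prob_chip + self.prob_germline + self.prob_artifact
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"class probabilities sum to {total}, not 1")
        if self.posterior_chip is not None and not 0 <= self.posterior_chip <= 1:
            raise ValueError("posterior_chip outside [0, 1]")
        if self.ci95 is not None:
            lo, hi = self.ci95
            if not (0 <= lo <= hi <= 1):
                raise ValueError(f"ci95 {self.ci95} not within [0, 1]")


def rescue_rules(
    pred: Prediction,
    merged_call: MergedCall,
    gene: str | None,
    rt: ResourceTables,
    cfg: RefinementConfig | None = None,
) -> Prediction:
    """Apply the two refinement rules to one prediction.

    (a) a non-CHIP prediction whose variant is a known CHIP mutation seen by
    at least ``rescue_min_callers`` callers is flagged for rescue;
    (b) any call above the germline VAF bound reverts to germline unless the
    gene is privileged, in which case it is held for review;
    (c) CHIP predictions at or below the bound pass through unchanged.
    """
    cfg = cfg or RefinementConfig()
    vaf = merged_call.best_evidence.vaf

    if vaf > cfg.vaf_germline_default:
        flag = (
            RefineFlag.PUTATIVE_CHIP_VAF_REVIEW
            if gene in cfg.privileged_genes
            else RefineFlag.GERMLINE_BY_VAF
        )
        return replace(pred, refined_flag=flag)

    if (
        pred.label != "CHIP"
        and merged_call.key in rt.known_chip
        and merged_call.status >= cfg.rescue_min_callers
    ):
        return replace(pred, refined_flag=RefineFlag.PUTATIVE_CHIP_RESCUED)

    return pred


# --------------------------------------------------------------------------
# cohort filtering
# --------------------------------------------------------------------------

def cohort_filter(
    subject_calls: Mapping[str, Sequence[tuple[MergedCall, Prediction]]],
    rt: ResourceTables,
    cfg: CohortFilterConfig | None = None,
    privileged_genes: frozenset[str] = RefinementConfig().privileged_genes,
    gene_of: Mapping[VariantKey, str] | None = None,
) -> tuple[dict[str, list[tuple[MergedCall, Prediction]]], dict[str, int]]:
    """Filter per-subject CHIP candidates at cohort level.

    ``subject_calls`` maps subject id to (merged call, prediction) pairs;
    only calls whose effective label is CHIP (predicted CHIP, or rescued /
    held for review) are considered candidates.  Removal rules run in fixed
    order and each removal is tallied exactly once:

    1. ``germline_maf`` — MAF >= threshold in any germline database;
    2. ``low_complexity`` — single-caller call inside a low-complexity region;
    3. ``recurrent`` — present in >= ``max_subject_fraction`` of subjects;
    4. ``vaf_or_catalogue`` — below minimum VAF, above the germline VAF
       bound in a non-privileged gene, or absent from the somatic catalogue;
    5. ``not_driver`` — optional driver-mutation restriction.

    Returns retained calls per subject and the per-rule tallies, including
    ``input`` and ``retained``; tallies conserve
    (retained + sum(removed) == input).
    """
    if not subject_calls:
        raise ValueError("cohort filter requires at least one subject")
    cfg = cfg or CohortFilterConfig()
    gene_of = gene_of or {}

    chip_flags = {RefineFlag.PUTATIVE_CHIP_RESCUED, RefineFlag.PUTATIVE_CHIP_VAF_REVIEW}
    candidates: list[tuple[str, MergedCall, Prediction]] = []
    for subject, pairs in subject_calls.items():
        for mc, pred in pairs:
            is_chip = (
                pred.label == "CHIP" and pred.refined_flag != RefineFlag.GERMLINE_BY_VAF
            ) or pred.refined_flag in chip_flags
            if is_chip:
                candidates.append((subject, mc, pred))

    n_subjects = len(subject_calls)
    carriers: dict[VariantKey, set[str]] = {}
    for subject, mc, _ in candidates:
        carriers.setdefault(mc.key, set()).add(subject)

    tallies = {
        "input": len(candidates),
        "germline_maf": 0,
        "low_complexity": 0,
        "recurrent": 0,
        "vaf_or_catalogue": 0,
        "not_driver": 0,
        "retained": 0,
    }
    retained: dict[str, list[tuple[MergedCall, Prediction]]] = {
        s: [] for s in subject_calls
    }
    for subject, mc, pred in candidates:
        key = mc.key
        if rt.max_germline_maf(key) >= cfg.max_germline_maf:
            tallies["germline_maf"] += 1
            continue
        in_lc = any(
            c == key.chrom and s <= key.pos <= e for c, s, e in rt.low_complexity
        )
        if mc.status == 1 and in_lc:
            tallies["low_complexity"] += 1
            continue
        if len(carriers[key]) / n_subjects >= cfg.max_subject_fraction:
            tallies["recurrent"] += 1
            continue
        vaf = mc.best_evidence.vaf
        gene = gene_of.get(key)
        vaf_ok = vaf >= cfg.min_vaf and (
            vaf <= 0.30 or gene in privileged_genes
        )
        cosmic_ok = (not cfg.require_catalogue) or bool(
            rt.cosmic_lookup(key, mc.variant.vtype)[0]
        )
        if not (vaf_ok and cosmic_ok):
            tallies["vaf_or_catalogue"] += 1
            continue
        if cfg.driver_restrict and key not in rt.driver_mutations:
            tallies["not_driver"] += 1
            continue
        tallies["retained"] += 1
        retained[subject].append((mc, pred))
    return retained, tallies


def cohort_vaf_matrix(
    retained: Mapping[str, Sequence[tuple[MergedCall, Prediction]]]
) -> pd.DataFrame:
    """Variant x subject matrix of VAFs for the retained cohort calls."""
    rows: dict[str, dict[str, float]] = {}
    for subject, pairs in retained.items():
        for mc, _ in pairs:
            vid = f"{mc.key.chrom}:{mc.key.pos}:{mc.key.ref}>{mc.key.alt}"
            rows.setdefault(vid, {})[subject] = mc.best_evidence.vaf
    return pd.DataFrame(rows).T.reindex(columns=sorted(retained)).fillna(0.0)


# --------------------------------------------------------------------------
# hierarchical background model and credible intervals
# --------------------------------------------------------------------------

#: Beta pseudocount floor for method-of-moments fits
_AB_FLOOR = 0.5
#: truncation bounds on the clone VAF prior
THETA_LO, THETA_HI = 0.005, 0.5


@dataclass
class BackgroundModel:
    """Per-site (with gene/global fallback) error model plus CHIP incidence.

    ``site_params`` maps (chrom, pos) to Beta(alpha, beta) parameters of the
    background alt fraction; ``gene_params``/``global_params`` are the
    fallbacks for unmodeled sites; ``chip_incidence`` is the prior clone
    probability pi estimated from the reference panel.
    """

    site_params: dict[tuple[str, int], tuple[float, float]] = field(
        default_factory=dict
    )
    gene_params: dict[str, tuple[float, float]] = field(default_factory=dict)
    global_params: tuple[float, float] = (_AB_FLOOR, 999.5)
    chip_incidence: float = 0.01

    def __post_init__(self) -> None:
        if not 0 < self.chip_incidence < 1:
            raise ValueError("chip_incidence must be in (0, 1)")

    def params_for(
        self, chrom: str, pos: int, gene: str | None = None
    ) -> tuple[float, float]:
        if (chrom, pos) in self.site_params:
            return self.site_params[(chrom, pos)]
        if gene is not None and gene in self.gene_params:
            return self.gene_params[gene]
        return self.global_params


def _beta_mom(counts: np.ndarray, depths: np.ndarray) -> tuple[float, float]:
    """Method-of-moments Beta fit from (count, depth) pairs.

    The observed variance of the per-subject alt fractions includes a
    binomial sampling component m(1-m)/n on top of the Beta variance; it is
    subtracted before solving for the concentration.  Pseudocount floors
    keep alpha, beta >= 0.5.
    """
    fractions = counts / depths
    m = float(np.mean(fractions))
    m = min(max(m, 1e-6), 1 - 1e-6)
    v = float(np.var(fractions)) - m * (1 - m) * float(np.mean(1.0 / depths))
    if v <= 0 or v >= m * (1 - m):
        # spread indistinguishable from pure binomial noise: concentrated Beta
        conc = 1000.0
    else:
        conc = m * (1 - m) / v - 1
    alpha = max(_AB_FLOOR, m * conc)
    beta = max(_AB_FLOOR, (1 - m) * conc)
    return alpha, beta


def fit_background(
    panel: pd.DataFrame,
    gene_of: Mapping[tuple[str, int], str] | None = None,
    chip_carriers: int = 0,
) -> BackgroundModel:
    """Fit the background error model from reference-panel pileups.

    ``panel`` has one row per (subject, site) with columns ``subject``,
    ``chrom``, ``pos``, ``alt_count``, ``depth``.  Sites observed in >= 2
    panel subjects get a per-site Beta fit of the alt fractions; sites with
    fewer observations contribute to (and fall back on) the gene-level fit,
    then the global fit.  ``chip_carriers`` is the number of panel subjects
    with a retained CHIP call; the incidence pi is floored at
    1/(2 * n_panel) so it is never exactly zero.
    """
    required = {"subject", "chrom", "pos", "alt_count", "depth"}
    if panel is None or len(panel) == 0:
        raise ValueError("empty reference panel")
    if not required <= set(panel.columns):
        raise ValueError(f"panel must have columns {sorted(required)}")
    n_panel = panel["subject"].nunique()
    if n_panel < 2:
        raise ValueError("need at least 2 panel subjects")
    gene_of = gene_of or {}

    model = BackgroundModel(
        global_params=_beta_mom(
            panel["alt_count"].to_numpy(float), panel["depth"].to_numpy(float)
        )
    )
    gene_rows: dict[str, list[pd.DataFrame]] = {}
    for (chrom, pos), grp in panel.groupby(["chrom", "pos"]):
        gene = gene_of.get((chrom, pos))
        if gene is not None:
            gene_rows.setdefault(gene, []).append(grp)
        if grp["subject"].nunique() >= 2:
            model.site_params[(chrom, int(pos))] = _beta_mom(
                grp["alt_count"].to_numpy(float), grp["depth"].to_numpy(float)
            )
    for gene, grps in gene_rows.items():
        g = pd.concat(grps)
        model.gene_params[gene] = _beta_mom(
            g["alt_count"].to_numpy(float), g["depth"].to_numpy(float)
        )
    floor = 1.0 / (2 * n_panel)
    model.chip_incidence = min(1 - floor, max(floor, chip_carriers / n_panel))
    return model


def _log_betabinom(k: int, n: int, a: float, b: float) -> float:
    return (
        gammaln(n + 1)
        - gammaln(k + 1)
        - gammaln(n - k + 1)
        + betaln(k + a, n - k + b)
        - betaln(a, b)
    )


def chip_log_odds(
    alt_count: int,
    depth: int,
    background: tuple[float, float],
    pi: float,
    a0: float = 1.0,
    b0: float = 1.0,
) -> float:
    """Log posterior odds of the clone component vs the error component.

    Numerically exact even where the posterior probability saturates at 1 in
    floating point; monotonicity checks run on this scale.
    """
    k, n = alt_count, depth
    if n <= 0:
        raise ValueError("depth must be positive")
    if not 0 <= k <= n:
        raise ValueError(f"alt_count {k} outside [0, depth={n}]")
    alpha, beta_ = background
    if alpha <= 0 or beta_ <= 0:
        raise ValueError("background Beta parameters must be positive")
    if not 0 < pi < 1:
        raise ValueError("pi must be in (0, 1)")

    log_l0 = _log_betabinom(k, n, alpha, beta_)
    prior = stats.beta(a0, b0)
    post = stats.beta(a0 + k, b0 + n - k)
    z_prior = prior.cdf(THETA_HI) - prior.cdf(THETA_LO)
    with np.errstate(divide="ignore"):
        log_z_post = stats.beta.logcdf(THETA_HI, a0 + k, b0 + n - k)
        tail_lo = post.cdf(THETA_LO)
        if tail_lo > 0:
            log_z_post = np.log(max(post.cdf(THETA_HI) - tail_lo, 0.0))
    # untruncated clone marginal is beta-binomial; correct by truncated masses
    log_l1 = _log_betabinom(k, n, a0, b0) + log_z_post - np.log(z_prior)
    return float(np.log(pi) - np.log1p(-pi) + log_l1 - log_l0)


def chip_posterior(
    alt_count: int,
    depth: int,
    background: tuple[float, float],
    pi: float,
    a0: float = 1.0,
    b0: float = 1.0,
) -> tuple[float, tuple[float, float]]:
    """Posterior clone probability and 95% credible interval for clone VAF.

    The marginal clone likelihood integrates Binomial(k | n, theta) over the
    Beta(a0, b0) prior truncated to (``THETA_LO``, ``THETA_HI``); the error
    likelihood is BetaBinomial(n, alpha, beta) with the background fit.
    The interval holds the 2.5/97.5% quantiles of the conjugate
    Beta(a0 + k, b0 + n - k) posterior re-truncated to the prior support.
    """
    k, n = alt_count, depth
    lo_odds = chip_log_odds(k, n, background, pi, a0, b0)
    posterior = float(1.0 / (1.0 + np.exp(-lo_odds))) if np.isfinite(lo_odds) else (
        1.0 if lo_odds > 0 else 0.0
    )

    post = stats.beta(a0 + k, b0 + n - k)
    z_post = post.cdf(THETA_HI) - post.cdf(THETA_LO)
    if z_post > 0:
        lo_q = post.cdf(THETA_LO) + 0.025 * z_post
        hi_q = post.cdf(THETA_LO) + 0.975 * z_post
        ci = (float(post.ppf(lo_q)), float(post.ppf(hi_q)))
    else:
        # posterior mass entirely outside the truncation: pin to nearest bound
        ci = (THETA_LO, THETA_LO) if post.mean() < THETA_LO else (THETA_HI, THETA_HI)
    ci = (min(max(ci[0], THETA_LO), THETA_HI), min(max(ci[1], THETA_LO), THETA_HI))
    return posterior, ci
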