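"""Covariate-corrected phenotyping and chromosome tests for crosses.

Implements the cross-analysis stage: size/sex/family correction with
back-transformation onto the tooth-number scale, diploid genotype-class
assignment from two-locus marker genotypes, one-way ANOVA of class effects,
the recombinant-direction likelihood-ratio test (does a recombinant
chromosome behave like a marine or a benthic chromosome?), per-benthic-
chromosome effect LRTs, and the Mendelian segregation chi-square.

All model comparisons use Gaussian linear models fitted by maximum
likelihood, so 2*delta-loglik = n*log(RSS_reduced / RSS_full) with a
chi-square reference distribution on the parameter difference.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import gaussian_loglik, group_mean_rss, lrt_from_rss, ols_rss
from .errors import DegenerateInputError

log = logging.getLogger(__name__)

MARINE_LIKE = "marine-like"
BENTHIC_LIKE = "benthic-like"
INDETERMINATE = "indeterminate"


# ---------------------------------------------------------------------------
# size correction
# ---------------------------------------------------------------------------

@dataclass
class CorrectedPhenotype:
    corrected: pd.Series  # fish_id -> corrected tooth number
    covariates_used: list[str]
    reference_length: float
    coefficients: dict = field(default_factory=dict)
    baselines: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)


def _marginal_pvalues(fish: pd.DataFrame, y: np.ndarray) -> dict[str, float]:
    """Marginal association p-value of each candidate covariate with y."""
    out: dict[str, float] = {}
    length = fish["std_length_mm"].to_numpy(dtype=float)
    if np.ptp(length) > 0:
        out["length"] = float(stats.linregress(length, y).pvalue)
    for col, name in (("sex", "sex"), ("family", "family")):
        if col not in fish.columns:
            continue
        groups = [y[fish[col].to_numpy() == lv] for lv in pd.unique(fish[col])]
        groups = [g for g in groups if len(g) >= 2]
        if len(groups) >= 2 and any(np.ptp(g) > 0 for g in groups):
            out[name] = float(stats.f_oneway(*groups).pvalue)
    return out


def size_correct(
    fish: pd.DataFrame,
    response: str = "tooth_total",
    alpha: float = 0.05,
) -> CorrectedPhenotype:
    """Correct a tooth phenotype for length, sex and family where significant.

    Each candidate covariate is first tested marginally at level ``alpha``;
    the significant ones enter a single joint linear model. Corrected values
    are the residuals back-transformed to the cross mean — the fitted value
    at the mean standard length with factor effects at their observed
    proportions — so they stay on the tooth-number scale and
    mean(corrected) == mean(raw) exactly.
    """
    if len(fish) < 4:
        raise DegenerateInputError("need at least 4 fish")
    if response not in fish.columns or fish[response].isna().any():
        raise DegenerateInputError(f"response {response!r} must be present for all fish")
    y = fish[response].to_numpy(dtype=float)
    idx = pd.Index(fish["fish_id"], name="fish_id")
    ref_length = float(fish["std_length_mm"].mean())
    warnings: list[str] = []

    if np.ptp(y) == 0:
        warnings.append("constant response; no correction applied")
        log.warning(warnings[-1])
        return CorrectedPhenotype(pd.Series(y, index=idx), [], ref_length, warnings=warnings)

    pvals = _marginal_pvalues(fish, y)
    selected = [c for c in ("length", "sex", "family") if pvals.get(c, 1.0) < alpha]

    if not selected:
        return CorrectedPhenotype(pd.Series(y, index=idx), [], ref_length, warnings=warnings)

    cols: list[np.ndarray] = [np.ones(len(y))]
    names = ["intercept"]
    baselines: dict[str, str] = {}
    used: list[str] = []
    for cov in selected:
        if cov == "length":
            cols.append(fish["std_length_mm"].to_numpy(dtype=float))
            names.append("std_length_mm")
            used.append(cov)
            continue
        col = "sex" if cov == "sex" else "family"
        levels = sorted(pd.unique(fish[col].astype(str)))
        if len(levels) < 2:
            warnings.append(f"covariate {cov} singular (one level); skipped")
            log.warning(warnings[-1])
            continue
        baselines[cov] = levels[0]
        for lv in levels[1:]:
            cols.append((fish[col].astype(str) == lv).to_numpy(dtype=float))
            names.append(f"{col}[{lv}]")
        used.append(cov)

    if not used:
        return CorrectedPhenotype(pd.Series(y, index=idx), [], ref_length, warnings=warnings)

    X = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    corrected = resid + y.mean()
    return CorrectedPhenotype(
        corrected=pd.Series(corrected, index=idx),
        covariates_used=used,
        reference_length=ref_length,
        coefficients=dict(zip(names, map(float, beta))),
        baselines=baselines,
        warnings=warnings,
    )


# ---------------------------------------------------------------------------
# genotype classes
# ---------------------------------------------------------------------------

@dataclass
class RecombinantSpec:
    """Names the flanking marker pair and the two-locus haplotype scored R."""

    left_marker: str
    right_marker: str
    recombinant_haplotypes: frozenset = frozenset({("M", "B")})


def canonical_class(labels: Sequence[str]) -> str:
    """Canonical diploid class from two haplotype labels: MM, MB, BB, RM, RB, RR."""
    order = {"M": 0, "B": 1, "R": 2}
    a, b = sorted(labels, key=lambda c: order[c])
    if b == "R":  # R listed first by convention (RM, RB, RR)
        return b + a if a != "R" else "RR"
    return a + b


def assign_genotype_class(
    fish: pd.DataFrame, spec: RecombinantSpec
) -> tuple[pd.Series, pd.DataFrame]:
    """Score each fish's diploid class from its two-locus marker genotypes.

    Each haplotype (one allele from each flanking marker, phase-ordered in
    the 'a/b' genotype strings) is labelled M (marine/marine), B
    (benthic/benthic), or R if it matches a recombinant haplotype of the
    spec. Fish with a haplotype outside the cross design are excluded and
    returned separately with reasons, never silently dropped.
    """
    classes: dict[str, str] = {}
    excluded: list[dict] = []
    for _, row in fish.iterrows():
        left = str(row[spec.left_marker]).split("/")
        right = str(row[spec.right_marker]).split("/")
        if len(left) != 2 or len(right) != 2:
            excluded.append({"fish_id": row["fish_id"], "reason": "unparseable genotype"})
            continue
        labels = []
        for hap in (0, 1):
            pair = (left[hap], right[hap])
            if pair in spec.recombinant_haplotypes:
                labels.append("R")
            elif pair == ("M", "M"):
                labels.append("M")
            elif pair == ("B", "B"):
                labels.append("B")
            else:
                labels.append(None)
        if None in labels:
            excluded.append(
                {"fish_id": row["fish_id"], "reason": f"haplotype outside cross design: {left}/{right}"}
            )
            log.warning("fish %s excluded: %s", row["fish_id"], excluded[-1]["reason"])
            continue
        classes[row["fish_id"]] = canonical_class(labels)
    return (
        pd.Series(classes, name="genotype_class"),
        pd.DataFrame(excluded, columns=["fish_id", "reason"]),
    )


def punnett_classes(parent1_haplotypes: Sequence[str], parent2_haplotypes: Sequence[str]) -> set[str]:
    """Enumerate the diploid classes of a cross from the parents' haplotypes."""
    return {
        canonical_class((h1, h2))
        for h1 in parent1_haplotypes
        for h2 in parent2_haplotypes
    }


# ---------------------------------------------------------------------------
# ANOVA
# ---------------------------------------------------------------------------

@dataclass
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p_value: float
    class_means: dict[str, float]
    class_se: dict[str, float]
    class_n: dict[str, int]


def genotype_anova(
    corrected: pd.Series,
    classes: pd.Series,
    restrict: Optional[Sequence[str]] = ("MM", "MB", "BB"),
) -> AnovaResult:
    """One-way fixed-effects ANOVA of corrected phenotype on genotype class.

    Classes with fewer than 2 fish are excluded with a warning. Reports F,
    degrees of freedom, p, and per-class back-transformed means with SE.
    """
    df = pd.DataFrame({"y": corrected, "cls": classes}).dropna()
    if restrict is not None:
        df = df[df["cls"].isin(restrict)]
    groups = {}
    for cls, sub in df.groupby("cls"):
        if len(sub) < 2:
            log.warning("class %s has < 2 fish; excluded from ANOVA", cls)
            continue
        groups[cls] = sub["y"].to_numpy(dtype=float)
    if len(groups) < 2:
        raise DegenerateInputError("ANOVA needs at least two classes with >= 2 fish")
    res = stats.f_oneway(*groups.values())
    n = sum(len(g) for g in groups.values())
    return AnovaResult(
        F=float(res.statistic),
        df_between=len(groups) - 1,
        df_within=n - len(groups),
        p_value=float(res.pvalue),
        class_means={c: float(g.mean()) for c, g in groups.items()},
        class_se={c: float(g.std(ddof=1) / np.sqrt(len(g))) for c, g in groups.items()},
        class_n={c: len(g) for c, g in groups.items()},
    )


# ---------------------------------------------------------------------------
# likelihood-ratio tests
# ---------------------------------------------------------------------------

@dataclass
class LrtResult:
    model_A_loglik: float  # merged model supporting the reported direction
    model_B_loglik: float  # the opposite merged model
    full_loglik: float
    statistic: float  # 2*delta-loglik of the rejected (opposite) merge vs FULL
    df: int
    p_value: float
    supported_direction: str
    details: dict = field(default_factory=dict)


def _merge_label(cls: str, as_allele: str) -> str:
    return canonical_class([as_allele if h == "R" else h for h in cls])


def recombinant_direction_lrt(
    corrected: pd.Series,
    classes: pd.Series,
    alpha: float = 0.05,
) -> LrtResult:
    """Test whether a recombinant chromosome behaves marine- or benthic-like.

    Fits three Gaussian cell-means models: FULL (every diploid class its own
    mean), R==M (each R-bearing class merged with its marine counterpart,
    e.g. RM with MM and RB with MB), and R==B (merged with the benthic
    counterparts). Each merged model is compared against FULL by LRT with
    df = the reduction in class count. The supported direction is the merge
    with the higher merged likelihood, declared only when the opposite merge
    is rejected at ``alpha`` and the supported one is not; otherwise the
    call is indeterminate and both p-values are reported. The headline
    ``p_value`` is that of rejecting the opposite merge.
    """
    df = pd.DataFrame({"y": corrected, "cls": classes}).dropna()
    labels = df["cls"].to_numpy()
    if not any("R" in c for c in labels):
        raise DegenerateInputError("no recombinant-bearing class present")
    y = df["y"].to_numpy(dtype=float)
    n = len(y)

    rss_full, k_full = group_mean_rss(y, labels)
    ll_full = gaussian_loglik(rss_full, n)

    merged = {}
    for direction, allele in ((MARINE_LIKE, "M"), (BENTHIC_LIKE, "B")):
        lab = np.array([_merge_label(c, allele) for c in labels])
        rss, k = group_mean_rss(y, lab)
        stat, p = lrt_from_rss(rss_full, rss, n, k_full - k)
        merged[direction] = {
            "loglik": gaussian_loglik(rss, n),
            "statistic": stat,
            "df": k_full - k,
            "p": p,
        }

    best = max(merged, key=lambda d: merged[d]["loglik"])
    other = BENTHIC_LIKE if best == MARINE_LIKE else MARINE_LIKE
    best_rejected = merged[best]["p"] < alpha
    other_rejected = merged[other]["p"] < alpha
    direction = best if (other_rejected and not best_rejected) else INDETERMINATE

    return LrtResult(
        model_A_loglik=merged[best]["loglik"],
        model_B_loglik=merged[other]["loglik"],
        full_loglik=ll_full,
        statistic=merged[other]["statistic"],
        df=merged[other]["df"],
        p_value=merged[other]["p"],
        supported_direction=direction,
        details={
            "alpha": alpha,
            "p_marine_merge": merged[MARINE_LIKE]["p"],
            "p_benthic_merge": merged[BENTHIC_LIKE]["p"],
            "stat_marine_merge": merged[MARINE_LIKE]["statistic"],
            "stat_benthic_merge": merged[BENTHIC_LIKE]["statistic"],
        },
    )


@dataclass
class ChromosomeLrt:
    chromosome: str
    applicable: bool
    statistic: Optional[float] = None
    df: Optional[int] = None
    p_value: Optional[float] = None
    reason: Optional[str] = None
    details: dict = field(default_factory=dict)


def benthic_chromosome_lrt(
    corrected: pd.Series,
    haplotypes: pd.DataFrame,
    marine_allele: str = "M",
) -> dict[str, ChromosomeLrt]:
    """Per-benthic-chromosome effect LRT in a cross testing two wild chromosomes.

    ``haplotypes`` has columns fish_id, hap1, hap2, where each haplotype is
    the marker allele ('M' for marine, distinct labels such as 'B1'/'B2' for
    the two benthic chromosomes at a four-allele marker). For each benthic
    chromosome the dosage model mu + d1*n1 + d2*n2 is compared against the
    model with that chromosome's effect fixed to zero (df = 1). When the
    marker cannot distinguish two benthic chromosomes, the result is
    reported not-applicable with a reason.
    """
    hap = haplotypes.set_index("fish_id")
    benthic = sorted((set(hap["hap1"]) | set(hap["hap2"])) - {marine_allele})
    if len(benthic) < 2:
        name = benthic[0] if benthic else "benthic"
        return {
            name: ChromosomeLrt(
                chromosome=name,
                applicable=False,
                reason="benthic chromosomes cannot be molecularly distinguished",
            )
        }
    if len(benthic) > 2:
        raise DegenerateInputError("expected at most two distinct benthic chromosomes")

    common = corrected.index.intersection(hap.index)
    y = corrected.loc[common].to_numpy(dtype=float)
    n1 = (
        (hap.loc[common, "hap1"] == benthic[0]).astype(int)
        + (hap.loc[common, "hap2"] == benthic[0]).astype(int)
    ).to_numpy()
    n2 = (
        (hap.loc[common, "hap1"] == benthic[1]).astype(int)
        + (hap.loc[common, "hap2"] == benthic[1]).astype(int)
    ).to_numpy()
    n = len(y)
    ones = np.ones(n)
    rss_full = ols_rss(y, np.column_stack([ones, n1, n2]))
    rss_shared = ols_rss(y, np.column_stack([ones, n1 + n2]))
    out: dict[str, ChromosomeLrt] = {}
    for name, other in ((benthic[0], n2), (benthic[1], n1)):
        rss_red = ols_rss(y, np.column_stack([ones, other]))
        stat, p = lrt_from_rss(rss_full, rss_red, n, 1)
        out[name] = ChromosomeLrt(
            chromosome=name,
            applicable=True,
            statistic=stat,
            df=1,
            p_value=p,
            details={
                "loglik_full": gaussian_loglik(rss_full, n),
                "loglik_reduced": gaussian_loglik(rss_red, n),
                "loglik_equal_effect": gaussian_loglik(rss_shared, n),
            },
        )
    return out


# ---------------------------------------------------------------------------
# Mendelian ratios
# ---------------------------------------------------------------------------

@dataclass
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float
    expected: list[float]


def mendelian_ratio_test(
    observed: Sequence[float], expected_ratio: Sequence[float]
) -> ChiSquareResult:
    """Pearson goodness-of-fit chi-square of observed counts against a ratio.

    E.g. genotype survival counts against 1:2:1 for an intercross or 1:1
    for a backcross.
    """
    obs = np.asarray(observed, dtype=float)
    ratio = np.asarray(expected_ratio, dtype=float)
    if obs.shape != ratio.shape:
        raise DegenerateInputError("observed and ratio must have the same arity")
    if (obs < 0).any() or (ratio <= 0).any():
        raise DegenerateInputError("counts must be >= 0 and ratio terms > 0")
    total = obs.sum()
    if total == 0:
        raise DegenerateInputError("total count is zero")
    expected = ratio / ratio.sum() * total
    res = stats.chisquare(obs, f_exp=expected)
    return ChiSquareResult(
        statistic=float(res.statistic),
        df=len(obs) - 1,
        p_value=float(res.pvalue),
        expected=[float(e) for e in expected],
    )


def percent_reduction(before: float, after: float) -> float:
    """Percentage reduction from fine-mapping, e.g. of interval size or gene count."""
    if before <= 0:
        raise DegenerateInputError("'before' must be positive")
    return 100.0 * (1.0 - after / before)
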