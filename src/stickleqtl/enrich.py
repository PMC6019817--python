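"""Gene-set enrichment on a two-group expression matrix.

The procedure: each gene gets a signed z-score from a two-sample t-test of
mutant vs wildtype on log2(FPKM + pseudocount); a gene set's statistic is a
1-sample t-test of its members' z-scores against zero (under the global
null the z's are standard normal); raw p-values receive a Bonferroni
correction over the N sets tested, and the t cutoff is additionally
calibrated by an empirical permutation null — random same-size gene subsets
drawn without replacement from the scored background — with cutoffs at the
2.5/N and 100 - 2.5/N percentiles. A set is called significant only when
both criteria agree.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError

log = logging.getLogger(__name__)

WILDTYPE = "wildtype"
MUTANT = "mutant"


@dataclass
class GeneZScores:
    """Per-gene signed z-scores; positive = higher in mutant."""

    z: pd.Series  # gene_id -> z
    excluded: dict[str, str]  # gene_id -> reason
    df: int
    pooled: bool
    pseudocount: float
    expression_floor: float


@dataclass
class SetResult:
    name: str
    n_genes_tested: int
    mean_z: Optional[float]
    t_statistic: Optional[float]
    p_value: Optional[float]
    reason: Optional[str] = None


@dataclass
class PermutationNull:
    set_size: int
    n_perm: int
    seed: int
    N: int
    statistics: np.ndarray
    cutoff_low: float
    cutoff_high: float

    @property
    def percentiles(self) -> tuple[float, float]:
        return permutation_percentiles(self.N)


@dataclass
class EnrichmentResult:
    name: str
    n_genes_tested: int
    mean_z: Optional[float]
    t_statistic: Optional[float]
    p_value: Optional[float]
    bonferroni_p: Optional[float]
    cutoff_low: Optional[float]
    cutoff_high: Optional[float]
    significant: bool
    direction: Optional[str]  # up / down
    reason: Optional[str] = None


def permutation_percentiles(n_hypotheses: int) -> tuple[float, float]:
    """Percentile pair (2.5/N, 100 - 2.5/N) of the permutation cutoff band."""
    if n_hypotheses < 1:
        raise DegenerateInputError("N must be >= 1")
    lo = 2.5 / n_hypotheses
    return lo, 100.0 - lo


def _group_columns(expr: pd.DataFrame, groups: Mapping[str, str]) -> tuple[list[str], list[str]]:
    wt = [s for s in expr.columns if groups.get(s) == WILDTYPE]
    mut = [s for s in expr.columns if groups.get(s) == MUTANT]
    if len(wt) < 2 or len(mut) < 2:
        raise DegenerateInputError("need >= 2 samples per group")
    return wt, mut


def per_gene_z(
    expr: pd.DataFrame,
    groups: Mapping[str, str],
    pseudocount: float = 1.0,
    expression_floor: float = 1.0,
    pooled: bool = True,
) -> GeneZScores:
    """Per-gene signed z-scores from mutant-vs-wildtype t-tests.

    Tests are on log2(abundance + pseudocount). The signed z is the probit
    transform of the t cumulative probability (z = Phi^-1(F_t(t))), which is
    exactly standard normal under the null even at n = 3 per group and
    carries the sign of the mean difference (positive = up in mutant).
    Genes below the expression floor (mean raw abundance across all
    samples) or with zero variance in both groups are excluded with
    reasons.
    """
    if expr.index.duplicated().any():
        raise DegenerateInputError("duplicate gene ids in expression matrix")
    wt_cols, mut_cols = _group_columns(expr, groups)
    X = np.log2(expr.to_numpy(dtype=float) + pseudocount)
    wt = X[:, [expr.columns.get_loc(c) for c in wt_cols]]
    mut = X[:, [expr.columns.get_loc(c) for c in mut_cols]]
    n1, n2 = wt.shape[1], mut.shape[1]

    mean_raw = expr.to_numpy(dtype=float).mean(axis=1)
    low = mean_raw < expression_floor
    var_wt = wt.var(axis=1, ddof=1)
    var_mut = mut.var(axis=1, ddof=1)
    zero_var = (var_wt == 0) & (var_mut == 0)

    diff = mut.mean(axis=1) - wt.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        if pooled:
            sp2 = ((n1 - 1) * var_wt + (n2 - 1) * var_mut) / (n1 + n2 - 2)
            se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
            df_arr = np.full(len(diff), n1 + n2 - 2, dtype=float)
        else:  # Welch
            a, b = var_wt / n1, var_mut / n2
            se = np.sqrt(a + b)
            df_arr = (a + b) ** 2 / (a**2 / (n1 - 1) + b**2 / (n2 - 1))
        t = diff / se
    cdf = stats.t.cdf(t, df_arr)
    z = stats.norm.ppf(np.clip(cdf, 1e-300, 1.0 - 1e-16))

    keep = ~(low | zero_var) & np.isfinite(z)
    excluded: dict[str, str] = {}
    for g, is_low, is_const in zip(expr.index, low, zero_var):
        if is_low:
            excluded[g] = "below expression floor"
        elif is_const:
            excluded[g] = "zero variance in both groups"
    for g, ok in zip(expr.index, keep):
        if not ok and g not in excluded:
            excluded[g] = "non-finite statistic"
    if excluded:
        log.info("excluded %d genes from scoring", len(excluded))
    return GeneZScores(
        z=pd.Series(z[keep], index=expr.index[keep], name="z"),
        excluded=excluded,
        df=int(n1 + n2 - 2),
        pooled=pooled,
        pseudocount=pseudocount,
        expression_floor=expression_floor,
    )


def _one_sample_t(values: np.ndarray) -> tuple[float, float, float]:
    """(mean, t, two-sided p) of a 1-sample t-test against zero.

    Zero-variance input: p = 1 when the common value is 0 (no signal, by
    convention), p = 0 otherwise.
    """
    m = float(values.mean())
    sd = float(values.std(ddof=1))
    n = len(values)
    if sd == 0:
        if m == 0:
            return m, 0.0, 1.0
        return m, float(np.inf) if m > 0 else float(-np.inf), 0.0
    t = m / (sd / np.sqrt(n))
    p = 2.0 * float(stats.t.sf(abs(t), n - 1))
    return m, float(t), p


def set_statistic(z: GeneZScores, members: Iterable[str], name: str = "") -> SetResult:
    """1-sample t-test of a gene set's z-scores against mean zero."""
    eff = z.z.index.intersection(pd.Index(members))
    if len(eff) < 2:
        reason = "no scored members" if len(eff) == 0 else "fewer than 2 scored members"
        return SetResult(name=name, n_genes_tested=len(eff), mean_z=None,
                         t_statistic=None, p_value=None, reason=reason)
    vals = z.z.loc[eff].to_numpy(dtype=float)
    mean, t, p = _one_sample_t(vals)
    if vals.std(ddof=1) == 0:
        log.warning("gene set %s has zero-variance z-scores; p by convention", name)
    return SetResult(name=name, n_genes_tested=len(eff), mean_z=mean, t_statistic=t, p_value=p)


def permutation_null(
    z: GeneZScores,
    set_size: int,
    n_perm: int = 10_000,
    N: int = 1,
    seed: int = 0,
    _rng: np.random.Generator | None = None,
) -> PermutationNull:
    """Empirical null of the set t-statistic from random same-size gene subsets.

    Draws ``n_perm`` subsets of ``set_size`` genes without replacement from
    the scored background, computes the 1-sample t statistic for each, and
    places cutoffs at the (2.5/N, 100 - 2.5/N) percentiles with linear
    interpolation. Deterministic under a fixed seed.
    """
    pool = z.z.to_numpy(dtype=float)
    n_genes = len(pool)
    if set_size > n_genes:
        raise DegenerateInputError("set_size exceeds the number of scored genes")
    if set_size < 2:
        raise DegenerateInputError("set_size must be >= 2")
    rng = _rng if _rng is not None else np.random.default_rng(seed)
    tstats = np.empty(n_perm)
    chunk = max(1, min(n_perm, int(4e6 // max(n_genes, 1)) or 1))
    done = 0
    sqrt_n = np.sqrt(set_size)
    while done < n_perm:
        m = min(chunk, n_perm - done)
        keys = rng.random((m, n_genes))
        idx = np.argpartition(keys, set_size - 1, axis=1)[:, :set_size]
        draws = pool[idx]
        means = draws.mean(axis=1)
        sds = draws.std(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            tstats[done : done + m] = means / (sds / sqrt_n)
        done += m
    lo_pct, hi_pct = permutation_percentiles(N)
    lo, hi = np.percentile(tstats, [lo_pct, hi_pct])  # linear interpolation
    return PermutationNull(
        set_size=set_size,
        n_perm=n_perm,
        seed=seed,
        N=N,
        statistics=tstats,
        cutoff_low=float(lo),
        cutoff_high=float(hi),
    )


def evaluate_gene_sets(
    expr: pd.DataFrame,
    sets: Mapping[str, Sequence[str]],
    groups: Mapping[str, str],
    n_perm: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
    pseudocount: float = 1.0,
    expression_floor: float = 1.0,
    pooled: bool = True,
) -> list[EnrichmentResult]:
    """Run the full enrichment: z-scores, set tests, Bonferroni, permutation band.

    N = number of sets tested. A set is significant iff its Bonferroni-
    corrected p is below ``alpha`` AND its observed t statistic falls
    outside the permutation cutoff band; direction is the sign of the mean
    z (up = higher in mutant). Permutation nulls are cached per effective
    set size.
    """
    if not sets:
        raise DegenerateInputError("no gene sets supplied")
    zs = per_gene_z(expr, groups, pseudocount=pseudocount,
                    expression_floor=expression_floor, pooled=pooled)
    N = len(sets)
    rng = np.random.default_rng(seed)
    null_cache: dict[int, PermutationNull] = {}
    results: list[EnrichmentResult] = []
    for name, members in sets.items():
        sr = set_statistic(zs, members, name=name)
        if sr.p_value is None:
            results.append(
                EnrichmentResult(
                    name=name, n_genes_tested=sr.n_genes_tested, mean_z=None,
                    t_statistic=None, p_value=None, bonferroni_p=None,
                    cutoff_low=None, cutoff_high=None, significant=False,
                    direction=None, reason=sr.reason,
                )
            )
            continue
        size = sr.n_genes_tested
        if size not in null_cache:
            null_cache[size] = permutation_null(zs, size, n_perm=n_perm, N=N, seed=seed, _rng=rng)
        null = null_cache[size]
        bonf = min(1.0, sr.p_value * N)
        outside = sr.t_statistic < null.cutoff_low or sr.t_statistic > null.cutoff_high
        results.append(
            EnrichmentResult(
                name=name,
                n_genes_tested=size,
                mean_z=sr.mean_z,
                t_statistic=sr.t_statistic,
                p_value=sr.p_value,
                bonferroni_p=bonf,
                cutoff_low=null.cutoff_low,
                cutoff_high=null.cutoff_high,
                significant=bool(bonf < alpha and outside),
                direction="up" if sr.mean_z > 0 else "down",
            )
        )
    return results


def results_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    """Tabular view of enrichment results (one row per set)."""
    return pd.DataFrame(
        [
            {
                "set": r.name,
                "n": r.n_genes_tested,
                "mean_z": r.mean_z,
                "t": r.t_statistic,
                "p": r.p_value,
                "bonferroni_p": r.bonferroni_p,
                "cutoff_low": r.cutoff_low,
                "cutoff_high": r.cutoff_high,
                "significant": r.significant,
                "direction": r.direction,
                "reason": r.reason,
            }
            for r in results
        ]
    )
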