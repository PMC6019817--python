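"""Synthetic-data generators with planted ground truth.

Three generators emulate the three input kinds of the pipeline:

* :func:`simulate_cross` — an F2 / recombinant stickleback cross with a
  length covariate, optional sex and family effects, and per-diploid-class
  tooth-number means.
* :func:`simulate_variant_panel` — a resequencing panel across a fine-mapped
  interval with a planted cluster of perfectly QTL-concordant SNPs among
  imperfectly differentiated noise variants, plus missingness, site-quality
  and repeat-flank noise, together with a toy genome.
* :func:`simulate_expression` — a two-group (wildtype vs mutant) FPKM-like
  expression matrix with concerted log-space shifts injected into designated
  gene sets.

Every generator is a pure function of (params, seed): the seed is split into
named sub-streams so adding a field does not perturb earlier draws, and the
planted truth is always returned alongside the data.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, GenerationError
from .screen import (
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    Call,
    SamplePanel,
    VariantRecord,
)

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _substreams(seed: int, names: Sequence[str]) -> dict[str, np.random.Generator]:
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _draw_law(law, size: int, rng: np.random.Generator) -> np.ndarray:
    """Draw from a ('uniform', lo, hi) or ('normal', mean, sd) distribution spec."""
    name = law[0]
    if name == "uniform":
        return rng.uniform(law[1], law[2], size)
    if name == "normal":
        return rng.normal(law[1], law[2], size)
    raise ConfigurationError(f"unknown distribution law {law!r}")


# ---------------------------------------------------------------------------
# crosses
# ---------------------------------------------------------------------------

@dataclass
class CrossSimParams:
    """Parameters of a simulated cross.

    ``class_means`` maps each diploid class of the cross design (e.g. MM,
    MB, BB or RM, RB, MM, MB) to its mean tooth number; classes are drawn
    with equal probability, as in a Punnett square with one class per cell.
    ``length_slope`` is in teeth per mm of standard length.
    """

    n_offspring: int = 150
    class_means: dict = field(default_factory=lambda: {"MM": 52.0, "MB": 56.0, "BB": 60.0})
    residual_sd: float = 4.0
    length_mean: float = 30.0
    length_sd: float = 2.0
    length_slope: float = 1.5
    sex_effect: float = 0.0
    family_effects: Sequence[float] = (0.0,)
    seed: int = 0
    markers: tuple[str, str] = ("Stn488", "Stn489")
    recombinant_haplotype: tuple[str, str] = ("M", "B")
    integer_counts: bool = False

    def validate(self):
        if self.n_offspring < 4:
            raise ConfigurationError("n_offspring must be >= 4")
        if self.residual_sd <= 0:
            raise ConfigurationError("residual_sd must be > 0")
        if self.length_sd < 0:
            raise ConfigurationError("length_sd must be >= 0")
        if not self.class_means:
            raise ConfigurationError("class_means must name at least one diploid class")
        for cls in self.class_means:
            if not (isinstance(cls, str) and len(cls) == 2 and set(cls) <= set("MBR")):
                raise ConfigurationError(
                    f"class {cls!r} is not a two-letter diploid class over M/B/R"
                )


_HAPLOTYPE_ALLELES = {"M": ("M", "M"), "B": ("B", "B")}


def _marker_genotypes(cls: str, recomb: tuple[str, str]) -> tuple[str, str]:
    """Two-locus marker genotype strings 'a/b' implied by a diploid class."""
    haps = []
    for h in cls:
        haps.append(recomb if h == "R" else _HAPLOTYPE_ALLELES[h])
    left = f"{haps[0][0]}/{haps[1][0]}"
    right = f"{haps[0][1]}/{haps[1][1]}"
    return left, right


def simulate_cross(params: CrossSimParams) -> pd.DataFrame:
    """Simulate one cross; returns a phenotype table with a truth column.

    Tooth number = class mean + length_slope * (length - length_mean)
    + sex/family offsets + Normal(0, residual_sd). The returned frame has
    columns fish_id, family, sex, std_length_mm, tooth_total, one column per
    flanking marker, and the truth column ``genotype_class``.
    """
    params.validate()
    rngs = _substreams(params.seed, ["class", "sex", "family", "length", "noise"])
    n = params.n_offspring
    classes = list(params.class_means)
    cls_idx = rngs["class"].integers(0, len(classes), n)
    cls = np.array(classes)[cls_idx]
    sex = np.where(rngs["sex"].random(n) < 0.5, "F", "M")
    fam_idx = rngs["family"].integers(0, len(params.family_effects), n)
    length = rngs["length"].normal(params.length_mean, params.length_sd, n)
    noise = rngs["noise"].normal(0.0, params.residual_sd, n)

    means = np.array([params.class_means[c] for c in cls])
    teeth = (
        means
        + params.length_slope * (length - params.length_mean)
        + np.where(sex == "F", params.sex_effect, 0.0)
        + np.asarray(params.family_effects, dtype=float)[fam_idx]
        + noise
    )
    if params.integer_counts:
        teeth = np.maximum(np.rint(teeth), 0)

    left_m, right_m = params.markers
    genos = [_marker_genotypes(c, params.recombinant_haplotype) for c in cls]
    return pd.DataFrame(
        {
            "fish_id": [f"fish_{i:04d}" for i in range(n)],
            "family": [f"fam_{i}" for i in fam_idx],
            "sex": sex,
            "std_length_mm": length,
            "tooth_total": teeth,
            left_m: [g[0] for g in genos],
            right_m: [g[1] for g in genos],
            "genotype_class": cls,
        }
    )


# ---------------------------------------------------------------------------
# variant panels
# ---------------------------------------------------------------------------

@dataclass
class VariantPanelParams:
    """Parameters of a simulated resequencing panel over a fine-mapped interval.

    Defaults mirror the screen this generator emulates: 372 differentiated
    variants (roughly 323 SNPs and 49 indels) across an 884 kb interval, ten
    of them perfectly concordant SNPs clustered within 4.4 kb, genotyped in
    7 QTL-positive and 3 QTL-negative samples of which two are
    high-coverage.
    """

    interval_bp: int = 884_000
    n_differentiated: int = 372
    n_perfect: int = 10
    cluster_span_bp: int = 4_400
    n_qtl_pos: int = 7
    n_qtl_neg: int = 3
    n_high_coverage: int = 2
    missing_rate: float = 0.03
    site_quality_law: tuple = ("uniform", 100.0, 3000.0)
    repeat_fraction: float = 0.05
    genome_bp: int = 1_200_000
    indel_fraction: float = 49.0 / 372.0
    flip_prob: float = 0.15
    low_gq_rate: float = 0.02
    flank_bp: int = 100
    n_repeat_copies: int = 6  # extra copies pasted; total occurrences = copies + 1
    planted_min_quality: float = 450.0
    chrom: str = "chr21"
    seed: int = 0

    def validate(self):
        if self.n_perfect > self.n_differentiated:
            raise ConfigurationError("n_perfect must be <= n_differentiated")
        if self.cluster_span_bp > self.interval_bp:
            raise ConfigurationError("cluster_span_bp must fit inside interval_bp")
        if self.n_high_coverage > self.n_qtl_pos + self.n_qtl_neg:
            raise ConfigurationError("n_high_coverage exceeds the sample count")
        if self.genome_bp < self.interval_bp:
            raise ConfigurationError("genome_bp must cover the interval")
        if not (0 <= self.missing_rate <= 1 and 0 <= self.repeat_fraction <= 1):
            raise ConfigurationError("rates must be probabilities")
        spacing = 2 * self.flank_bp + 1
        if (self.n_perfect - 1) * spacing > self.cluster_span_bp and self.n_perfect > 1:
            raise ConfigurationError("cluster too tight for the flank spacing constraint")
        if self.n_differentiated * spacing > self.interval_bp - 2 * self.flank_bp:
            raise ConfigurationError("interval too small for this many spaced variants")


def _spaced_positions(rng, n, lo, hi, spacing, taken):
    """n random positions in [lo, hi], pairwise >= spacing apart and from `taken`."""
    out: list[int] = []
    existing = sorted(taken)
    tries = 0
    while len(out) < n:
        tries += 1
        if tries > 200 * max(n, 1) + 1000:
            raise GenerationError("could not place variants with the required spacing")
        cand = int(rng.integers(lo, hi + 1))
        if all(abs(cand - p) >= spacing for p in out) and all(
            abs(cand - p) >= spacing for p in existing
        ):
            out.append(cand)
    return sorted(out)


def simulate_variant_panel(params: VariantPanelParams):
    """Simulate (variants, panel, genome, truth).

    Planted perfect variants are alt-homozygous in every QTL_pos sample and
    ref-homozygous in every QTL_neg sample, clustered within
    ``cluster_span_bp``, with full calls, site quality above
    ``planted_min_quality`` and unique flanks — they emulate the causal
    haplotype the screen is meant to recover. Noise variants start from the
    same group-consistent pattern and have each genotype flipped to the
    opposite homozygote with probability ``flip_prob``; at least one flip is
    forced onto a sample left callable, so no noise variant is accidentally
    perfect. A ``repeat_fraction`` of noise variants have their flank window
    pasted ``n_repeat_copies`` times outside the interval so the flank-
    uniqueness rule fires on them.
    """
    params.validate()
    rngs = _substreams(
        params.seed,
        ["genome", "positions", "genotypes", "quality", "missing", "repeat", "gq", "alleles"],
    )
    fl = params.flank_bp
    spacing = 2 * fl + 1

    genome_arr = _BASES[rngs["genome"].integers(0, 4, params.genome_bp)]

    # --- positions: perfect cluster, then spaced noise positions
    lo, hi = fl + 1, params.interval_bp - fl - 1
    pos_rng = rngs["positions"]
    n_noise = params.n_differentiated - params.n_perfect
    if params.n_perfect > 0:
        span = min(params.cluster_span_bp, hi - lo)
        c0 = int(pos_rng.integers(lo, hi - span + 1))
        if params.n_perfect == 1:
            perfect_pos = [int(pos_rng.integers(c0, c0 + span + 1))]
        else:
            free = span - (params.n_perfect - 1) * spacing
            offs = np.sort(pos_rng.integers(0, free + 1, params.n_perfect))
            perfect_pos = sorted(int(c0 + o + i * spacing) for i, o in enumerate(offs))
    else:
        perfect_pos = []
    noise_pos = _spaced_positions(pos_rng, n_noise, lo, hi, spacing, perfect_pos)

    samples = [f"qtl_pos_{i+1}" for i in range(params.n_qtl_pos)] + [
        f"qtl_neg_{i+1}" for i in range(params.n_qtl_neg)
    ]
    status = {s: ("QTL_pos" if s.startswith("qtl_pos") else "QTL_neg") for s in samples}
    coverage = {s: ("high" if i < params.n_high_coverage else "low") for i, s in enumerate(samples)}
    panel = SamplePanel(status=status, coverage=coverage)

    qual_rng, miss_rng, gt_rng, gq_rng, al_rng = (
        rngs["quality"],
        rngs["missing"],
        rngs["genotypes"],
        rngs["gq"],
        rngs["alleles"],
    )

    def perfect_genotype(s: str) -> str:
        return HOM_ALT if status[s] == "QTL_pos" else HOM_REF

    def draw_gq(low_ok: bool) -> float:
        if low_ok and gq_rng.random() < params.low_gq_rate:
            return float(gq_rng.uniform(0.0, 9.9))
        return float(gq_rng.uniform(30.0, 99.0))

    def alleles_at(pos: int, indel: bool) -> tuple[str, str]:
        ref_base = genome_arr[pos - 1].decode()
        if indel:
            nxt = genome_arr[pos].decode()
            return ref_base + nxt, ref_base  # 1 bp deletion
        alt = al_rng.choice([b for b in "ACGT" if b != ref_base])
        return ref_base, str(alt)

    variants: list[VariantRecord] = []
    truth_repeat: list[int] = []

    for pos in perfect_pos:
        ref, alt = alleles_at(pos, indel=False)  # planted variants are SNPs
        q = float(qual_rng.uniform(params.planted_min_quality, 3000.0))
        calls = {s: Call(perfect_genotype(s), float(gq_rng.uniform(60.0, 99.0))) for s in samples}
        variants.append(VariantRecord(params.chrom, pos, ref, alt, q, calls))

    flip_opposite = {HOM_ALT: HOM_REF, HOM_REF: HOM_ALT}
    for pos in noise_pos:
        indel = bool(gt_rng.random() < params.indel_fraction)
        ref, alt = alleles_at(pos, indel=indel)
        q = float(_draw_law(params.site_quality_law, 1, qual_rng)[0])
        missing_mask = miss_rng.random(len(samples)) < params.missing_rate
        callable_idx = [i for i, m in enumerate(missing_mask) if not m]
        flips = gt_rng.random(len(samples)) < params.flip_prob
        if callable_idx:
            # force >= 1 flip on a callable sample so the score stays < 1
            for _ in range(1000):
                if any(flips[i] for i in callable_idx):
                    break
                flips = gt_rng.random(len(samples)) < params.flip_prob
            else:
                flips[callable_idx[0]] = True
        calls = {}
        for i, s in enumerate(samples):
            if missing_mask[i]:
                calls[s] = Call(MISSING, None)
                continue
            g = perfect_genotype(s)
            if flips[i]:
                g = flip_opposite[g]
            calls[s] = Call(g, draw_gq(low_ok=True))
        variants.append(VariantRecord(params.chrom, pos, ref, alt, q, calls))

    # --- repeat noise: paste flank windows of selected noise variants
    repeat_rng = rngs["repeat"]
    repeat_mask = repeat_rng.random(len(noise_pos)) < params.repeat_fraction
    cursor = params.interval_bp + 500
    win = 2 * fl + 1
    for pos, is_rep in zip(noise_pos, repeat_mask):
        if not is_rep:
            continue
        block = genome_arr[pos - fl - 1 : pos + fl].copy()
        for _ in range(params.n_repeat_copies):
            if cursor + win + 10 > params.genome_bp:
                raise GenerationError("toy genome too small for the requested repeat copies")
            genome_arr[cursor : cursor + win] = block
            cursor += win + 10
        truth_repeat.append(pos)

    variants.sort(key=lambda v: v.pos)
    genome = {params.chrom: genome_arr.tobytes().decode()}
    truth = {
        "perfect_positions": perfect_pos,
        "noise_positions": noise_pos,
        "repeat_positions": truth_repeat,
        "cluster_span_bp": (max(perfect_pos) - min(perfect_pos) + 1) if len(perfect_pos) >= 2 else None,
        "samples": status,
    }
    return variants, panel, genome, truth


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

@dataclass
class ExprSimParams:
    """Parameters of a two-group expression simulation.

    ``sets`` is a list of (name, size, injected_shift) triples; the shift is
    in log2 units and is added to the mutant group for every member gene.
    Defaults emulate an n = 3 vs n = 3 design.
    """

    n_genes: int = 5_000
    n_per_group: int = 3
    baseline_law: tuple = ("normal", 5.0, 2.0)  # log2 abundance
    noise_sd: float = 0.5
    sets: Sequence[tuple[str, int, float]] = ()
    seed: int = 0

    def validate(self):
        if self.n_per_group < 2:
            raise ConfigurationError("n_per_group must be >= 2")
        if sum(s[1] for s in self.sets) > self.n_genes:
            raise ConfigurationError("set sizes exceed n_genes")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be > 0")
        names = [s[0] for s in self.sets]
        if len(names) != len(set(names)):
            raise GenerationError("duplicate gene-set names")


def simulate_expression(params: ExprSimParams):
    """Simulate (expression frame, groups, gene_sets, truth).

    Abundances are log-normal: log2 values are baseline + shift + Normal(0,
    noise_sd), exponentiated to FPKM-like non-negative values. Gene sets are
    disjoint; truth maps each set name to its injected shift.
    """
    params.validate()
    rngs = _substreams(params.seed, ["baseline", "noise", "sets"])
    genes = [f"gene_{i:05d}" for i in range(params.n_genes)]
    samples = [f"wt_{i+1}" for i in range(params.n_per_group)] + [
        f"mut_{i+1}" for i in range(params.n_per_group)
    ]
    groups = {s: ("wildtype" if s.startswith("wt") else "mutant") for s in samples}

    base = _draw_law(params.baseline_law, params.n_genes, rngs["baseline"])
    log2 = base[:, None] + rngs["noise"].normal(0.0, params.noise_sd, (params.n_genes, len(samples)))

    # disjoint member draw, then inject shifts into the mutant columns
    perm = rngs["sets"].permutation(params.n_genes)
    gene_sets: dict[str, list[str]] = {}
    truth: dict[str, float] = {}
    cursor = 0
    mut_cols = np.array([groups[s] == "mutant" for s in samples])
    for name, size, shift in params.sets:
        members = perm[cursor : cursor + size]
        cursor += size
        gene_sets[name] = [genes[i] for i in members]
        truth[name] = float(shift)
        if shift != 0.0:
            log2[np.ix_(members, np.where(mut_cols)[0])] += shift

    expr = pd.DataFrame(np.power(2.0, log2), index=pd.Index(genes, name="gene_id"), columns=samples)
    return expr, groups, gene_sets, truth
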