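"""Variant filtering and QTL concordance screening.

Screens a panel of variants segregating between samples that carry a tooth
QTL (``QTL_pos``) and samples that do not (``QTL_neg``): a quality /
missingness filter chain, a repeat filter based on flanking-sequence
uniqueness in the genome, a per-variant QTL concordance score, and a report
of the perfectly associated cluster.

The concordance score of a variant is::

    score = | p_pos - p_neg |

where ``p_g`` is the proportion of called chromosomes in group ``g`` that
carry the variant allele (hom_alt contributes 2/2, het 1/2; missing calls
are excluded from denominators). A score of 1.0 means the variant perfectly
separates the two groups.
"""
from __future__ import annotations

import logging
from collections import OrderedDict
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Optional, Sequence

from .errors import StickleQtlError

log = logging.getLogger(__name__)

HOM_REF = "hom_ref"
HET = "het"
HOM_ALT = "hom_alt"
MISSING = "missing"

QTL_POS = "QTL_pos"
QTL_NEG = "QTL_neg"


@dataclass
class Call:
    """One sample's genotype at one site; ``gq`` may be absent (None)."""

    genotype: str
    gq: Optional[float] = None


@dataclass
class VariantRecord:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    site_quality: float
    calls: dict[str, Call]

    @property
    def variant_class(self) -> str:
        return "SNP" if len(self.ref) == 1 and len(self.alt) == 1 else "indel"

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class SamplePanel:
    """sample_id -> (qtl_status in {QTL_pos, QTL_neg}, coverage in {high, low})."""

    status: dict[str, str]
    coverage: dict[str, str]

    def __post_init__(self):
        for s, st in self.status.items():
            if st not in (QTL_POS, QTL_NEG):
                raise ValueError(f"sample {s}: unknown qtl_status {st!r}")
        for s, cv in self.coverage.items():
            if cv not in ("high", "low"):
                raise ValueError(f"sample {s}: unknown coverage {cv!r}")

    @property
    def samples(self) -> list[str]:
        return list(self.status)

    def group(self, which: str) -> list[str]:
        return [s for s, st in self.status.items() if st == which]

    @property
    def high_coverage(self) -> list[str]:
        return [s for s, cv in self.coverage.items() if cv == "high"]


@dataclass
class FilterThresholds:
    """Thresholds of the variant filter chain (defaults follow the screen design)."""

    min_site_quality: float = 400.0  # strict '>'
    min_genotype_quality: float = 10.0
    max_bad_genomes: int = 2
    flank_bp: int = 100
    max_genome_matches: int = 6
    flank_identity: float = 0.99
    evalue_ceiling: float = 1e-30  # honoured only by external matchers


@dataclass
class ConcordanceRecord:
    chrom: str
    pos: int
    ref: str
    alt: str
    variant_class: str
    score: float  # NaN when undefined
    p_pos: float
    p_neg: float
    n_called_pos: int
    n_called_neg: int
    undefined: bool = False

    @property
    def key(self):
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class ClusterReport:
    variants: list  # keys of the variants at/above the score threshold
    count: int
    snp_count: int
    indel_count: int
    min_pos: Optional[int]
    max_pos: Optional[int]
    span_bp: Optional[int]  # max_pos - min_pos + 1, defined when count >= 2
    score_track: list = field(default_factory=list)  # (pos, score) for plotting


def _bad_call(call: Call, thresholds: FilterThresholds) -> bool:
    """Missing, or genotype quality below threshold. Absent GQ passes (logged)."""
    if call.genotype == MISSING:
        return True
    if call.gq is None:
        return False
    return call.gq < thresholds.min_genotype_quality


def filter_variants(
    variants: Sequence[VariantRecord],
    panel: SamplePanel,
    thresholds: FilterThresholds | None = None,
) -> tuple[list[VariantRecord], "OrderedDict[str, int]"]:
    """Apply the quality / missingness filter chain in its fixed order.

    Rules, applied in order (a variant is tallied against the first rule it
    fails):

    1. ``site_quality`` — QUAL must be strictly greater than
       ``min_site_quality`` (a site at exactly the threshold is removed).
    2. ``high_coverage`` — no high-coverage sample may be missing or have
       GQ below ``min_genotype_quality``.
    3. ``missingness`` — at most ``max_bad_genomes`` samples in total may be
       missing / low-GQ.

    Returns (retained variants, per-rule removal tally).
    """
    thresholds = thresholds or FilterThresholds()
    panel_samples = set(panel.samples)
    high_cov = set(panel.high_coverage)
    retained: list[VariantRecord] = []
    tally: OrderedDict[str, int] = OrderedDict(
        [("site_quality", 0), ("high_coverage", 0), ("missingness", 0)]
    )
    for v in variants:
        extra = set(v.calls) - panel_samples
        if extra:
            raise StickleQtlError(
                f"sample(s) {sorted(extra)} at {v.chrom}:{v.pos} absent from the panel"
            )
        if not v.site_quality > thresholds.min_site_quality:
            tally["site_quality"] += 1
            continue
        bad = [s for s, c in v.calls.items() if _bad_call(c, thresholds)]
        if any(s in high_cov for s in bad):
            tally["high_coverage"] += 1
            continue
        if len(bad) > thresholds.max_bad_genomes:
            tally["missingness"] += 1
            continue
        for s, c in v.calls.items():
            if c.genotype != MISSING and c.gq is None:
                log.debug("%s:%d sample %s has no GQ; treated as passing", v.chrom, v.pos, s)
        retained.append(v)
    return retained, tally


def exact_flank_matcher(genome: str, left: str, right: str) -> int:
    """Count genome locations where both flanks match exactly around a free base.

    A location is a position i such that genome[i : i+len(left)] == left and
    genome[i+len(left)+1 : ...] == right — i.e. the two flanks with any single
    base in between. The variant's own locus counts as one match.
    """
    n = 0
    gap = len(left) + 1
    start = 0
    if left:
        while True:
            i = genome.find(left, start)
            if i < 0:
                break
            if genome[i + gap : i + gap + len(right)] == right:
                n += 1
            start = i + 1
    else:  # fully truncated left flank: fall back to right-flank occurrences
        while True:
            i = genome.find(right, start)
            if i < 0:
                break
            n += 1
            start = i + 1
    return n


def flank_uniqueness_filter(
    variants: Sequence[VariantRecord],
    genome: Mapping[str, str],
    thresholds: FilterThresholds | None = None,
    matcher: Callable[[str, str, str], int] | None = None,
) -> tuple[list[VariantRecord], list[VariantRecord]]:
    """Remove variants whose flanking sequence recurs in the genome.

    A variant is removed iff its ``flank_bp`` flanks (positions
    [pos-flank_bp, pos-1] and [pos+1, pos+flank_bp], 1-based inclusive) match
    more than ``max_genome_matches`` places in the genome under the
    configured matcher. The built-in matcher is exact-substring; an external
    similarity-search matcher honouring ``flank_identity`` and
    ``evalue_ceiling`` can be plugged in via ``matcher``.

    Returns (retained, removed).
    """
    thresholds = thresholds or FilterThresholds()
    matcher = matcher or exact_flank_matcher
    fl = thresholds.flank_bp
    retained: list[VariantRecord] = []
    removed: list[VariantRecord] = []
    for v in variants:
        seq = genome.get(v.chrom)
        if seq is None:
            raise StickleQtlError(f"genome lacks contig {v.chrom!r}")
        lo = max(v.pos - fl, 1)
        hi = min(v.pos + fl, len(seq))
        if lo != v.pos - fl or hi != v.pos + fl:
            log.warning(
                "%s:%d flank truncated to [%d, %d] at sequence end", v.chrom, v.pos, lo, hi
            )
        left = seq[lo - 1 : v.pos - 1]
        right = seq[v.pos : hi]
        n = matcher(seq, left, right)
        if n > thresholds.max_genome_matches:
            removed.append(v)
        else:
            retained.append(v)
    return retained, removed


def concordance_scores(
    variants: Iterable[VariantRecord],
    panel: SamplePanel,
    per_fish: bool = False,
) -> list[ConcordanceRecord]:
    """Score each variant's concordance with QTL status.

    By default allele presence is counted per called chromosome (allele
    frequency); with ``per_fish=True`` it is the proportion of called fish
    carrying at least one variant allele. A group with no called samples
    yields a flagged record with score NaN, never a silent 0.
    """
    pos_samples = panel.group(QTL_POS)
    neg_samples = panel.group(QTL_NEG)
    if not pos_samples or not neg_samples:
        raise StickleQtlError("panel must contain at least one sample per QTL group")
    out: list[ConcordanceRecord] = []
    for v in variants:
        props = []
        ns = []
        for group in (pos_samples, neg_samples):
            called = [v.calls[s] for s in group if s in v.calls and v.calls[s].genotype != MISSING]
            ns.append(len(called))
            if not called:
                props.append(float("nan"))
                continue
            if per_fish:
                carriers = sum(1 for c in called if c.genotype in (HET, HOM_ALT))
                props.append(carriers / len(called))
            else:
                alt = sum({HOM_REF: 0, HET: 1, HOM_ALT: 2}[c.genotype] for c in called)
                props.append(alt / (2 * len(called)))
        undefined = any(n == 0 for n in ns)
        score = float("nan") if undefined else abs(props[0] - props[1])
        if undefined:
            log.warning("%s:%d has an entirely-missing group; score undefined", v.chrom, v.pos)
        out.append(
            ConcordanceRecord(
                chrom=v.chrom,
                pos=v.pos,
                ref=v.ref,
                alt=v.alt,
                variant_class=v.variant_class,
                score=score,
                p_pos=props[0],
                p_neg=props[1],
                n_called_pos=ns[0],
                n_called_neg=ns[1],
                undefined=undefined,
            )
        )
    return out


def perfect_cluster_report(
    records: Sequence[ConcordanceRecord],
    score_threshold: float = 1.0,
) -> ClusterReport:
    """Report the variants at or above the score threshold and their span."""
    hits = [r for r in records if not r.undefined and r.score >= score_threshold]
    positions = [r.pos for r in hits]
    count = len(hits)
    return ClusterReport(
        variants=[r.key for r in hits],
        count=count,
        snp_count=sum(1 for r in hits if r.variant_class == "SNP"),
        indel_count=sum(1 for r in hits if r.variant_class == "indel"),
        min_pos=min(positions) if positions else None,
        max_pos=max(positions) if positions else None,
        span_bp=(max(positions) - min(positions) + 1) if count >= 2 else None,
        score_track=[(r.pos, r.score) for r in records if not r.undefined],
    )


def run_screen(
    variants: Sequence[VariantRecord],
    panel: SamplePanel,
    genome: Mapping[str, str] | None = None,
    thresholds: FilterThresholds | None = None,
    score_threshold: float = 1.0,
    per_fish: bool = False,
):
    """Full screen: filter chain -> flank filter -> scores -> cluster report.

    Returns a dict with the retained variants, the per-rule tally (including
    the flank rule), the concordance records and the cluster report.
    """
    thresholds = thresholds or FilterThresholds()
    retained, tally = filter_variants(variants, panel, thresholds)
    if genome is not None:
        retained, removed = flank_uniqueness_filter(retained, genome, thresholds)
        tally["flank_uniqueness"] = len(removed)
    records = concordance_scores(retained, panel, per_fish=per_fish)
    report = perfect_cluster_report(records, score_threshold)
    return {
        "retained": retained,
        "tally": tally,
        "records": records,
        "cluster": report,
    }
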