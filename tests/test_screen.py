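"""Variant filter chain, flank-uniqueness filter, concordance scores, cluster."""
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from stickleqtl import screen, simulate
from stickleqtl.errors import StickleQtlError
from stickleqtl.screen import Call, FilterThresholds, SamplePanel, VariantRecord

from conftest import make_panel, make_variant


def _all_called(panel, genotype="hom_alt"):
    return {s: genotype for s in panel.samples}


class TestFilterVariants:
    def test_site_quality_threshold_is_strict(self):
        panel = make_panel(2, 2)
        at = make_variant(qual=400.0, genotypes=_all_called(panel))
        above = make_variant(qual=400.0 + 1e-9, genotypes=_all_called(panel))
        retained, tally = screen.filter_variants([at, above], panel)
        assert retained == [above]
        assert tally["site_quality"] == 1

    def test_missing_high_coverage_sample_removes_variant(self):
        panel = make_panel(2, 2, n_high=1)
        genos = _all_called(panel)
        genos["p0"] = "missing"  # p0 is high coverage
        v = make_variant(qual=1000.0, genotypes=genos)
        retained, tally = screen.filter_variants([v], panel)
        assert retained == [] and tally["high_coverage"] == 1

    def test_low_gq_high_coverage_sample_removes_variant(self):
        panel = make_panel(2, 2, n_high=1)
        v = make_variant(qual=1000.0, genotypes=_all_called(panel),
                         gqs={"p0": 9.0})
        retained, tally = screen.filter_variants([v], panel)
        assert retained == [] and tally["high_coverage"] == 1

    def test_two_bad_low_coverage_genomes_retained_three_removed(self):
        panel = make_panel(3, 3)
        two = _all_called(panel)
        two["p1"] = two["n1"] = "missing"
        three = _all_called(panel)
        three["p1"] = three["n1"] = three["n2"] = "missing"
        retained, tally = screen.filter_variants(
            [make_variant(pos=10, genotypes=two), make_variant(pos=20, genotypes=three)],
            panel,
        )
        assert [v.pos for v in retained] == [10]
        assert tally["missingness"] == 1

    def test_absent_gq_treated_as_passing(self):
        panel = make_panel(2, 2)
        v = make_variant(genotypes=_all_called(panel))
        for c in v.calls.values():
            c.gq = None
        retained, _ = screen.filter_variants([v], panel)
        assert retained == [v]

    def test_unknown_sample_raises_naming_it(self):
        panel = make_panel(1, 1)
        v = make_variant(genotypes={"p0": "hom_alt", "n0": "hom_ref", "ghost": "het"})
        with pytest.raises(StickleQtlError, match="ghost"):
            screen.filter_variants([v], panel)

    def test_tally_sums_to_removed_count(self):
        p = simulate.VariantPanelParams(
            interval_bp=30_000, n_differentiated=60, n_perfect=5,
            genome_bp=90_000, missing_rate=0.15, low_gq_rate=0.1, seed=13,
        )
        variants, panel, _, _ = simulate.simulate_variant_panel(p)
        retained, tally = screen.filter_variants(variants, panel)
        assert sum(tally.values()) == len(variants) - len(retained)


def _genome_with_copies(core_left, core_right, n_copies, rng, pad=3000):
    """Toy genome with n_copies of the flank window (variant base = 'A')."""
    window = core_left + "A" + core_right
    bases = rng.choice(list("ACGT"), pad).tolist()
    seq = "".join(bases)
    parts = []
    for i in range(n_copies):
        parts.append(seq[i * 50 : i * 50 + 200])
        parts.append(window)
    parts.append(seq)
    return "".join(parts)


class TestFlankUniqueness:
    def _setup(self, n_copies, rng, flank=30):
        left = "".join(rng.choice(list("ACGT"), flank))
        right = "".join(rng.choice(list("ACGT"), flank))
        genome = _genome_with_copies(left, right, n_copies, rng)
        pos = genome.find(left + "A" + right) + flank + 1  # 1-based variant base
        v = VariantRecord("chr21", pos, "A", "T", 1000.0, {})
        thr = FilterThresholds(flank_bp=flank)
        return v, {"chr21": genome}, thr

    def test_seven_occurrences_removed(self, rng):
        v, genome, thr = self._setup(7, rng)
        retained, removed = screen.flank_uniqueness_filter([v], genome, thr)
        assert removed == [v]

    def test_six_occurrences_retained(self, rng):
        v, genome, thr = self._setup(6, rng)
        retained, removed = screen.flank_uniqueness_filter([v], genome, thr)
        assert retained == [v]

    def test_unique_flank_retained(self, rng):
        v, genome, thr = self._setup(1, rng)
        retained, _ = screen.flank_uniqueness_filter([v], genome, thr)
        assert retained == [v]

    def test_truncated_flank_near_sequence_end_is_handled(self, rng):
        genome = {"chr21": "".join(rng.choice(list("ACGT"), 500))}
        v = VariantRecord("chr21", 5, "A", "T", 1000.0, {})
        retained, _ = screen.flank_uniqueness_filter([v], genome,
                                                     FilterThresholds(flank_bp=30))
        assert retained == [v]


class TestConcordanceScores:
    def test_perfect_segregation_scores_one(self):
        panel = make_panel(7, 3)
        genos = {s: ("hom_alt" if s.startswith("p") else "hom_ref") for s in panel.samples}
        (rec,) = screen.concordance_scores([make_variant(genotypes=genos)], panel)
        assert rec.score == 1.0 and rec.p_pos == 1.0 and rec.p_neg == 0.0

    def test_identical_groups_score_zero(self):
        panel = make_panel(4, 4)
        (rec,) = screen.concordance_scores(
            [make_variant(genotypes=_all_called(panel, "hom_alt"))], panel
        )
        assert rec.score == 0.0

    def test_hand_arithmetic_oracle(self):
        # alt on 10/14 QTL_pos chromosomes, 2/6 QTL_neg: |10/14 - 2/6| = 8/21
        panel = make_panel(7, 3)
        genos = {}
        pos = panel.group("QTL_pos")
        genos.update({s: "hom_alt" for s in pos[:3]})   # 6 alt alleles
        genos.update({s: "het" for s in pos[3:7]})      # 4 more -> 10/14
        neg = panel.group("QTL_neg")
        genos.update({neg[0]: "het", neg[1]: "het", neg[2]: "hom_ref"})  # 2/6
        (rec,) = screen.concordance_scores([make_variant(genotypes=genos)], panel)
        assert abs(rec.score - float(Fraction(8, 21))) < 1e-12
        assert rec.n_called_pos == 7 and rec.n_called_neg == 3

    def test_all_missing_group_is_flagged_not_zero(self):
        panel = make_panel(2, 2)
        genos = {"p0": "hom_alt", "p1": "hom_alt", "n0": "missing", "n1": "missing"}
        (rec,) = screen.concordance_scores([make_variant(genotypes=genos)], panel)
        assert rec.undefined and np.isnan(rec.score)

    def test_per_fish_mode_counts_carriers(self):
        panel = make_panel(2, 2)
        genos = {"p0": "het", "p1": "hom_ref", "n0": "hom_ref", "n1": "hom_ref"}
        (rec,) = screen.concordance_scores([make_variant(genotypes=genos)], panel,
                                           per_fish=True)
        assert rec.score == 0.5  # 1/2 carriers vs 0/2

    @given(st.data())
    def test_brute_force_recount_and_symmetries(self, data):
        n_pos = data.draw(st.integers(1, 5))
        n_neg = data.draw(st.integers(1, 5))
        panel = make_panel(n_pos, n_neg)
        states = ["hom_ref", "het", "hom_alt", "missing"]
        n_var = data.draw(st.integers(1, 6))
        variants = []
        for i in range(n_var):
            genos = {s: data.draw(st.sampled_from(states)) for s in panel.samples}
            variants.append(make_variant(pos=100 + i, genotypes=genos))
        records = screen.concordance_scores(variants, panel)

        alt_per_gt = {"hom_ref": 0, "het": 1, "hom_alt": 2}
        for v, rec in zip(variants, records):
            # independent brute-force recount of allele proportions
            props = {}
            for grp in ("QTL_pos", "QTL_neg"):
                alt = chroms = 0
                for s in panel.group(grp):
                    g = v.calls[s].genotype
                    if g == "missing":
                        continue
                    alt += alt_per_gt[g]
                    chroms += 2
                props[grp] = Fraction(alt, chroms) if chroms else None
            if None in props.values():
                assert rec.undefined
                continue
            expected = abs(float(props["QTL_pos"] - props["QTL_neg"]))
            assert abs(rec.score - expected) < 1e-12

        # swapping ref/alt labels flips genotypes, preserving the score
        flip = {"hom_ref": "hom_alt", "hom_alt": "hom_ref", "het": "het",
                "missing": "missing"}
        swapped = [
            make_variant(pos=v.pos,
                         genotypes={s: flip[c.genotype] for s, c in v.calls.items()})
            for v in variants
        ]
        for a, b in zip(records, screen.concordance_scores(swapped, panel)):
            if not a.undefined:
                assert abs(a.score - b.score) < 1e-12

        # sample reordering does not change scores
        reordered = SamplePanel(
            status=dict(reversed(list(panel.status.items()))),
            coverage=dict(reversed(list(panel.coverage.items()))),
        )
        for a, b in zip(records, screen.concordance_scores(variants, reordered)):
            if not a.undefined:
                assert abs(a.score - b.score) < 1e-12


class TestPerfectClusterReport:
    def _records(self):
        panel = make_panel(3, 3)
        variants = []
        for i, frac_pos in enumerate([1.0, 1.0, 0.5]):
            genos = {}
            for j, s in enumerate(panel.group("QTL_pos")):
                genos[s] = "hom_alt" if (j + 1) / 3 <= frac_pos else "hom_ref"
            genos.update({s: "hom_ref" for s in panel.group("QTL_neg")})
            variants.append(make_variant(pos=1000 + 500 * i, genotypes=genos))
        return screen.concordance_scores(variants, panel)

    def test_count_span_and_classes(self):
        report = screen.perfect_cluster_report(self._records())
        assert report.count == 2 and report.snp_count == 2
        assert report.span_bp == 501  # positions 1000 and 1500 inclusive

    def test_no_perfect_variants_yields_empty_report(self):
        records = [r for r in self._records() if r.score < 1.0]
        report = screen.perfect_cluster_report(records)
        assert report.count == 0 and report.span_bp is None

    def test_threshold_monotonicity(self):
        records = self._records()
        counts = [screen.perfect_cluster_report(records, t).count
                  for t in (1.0, 0.9, 0.5)]
        assert counts == sorted(counts)

    def test_empty_input_is_not_an_error(self):
        report = screen.perfect_cluster_report([])
        assert report.count == 0 and report.variants == []
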