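import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from stickleqtl.screen import Call, SamplePanel, VariantRecord

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_variant(pos=100, qual=1000.0, genotypes=None, gqs=None, chrom="chr21",
                 ref="A", alt="T"):
    """Variant with per-sample genotype strings (hom_ref/het/hom_alt/missing)."""
    genotypes = genotypes or {}
    calls = {}
    for s, g in genotypes.items():
        gq = (gqs or {}).get(s, 99.0)
        calls[s] = Call(g, gq)
    return VariantRecord(chrom=chrom, pos=pos, ref=ref, alt=alt,
                         site_quality=qual, calls=calls)


def make_panel(n_pos=2, n_neg=2, n_high=0):
    samples = [f"p{i}" for i in range(n_pos)] + [f"n{i}" for i in range(n_neg)]
    status = {s: ("QTL_pos" if s.startswith("p") else "QTL_neg") for s in samples}
    coverage = {s: ("high" if i < n_high else "low") for i, s in enumerate(samples)}
    return SamplePanel(status=status, coverage=coverage)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
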