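import pytest
from hypothesis import HealthCheck, settings

from superhla import Cohort, Gene, Genotype, parse_allele

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_genotype(ind_id, a1, a2, b1, b2, c1, c2):
    """Build a Genotype from six allele-name strings."""
    return Genotype(
        individual_id=ind_id,
        calls={
            Gene.A: (parse_allele(a1), parse_allele(a2)),
            Gene.B: (parse_allele(b1), parse_allele(b2)),
            Gene.C: (parse_allele(c1), parse_allele(c2)),
        },
    )


@pytest.fixture
def tiny_cohort():
    """Four individuals: one triple homozygote, one A/B double homozygote,
    one A-only homozygote, one full heterozygote."""
    return Cohort(
        [
            make_genotype("trip", "A*01:01:01", "A*01:01:01", "B*08:01:01",
                          "B*08:01:01", "C*07:01:01", "C*07:01:01"),
            make_genotype("dblAB", "A*02:01:01", "A*02:01:01", "B*07:02:01",
                          "B*07:02:01", "C*07:01:01", "C*07:02:01"),
            make_genotype("homA", "A*02:01:01", "A*02:01:01", "B*07:02:01",
                          "B*08:01:01", "C*07:01:01", "C*07:02:01"),
            make_genotype("het", "A*01:01:01", "A*02:01:01", "B*07:02:01",
                          "B*08:01:01", "C*06:02:01", "C*07:02:01"),
        ],
        label="tiny",
    )
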