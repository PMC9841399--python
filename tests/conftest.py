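import json

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from varzip import SynthSpec, build_archive, generate_vcf, parse_config
from varzip.fixtures import FieldSpec, default_fields


def standard_config_json() -> str:
    """Field configuration used by most integration tests."""
    return json.dumps(
        [
            {"field": "AC", "alias": "pop_AC"},
            {"field": "AF", "alias": "pop_AF", "multiplier": 100000},
            {"field": "CSQ", "alias": "pop_CSQ"},
            {"field": "nhomalt", "alias": "pop_nhomalt"},
            {"field": "AN", "alias": "pop_AN"},
        ]
    )


def cohort_fields() -> list[FieldSpec]:
    return default_fields() + [
        FieldSpec("nhomalt", "integer"),
        FieldSpec("AN", "integer", dist="allele_number"),
    ]


@pytest.fixture(scope="session")
def cohort(tmp_path_factory):
    """A 10^4-variant synthetic cohort with its archive.

    Returns (spec, truth_records, vcf_path, archive_path, configs).  The
    generator defaults carry the study conditions: 30% long alleles, two
    chromosomes (one 'chr'-prefixed), integer/float/string fields.
    """
    d = tmp_path_factory.mktemp("cohort")
    spec = SynthSpec(seed=11, fields=cohort_fields())
    vcf_path = d / "cohort.vcf"
    truth = generate_vcf(spec, vcf_path)
    configs = parse_config(standard_config_json())
    archive_path = d / "cohort.zip"
    build_archive(vcf_path, configs, archive_path)
    return spec, truth, str(vcf_path), str(archive_path), configs


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """A quick 1500-variant cohort for tests that rebuild or rewrite archives."""
    d = tmp_path_factory.mktemp("small")
    spec = SynthSpec(seed=3, n_variants=1500, fields=cohort_fields())
    vcf_path = d / "small.vcf"
    truth = generate_vcf(spec, vcf_path)
    configs = parse_config(standard_config_json())
    archive_path = d / "small.zip"
    build_archive(vcf_path, configs, archive_path)
    return spec, truth, str(vcf_path), str(archive_path), configs
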