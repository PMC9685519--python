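import pytest
from hypothesis import HealthCheck, settings

from sfscreen.report import run_pipeline
from sfscreen.synthetic import table2_cohort

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def canonical_cohort(tmp_path_factory):
    """The canonical synthetic cohort: default design, fixed seed."""
    out = tmp_path_factory.mktemp("table2_cohort")
    return table2_cohort(out)


@pytest.fixture(scope="session")
def pipeline_result(canonical_cohort, tmp_path_factory):
    out = tmp_path_factory.mktemp("report")
    return run_pipeline(
        canonical_cohort.vcf,
        canonical_cohort.annotations,
        canonical_cohort.evidence,
        canonical_cohort.panel,
        out_dir=out,
        subjects_path=canonical_cohort.subjects,
    )
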