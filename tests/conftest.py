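import logging

import pytest

from natseek.pipeline import PipelineConfig, run_pipeline
from natseek.synthetic import generate_fixture

logging.getLogger("natseek").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def fixture_bundle(tmp_path_factory):
    """The default planted-truth fixture, generated once per session."""
    return generate_fixture(tmp_path_factory.mktemp("fixture"), seed=1)


@pytest.fixture(scope="session")
def pipeline_result(fixture_bundle):
    """Full pipeline run over the session fixture, reports written."""
    p = fixture_bundle.paths
    return run_pipeline(
        PipelineConfig(),
        p["genome"],
        p["genes"],
        p["transcripts"],
        expression_tsv=p["expression"],
        evidence_dir=p["evidence_dir"],
        annotation_tsv=p["annotation"],
        outdir=fixture_bundle.outdir / "report",
    )


@pytest.fixture(scope="session")
def member_to_unit(pipeline_result):
    return {m: u.id for u in pipeline_result.units for m in u.members}
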