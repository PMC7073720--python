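import pytest
from hypothesis import HealthCheck, settings

import pgmine as pg

settings.register_profile(
    "pgmine",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("pgmine")


@pytest.fixture(scope="session")
def vocab():
    return pg.load_vocabulary()


@pytest.fixture(scope="session")
def default_sim():
    """Default study conditions: bundles plus planted truth (seed 0)."""
    config = pg.SimulationConfig(seed=0)
    bundles, truth = pg.generate_bundles(config)
    return config, bundles, truth


@pytest.fixture()
def tiny_bundle():
    """Hand-built three-transcript bundle with one pathway annotation."""
    transcripts = [
        pg.TranscriptRecord("t1", 900, 120, "MKLVAAGH"),
        pg.TranscriptRecord("t2", 1200, 0, "MKWWH"),
        pg.TranscriptRecord("t3", 600, 55),
    ]
    annotations = [
        pg.AnnotationHit("t1", "P12345", "Prostaglandin E synthase 2", 1, 900),
        pg.AnnotationHit("t2", "Q99999", "Heat shock protein 70", 1, 1200),
    ]
    return pg.TranscriptomeBundle(
        mmetsp_code="TEST0001",
        species="Testia exempli",
        genus="Testia",
        transcripts=transcripts,
        annotations=annotations,
        total_read_pairs=1_000_000,
        growth_metadata={"light": 60},
    )


@pytest.fixture()
def tiny_bundle_dir(tiny_bundle, tmp_path):
    return pg.write_bundle(tiny_bundle, tmp_path / "TEST0001")
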