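import os

import pytest
from hypothesis import HealthCheck, settings

import faerskit as fk

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_corpus(tmp_path_factory):
    """A seeded synthetic corpus with vocabulary and ground truth."""
    root = tmp_path_factory.mktemp("corpus")
    config = fk.SyntheticConfig(n_cases=120, seed=42)
    fixture, refs, truth = fk.generate_all(config, str(root))
    return {
        "root": str(root),
        "data_dir": os.path.join(str(root), "data"),
        "vocab_dir": os.path.join(str(root), "vocab"),
        "config": config,
        "fixture": fixture,
        "refs": refs,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def small_run(small_corpus, tmp_path_factory):
    """The full pipeline run on the small corpus."""
    out_dir = str(tmp_path_factory.mktemp("run"))
    config = fk.PipelineConfig(
        input_dir=small_corpus["data_dir"],
        vocab_dir=small_corpus["vocab_dir"],
        output_dir=out_dir,
    )
    report = fk.run_pipeline(config)
    return {"out_dir": out_dir, "report": report, "config": config,
            **small_corpus}


def curate(data_dir):
    """Parse + merge + impute + deduplicate, returning survivors."""
    from faerskit import dedup, merge
    from faerskit.pipeline import PipelineConfig, _parse_stage

    config = PipelineConfig(input_dir=data_dir, vocab_dir=data_dir,
                            output_dir=data_dir)
    versions, _ = _parse_stage(config)
    legacy = [v for v in versions if v.dialect is fk.SourceDialect.LEGACY]
    current = [v for v in versions if v.dialect is fk.SourceDialect.CURRENT]
    merged = merge.impute_all(merge.merge_datasets(legacy, current))
    return merged, dedup.deduplicate(merged)
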