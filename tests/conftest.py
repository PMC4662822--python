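"""Shared fixtures: the canonical synthetic dataset and derived strata.

The heavy objects (dataset, exact-mapper alignments, the end-to-end
pipeline bundle) are session-scoped so the whole suite pays for them once.
"""

import pytest

from pirnakit import library_prep as lp
from pirnakit import synthetic_data as sd
from pirnakit.cli import RunConfig, run_pipeline


@pytest.fixture(scope="session")
def default_dataset():
    return sd.generate(sd.default_spec(seed=1))


@pytest.fixture(scope="session")
def default_alignments(default_dataset):
    return lp.map_reads_exact(default_dataset.reads, default_dataset.genome)


@pytest.fixture(scope="session")
def pirna_strata(default_dataset, default_alignments):
    reads = lp.size_filter(default_dataset.reads, 24, 29)
    ids = {r.id for r in reads}
    alns = [a for a in default_alignments if a.read_id in ids]
    return lp.build_strata(reads, alns)


@pytest.fixture(scope="session")
def pipeline_bundle(default_dataset, tmp_path_factory):
    """The full file-based pipeline run once over the default landscape."""
    base = tmp_path_factory.mktemp("pipeline")
    paths = sd.write_outputs(default_dataset, base / "sim")
    config = RunConfig(
        reads=str(paths["reads"]),
        genome=str(paths["genome"]),
        te_consensus=str(paths["te_consensus"]),
        masked=str(paths["masked"]),
        transcripts=str(paths["transcripts"]),
        domains=str(paths["domains"]),
        mirna=str(paths["mirna"]),
        out_dir=str(base / "out"),
        count_dialect="none",
    )
    bundle = run_pipeline(config)
    bundle["_config"] = config
    bundle["_paths"] = paths
    return bundle
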