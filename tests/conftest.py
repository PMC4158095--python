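import logging
from pathlib import Path

import pytest

from dgetag.pipeline import PipelineConfig, run_pipeline
from dgetag.simulate import SimulationConfig, simulate_experiment

logging.disable(logging.INFO)


@pytest.fixture(scope="session")
def small_experiment(tmp_path_factory):
    """A complete small synthetic experiment plus its pipeline run.

    150 genes, 12 libraries of 8,000 tags — large enough to exercise every
    stage, small enough to run in a couple of seconds.
    """
    root = tmp_path_factory.mktemp("small_experiment")
    config = SimulationConfig(seed=20, n_genes=150, depth=8000)
    design, truth, paths = simulate_experiment(config, root / "sim")
    pipeline_config = PipelineConfig(
        transcript_fasta=str(paths[f"transcripts_{config.species_names[0]}"]),
        genome_fasta=str(paths["genome"]),
        design_table=str(paths["design"]),
        annotation_table=str(paths["annotation"]),
        output_dir=str(root / "out"),
        adaptor=config.adaptor,
        saturation_depths=[500, 2000, 8000],
        seed=20,
    )
    result = run_pipeline(pipeline_config)
    return {
        "config": config,
        "design": design,
        "truth": truth,
        "paths": paths,
        "pipeline_config": pipeline_config,
        "result": result,
        "root": root,
    }


@pytest.fixture()
def toy_fasta(tmp_path) -> Path:
    """Three toy genes, two CATG+17 sites each, all six tags distinct."""
    base = "TTTTT"
    seqs = {}
    for i, (a, b) in enumerate([("AAAAA", "CCCCC"), ("GGGGG", "ACACA"), ("TGTGT", "AGAGA")]):
        tag1 = "CATG" + (a * 4)[:17]
        tag2 = "CATG" + (b * 4)[:17]
        seqs[f"g{i}"] = base + tag1 + base + tag2 + base
    path = tmp_path / "toy.fasta"
    path.write_text("".join(f">{g}\n{s}\n" for g, s in seqs.items()))
    return path
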