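import pytest

from sorfscan import orfcall
from sorfscan.models import SEVEN_CLASSES
from sorfscan.synthio import SimConfig, simulate


@pytest.fixture(scope="session")
def default_sim():
    """One full simulation at the study-design defaults (6 tissues x 2 reps,
    10 planted sORFs per class, coverage 30/codon, periodicity 0.9)."""
    return simulate(SimConfig(seed=1))


@pytest.fixture(scope="session")
def default_called(default_sim):
    sim, psites, _, _ = default_sim
    sorfs, results = orfcall.call_sorfs(sim.models, psites)
    return sorfs, results


@pytest.fixture(scope="session")
def small_sim():
    """A minimal dataset (one planted sORF per class) for fast unit tests."""
    cfg = SimConfig(
        seed=3,
        n_coding_transcripts=8,
        n_noncoding_transcripts=3,
        planted_class_counts={c: 1 for c in SEVEN_CLASSES},
    )
    return simulate(cfg)


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One full pipeline run on the default synthetic dataset."""
    from sorfscan.cli import run_pipeline

    outdir = tmp_path_factory.mktemp("pipeline")
    manifest = run_pipeline(
        {"seed": 1, "simulate": {}, "params": {"n_permutations": 200}},
        outdir=str(outdir),
    )
    return outdir, manifest
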