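"""Shared fixtures: small profiles, and one session-scoped simulated study.

The study fixtures run the full pipeline once (8 taxa x 20 markers x 300
residues, no duplications, fixed seed) so that end-to-end recovery checks
and stage-level tests can share the cost of the search stage.
"""

import numpy as np
import pytest

from phylomark import (
    Alphabet,
    Msa,
    SimConfig,
    build_marker_set_from_seed_msas,
    build_profile_from_msa,
    generate_dataset,
)
from phylomark.cli import run_align, run_tree
from phylomark import trees as _t

STUDY_SEED = 1


@pytest.fixture(scope="session")
def study_dataset(tmp_path_factory):
    out = tmp_path_factory.mktemp("study-data")
    return generate_dataset(SimConfig(seed=STUDY_SEED), out)


@pytest.fixture(scope="session")
def study_markers(study_dataset):
    return build_marker_set_from_seed_msas(
        study_dataset.seed_msa_dir, name="study"
    )


@pytest.fixture(scope="session")
def study_pipeline(study_dataset, study_markers, tmp_path_factory):
    """Full pipeline outputs on the study dataset, both inference modes."""
    work = tmp_path_factory.mktemp("study-work")
    align = run_align(
        [str(p) for p in study_dataset.peptide_fastas.values()],
        study_markers,
        work,
    )
    consensus = run_tree(work / "alignments", work / "consensus", mode="consensus")
    concat = run_tree(
        work / "alignments", work / "concat", mode="concat", bootstrap=100, seed=7
    )
    return {
        "dataset": study_dataset,
        "markers": study_markers,
        "work": work,
        "align": align,
        "consensus": consensus,
        "concat": concat,
        "true_tree": _t.read_newick(str(study_dataset.true_tree_path)),
    }


@pytest.fixture
def toy_profile():
    """A 10-column peptide profile built from three identical rows."""
    msa = Msa(
        [("a", "ACDEFGHIKL"), ("b", "ACDEFGHIKL"), ("c", "ACDEFGHIKL")],
        Alphabet.AMINO20,
    )
    return build_profile_from_msa(msa, marker_id="toy")


@pytest.fixture
def rng():
    return np.random.default_rng(20250924)
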