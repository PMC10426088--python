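import numpy as np
import pytest
from hypothesis import settings

import longevol as lv

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from longevol.likelihood import PatternData
from longevol.ratematrix import uniform_pi
from longevol.trees import ArrayTree


@pytest.fixture(scope="session")
def three_taxon_tree() -> ArrayTree:
    return ArrayTree.from_newick("((A:0.1,B:0.2):0.15,C:0.3);", is_path=False)


@pytest.fixture(scope="session")
def small_tree() -> ArrayTree:
    """8-tip simulated tree, moderate depth."""
    return lv.simulate_tree(8, seed=11)


@pytest.fixture(scope="session")
def small_alignment(small_tree):
    aln, _ = lv.simulate_alignment(
        lv.AlignmentRecipe(tree=small_tree, n_codons=120,
                           classes=[(1.0, 0.3, 0.3)], gene_id="fix"),
        seed=5,
    )
    return aln


@pytest.fixture(scope="session")
def pi_uniform():
    return uniform_pi()


@pytest.fixture(scope="session")
def study_run(tmp_path_factory):
    """One full pipeline execution on the seed-42 synthetic study.

    Shared by the end-to-end checks; the determinism check performs its own
    second run and compares against this one.
    """
    from longevol.pipeline import run_pipeline

    root = tmp_path_factory.mktemp("study")
    bundle = lv.make_fixture_study(42, n_tips=8, n_codons=60)
    bundle_dir = root / "bundle"
    bundle.write(bundle_dir)
    import time
    t0 = time.perf_counter()
    out = run_pipeline(bundle.pipeline_config(bundle_dir), root / "results")
    elapsed = time.perf_counter() - t0
    return {"bundle": bundle, "bundle_dir": bundle_dir, "out": out,
            "elapsed": elapsed}
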