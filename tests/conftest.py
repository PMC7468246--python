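"""Shared fixtures: synthetic workspaces and pipeline runs.

The full-size workspace (the study conditions: 20 taxa, 60 loci, 10%
planted contaminants and symbiont inserts, 3 misplaced taxa, 1 barcode
cross-contaminant at 1/150 coverage, seed 42) is built once per session
and both workflows are run on it once; the planted-anomaly and
conservation tests all read from that single run.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from coralbaits.fixtures import FixtureConfig, make_workspace
from coralbaits.pipeline import run_design, run_postcapture

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture(scope="session")
def study_workspace(tmp_path_factory):
    """The full planted-anomaly workspace plus both workflow runs."""
    root = tmp_path_factory.mktemp("study")
    cfg = FixtureConfig(seed=42)
    truth = make_workspace(cfg, root / "ws")
    design_summary = run_design(root / "ws", root / "out" / "design")
    post_summary = run_postcapture(root / "ws", root / "out" / "post")
    return {
        "cfg": cfg,
        "root": root,
        "workspace": root / "ws",
        "outdir": root / "out",
        "truth": truth,
        "design": design_summary,
        "postcapture": post_summary,
    }


@pytest.fixture(scope="session")
def small_cfg():
    """A miniature configuration for byte-determinism and CLI tests."""
    return FixtureConfig(
        seed=7,
        n_robust=4,
        n_complex=4,
        n_outgroup=2,
        n_loci=8,
        n_misplaced=1,
    )
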