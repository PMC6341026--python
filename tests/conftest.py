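import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from coxmix.io_genomics import GenomicInterval, PeakSet, StateSegmentation
from coxmix.lgcp import GridSpec, PriorSpec
from coxmix.projection import PointPattern


@pytest.fixture
def small_grid():
    return GridSpec(B=5, L=50.0)


@pytest.fixture
def default_theta():
    return PriorSpec()


@pytest.fixture
def three_window_seg():
    """Segmentation with 3 windows of state D5 (plus one distractor state)."""
    return StateSegmentation(
        windows=(
            GenomicInterval("chr1", 0, 1000, "D5"),
            GenomicInterval("chr1", 2000, 2500, "D5"),
            GenomicInterval("chr2", 100, 600, "D5"),
            GenomicInterval("chr1", 1000, 2000, "D1"),
        )
    )


@pytest.fixture
def toy_bed(tmp_path):
    p = tmp_path / "TFX.bed"
    p.write_text("chr1\t100\t300\nchr1\t500\t700\nchr2\t0\t200\n")
    return p


def make_pattern(events, protein="P", state="D5", L=50.0):
    return PointPattern(protein=protein, state=state,
                        events=np.asarray(events, dtype=float), L=L)


@pytest.fixture
def pattern_factory():
    return make_pattern
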