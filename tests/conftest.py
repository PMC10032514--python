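import numpy as np
import pytest

from scentmatch.peak_io import Carrier, Peak, PeakTable
from scentmatch.ri_alignment import MarkerLadder


@pytest.fixture
def identity_ladder():
    """Ladder whose RI equals rt1 (unit slope through the origin)."""
    return MarkerLadder(markers=((100.0, 100.0), (2000.0, 2000.0)))


def make_table(sample_id, peaks, subject_id=None, carrier=Carrier.glass_beads):
    """Build a PeakTable from (rt1, area) or (rt1, area, label) tuples."""
    rows = []
    for k, spec in enumerate(peaks):
        rt1, area, label = (*spec, None) if len(spec) == 2 else spec
        rows.append(Peak(peak_id=f"{sample_id}_p{k}", rt1=rt1, rt2=1.0, area=area, label=label))
    return PeakTable(sample_id=sample_id, peaks=rows, subject_id=subject_id, carrier=carrier)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
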