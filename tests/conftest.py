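import numpy as np
import pandas as pd
import pytest

from titrseq.io_formats import EventCallRecord, EventCoords, ExpressionTable, PWMRecord
from titrseq.synthetic_data import SimulationConfig


@pytest.fixture
def toy_expression() -> ExpressionTable:
    """3 features × 4 doses, all passing the abundance filter."""
    data = pd.DataFrame(
        {
            "DMSO": [2.0, 5.0, 10.0],
            "0.5uM": [2.5, 4.0, 10.0],
            "2uM": [3.0, 3.0, 10.0],
            "5uM": [4.0, 2.0, 10.0],
        },
        index=["g1", "g2", "g3"],
    )
    return ExpressionTable(data=data, dose_values=(0.0, 0.5, 2.0, 5.0), feature_kind="gene")


def make_se_event(
    event_id: str = "ev1",
    strand: str = "+",
    alt_len: int = 90,
    intron_len: int = 1000,
    exon_len: int = 150,
    origin: int = 500,
    psi=None,
    caller: str = "misolike",
    delta_psi: float = 0.3,
    confidence: float = 20.0,
    chrom: str = "chrS",
) -> EventCallRecord:
    pos = origin
    segs = []
    for name, length in [
        ("upstream_exon", exon_len),
        ("upstream_intron", intron_len),
        ("alt", alt_len),
        ("downstream_intron", intron_len),
        ("downstream_exon", exon_len),
    ]:
        segs.append((name, pos, pos + length))
        pos += length
    return EventCallRecord(
        event_id=event_id,
        caller=caller,
        event_type="SE",
        psi=psi or {"DMSO": 0.2, "2uM": 0.5, "5uM": 0.8},
        delta_psi=delta_psi,
        confidence=confidence,
        coords=EventCoords(chrom=chrom, strand=strand, segments=tuple(segs)),
    )


@pytest.fixture
def uniform_pwm() -> PWMRecord:
    """4-position PWM with 0.85 on a fixed base per position (AC GU consensus)."""
    probs = np.full((4, 4), 0.05)
    for i, b in enumerate([0, 1, 2, 3]):  # consensus ACGU
        probs[i, b] = 0.85
    return PWMRecord(motif_id="M1", rbp_names=("RBPX",), probs=probs)


@pytest.fixture
def sim_config() -> SimulationConfig:
    return SimulationConfig(seed=1)
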