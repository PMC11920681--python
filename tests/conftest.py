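import numpy as np
import pandas as pd
import pytest

from cytoglia import ChannelInfo, EventTable, simulate_run, timecourse_config


@pytest.fixture(scope="session")
def artifact_run():
    """A 20-sample pooled run with all artifact classes planted: 2x drift,
    doublets, dead cells, beads.  Shared by the normalization, debarcoding
    and gating tests."""
    cfg = timecourse_config(
        "LPS", "microglia_only", replicates=(1, 2), events_per_sample=800, seed=11
    )
    table, truth = simulate_run(cfg)
    return cfg, table, truth


@pytest.fixture()
def tiny_table():
    """A 4-event, 3-channel table for serialization and container tests."""
    channels = [
        ChannelInfo("CD11b", marker="CD11b", metal="115In", role="identity"),
        ChannelInfo("pERK", marker="pERK", metal="167Er", role="signaling"),
        ChannelInfo("Event_length", role="instrument"),
    ]
    values = np.array(
        [[1.0, 2.0, 30.0], [0.0, 5.5, 28.0], [7.25, 0.0, 31.0], [3.0, 1.0, 29.0]],
        dtype=np.float32,
    )
    return EventTable(values, channels)


def barcode_table(raw_rows, channels=None, background=1.0, n_background=100):
    """Build an EventTable whose barcode channels have unit positive span,
    so the rescaled values of the appended ``raw_rows`` are simply
    row / row-max.  Returns (table, index of first appended row)."""
    from cytoglia.panel import BARCODE_CHANNELS

    channels = channels or list(BARCODE_CHANNELS)
    bg = np.full((n_background, len(channels)), background, dtype=np.float64)
    rows = np.asarray(raw_rows, dtype=np.float64)
    values = np.vstack([bg, rows])
    infos = [ChannelInfo(c, role="barcode") for c in channels]
    return EventTable(values, infos), n_background
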