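"""Shared assertion helpers for the test suite."""

import numpy as np


def assert_ascent(trace, slack=1e-6):
    """Objective trace must be non-decreasing up to absolute/relative slack."""
    trace = np.asarray(trace, float)
    if trace.size < 2:
        return
    drops = np.diff(trace)
    floor = -slack * (1.0 + np.abs(trace[:-1]))
    assert np.all(drops >= floor), f"objective decreased by {drops.min():.3g}"
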