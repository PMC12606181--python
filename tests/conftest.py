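import numpy as np
import pandas as pd
import pytest

from dyadseq.ethogram import TIER_OF, REPERTOIRE, DyadBinMatrix, enumerate_dyads


@pytest.fixture
def tiny_roster():
    """Four birds, two capture sites -> 2 familiar + 4 stranger dyads."""
    return pd.DataFrame({
        "id": ["A", "B", "C", "D"],
        "sex": ["F", "M", "M", "F"],
        "site": ["S1", "S1", "S2", "S2"],
    })


@pytest.fixture
def one_session_schedule():
    """A single 1-hour session (12 five-minute bins)."""
    return pd.DataFrame({
        "session_id": ["s1"],
        "date": ["2021-04-01"],
        "start": ["08:00:00"],
        "end": ["09:00:00"],
    })


def make_matrix(roster, occurrences, n_bins, bin_width=300):
    """Build a DyadBinMatrix directly from (member_a, member_b, behavior, bin) tuples."""
    dyads = enumerate_dyads(roster)
    index = {
        (a, b): i
        for i, (a, b) in enumerate(zip(dyads["member_low"], dyads["member_high"]))
    }
    rows = []
    for a, b, beh, g in occurrences:
        lo, hi = min(a, b), max(a, b)
        rows.append((index[(lo, hi)], beh, int(TIER_OF[beh]), int(g)))
    occ = pd.DataFrame(rows, columns=["dyad", "behavior", "tier", "bin"])
    occ = occ.drop_duplicates().sort_values(["dyad", "behavior", "bin"]).reset_index(drop=True)
    hours = n_bins * bin_width / 3600
    return DyadBinMatrix(dyads, REPERTOIRE, n_bins, bin_width, occ, hours)


@pytest.fixture
def matrix_factory():
    return make_matrix
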