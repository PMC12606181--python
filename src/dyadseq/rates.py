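"""Pre-contact proximity rates and the sign-flip paired permutation test.

If approaching and maintaining no-contact proximity is how strangers vet
future contact partners, then — *before any contact happens* — a bird should
be seen in proximity more often with the stranger partners it later contacts
than with the stranger partners it never contacts.  For each bird we compute
its mean hourly proximity rate over the two partner classes (contacted
partners truncated to the window before the dyad's first contact) and test
the paired difference with a permuted paired t-test: the null distribution
comes from independently flipping the sign of each bird's difference.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ethogram import DyadBinMatrix, RiskTier
from .permutation import PermutationResult
from .sequences import first_occurrence_matrix

logger = logging.getLogger(__name__)


def dyad_hourly_rate(
    matrix: DyadBinMatrix,
    dyad: int,
    truncate_at: int | None = None,
) -> float | None:
    """Proximity occurrences per observed hour for one dyad.

    Counts the 5-minute bins with a LOW (no-contact proximity) occurrence in
    ``[0, truncate_at)`` and divides by the observed hours those bins
    represent.  ``truncate_at=None`` uses the whole study.  Because the
    global bin index only covers in-session time, the window's observed hours
    are simply ``truncate_at * bin_width / 3600``.

    Returns None (excluded, with a warning) when the window is empty.
    """
    end = matrix.n_bins if truncate_at is None else int(truncate_at)
    if end <= 0:
        logger.warning("dyad %d: empty pre-contact window, rate undefined", dyad)
        return None
    hours = end * matrix.bin_width / 3600.0
    o = matrix.occurrences
    n = int(((o["dyad"] == dyad) & (o["tier"] == int(RiskTier.LOW)) & (o["bin"] < end)).sum())
    return n / hours


@dataclass
class PairedRateRecord:
    bird: str
    rate_contact: float
    rate_noncontact: float
    n_partners_contact: int
    n_partners_noncontact: int


def paired_rates(matrix: DyadBinMatrix) -> pd.DataFrame:
    """Per-bird mean hourly proximity rates with contacted vs never-contacted strangers.

    Stranger partners are split by whether the dyad was *ever* observed in
    any contact behaviour (MODERATE or HIGH).  For contacted partners the
    rate is truncated to before the dyad's first contact bin; for
    never-contacted partners the whole study counts.  Partner means are
    unweighted.  Birds with an empty partner class (or whose only contacted
    partners made contact in bin 0, leaving no pre-contact window) are
    excluded from the paired table, with a log entry.
    """
    firsts = first_occurrence_matrix(matrix)
    first_contact = np.minimum(firsts[:, 1], firsts[:, 2])  # inf if never contacted
    dyads = matrix.dyads
    stranger = (dyads["familiarity"] == "stranger").to_numpy()

    birds = sorted(set(dyads["member_low"]) | set(dyads["member_high"]))
    rows = []
    for bird in birds:
        member = ((dyads["member_low"] == bird) | (dyads["member_high"] == bird)).to_numpy()
        contact_rates, noncontact_rates = [], []
        for d in np.flatnonzero(member & stranger):
            if np.isfinite(first_contact[d]):
                r = dyad_hourly_rate(matrix, d, truncate_at=int(first_contact[d]))
                if r is not None:
                    contact_rates.append(r)
            else:
                r = dyad_hourly_rate(matrix, d)
                if r is not None:
                    noncontact_rates.append(r)
        if not contact_rates or not noncontact_rates:
            logger.info("bird %s excluded from paired rates (empty partner class)", bird)
            continue
        rows.append(PairedRateRecord(
            bird,
            float(np.mean(contact_rates)),
            float(np.mean(noncontact_rates)),
            len(contact_rates),
            len(noncontact_rates),
        ))
    return pd.DataFrame([vars(r) for r in rows])


def _paired_t(diffs: np.ndarray) -> np.ndarray:
    """Paired t statistic along the last axis; 0/±inf conventions for sd == 0."""
    diffs = np.atleast_2d(diffs)
    n = diffs.shape[-1]
    mean = diffs.mean(axis=-1)
    sd = diffs.std(axis=-1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
        t = np.where(sd == 0, np.sign(mean) * np.inf, t)
        return np.where((sd == 0) & (mean == 0), 0.0, t)


def permuted_paired_test(
    pairs: pd.DataFrame,
    n_iter: int = 5000,
    seed: int = 0,
    exact: bool = False,
) -> PermutationResult:
    """One-sided sign-flip permutation test of contact > non-contact rates.

    The statistic is the paired t on per-bird differences
    ``rate_contact - rate_noncontact``; each null draw independently negates
    every difference with probability 1/2 (under the no-preference null the
    labelling of the two partner classes is exchangeable within a bird).
    ``exact=True`` enumerates all 2^n sign patterns instead of sampling and
    reports ``p = #{null t >= observed t} / 2^n``.
    """
    if len(pairs) < 2:
        raise ValueError("paired test needs at least 2 birds with both partner classes")
    diffs = (pairs["rate_contact"] - pairs["rate_noncontact"]).to_numpy(float)
    n = len(diffs)
    obs = float(_paired_t(diffs)[0])
    degenerate = bool(np.all(diffs == 0))
    if degenerate:
        logger.warning("all paired differences are zero: test degenerate, p = 1")

    if exact:
        signs = np.array(list(itertools.product((1.0, -1.0), repeat=n)))
        null = _paired_t(signs * diffs)
        k = int(np.sum(null >= obs - 1e-12))
        res = PermutationResult("paired_rate_t", obs, null, len(null), seed, degenerate)
        # exact enumeration: p over the full group, no add-one needed
        res.exact_p = k / len(null)
        return res

    rng = np.random.default_rng(seed)
    signs = rng.choice((1.0, -1.0), size=(n_iter, n))
    null = _paired_t(signs * diffs)
    return PermutationResult("paired_rate_t", obs, null, n_iter, seed, degenerate)
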