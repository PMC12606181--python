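"""First-occurrence extraction and escalation-sequence verdicts.

The hypothesis under test — that strangers reduce social uncertainty by
escalating from low- to high-risk behaviours ("testing the waters") — makes
two ordered predictions about a dyad's *first* use of each risk tier:

* **generalized sequence**: the first LOW (no-contact proximity) bin strictly
  precedes the first bin of any contact tier (MODERATE or HIGH);
* **precise sequence**: additionally, the first MODERATE bin precedes the
  first HIGH bin, or the two fall in the same 5-minute bin (the only
  simultaneity the prediction tolerates).

Dyads never observed in any contact behaviour have nothing to order against
proximity and are *not evaluable*; they are excluded from sequence
denominators by default (``noncontact_as_supported`` flips that for
sensitivity analysis).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ethogram import DyadBinMatrix, RiskTier

#: Verdict codes used in the vectorized representation.
SUPPORTED, VIOLATED, NOT_EVALUABLE = "supported", "violated", "not_evaluable"

_ABSENT = np.inf  # first-bin sentinel for a tier never observed


@dataclass
class FirstOccurrences:
    """Per-dyad first bin of each risk tier (None where never observed)."""

    dyad: int
    low: int | None
    moderate: int | None
    high: int | None

    def as_array(self) -> np.ndarray:
        return np.array(
            [_ABSENT if v is None else v for v in (self.low, self.moderate, self.high)],
            dtype=float,
        )


def first_occurrence_matrix(matrix: DyadBinMatrix) -> np.ndarray:
    """(n_dyads, 3) array of first bins per tier; inf where a tier was never seen.

    The first bin of a tier is the minimum bin over all behaviours of that
    tier — within-tier behaviour order is deliberately ignored.
    """
    dyad, tier, bins = matrix.occ_arrays()
    return _firsts_from_records(dyad, tier, bins, matrix.n_dyads)


def _firsts_from_records(
    dyad: np.ndarray, tier: np.ndarray, bins: np.ndarray, n_dyads: int
) -> np.ndarray:
    firsts = np.full((n_dyads, 3), _ABSENT)
    np.minimum.at(firsts, (dyad, tier), bins.astype(float))
    return firsts


def first_occurrences(matrix: DyadBinMatrix, dyad: int) -> FirstOccurrences:
    """First-occurrence bins of one dyad (by integer dyad index)."""
    if not 0 <= dyad < matrix.n_dyads:
        raise IndexError(f"dyad index {dyad} out of range")
    row = first_occurrence_matrix(matrix)[dyad]
    vals = [None if np.isinf(v) else int(v) for v in row]
    return FirstOccurrences(dyad, *vals)


def _verdicts(firsts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized generalized/precise verdicts from an (n, 3) firsts array.

    Returns two object arrays of verdict strings.
    """
    firsts = np.atleast_2d(np.asarray(firsts, dtype=float))
    low, mod, high = firsts[:, 0], firsts[:, 1], firsts[:, 2]
    contact = np.minimum(mod, high)
    evaluable = np.isfinite(contact)

    # LOW must strictly precede the earliest contact tier; a tie violates.
    gen_sup = evaluable & np.isfinite(low) & (low < contact)

    # HIGH absent, or MODERATE at or before HIGH (same bin tolerated).
    prec_sup = gen_sup & (~np.isfinite(high) | (mod <= high))

    gen = np.where(evaluable, np.where(gen_sup, SUPPORTED, VIOLATED), NOT_EVALUABLE)
    prec = np.where(evaluable, np.where(prec_sup, SUPPORTED, VIOLATED), NOT_EVALUABLE)
    return gen.astype(object), prec.astype(object)


def classify_generalized(firsts: FirstOccurrences | np.ndarray) -> str:
    """Verdict for the generalized sequence (LOW strictly before any contact)."""
    arr = firsts.as_array() if isinstance(firsts, FirstOccurrences) else np.asarray(firsts)
    return _verdicts(arr.reshape(1, 3))[0][0]


def classify_precise(firsts: FirstOccurrences | np.ndarray) -> str:
    """Verdict for the precise sequence (LOW, then MODERATE before/with HIGH)."""
    arr = firsts.as_array() if isinstance(firsts, FirstOccurrences) else np.asarray(firsts)
    return _verdicts(arr.reshape(1, 3))[1][0]


def classify_all(
    matrix: DyadBinMatrix,
    noncontact_as_supported: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify every dyad and summarize proportions per familiarity stratum.

    Returns
    -------
    classifications : DataFrame
        One row per dyad: members, familiarity, sex composition, first bins
        per tier (NaN = never observed), and the two verdicts.
    summary : DataFrame
        Per (familiarity stratum, sequence type): number supported, number
        evaluable, and the supported proportion (NaN when no dyad in the
        stratum is evaluable).
    """
    firsts = first_occurrence_matrix(matrix)
    gen, prec = _verdicts(firsts)
    if noncontact_as_supported:
        gen = np.where(gen == NOT_EVALUABLE, SUPPORTED, gen)
        prec = np.where(prec == NOT_EVALUABLE, SUPPORTED, prec)

    out = matrix.dyads.copy()
    with np.errstate(invalid="ignore"):
        ff = np.where(np.isinf(firsts), np.nan, firsts)
    out["first_low_bin"] = ff[:, 0]
    out["first_mod_bin"] = ff[:, 1]
    out["first_high_bin"] = ff[:, 2]
    out["generalized"] = gen
    out["precise"] = prec

    rows = []
    for stratum in ("stranger", "familiar", "all"):
        mask = np.ones(len(out), bool) if stratum == "all" else (out["familiarity"] == stratum).to_numpy()
        for seq, v in (("generalized", gen), ("precise", prec)):
            ev = int(np.sum(mask & (v != NOT_EVALUABLE)))
            sup = int(np.sum(mask & (v == SUPPORTED)))
            rows.append((stratum, seq, sup, ev, sup / ev if ev else np.nan))
    summary = pd.DataFrame(
        rows, columns=["stratum", "sequence", "n_supported", "n_evaluable", "proportion"]
    )
    return out, summary


def supported_proportion(
    firsts: np.ndarray, stratum_mask: np.ndarray, sequence: str = "generalized"
) -> float:
    """Supported / evaluable within a stratum; NaN when nothing is evaluable."""
    gen, prec = _verdicts(firsts)
    v = gen if sequence == "generalized" else prec
    ev = stratum_mask & (v != NOT_EVALUABLE)
    n_ev = int(ev.sum())
    if n_ev == 0:
        return np.nan
    return float(np.sum(v[ev] == SUPPORTED) / n_ev)
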