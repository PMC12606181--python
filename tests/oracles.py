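"""Hand-derived expectations and brute-force reference computations for tests.

Everything here is written from the verbal definitions of the analysis and
kept free of the package's own vectorized code paths, so agreement is a real
cross-check rather than a tautology.
"""

import itertools

import numpy as np

#: Hand-worked truth table for the sequence verdicts.  Keys are the first
#: bins of (LOW, MODERATE, HIGH), None = tier never observed; values are the
#: expected (generalized, precise) verdicts.  S = supported, V = violated,
#: NE = not evaluable.  Rules: no contact tier -> nothing to order (NE);
#: generalized requires LOW strictly before the earliest contact tier (a tie
#: violates); precise additionally requires MODERATE before or in the same
#: bin as HIGH, and a HIGH with no MODERATE at all breaks the full ladder.
TRUTH_TABLE = {
    (None, None, None): ("NE", "NE"),
    (5, None, None): ("NE", "NE"),
    (None, 5, None): ("V", "V"),
    (None, None, 5): ("V", "V"),
    (None, 5, 5): ("V", "V"),
    (3, 7, None): ("S", "S"),
    (7, 3, None): ("V", "V"),
    (3, 3, None): ("V", "V"),
    (3, None, 9): ("S", "V"),
    (5, None, 3): ("V", "V"),
    (None, 3, 9): ("V", "V"),
    (None, 9, 3): ("V", "V"),
    (3, 5, 9): ("S", "S"),
    (3, 9, 5): ("S", "V"),
    (5, 3, 9): ("V", "V"),
    (9, 3, 5): ("V", "V"),
    (5, 9, 3): ("V", "V"),
    (9, 5, 3): ("V", "V"),
    (3, 5, 5): ("S", "S"),
    (3, 3, 9): ("V", "V"),
    (3, 9, 9): ("S", "S"),
    (3, 3, 3): ("V", "V"),
}

_CODE = {"S": "supported", "V": "violated", "NE": "not_evaluable"}


def expected_verdicts(low, mod, high):
    gen, prec = TRUTH_TABLE[(low, mod, high)]
    return _CODE[gen], _CODE[prec]


def classify_firsts(low, mod, high):
    """Reference classifier: a direct, scalar transcription of the rules."""
    contact = [b for b in (mod, high) if b is not None]
    if not contact:
        return "not_evaluable", "not_evaluable"
    gen = "supported" if (low is not None and low < min(contact)) else "violated"
    if gen == "violated":
        return gen, "violated"
    if high is None or (mod is not None and mod <= high):
        return gen, "supported"
    return gen, "violated"


def brute_force_null_mean(records, stratum_dyads, all_dyads, sequence="generalized"):
    """Exact permutation-null mean of the supported proportion.

    ``records`` is a list of (dyad, tier, bin) tuples.  Enumerates every
    assignment of the observed bin multiset to the records, reclassifies
    each dyad from scratch with the scalar reference classifier, and
    averages the stratum's supported/evaluable proportion over all
    assignments (skipping assignments where nothing is evaluable).
    """
    bins = [r[2] for r in records]
    vals = []
    for perm in itertools.permutations(bins):
        firsts = {}
        for (d, t, _), b in zip(records, perm):
            key = (d, t)
            firsts[key] = min(firsts.get(key, b), b)
        sup = ev = 0
        for d in stratum_dyads:
            low = firsts.get((d, 0))
            mod = firsts.get((d, 1))
            high = firsts.get((d, 2))
            gen, prec = classify_firsts(low, mod, high)
            v = gen if sequence == "generalized" else prec
            if v != "not_evaluable":
                ev += 1
                sup += v == "supported"
        vals.append(sup / ev if ev else np.nan)
    return float(np.nanmean(vals))


def paired_t(diffs):
    diffs = np.asarray(diffs, float)
    n = len(diffs)
    sd = diffs.std(ddof=1)
    if sd == 0:
        return 0.0 if diffs.mean() == 0 else np.sign(diffs.mean()) * np.inf
    return diffs.mean() / (sd / np.sqrt(n))


def exhaustive_signflip_p(diffs):
    """One-sided p over all 2^n sign patterns of the paired differences."""
    diffs = np.asarray(diffs, float)
    obs = paired_t(diffs)
    hits = total = 0
    for signs in itertools.product((1.0, -1.0), repeat=len(diffs)):
        total += 1
        hits += paired_t(np.array(signs) * diffs) >= obs - 1e-12
    return hits / total
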