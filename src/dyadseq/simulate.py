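"""Synthetic observation-stream generator with known ground truth.

Emulates the observational design the pipeline consumes: a single captive
group assembled from several capture sites (default 22 birds from sites of
5/6/7/4), observed over ~22 days of split morning/evening sessions (~6 h per
day), with nearest-neighbour proximity scans every 5 minutes and
all-occurrence sampling of five contact behaviours, logged by four observers
who occasionally duplicate the same contact event.

The latent relationship process is a discrete-time per-bin hazard chain at
the 5-minute granularity of everything downstream.  A *progressing* dyad
draws an escalation order over the three risk tiers — the predicted
LOW -> MODERATE -> HIGH order with probability ``adherence``, otherwise a
uniformly random order — and then passes through tier onsets separated by
geometric waiting times.  Each observed tier emits events from its onset at a
tier-specific hourly rate (proximity only at scan marks, contact at arbitrary
times).  Non-progressing dyads show only background proximity.  Familiar
dyads skip the mandatory proximity lead-in with a configurable probability
(their relationships predate the study) which is what makes the familiarity
contrast recoverable.

``null_mode`` replaces the hazard chain with fully exchangeable event
timing: event counts are drawn per dyad and tier, and every event's bin is
independent and uniform over the study, with identical proximity rates for
all dyads.  Under this regime tier order is random and no proximity
preference exists, which is exactly the regime the permutation null and the
sign-flip test assume.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .ethogram import enumerate_dyads
from .mmodel import ModelData

logger = logging.getLogger(__name__)

_TIERS = ("LOW", "MODERATE", "HIGH")
_MOD_BEHAVIORS = ("shoulder_contact", "allopreen", "beak_touch")
_HIGH_BEHAVIORS = ("allofeed", "copulation")
_OBSERVERS = ("obs1", "obs2", "obs3", "obs4")


class ConfigError(ValueError):
    """The simulation configuration is infeasible."""


@dataclass
class EscalationHazards:
    """Per-5-min-bin probabilities of the three escalation steps.

    ``init`` starts the first tier of a progressing dyad's order (default
    mean wait ~150 bins, i.e. ~2 observation days); ``low_to_moderate`` and
    ``moderate_to_high`` govern the waits between successive tier onsets.
    """

    init: float = 1 / 150
    low_to_moderate: float = 1 / 250
    moderate_to_high: float = 1 / 1200


@dataclass
class SimulationConfig:
    """Study-design and behavioural parameters of the generator.

    Defaults mirror the observational design described above: 22 birds from
    four sites, 22 days at ~6 observation hours per day (two sessions), a
    300 s scan/bin interval.  Behavioural defaults give roughly a third of
    stranger dyads a progressing relationship, strong (but imperfect)
    adherence to the predicted order among strangers and weaker adherence
    among familiars, and a ~3x higher pre-contact proximity rate for
    progressing dyads than background — the regime the analysis is meant to
    detect.
    """

    site_sizes: tuple[int, ...] = (5, 6, 7, 4)
    sex_ratio: float = 8 / 22          # fraction female
    n_days: int = 22
    session_hours_per_day: float = 6.0  # split into two equal sessions
    bin_width: int = 300
    adherence: float = 0.92            # stranger dyads' P(predicted order)
    familiar_adherence: float = 0.75
    escalation_hazards: EscalationHazards = field(default_factory=EscalationHazards)
    familiar_boost: float = 2.2        # multiplier on contact propensity for familiars
    preference_fraction: float = 0.31  # strangers that will ever progress
    proximity_rate_progressing: float = 0.06   # LOW events / observed hour after onset
    proximity_rate_background: float = 0.012
    moderate_rate: float = 0.05        # contact events / hour after tier onset
    high_rate: float = 0.02
    observer_duplication_rate: float = 0.15
    sex_effect: float = 0.0            # logit shift of adherence: +FF, -MM
    null_mode: bool = False

    def validate(self) -> None:
        if sum(self.site_sizes) < 2:
            raise ConfigError("need at least two birds")
        if self.n_days < 1 or self.session_hours_per_day <= 0:
            raise ConfigError("need at least one session")
        for name in ("adherence", "familiar_adherence", "preference_fraction",
                     "observer_duplication_rate", "sex_ratio"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} = {v} outside [0, 1]")
        if self.bin_width <= 0:
            raise ConfigError("bin_width must be positive")

    @property
    def bins_per_session(self) -> int:
        nb = round(self.session_hours_per_day / 2 * 3600 / self.bin_width)
        if nb < 1:
            raise ConfigError("sessions shorter than one bin")
        return nb

    @property
    def n_bins(self) -> int:
        return 2 * self.n_days * self.bins_per_session

    def implied_beta_stranger(self) -> float:
        """Log-odds contrast implied by the adherence settings.

        Uses the no-tie, no-truncation approximation that a random order is
        supported (generalized) with probability 1/3.
        """
        p_s = self.adherence + (1 - self.adherence) / 3
        p_f = self.familiar_adherence + (1 - self.familiar_adherence) / 3
        return float(logit(p_s) - logit(p_f))


@dataclass
class SimulatedCohort:
    """Roster, schedule and observation tables plus per-dyad ground truth."""

    roster: pd.DataFrame
    schedule: pd.DataFrame
    observations: pd.DataFrame
    truth: pd.DataFrame
    config: SimulationConfig
    seed: int

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, df in (
            ("roster", self.roster),
            ("schedule", self.schedule),
            ("observations", self.observations),
            ("ground_truth", self.truth),
        ):
            p = outdir / f"{name}.csv"
            df.to_csv(p, index=False)
            paths[name] = p
        return paths


def _make_roster(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = sum(config.site_sizes)
    ids = [f"B{k + 1:02d}" for k in range(n)]
    sites = np.repeat([f"S{s + 1}" for s in range(len(config.site_sizes))], config.site_sizes)
    n_f = int(round(config.sex_ratio * n))
    sex = np.array(["F"] * n_f + ["M"] * (n - n_f))
    rng.shuffle(sex)
    return pd.DataFrame({"id": ids, "sex": sex, "site": sites})


def _make_schedule(config: SimulationConfig) -> pd.DataFrame:
    dur_h = config.bins_per_session * config.bin_width / 3600
    rows = []
    base = pd.Timestamp("2021-04-01")
    for d in range(config.n_days):
        date = (base + pd.Timedelta(days=d)).date().isoformat()
        for tag, start_h in (("m", 8.0), ("e", 15.0)):
            start = pd.Timestamp(date) + pd.Timedelta(hours=start_h)
            end = start + pd.Timedelta(hours=dur_h)
            rows.append((f"d{d + 1:02d}{tag}", date,
                         start.strftime("%H:%M:%S"), end.strftime("%H:%M:%S")))
    return pd.DataFrame(rows, columns=["session_id", "date", "start", "end"])


def _draw_order(rng: np.random.Generator, theta: float) -> tuple[int, ...]:
    if rng.random() < theta:
        return (0, 1, 2)
    return tuple(rng.permutation(3))


def simulate(config: SimulationConfig | None = None, seed: int = 0) -> SimulatedCohort:
    """Generate a cohort: roster, session schedule, raw observations, truth.

    Fully reproducible: the same config and seed yield byte-identical CSVs.
    """
    config = config or SimulationConfig()
    config.validate()
    rng = np.random.default_rng(seed)
    roster = _make_roster(config, rng)
    schedule = _make_schedule(config)
    dyads = enumerate_dyads(roster)
    n_bins = config.n_bins
    per_bin = config.bin_width / 3600.0  # hours per bin
    hz = config.escalation_hazards

    truth_rows = []
    ev_dyad: list[int] = []
    ev_tier: list[int] = []
    ev_bins: list[np.ndarray] = []

    for d, row in dyads.iterrows():
        familiar = row["familiarity"] == "familiar"
        p_prog = config.preference_fraction * (config.familiar_boost if familiar else 1.0)
        progressing = rng.random() < min(1.0, p_prog)
        theta = config.familiar_adherence if familiar else config.adherence
        if config.sex_effect:
            shift = {"FF": config.sex_effect, "MM": -config.sex_effect}.get(row["sex_composition"], 0.0)
            theta = float(expit(logit(min(max(theta, 1e-9), 1 - 1e-9)) + shift))

        onsets = [None, None, None]
        order = None
        if config.null_mode:
            # exchangeable regime: iid-uniform bins, equal proximity rates
            counts = {
                0: rng.binomial(n_bins, min(1.0, config.proximity_rate_background * per_bin)),
                1: 0,
                2: 0,
            }
            if progressing:
                counts[1] = max(1, rng.binomial(n_bins, min(1.0, config.moderate_rate * per_bin)))
                counts[2] = rng.binomial(n_bins, min(1.0, config.high_rate * per_bin))
            for t, c in counts.items():
                if c:
                    ev_dyad.append(d)
                    ev_tier.append(t)
                    ev_bins.append(rng.integers(0, n_bins, size=c))
        elif progressing:
            order = _draw_order(rng, theta)
            boost = config.familiar_boost if familiar else 1.0
            o1 = rng.geometric(hz.init) - 1
            o2 = o1 + rng.geometric(min(1.0, hz.low_to_moderate * boost))
            o3 = o2 + rng.geometric(min(1.0, hz.moderate_to_high * boost))
            for tier, onset in zip(order, (o1, o2, o3)):
                if onset >= n_bins:
                    continue
                onsets[tier] = int(onset)
                rate = {
                    0: config.proximity_rate_progressing,
                    1: config.moderate_rate,
                    2: config.high_rate,
                }[tier]
                later = onset + 1 + np.flatnonzero(
                    rng.random(n_bins - onset - 1) < rate * per_bin
                )
                ev_dyad.append(d)
                ev_tier.append(tier)
                ev_bins.append(np.concatenate(([onset], later)))
            if onsets == [None, None, None]:
                progressing = False  # censored before any onset
        else:
            c = rng.binomial(n_bins, min(1.0, config.proximity_rate_background * per_bin))
            if c:
                ev_dyad.append(d)
                ev_tier.append(0)
                ev_bins.append(np.sort(rng.integers(0, n_bins, size=c)))

        truth_rows.append({
            "member_low": row["member_low"],
            "member_high": row["member_high"],
            "familiarity": row["familiarity"],
            "progressing": progressing,
            "order": "" if order is None else "".join("LMH"[t] for t in order),
            "onset_low": onsets[0],
            "onset_moderate": onsets[1],
            "onset_high": onsets[2],
        })

    obs = _emit_records(config, rng, dyads, schedule, ev_dyad, ev_tier, ev_bins)
    truth = pd.DataFrame(truth_rows)
    return SimulatedCohort(roster, schedule, obs, truth, config, seed)


def _emit_records(config, rng, dyads, schedule, ev_dyad, ev_tier, ev_bins) -> pd.DataFrame:
    """Turn latent (dyad, tier, bin) events into raw observer records."""
    bps = config.bins_per_session
    sess_ids = schedule["session_id"].to_numpy()
    rows = {k: [] for k in ("session_id", "observer_id", "timestamp", "behavior", "actor", "receiver")}

    def add(sess, obs_id, t, beh, a, b):
        rows["session_id"].append(sess)
        rows["observer_id"].append(obs_id)
        rows["timestamp"].append(t)
        rows["behavior"].append(beh)
        rows["actor"].append(a)
        rows["receiver"].append(b)

    lows = dyads["member_low"].to_numpy()
    highs = dyads["member_high"].to_numpy()
    for d, tier, bins in zip(ev_dyad, ev_tier, ev_bins):
        a, b = lows[d], highs[d]
        for g in np.asarray(bins, dtype=int):
            sess = sess_ids[g // bps]
            local = (g % bps) * config.bin_width
            if rng.random() < 0.5:
                a, b = b, a
            if tier == 0:
                # scan record: exactly at the 5-min mark
                add(sess, _OBSERVERS[rng.integers(4)], float(local), "proximity", a, b)
            else:
                beh = (_MOD_BEHAVIORS[rng.choice(3, p=[0.4, 0.4, 0.2])] if tier == 1
                       else _HIGH_BEHAVIORS[rng.choice(2, p=[0.7, 0.3])])
                t = local + rng.uniform(0, config.bin_width)
                obs_pair = rng.permutation(4)
                add(sess, _OBSERVERS[obs_pair[0]], round(float(t), 1), beh, a, b)
                if rng.random() < config.observer_duplication_rate:
                    t2 = local + rng.uniform(0, config.bin_width)
                    add(sess, _OBSERVERS[obs_pair[1]], round(float(t2), 1), beh, a, b)

    obs = pd.DataFrame(rows)
    if obs.empty:
        return obs
    order_key = {s: i for i, s in enumerate(sess_ids)}
    obs["_k"] = obs["session_id"].map(order_key)
    obs = obs.sort_values(["_k", "timestamp", "behavior", "actor", "observer_id"],
                          kind="stable").drop(columns="_k")
    return obs.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Direct-from-model cohorts (for parameter recovery and calibration)
# ---------------------------------------------------------------------------

def model_cohort(
    rng: np.random.Generator,
    site_sizes: tuple[int, ...] = (5, 6, 7, 4),
    beta_stranger: float = 1.2,
    intercept: float = 0.5,
    sigma_u: float = 0.8,
    u: np.ndarray | None = None,
) -> tuple[ModelData, dict]:
    """Simulate dyadic outcomes straight from the multi-membership model.

    Bypasses the observation stream: every dyad is treated as evaluable and
    its binary outcome is drawn from the model's own likelihood.  Used for
    parameter-recovery and simulation-based-calibration checks, where the
    quantity of interest is the sampler and not the ethogram plumbing.
    """
    n = sum(site_sizes)
    ids = [f"B{k + 1:02d}" for k in range(n)]
    sites = np.repeat(np.arange(len(site_sizes)), site_sizes)
    if u is None:
        u = rng.normal(0.0, sigma_u, size=n)
    rows_i, rows_j, stranger = [], [], []
    for i in range(n):
        for j in range(i + 1, n):
            rows_i.append(i)
            rows_j.append(j)
            stranger.append(0.0 if sites[i] == sites[j] else 1.0)
    i_idx = np.array(rows_i)
    j_idx = np.array(rows_j)
    stranger = np.array(stranger)
    lin = intercept + beta_stranger * stranger + u[i_idx] + u[j_idx]
    y = (rng.random(len(lin)) < expit(lin)).astype(float)
    data = ModelData(y, stranger, i_idx, j_idx, ids)
    truth = {"intercept": intercept, "beta_stranger": beta_stranger, "sigma_u": sigma_u, "u": u}
    return data, truth


def config_to_dict(config: SimulationConfig) -> dict:
    return asdict(config)
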