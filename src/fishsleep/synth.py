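"""Seeded synthetic cohorts with the statistical structure the analysis
assumes: diel regime-switching activity, effect cohorts, sleep-deprivation
schedules, and per-second arousal assays.

Every generator is bit-reproducible given its config seed, stores the
ground-truth hidden paths, and records its tuning constants in the manifest.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .arousal import ArousalDataset
from .types import (
    MAX_ACTIVITY,
    ActivityTrace,
    HMMParameters,
    StateSequence,
    parse_clock,
    photoperiod_mask,
)

#: Wild-type-like per-state activity rates (s/min), ascending: S2, S1, W1, W2.
DEFAULT_RATES = (0.02, 1.14, 3.82, 7.53)

#: Night regime: sticky sleep states; stationary sleep (S2+S1) fraction ~0.7.
DEFAULT_NIGHT_T = (
    (0.90, 0.06, 0.03, 0.01),
    (0.10, 0.76, 0.07, 0.07),
    (0.09, 0.09, 0.72, 0.10),
    (0.01, 0.04, 0.15, 0.80),
)

#: Day regime: wake-dominated, shorter sleep bouts.
DEFAULT_DAY_T = (
    (0.60, 0.20, 0.15, 0.05),
    (0.04, 0.55, 0.30, 0.11),
    (0.02, 0.06, 0.77, 0.15),
    (0.01, 0.03, 0.20, 0.76),
)

#: Post-deprivation regime: S2 self-transition and entry boosted, draining S1.
DEFAULT_REBOUND_T = (
    (0.96, 0.02, 0.015, 0.005),
    (0.30, 0.56, 0.07, 0.07),
    (0.25, 0.09, 0.56, 0.10),
    (0.10, 0.04, 0.15, 0.71),
)

STATE_NAMES_4 = {0: "S2", 1: "S1", 2: "W1", 3: "W2"}

#: Phenomenological effect presets: multiplicative row edits (renormalized)
#: reproducing the directional changes seen in the perturbation experiments.
EFFECT_PRESETS: dict[str, dict] = {
    # less deep sleep, more light sleep, night only
    "melatonin_deficient": {
        "night_multipliers": (
            (0.87, 3.0, 1.0, 1.0),
            (0.40, 1.08, 1.0, 1.0),
            (0.55, 1.45, 1.0, 1.0),
            (1.0, 1.0, 1.0, 1.0),
        )
    },
    # more deep sleep at light sleep's expense, night only
    "serotonin_agonist": {
        "night_multipliers": (
            (1.06, 0.2, 0.5, 0.5),
            (2.5, 0.8, 1.0, 1.0),
            (1.8, 0.9, 1.0, 1.0),
            (1.5, 1.0, 1.0, 1.0),
        )
    },
}

SCENARIOS = {"baseline", "deprivation", "arousal", "free_running", "effect_cohort"}


def _validate_stochastic(T: np.ndarray, what: str) -> np.ndarray:
    T = np.asarray(T, dtype=float)
    if T.ndim != 2 or T.shape[0] != T.shape[1]:
        raise ValueError(f"{what} must be square")
    if np.any(T < 0) or np.any(np.abs(T.sum(axis=1) - 1.0) > 1e-9):
        raise ValueError(f"{what} must be row-stochastic")
    return T


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs for the synthetic cohort generators."""

    scenario: str = "baseline"
    rates: tuple = DEFAULT_RATES
    day_transition: tuple = DEFAULT_DAY_T
    night_transition: tuple = DEFAULT_NIGHT_T
    rebound_transition: tuple = DEFAULT_REBOUND_T
    lights_on: str = "09:00"
    lights_off: str = "23:00"
    n_animals: int = 12
    n_days: int = 2
    rate_sigma: float = 0.08  # lognormal sd of per-animal rate multipliers
    transition_concentration: float = 300.0  # Dirichlet conc. per row
    effect: dict | None = None
    # arousal-scenario knobs
    stimulus_start: str = "00:30"
    stimulus_period_min: int = 5
    n_stimuli: int = 99
    response_probs: tuple = (0.1, 0.3, 0.6, 0.8)
    n_inactive: int = 0
    deprivation_end: str = "05:00"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        _validate_stochastic(np.asarray(self.day_transition), "day transition")
        _validate_stochastic(np.asarray(self.night_transition), "night transition")
        if np.any(np.asarray(self.rates) < 0):
            raise ValueError("rates must be nonnegative")
        if self.scenario == "arousal":
            p = np.asarray(self.response_probs, dtype=float)
            if np.any(p < 0) or np.any(p > 1):
                raise ValueError("response probabilities must lie in [0, 1]")
        if self.scenario == "effect_cohort" and not self.effect:
            raise ValueError("effect_cohort scenario needs an effect specification")


@dataclass
class Cohort:
    """Generated traces with ground truth."""

    traces: list[ActivityTrace]
    states: list[StateSequence]
    manifest: dict

    @property
    def photoperiods(self) -> list[np.ndarray]:
        return [t.photoperiod for t in self.traces]


def _apply_effect(
    rates: np.ndarray, day_T: np.ndarray, night_T: np.ndarray, effect: dict | None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if not effect:
        return rates, day_T, night_T
    if isinstance(effect, str):
        effect = EFFECT_PRESETS[effect]
    if "rate_multipliers" in effect:
        rates = rates * np.asarray(effect["rate_multipliers"], dtype=float)
    for key, T in (("day_multipliers", "day"), ("night_multipliers", "night")):
        if key in effect:
            mult = np.asarray(effect[key], dtype=float)
            if T == "day":
                day_T = day_T * mult
                day_T = day_T / day_T.sum(axis=1, keepdims=True)
            else:
                night_T = night_T * mult
                night_T = night_T / night_T.sum(axis=1, keepdims=True)
    if "day_transition" in effect:
        day_T = _validate_stochastic(np.asarray(effect["day_transition"]), "day effect")
    if "night_transition" in effect:
        night_T = _validate_stochastic(np.asarray(effect["night_transition"]), "night effect")
    return rates, day_T, night_T


def _eliminate_state(T: np.ndarray, state: int) -> np.ndarray:
    """Zero all transitions into a state and renormalize, making it unreachable."""
    T = T.copy()
    T[:, state] = 0.0
    return T / T.sum(axis=1, keepdims=True)


def _animal_params(
    rng: np.random.Generator, cfg: GeneratorConfig, rates, day_T, night_T, rebound_T
):
    """Per-animal parameter draw: lognormal rate jitter, Dirichlet row jitter."""
    K = len(rates)
    lam = np.asarray(rates) * rng.lognormal(0.0, cfg.rate_sigma, size=K)
    def jitter(T):
        out = np.empty_like(T)
        for i in range(K):
            alpha = cfg.transition_concentration * np.maximum(T[i], 1e-12)
            out[i] = rng.dirichlet(alpha)
            zero = T[i] == 0
            if zero.any():  # keep structural zeros exact
                out[i][zero] = 0.0
                out[i] /= out[i].sum()
        return out
    return lam, jitter(day_T), jitter(night_T), jitter(rebound_T)


def _stationary(T: np.ndarray) -> np.ndarray:
    from .hmm import stationary_distribution

    return stationary_distribution(T)


def _sample_regime_path(
    rng: np.random.Generator, pi: np.ndarray, mats: np.ndarray, regime: np.ndarray
) -> np.ndarray:
    n = regime.size
    path = np.empty(n, dtype=np.int64)
    cdfs = np.cumsum(mats, axis=2)
    u = rng.random(n)
    s = int(np.searchsorted(np.cumsum(pi), u[0], side="left"))
    s = min(s, pi.size - 1)
    path[0] = s
    for t in range(1, n):
        row = cdfs[regime[t], s]
        s = int(np.searchsorted(row, u[t], side="left"))
        s = min(s, pi.size - 1)
        path[t] = s
    return path


def _emit(rng: np.random.Generator, lam: np.ndarray, path: np.ndarray) -> tuple[np.ndarray, int]:
    obs = rng.poisson(lam[path])
    n_clipped = int(np.count_nonzero(obs > MAX_ACTIVITY))
    return np.minimum(obs, MAX_ACTIVITY), n_clipped


def generate_cohort(config: GeneratorConfig) -> Cohort:
    """Diel regime-switching cohort (baseline / free_running / effect_cohort).

    The hidden chain follows the day matrix during lights-on bins and the
    night matrix otherwise; free-running keeps the same (now subjective)
    schedule but eliminates W2, as constant dark removes light-driven arousal.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    rates = np.asarray(cfg.rates, dtype=float)
    day_T = np.asarray(cfg.day_transition, dtype=float)
    night_T = np.asarray(cfg.night_transition, dtype=float)
    rebound_T = np.asarray(cfg.rebound_transition, dtype=float)
    rates, day_T, night_T = _apply_effect(rates, day_T, night_T, cfg.effect)
    subjective = cfg.scenario == "free_running"
    if subjective:
        w2 = len(rates) - 1
        day_T = _eliminate_state(day_T, w2)
        night_T = _eliminate_state(night_T, w2)
    n_bins = cfg.n_days * 24 * 60
    mask = photoperiod_mask(n_bins, cfg.lights_on, cfg.lights_on, cfg.lights_off)
    regime = np.where(mask, 0, 1)  # 0 = day matrix, 1 = night matrix
    traces, states, animals = [], [], []
    total_clipped = 0
    for a in range(cfg.n_animals):
        lam, dT, nT, _ = _animal_params(rng, cfg, rates, day_T, night_T, rebound_T)
        pi = _stationary(dT if mask[0] else nT)
        path = _sample_regime_path(rng, pi, np.stack([dT, nT]), regime)
        obs, clipped = _emit(rng, lam, path)
        total_clipped += clipped
        aid = f"fish_{a:03d}"
        traces.append(
            ActivityTrace(
                animal_id=aid,
                values=obs,
                start_clock=cfg.lights_on,
                lights_on=cfg.lights_on,
                lights_off=cfg.lights_off,
                photoperiod=mask,
            )
        )
        states.append(StateSequence(states=path, labels=dict(STATE_NAMES_4)))
        animals.append(
            {
                "animal_id": aid,
                "rates": lam.tolist(),
                "day_transition": dT.tolist(),
                "night_transition": nT.tolist(),
            }
        )
    manifest = {
        "scenario": cfg.scenario,
        "seed": cfg.seed,
        "n_bins": n_bins,
        "subjective_photoperiod": subjective,
        "base_rates": rates.tolist(),
        "day_transition": day_T.tolist(),
        "night_transition": night_T.tolist(),
        "clipped_observations": total_clipped,
        "animals": animals,
    }
    return Cohort(traces=traces, states=states, manifest=manifest)


def generate_deprivation(config: GeneratorConfig, deprived: bool = True) -> Cohort:
    """48-h cohort where night 2 starts with lights on (day regime) until
    ``deprivation_end``, followed by a rebound regime until lights-on.

    With ``deprived=False`` the control schedule (plain baseline regimes)
    is used, for null contrasts.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    rates = np.asarray(cfg.rates, dtype=float)
    day_T = np.asarray(cfg.day_transition, dtype=float)
    night_T = np.asarray(cfg.night_transition, dtype=float)
    rebound_T = np.asarray(cfg.rebound_transition, dtype=float)
    rates, day_T, night_T = _apply_effect(rates, day_T, night_T, cfg.effect)
    if cfg.n_days != 2:
        raise ValueError("the deprivation schedule spans exactly 2 days")
    n_bins = 2 * 24 * 60
    on = parse_clock(cfg.lights_on)
    off = parse_clock(cfg.lights_off)
    dep_end = parse_clock(cfg.deprivation_end)
    day_len = (off - on) % (24 * 60)
    night_len = 24 * 60 - day_len
    dep_len = (dep_end - off) % (24 * 60)
    night2_start = 24 * 60 + day_len
    mask = photoperiod_mask(n_bins, cfg.lights_on, cfg.lights_on, cfg.lights_off)
    regime = np.where(mask, 0, 1)
    lights = mask.copy()
    if deprived:
        dep = slice(night2_start, night2_start + dep_len)
        reb = slice(night2_start + dep_len, night2_start + night_len)
        regime[dep] = 0  # lights on: day regime
        lights[dep] = True
        regime[reb] = 2  # rebound regime
    traces, states, animals = [], [], []
    total_clipped = 0
    for a in range(cfg.n_animals):
        lam, dT, nT, rT = _animal_params(rng, cfg, rates, day_T, night_T, rebound_T)
        pi = _stationary(dT)
        path = _sample_regime_path(rng, pi, np.stack([dT, nT, rT]), regime)
        obs, clipped = _emit(rng, lam, path)
        total_clipped += clipped
        aid = f"fish_{a:03d}"
        traces.append(
            ActivityTrace(
                animal_id=aid,
                values=obs,
                start_clock=cfg.lights_on,
                lights_on=cfg.lights_on,
                lights_off=cfg.lights_off,
                photoperiod=lights,
            )
        )
        states.append(StateSequence(states=path, labels=dict(STATE_NAMES_4)))
        animals.append({"animal_id": aid, "rates": lam.tolist()})
    manifest = {
        "scenario": "deprivation",
        "deprived": deprived,
        "seed": cfg.seed,
        "n_bins": n_bins,
        "deprivation_bins": [night2_start, night2_start + dep_len] if deprived else None,
        "rebound_bins": [night2_start + dep_len, night2_start + night_len] if deprived else None,
        "rebound_transition": rebound_T.tolist(),
        "clipped_observations": total_clipped,
        "animals": animals,
    }
    return Cohort(traces=traces, states=states, manifest=manifest)


def generate_arousal(config: GeneratorConfig) -> tuple[ArousalDataset, Cohort]:
    """Single-night arousal assay with per-second movement traces.

    Each second is active with probability rate/60 given the hidden state;
    at each stimulus a response is drawn with state-dependent probability
    and, if positive, movement is injected into the 2-s post-stimulus
    window. The first ``n_inactive`` animals are pinned to S2 throughout
    (they will fail the complete-state-usage filter).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    rates = np.asarray(cfg.rates, dtype=float)
    night_T = np.asarray(cfg.night_transition, dtype=float)
    resp_p = np.asarray(cfg.response_probs, dtype=float)
    start = parse_clock(cfg.lights_off)  # assay starts at lights-off
    end = parse_clock(cfg.lights_on)
    n_bins = (end - start) % (24 * 60)
    stim_start_bin = (parse_clock(cfg.stimulus_start) - start) % (24 * 60)
    stim_bins = stim_start_bin + cfg.stimulus_period_min * np.arange(cfg.n_stimuli)
    if stim_bins[-1] >= n_bins:
        raise ValueError("stimulus schedule extends past the assay night")
    seconds, paths, responses = [], [], []
    animals = []
    for a in range(cfg.n_animals):
        lam, _, nT, _ = _animal_params(rng, cfg, rates, np.asarray(cfg.day_transition), night_T, np.asarray(cfg.rebound_transition))
        if a < cfg.n_inactive:
            path = np.zeros(n_bins, dtype=np.int64)
        else:
            pi = _stationary(nT)
            path = _sample_regime_path(rng, pi, np.stack([nT]), np.zeros(n_bins, dtype=np.int64))
        p_sec = np.minimum(lam / 60.0, 1.0)
        sec = (rng.random(n_bins * 60) < np.repeat(p_sec[path], 60)).astype(np.int64)
        resp_draws = {}
        for b in stim_bins:
            state = int(path[b - 1])
            responded = bool(rng.random() < resp_p[state])
            resp_draws[int(b)] = responded
            if responded:
                sec[b * 60 + int(rng.integers(0, 2))] = 1
        seconds.append(sec)
        paths.append(path)
        responses.append(resp_draws)
        animals.append({"animal_id": f"fish_{a:03d}", "rates": lam.tolist()})
    dataset = ArousalDataset(
        animal_ids=[a["animal_id"] for a in animals],
        seconds=seconds,
        stimulus_bins=stim_bins,
        start_clock=cfg.lights_off,
        meta={"seed": cfg.seed, "response_probs": resp_p.tolist()},
    )
    night_mask = np.zeros(n_bins, dtype=bool)  # whole assay is lights-off
    traces = dataset.binned_traces()
    traces = [
        ActivityTrace(
            animal_id=t.animal_id,
            values=t.values,
            start_clock=cfg.lights_off,
            lights_on=cfg.lights_on,
            lights_off=cfg.lights_off,
            photoperiod=night_mask,
        )
        for t in traces
    ]
    cohort = Cohort(
        traces=traces,
        states=[StateSequence(states=p, labels=dict(STATE_NAMES_4)) for p in paths],
        manifest={
            "scenario": "arousal",
            "seed": cfg.seed,
            "n_bins": n_bins,
            "stimulus_bins": stim_bins.tolist(),
            "response_probs": resp_p.tolist(),
            "n_inactive": cfg.n_inactive,
            "responses": responses,
            "animals": animals,
        },
    )
    return dataset, cohort
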