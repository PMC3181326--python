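"""Voltage-dependent birth–death gating simulator for an oligomeric pore.

The pore is a continuous-time Markov chain on levels 0..K: level 0 is closed,
level k conducts ``g_k``.  The accepted picture for alamethicin-like peptides
is that the transmembrane field drives monomer insertion, so the only
voltage-dependent rate is the opening (insertion) step

    k_ins(D) = k0 * exp(D / V_e),

where D is the driving term |V_applied| + delta_U(membrane) in mV and V_e the
characteristic e-fold voltage.  Substate growth/shrinkage (1 <-> 2 <-> ... K)
is voltage independent.  At low open probability this makes every open-level
occupancy — and hence the variance of the current — exponential in D, the
premise the downstream activity analysis rests on.

Amphiphile effects enter exclusively through delta_U computed by the
electrostatics module, plus an optional phenomenological attenuation of k0
standing in for the positive spontaneous curvature a cis-facing detergent
imposes (it does not cancel electrically when the detergent is symmetric).
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .electrostatics import MembraneSpec, equivalent_voltage_shift
from .traceio import TraceRecording

__all__ = [
    "GatingModel",
    "SimulationCondition",
    "DEFAULT_MODEL",
    "driving_term",
    "stationary_distribution",
    "simulate_events",
    "simulate_trace",
    "generate_experiment",
    "expected_sigma",
    "condition_seed",
    "model_hash",
]


@dataclass(frozen=True)
class GatingModel:
    """Kinetic and acquisition parameters of the simulated pore.

    Default conductances are the control-condition substate values from the
    I–V fits being emulated (0.09, 0.37, 1.04 nS); kinetic rates are chosen so
    that the occupancy of levels >= 2 under control at -60 mV is ~18%.
    """

    conductances: tuple[float, ...] = (0.09, 0.37, 1.04)  # nS, levels 1..K
    base_insertion_rate: float = 2.4576e-3  # 1/s, k0
    characteristic_voltage: float = 5.0  # mV, V_e
    step_up_rate: float = 500.0  # 1/s, k -> k+1 for k >= 1
    step_down_rate: float = 1000.0  # 1/s, k -> k-1 for k >= 2
    closure_rate: float = 1000.0  # 1/s, 1 -> 0
    noise_sd: float = 1.0  # pA, additive Gaussian thermal noise
    sampling_rate: float = 20.0  # kHz
    curvature_attenuation: float = 1.0  # dimensionless, (0, 1]

    def __post_init__(self) -> None:
        g = np.asarray(self.conductances, dtype=float)
        if g.size < 1:
            raise ValueError("need at least one conductive substate")
        if not (np.all(g > 0) and np.all(np.diff(g) > 0)):
            raise ValueError("conductances must be positive and strictly increasing")
        for name in (
            "base_insertion_rate", "step_up_rate", "step_down_rate", "closure_rate",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.characteristic_voltage <= 0:
            raise ValueError("characteristic_voltage must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not (0.0 < self.curvature_attenuation <= 1.0):
            raise ValueError("curvature_attenuation must be in (0, 1]")

    @property
    def n_substates(self) -> int:
        return len(self.conductances)

    def level_currents(self, v_applied: float) -> np.ndarray:
        """Mean current of each level 0..K at a holding potential, in pA."""
        g = np.concatenate([[0.0], np.asarray(self.conductances, dtype=float)])
        return -g * abs(v_applied)


DEFAULT_MODEL = GatingModel()


@dataclass(frozen=True)
class SimulationCondition:
    """One recording condition: membrane state, holding potential, duration.

    ``curvature_attenuated`` marks conditions whose cis-facing leaflet carries
    the curvature-perturbing detergent; the simulator then multiplies k0 by
    the model's ``curvature_attenuation``.
    """

    v_applied: float  # mV, <= 0
    membrane: MembraneSpec = field(default_factory=MembraneSpec)
    duration: float = 20.0  # s
    seed: int = 0
    label: str = ""
    curvature_attenuated: bool = False

    def __post_init__(self) -> None:
        if self.v_applied > 0:
            raise ValueError("v_applied must be non-positive (trans negative)")
        if self.duration <= 0:
            raise ValueError("duration must be positive")


def driving_term(v_applied: float, membrane: MembraneSpec) -> float:
    """Net driving potential D (mV) sensed across the hydrophobic core.

    D = |v_applied| + delta_U(membrane): leaflet perturbations shift the core
    drop exactly as an equivalent change of the holding potential would.
    """
    if v_applied > 0:
        raise ValueError("v_applied must be non-positive")
    return abs(v_applied) + equivalent_voltage_shift(membrane)


def _rate_table(model: GatingModel, k_ins: float) -> tuple[np.ndarray, np.ndarray]:
    k = model.n_substates
    up = np.zeros(k + 1)
    down = np.zeros(k + 1)
    up[0] = k_ins
    if k >= 2:
        up[1:k] = model.step_up_rate
    down[1] = model.closure_rate
    if k >= 2:
        down[2:] = model.step_down_rate
    return up, down


def stationary_distribution(model: GatingModel, driving_mV: float) -> np.ndarray:
    """Stationary law of the birth–death chain at driving D, levels 0..K.

    Uses the detailed-balance product formula pi_k ∝ prod up_i/down_{i+1}.
    Configurations with a zero rate on the reachable path are rejected (the
    chain would be absorbing and have no unique stationary law on 0..K).
    """
    k_ins = model.base_insertion_rate * math.exp(
        driving_mV / model.characteristic_voltage
    )
    up, down = _rate_table(model, k_ins)
    if np.any(up[:-1] <= 0) or np.any(down[1:] <= 0):
        raise ValueError("all up/down rates on 0..K must be positive")
    log_pi = np.concatenate([[0.0], np.cumsum(np.log(up[:-1]) - np.log(down[1:]))])
    pi = np.exp(log_pi - log_pi.max())
    return pi / pi.sum()


def _effective_insertion_rate(
    model: GatingModel, condition: SimulationCondition
) -> float:
    d = driving_term(condition.v_applied, condition.membrane)
    k_ins = model.base_insertion_rate * math.exp(d / model.characteristic_voltage)
    if condition.curvature_attenuated:
        k_ins *= model.curvature_attenuation
    return k_ins


def simulate_events(
    model: GatingModel, condition: SimulationCondition
) -> tuple[np.ndarray, np.ndarray]:
    """Exact-event simulation of the level process over the condition duration.

    Returns ``(event_times_s, levels_after_event)``; the chain starts closed
    (level 0) at t = 0.  Identical (model, condition) pairs give identical
    event sequences because all randomness flows from ``condition.seed``.
    """
    rng = np.random.default_rng(condition.seed)
    k_ins = _effective_insertion_rate(model, condition)
    up, down = _rate_table(model, k_ins)
    total = up + down
    p_up = np.divide(up, total, out=np.zeros_like(up), where=total > 0)

    duration = condition.duration
    times: list[float] = []
    levels: list[int] = []
    t = 0.0
    state = 0
    block = 8192
    exp_draws = rng.exponential(size=block)
    uni_draws = rng.random(size=block)
    i = 0
    while True:
        rate = total[state]
        if rate <= 0.0:  # absorbing closed state (k0 = 0): trace stays baseline
            break
        if i >= block:
            exp_draws = rng.exponential(size=block)
            uni_draws = rng.random(size=block)
            i = 0
        t += exp_draws[i] / rate
        if t >= duration:
            break
        state += 1 if uni_draws[i] < p_up[state] else -1
        times.append(t)
        levels.append(state)
        i += 1
    return np.asarray(times), np.asarray(levels, dtype=int)


def simulate_trace(model: GatingModel, condition: SimulationCondition) -> TraceRecording:
    """Sampled current trace for one condition.

    The level process is simulated event-exactly, point-sampled at the model
    sampling rate (level l contributes -g_l * |V|, i.e. downward deflections),
    and white Gaussian noise of sd ``noise_sd`` is added per sample.
    """
    times, levels = simulate_events(model, condition)
    n = int(condition.duration * model.sampling_rate * 1e3)
    sample_times = np.arange(n) / (model.sampling_rate * 1e3)
    level_path = np.concatenate([[0], levels])
    idx = np.searchsorted(times, sample_times, side="right")
    level_at_sample = level_path[idx]
    currents = model.level_currents(condition.v_applied)[level_at_sample]
    if model.noise_sd > 0:
        # separate stream so the noise does not perturb the event sequence
        noise_rng = np.random.default_rng(
            np.random.SeedSequence(entropy=condition.seed, spawn_key=(1,))
        )
        currents = currents + noise_rng.normal(0.0, model.noise_sd, size=n)
    metadata = {
        "label": condition.label,
        "seed": int(condition.seed),
        "duration_s": condition.duration,
        "delta_u_mV": equivalent_voltage_shift(condition.membrane),
        "curvature_attenuated": condition.curvature_attenuated,
        "model_hash": model_hash(model),
    }
    return TraceRecording(
        currents=currents,
        sampling_rate=model.sampling_rate,
        v_applied=condition.v_applied,
        metadata=metadata,
    )


def expected_sigma(
    model: GatingModel,
    v_applied: float,
    delta_u_mV: float = 0.0,
    attenuated: bool = False,
) -> float:
    """Analytic stationary sd of the sampled current (pA), noise included.

    Oracle counterpart of :func:`simulate_trace`: variance of the level-current
    mixture under the stationary law plus the independent noise variance.
    """
    d = abs(v_applied) + delta_u_mV
    k_ins = model.base_insertion_rate * math.exp(d / model.characteristic_voltage)
    if attenuated:
        k_ins *= model.curvature_attenuation
    up, down = _rate_table(model, k_ins)
    if np.any(up[:-1] <= 0):
        return model.noise_sd
    log_pi = np.concatenate([[0.0], np.cumsum(np.log(up[:-1]) - np.log(down[1:]))])
    pi = np.exp(log_pi - log_pi.max())
    pi /= pi.sum()
    currents = model.level_currents(v_applied)
    mean = float(pi @ currents)
    var = float(pi @ currents**2) - mean**2
    return math.sqrt(var + model.noise_sd**2)


def condition_seed(master_seed: int, label: str) -> int:
    """Stable 63-bit per-condition seed derived from (master_seed, label)."""
    digest = hashlib.sha256(f"{int(master_seed)}|{label}".encode()).digest()
    return int.from_bytes(digest[:8], "big") & (2**63 - 1)


def model_hash(model: GatingModel) -> str:
    payload = json.dumps(asdict(model), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def generate_experiment(
    design: list[SimulationCondition],
    model: GatingModel = DEFAULT_MODEL,
    master_seed: int = 0,
) -> tuple[dict[str, TraceRecording], pd.DataFrame]:
    """Simulate a whole design with per-condition seeds derived from one master.

    Condition labels must be unique; each condition's seed is replaced by the
    stable hash of (master_seed, label), so a rerun with the same master seed
    reproduces every trace bit for bit.  Returns the traces keyed by label and
    a manifest recording all per-condition parameters.
    """
    labels = [c.label for c in design]
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate condition labels: {dupes}")
    traces: dict[str, TraceRecording] = {}
    rows = []
    for cond in design:
        seeded = SimulationCondition(
            v_applied=cond.v_applied,
            membrane=cond.membrane,
            duration=cond.duration,
            seed=condition_seed(master_seed, cond.label),
            label=cond.label,
            curvature_attenuated=cond.curvature_attenuated,
        )
        traces[cond.label] = simulate_trace(model, seeded)
        rows.append(
            {
                "label": cond.label,
                "v_applied_mV": cond.v_applied,
                "duration_s": cond.duration,
                "seed": seeded.seed,
                "delta_u_mV": equivalent_voltage_shift(cond.membrane),
                "curvature_attenuated": cond.curvature_attenuated,
                "sampling_rate_kHz": model.sampling_rate,
                "model_hash": model_hash(model),
            }
        )
    manifest = pd.DataFrame(
        rows,
        columns=[
            "label", "v_applied_mV", "duration_s", "seed", "delta_u_mV",
            "curvature_attenuated", "sampling_rate_kHz", "model_hash",
        ],
    )
    return traces, manifest
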