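"""Population-coding models of serial dependence.

Two data-generating architectures share a three-stage design: a bank of 180
orientation-tuned channels (preferred orientations 0..179 deg), a decision
unit that decodes the population response as a weighted circular mean, and a
response stage that adds Gaussian motor/report noise.

* **Gain model** — after each stimulus, channel sensitivity is *increased*
  around the orientation just seen (``G = 1 + alpha_g * tuning``), attracting
  the next decode toward the previous stimulus.  Readout weights stay uniform.
* **Two-process model** — channel sensitivity is *suppressed* around the
  previous orientation (``A = 1 - alpha_g * tuning``, classical adaptation,
  repulsive), while the decision unit re-centers its readout template on each
  decoded/reported orientation and carries it forward with a forgetting
  factor ``w_decay`` (decisional inertia, attractive).

Angle conventions: channel tuning, sensory gain/adaptation and decoding
operate on doubled angles so the 180-degree orientation circle wraps
correctly.  The decisional template defaults to the identity cosine on
orientation degrees, whose circular SD at concentration 24.5 is about 11.6
degrees; both mappings are switchable per component.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .circular import orientation_cos, wrap_orientation, DEG
from .tables import parse_sequence

N_CHANNELS = 180
PREFERRED = np.arange(N_CHANNELS, dtype=float)


def tuning_response(theta, theta0, amplitude=1.0, beta=4.68, mapping="double"):
    """Response of a channel preferring ``theta0`` to orientation ``theta``.

    ``r = amplitude * exp(beta * (cos(delta) - 1))``; maximal (= amplitude)
    at ``theta == theta0``.
    """
    return amplitude * np.exp(
        beta * (orientation_cos(np.asarray(theta, float) - np.asarray(theta0, float), mapping) - 1.0)
    )


def gain_profile(theta_prev, alpha_g, beta=4.68, preferred=PREFERRED, mapping="double"):
    """Amplitude multipliers after a gain change keyed to ``theta_prev``.

    ``G = 1 + alpha_g * exp(beta*(cos(theta_prev - theta0) - 1))``; peaks at
    ``1 + alpha_g`` on the channel tuned to the previous orientation.
    """
    if alpha_g < 0:
        raise ValueError("alpha_g must be >= 0")
    return 1.0 + alpha_g * np.exp(beta * (orientation_cos(theta_prev - preferred, mapping) - 1.0))


def adaptation_profile(theta_prev, alpha_g, beta=4.68, preferred=PREFERRED, mapping="double"):
    """Amplitude multipliers after adaptation: gain change with inverted sign.

    Minimum ``1 - alpha_g`` at the previous orientation; ``alpha_g`` must be
    < 1 so amplitudes stay positive.
    """
    if not 0.0 <= alpha_g < 1.0:
        raise ValueError("adaptation requires 0 <= alpha_g < 1 (negative amplitudes otherwise)")
    return 1.0 - alpha_g * np.exp(beta * (orientation_cos(theta_prev - preferred, mapping) - 1.0))


def decode_orientation(population_response, weights, preferred=PREFERRED, mapping="double"):
    """Weighted circular mean of preferred orientations.

    Effective weights are ``population_response * weights``; the mean is
    computed in doubled-angle space and halved back, so the decode is
    invariant to rescaling of ``weights``.
    """
    r = np.asarray(population_response, float)
    w = np.asarray(weights, float)
    if np.any(r < 0) or np.any(w < 0):
        raise ValueError("population response and weights must be nonnegative")
    eff = r * w
    scale = 2.0 if mapping == "double" else 1.0
    z = np.sum(eff * np.exp(1j * scale * preferred * DEG))
    if np.abs(z) < 1e-300:
        raise ValueError("all-zero effective readout weights: decode undefined")
    return wrap_orientation(np.angle(z) / scale / DEG)


def template_weights(r_j, alpha_w, beta_w, offset=0.1, preferred=PREFERRED, mapping="identity"):
    """Decisional template centered on the decoded/reported orientation.

    ``w_j`` is proportional to ``offset + alpha_w * exp(beta_w*(cos(X - R_j) - 1))``
    and normalized to sum to 1 over the 180 channels.
    """
    if alpha_w < 0 or beta_w <= 0 or offset <= 0:
        raise ValueError("require alpha_w >= 0, beta_w > 0, offset > 0")
    w = offset + alpha_w * np.exp(beta_w * (orientation_cos(r_j - preferred, mapping) - 1.0))
    return w / w.sum()


def update_weights(weights, w_j, responded, w_decay):
    """Trial-to-trial evolution of readout weights.

    ``W' = W * w_decay + w_j`` when a response was made, else ``W`` unchanged.
    No renormalization: decoding is scale-invariant and the running sum
    converges geometrically to ``1 / (1 - w_decay)``.
    """
    if not responded:
        return np.asarray(weights, float)
    return np.asarray(weights, float) * w_decay + np.asarray(w_j, float)


@dataclass
class PopulationState:
    """Encoding stage: channel amplitudes after any gain/adaptation."""

    base_amplitude: float = 1.0
    beta: float = 4.68
    amplitude: np.ndarray = field(default_factory=lambda: np.ones(N_CHANNELS))
    preferred: np.ndarray = field(default_factory=lambda: PREFERRED.copy())


@dataclass
class DecisionState:
    """Readout stage: running weights and template parameters."""

    weights: np.ndarray = field(default_factory=lambda: np.full(N_CHANNELS, 1.0 / N_CHANNELS))
    template_amplitude: float = 0.08
    template_concentration: float = 24.5
    template_offset: float = 0.1
    w_decay: float = 0.19


@dataclass
class SimulationConfig:
    """Parameters of a simulation run.

    ``template_center`` selects whether the Eq-style reweighting is centered
    on the noise-free decoded orientation ("decoded", default) or on the
    noisy report ("response").
    """

    model: str = "two_process"  # "gain" | "two_process"
    gain_factor: float = 0.14
    template_amplitude: float = 0.08
    template_concentration: float = 24.5
    template_offset: float = 0.1
    w_decay: float = 0.19
    response_noise_sd: float = 10.0
    beta: float = 4.68
    adaptation_memory: str = "one_back"  # "one_back" | "accumulate"
    adaptation_recovery: float = 0.5
    angle_mapping: str = "double"
    template_angle_mapping: str = "identity"
    template_center: str = "response"  # "response" | "decoded"
    seed: int | None = None

    def __post_init__(self):
        if self.model not in ("gain", "two_process"):
            raise ValueError(f"unknown model {self.model!r}")
        if not 0.0 <= self.gain_factor < 1.0:
            raise ValueError("gain_factor must be in [0, 1)")
        if self.response_noise_sd < 0:
            raise ValueError("response_noise_sd must be >= 0")


class SerialDependenceSimulator:
    """Stateful trial-by-trial simulator for either model.

    Encoding kernels for grid-valued stimuli are cached, so long runs on the
    standard orientation grids cost one 180-vector exponential per response
    (the decisional template) plus elementwise products.
    """

    def __init__(self, config: SimulationConfig, rng: np.random.Generator | None = None):
        self.config = config
        self.rng = rng if rng is not None else np.random.default_rng(config.seed)
        self.population = PopulationState(beta=config.beta)
        self.decision = DecisionState(
            template_amplitude=config.template_amplitude,
            template_concentration=config.template_concentration,
            template_offset=config.template_offset,
            w_decay=config.w_decay,
        )
        self._modulation = np.zeros(N_CHANNELS)  # deviation of amplitude from base
        self._kernel_cache: dict[float, np.ndarray] = {}

    def _kernel(self, theta: float) -> np.ndarray:
        key = round(float(theta), 6)
        k = self._kernel_cache.get(key)
        if k is None:
            k = np.exp(
                self.config.beta
                * (orientation_cos(theta - self.population.preferred, self.config.angle_mapping) - 1.0)
            )
            if len(self._kernel_cache) < 4096:
                self._kernel_cache[key] = k
            else:
                return k
        return k

    def present(self, stimulus: float) -> None:
        """Register a stimulus at the encoding stage without decoding it.

        Used for nonreported items inside a sequence: the gain/adaptation
        profile for the *next* item is keyed to this stimulus.
        """
        self._update_modulation(stimulus)

    def _update_modulation(self, stimulus: float) -> None:
        profile = self.config.gain_factor * self._kernel(stimulus)
        if self.config.adaptation_memory == "accumulate":
            self._modulation = self._modulation * self.config.adaptation_recovery + profile
        else:
            self._modulation = profile

    def _amplitude(self) -> np.ndarray:
        base = self.population.base_amplitude
        if self.config.model == "gain":
            return base + self._modulation
        return np.clip(base - self._modulation, 0.0, None)

    def simulate_trial(self, stimulus: float, respond: bool = True):
        """Encode, decode, (optionally) respond, then update both stages.

        Returns ``(response, decoded)``; ``response`` is None on catch trials.
        """
        cfg = self.config
        self.population.amplitude = self._amplitude()
        r = self.population.amplitude * self._kernel(stimulus)
        decoded = decode_orientation(r, self.decision.weights,
                                     self.population.preferred, cfg.angle_mapping)
        response = None
        if respond:
            noise = self.rng.normal(0.0, cfg.response_noise_sd) if cfg.response_noise_sd > 0 else 0.0
            response = float(wrap_orientation(decoded + noise))
        # encoding-stage history keyed to the presented stimulus
        self._update_modulation(stimulus)
        # decisional template persists only in the two-process model, and
        # only when a report was actually made
        if cfg.model == "two_process" and respond:
            center = decoded if cfg.template_center == "decoded" else response
            w_j = template_weights(
                center,
                self.decision.template_amplitude,
                self.decision.template_concentration,
                self.decision.template_offset,
                self.population.preferred,
                cfg.template_angle_mapping,
            )
            self.decision.weights = update_weights(
                self.decision.weights, w_j, True, self.decision.w_decay
            )
        return response, float(decoded)


def run_simulation(trial_table: pd.DataFrame, config: SimulationConfig,
                   rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Simulate responses for every respond-trial of a trial table.

    Catch trials (``condition == "catch"`` or NaN-flagged) are presented but
    not reported; rows with a ``sequence_json`` present their nonreported
    items in order before the final, reported stimulus.  Simulation state is
    reset at each subject boundary.
    """
    out = trial_table.copy()
    responses = np.full(len(out), np.nan)
    decoded_col = np.full(len(out), np.nan)
    has_cond = "condition" in out.columns
    has_seq = "sequence_json" in out.columns
    shared_rng = rng if rng is not None else np.random.default_rng(config.seed)
    stim_arr = out["stimulus"].to_numpy(dtype=float)
    catch_arr = (out["condition"].astype(str) == "catch").to_numpy() if has_cond else np.zeros(len(out), bool)
    seq_arr = [parse_sequence(v) for v in out["sequence_json"]] if has_seq else [None] * len(out)
    for _, idx in out.groupby("subject", sort=False).indices.items():
        sim = SerialDependenceSimulator(config, rng=shared_rng)
        for i in idx:
            seq = seq_arr[i]
            if seq is not None:
                for s in seq[:-1]:
                    sim.present(s)
                stimulus = seq[-1]
            else:
                stimulus = stim_arr[i]
            resp, dec = sim.simulate_trial(stimulus, respond=not catch_arr[i])
            decoded_col[i] = dec
            if resp is not None:
                responses[i] = resp
    out["response"] = responses
    out["decoded"] = decoded_col
    return out
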