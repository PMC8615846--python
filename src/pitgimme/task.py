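"""Synthetic three-phase avoidance-transfer task and ground-truth BOLD generator.

The task has three phases:

1. **Instrumental** — two 180-s sessions in which an aversive outcome is scheduled every
   second unless the correct button press within the current 1-s window defers the next
   attack by 3 s.  A learning agent's correct-press probability rises linearly over the
   session.
2. **Pavlovian** — 45 passive conditioning trials (5 stimulus-outcome pairings x 9
   repetitions): 4-s conditioned stimulus, 1-s outcome, inter-trial interval jittered
   over {7, 9, 11} s.
3. **Transfer** — 60 extinction trials (5 stimuli x 12): pre-stimulus fixation, 4-s
   stimulus, then a 2-12-s "recharge" screen during which responding is disallowed.
   A Poisson agent responds at a baseline rate, multiplied by ``specific_gain`` for the
   congruent response under CS1/CS2 and by ``general_gain`` for both responses under CS3.

Ground-truth BOLD series for five regions of interest are generated from an extended
unified SEM: contemporaneous (A), lagged (phi), direct-input (gamma) and bilinear (tau)
paths, with the task-input vectors convolved through subject-specific canonical HRFs on a
16x-upsampled microtime grid before entering the dynamics.

All schedules and draws are deterministic functions of (config, master seed, subject).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._rng import substream
from .edges import INPUT_NAMES, ROI_ORDER, Edge, NetworkStructure
from .hrf import double_gamma_hrf

__all__ = [
    "TaskConfig",
    "AgentParams",
    "TrueNetwork",
    "ConfigError",
    "PhaseMismatchError",
    "SimulationError",
    "gen_instrumental_run",
    "gen_pavlovian_schedule",
    "gen_transfer_schedule",
    "gen_transfer_behavior",
    "simulate_bold",
    "make_voxel_volume",
    "write_events",
    "read_events",
]

EVENT_COLUMNS = ["onset", "duration", "trial_type", "phase"]


class ConfigError(ValueError):
    """Invalid task configuration."""


class PhaseMismatchError(ValueError):
    """A schedule from the wrong task phase was supplied."""


class SimulationError(RuntimeError):
    """The generative model became singular during simulation."""


@dataclass(frozen=True)
class TaskConfig:
    """Timing constants of the three-phase task (seconds unless noted)."""

    session_length_s: float = 180.0
    attack_interval_s: float = 1.0
    correct_press_delay_s: float = 3.0
    cs_duration_s: float = 4.0
    outcome_duration_s: float = 1.0
    pav_iti_choices_s: tuple[float, ...] = (7.0, 9.0, 11.0)
    pav_reps_per_pairing: int = 9
    transfer_reps_per_cs: int = 12
    pre_stimulus_s: float = 4.0
    recharge_range_s: tuple[float, float] = (2.0, 12.0)
    tr_s: float = 2.0
    n_rois: int = 5
    n_trs: int = 540

    def __post_init__(self):
        for name in (
            "session_length_s",
            "attack_interval_s",
            "correct_press_delay_s",
            "cs_duration_s",
            "outcome_duration_s",
            "pre_stimulus_s",
            "tr_s",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.pav_reps_per_pairing < 0 or self.transfer_reps_per_cs < 0:
            raise ConfigError("repetition counts must be non-negative")
        if not self.pav_iti_choices_s or any(v <= 0 for v in self.pav_iti_choices_s):
            raise ConfigError("Pavlovian ITI choices must be positive")
        lo, hi = self.recharge_range_s
        if not (0 < lo <= hi):
            raise ConfigError("recharge_range_s must be a positive interval [lo, hi]")
        if self.n_rois < 1 or self.n_trs < 1:
            raise ConfigError("n_rois and n_trs must be positive")

    @property
    def n_pavlovian_trials(self) -> int:
        return self.pav_reps_per_pairing * 5

    @property
    def n_transfer_trials(self) -> int:
        return self.transfer_reps_per_cs * 5


@dataclass(frozen=True)
class AgentParams:
    """Behavioral agent: avoidance learning plus Poisson transfer responding.

    ``baseline_rate`` is presses/second per response channel; ``specific_gain``
    multiplies the congruent response rate under CS1/CS2; ``general_gain`` multiplies
    both response rates under CS3.  ``learn_start_p``/``learn_end_p`` are the correct
    avoidance-press probabilities at the start/end of an instrumental session.
    """

    baseline_rate: float = 0.1
    specific_gain: float = 5.0
    general_gain: float = 1.0
    learn_start_p: float = 0.3
    learn_end_p: float = 0.9

    def __post_init__(self):
        if self.baseline_rate < 0 or self.specific_gain < 0 or self.general_gain < 0:
            raise ConfigError("rates and gains must be non-negative")
        for p in (self.learn_start_p, self.learn_end_p):
            if not 0 <= p <= 1:
                raise ConfigError("learning probabilities must lie in [0, 1]")


def null_agent() -> AgentParams:
    """An agent with no transfer effect (all gains 1)."""
    return AgentParams(specific_gain=1.0, general_gain=1.0)


# ---------------------------------------------------------------------------------------
# Ground-truth generating network
# ---------------------------------------------------------------------------------------


@dataclass(frozen=True)
class TrueNetwork:
    """Known generating euSEM used by the simulator.

    ``a`` (p x p, zero diagonal) holds contemporaneous weights [target, source];
    ``phi`` (p x p) lagged weights (diagonal = autoregressive); ``gamma`` (p x q)
    direct-input weights; ``tau`` (p x q x p) bilinear weights [target, input, source];
    ``noise_sd`` per-ROI dynamic-noise SD; ``hrf_params_per_subject`` a list of
    dicts with canonical-HRF ``peak_delay_s`` and ``dispersion`` per subject.
    """

    a: np.ndarray
    phi: np.ndarray
    gamma: np.ndarray
    tau: np.ndarray
    noise_sd: np.ndarray
    hrf_params_per_subject: tuple[dict, ...]
    roi_names: tuple[str, ...] = ROI_ORDER
    input_names: tuple[str, ...] = INPUT_NAMES

    def __post_init__(self):
        p, q = len(self.roi_names), len(self.input_names)
        a = np.asarray(self.a, float)
        phi = np.asarray(self.phi, float)
        gamma = np.asarray(self.gamma, float)
        tau = np.asarray(self.tau, float)
        noise = np.broadcast_to(np.asarray(self.noise_sd, float), (p,)).copy()
        if a.shape != (p, p) or phi.shape != (p, p):
            raise ConfigError("A and phi must be p x p")
        if gamma.shape != (p, q) or tau.shape != (p, q, p):
            raise ConfigError("gamma must be p x q and tau p x q x p")
        if np.any(np.diag(a) != 0):
            raise ConfigError("contemporaneous matrix must have a zero diagonal")
        if np.any(noise <= 0):
            raise ConfigError("noise_sd must be positive")
        eye = np.eye(p)
        try:
            m = np.linalg.inv(eye - a)
        except np.linalg.LinAlgError as err:
            raise ConfigError("(I - A) is singular") from err
        rho = np.max(np.abs(np.linalg.eigvals(m @ phi)))
        if rho >= 1:
            raise ConfigError(f"network is non-stationary (spectral radius {rho:.3f} >= 1)")
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "phi", phi)
        object.__setattr__(self, "gamma", gamma)
        object.__setattr__(self, "tau", tau)
        object.__setattr__(self, "noise_sd", noise)
        object.__setattr__(self, "hrf_params_per_subject", tuple(self.hrf_params_per_subject))

    @property
    def n_subjects(self) -> int:
        return len(self.hrf_params_per_subject)

    @property
    def n_rois(self) -> int:
        return len(self.roi_names)

    def structure(self) -> NetworkStructure:
        """The NetworkStructure of all nonzero paths (AR base always included)."""
        edges = [Edge("lagged", r, r) for r in self.roi_names]
        p, q = self.n_rois, len(self.input_names)
        for i in range(p):
            for j in range(p):
                if i != j and self.a[i, j] != 0:
                    edges.append(Edge("contemporaneous", self.roi_names[j], self.roi_names[i]))
                if i != j and self.phi[i, j] != 0:
                    edges.append(Edge("lagged", self.roi_names[j], self.roi_names[i]))
        for i in range(p):
            for k in range(q):
                if self.gamma[i, k] != 0:
                    edges.append(Edge("direct", self.input_names[k], self.roi_names[i]))
                for j in range(p):
                    if self.tau[i, k, j] != 0:
                        edges.append(
                            Edge("bilinear", self.roi_names[j], self.roi_names[i], input=self.input_names[k])
                        )
        return NetworkStructure(tuple(edges), self.roi_names, self.input_names)

    def true_value(self, edge: Edge) -> float:
        """Generating weight of an edge (0.5 AR default if absent from matrices)."""
        i = self.roi_names.index(edge.target)
        if edge.kind == "contemporaneous":
            return float(self.a[i, self.roi_names.index(edge.source)])
        if edge.kind == "lagged":
            return float(self.phi[i, self.roi_names.index(edge.source)])
        if edge.kind == "direct":
            return float(self.gamma[i, self.input_names.index(edge.source)])
        return float(self.tau[i, self.input_names.index(edge.input), self.roi_names.index(edge.source)])

    # -- serialization --------------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "roi_names": list(self.roi_names),
            "input_names": list(self.input_names),
            "a": self.a.tolist(),
            "phi": self.phi.tolist(),
            "gamma": self.gamma.tolist(),
            "tau": self.tau.tolist(),
            "noise_sd": self.noise_sd.tolist(),
            "hrf_params_per_subject": list(self.hrf_params_per_subject),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrueNetwork":
        return cls(
            np.asarray(d["a"], float),
            np.asarray(d["phi"], float),
            np.asarray(d["gamma"], float),
            np.asarray(d["tau"], float),
            np.asarray(d["noise_sd"], float),
            tuple(d["hrf_params_per_subject"]),
            tuple(d["roi_names"]),
            tuple(d["input_names"]),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "TrueNetwork":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def default_hrf_params(n_subjects: int) -> tuple[dict, ...]:
    """Deterministic subject-varying HRF shapes (peak delays 4.5-7.5 s)."""
    peaks = (6.0, 5.0, 7.0, 4.5, 6.5, 5.5, 7.5, 6.0, 5.0, 7.0, 6.5, 5.5)
    disps = (1.0, 0.9, 1.1, 1.0, 0.95, 1.05)
    return tuple(
        {"peak_delay_s": peaks[i % len(peaks)], "dispersion": disps[i % len(disps)]}
        for i in range(n_subjects)
    )


def _zeros(p: int = 5, q: int = 2):
    return np.zeros((p, p)), np.zeros((p, p)), np.zeros((p, q)), np.zeros((p, q, p))


def benchmark_network(n_subjects: int = 10, noise_sd: float = 1.0) -> TrueNetwork:
    """Desk-scale recovery benchmark: 5 AR paths (0.5) plus 4 non-AR paths (0.5-0.6).

    Non-AR paths mirror the classes of the group map recovered in the avoidance-transfer
    study: three contemporaneous putamen->cortex paths and one lagged insula->cingulate
    path.
    """
    a, phi, gamma, tau = _zeros()
    names = list(ROI_ORDER)
    np.fill_diagonal(phi, 0.5)
    a[names.index("insula_r"), names.index("putamen_l")] = 0.6
    a[names.index("cingulate_r"), names.index("putamen_r")] = 0.55
    a[names.index("insula_l"), names.index("putamen_l")] = 0.5
    phi[names.index("cingulate_r"), names.index("insula_l")] = 0.5
    return TrueNetwork(a, phi, gamma, tau, noise_sd, default_hrf_params(n_subjects))


def paper_like_network(n_subjects: int = 11, noise_sd: float = 1.0) -> TrueNetwork:
    """Group-map-style truth: four contemporaneous paths, one lagged path, and a direct
    effect of the specific transfer input on the left putamen."""
    a, phi, gamma, tau = _zeros()
    names = list(ROI_ORDER)
    np.fill_diagonal(phi, 0.5)
    a[names.index("insula_r"), names.index("putamen_l")] = 0.4
    a[names.index("cingulate_r"), names.index("putamen_r")] = 0.4
    a[names.index("insula_l"), names.index("putamen_l")] = 0.35
    a[names.index("insula_r"), names.index("putamen_r")] = 0.35
    phi[names.index("cingulate_r"), names.index("insula_l")] = 0.3
    gamma[names.index("putamen_l"), 0] = 1.0
    return TrueNetwork(a, phi, gamma, tau, noise_sd, default_hrf_params(n_subjects))


def null_network(n_subjects: int = 10, noise_sd: float = 1.0, ar: float = 0.5) -> TrueNetwork:
    """AR-only truth (no cross paths, no input effects) for null calibration."""
    a, phi, gamma, tau = _zeros()
    np.fill_diagonal(phi, ar)
    return TrueNetwork(a, phi, gamma, tau, noise_sd, default_hrf_params(n_subjects))


NETWORK_PRESETS = {
    "benchmark": benchmark_network,
    "paper_like": paper_like_network,
    "null": null_network,
}


# ---------------------------------------------------------------------------------------
# Schedules and agents
# ---------------------------------------------------------------------------------------


def _events_frame(rows: list[tuple], phase: str) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=["onset", "duration", "trial_type"])
    df["phase"] = phase
    return df


def gen_instrumental_run(
    config: TaskConfig,
    agent: AgentParams,
    seed: int,
    outcome: str = "O1",
    response: str = "R1",
):
    """Simulate one instrumental avoidance session.

    The session is a discrete 1-s clock.  In each window the agent makes the correct
    press with a probability interpolating ``learn_start_p`` -> ``learn_end_p`` linearly
    over the session.  A window without a press (and not covered by a deferral) emits one
    attack at the window's end; a press defers the next scheduled attack by
    ``correct_press_delay_s``.

    Returns ``(schedule, record, attack_times)``: attack events as an event table, press
    times as a behavioral record, and the raw attack-onset array (seconds).
    """
    if config.session_length_s <= 0:
        raise ConfigError("session length must be positive")
    rng = substream(seed, "instrumental", outcome)
    n_windows = int(round(config.session_length_s / config.attack_interval_s))
    w_len = config.attack_interval_s
    deferral_until = 0.0
    attacks: list[float] = []
    presses: list[float] = []
    for w in range(n_windows):
        frac = w / (n_windows - 1) if n_windows > 1 else 0.0
        p = agent.learn_start_p + (agent.learn_end_p - agent.learn_start_p) * frac
        t_end = (w + 1) * w_len
        if rng.random() < p:
            presses.append(w * w_len + rng.uniform(0, w_len))
            deferral_until = max(deferral_until, t_end + config.correct_press_delay_s)
        elif t_end > deferral_until:
            attacks.append(t_end)
    schedule = _events_frame(
        [(t, config.outcome_duration_s, outcome) for t in attacks], "instrumental"
    )
    record = pd.DataFrame({"timestamp": presses, "response": response})
    record["phase"] = "instrumental"
    return schedule, record, np.asarray(attacks)


def gen_pavlovian_schedule(config: TaskConfig, seed: int) -> pd.DataFrame:
    """45 conditioning trials: CS (4 s) -> outcome (1 s) -> jittered ITI in {7, 9, 11} s."""
    rng = substream(seed, "pavlovian")
    pairings = np.repeat(np.arange(1, 6), config.pav_reps_per_pairing)
    order = rng.permutation(pairings)
    rows = []
    t = 0.0
    for k in order:
        rows.append((t, config.cs_duration_s, f"CS{k}"))
        t += config.cs_duration_s
        rows.append((t, config.outcome_duration_s, f"O{k}"))
        t += config.outcome_duration_s
        iti = float(rng.choice(config.pav_iti_choices_s))
        rows.append((t, iti, "fixation"))
        t += iti
    return _events_frame(rows, "pavlovian")


def gen_transfer_schedule(config: TaskConfig, seed: int) -> pd.DataFrame:
    """60 extinction trials: fixation -> CS (4 s) -> recharge (uniform 2-12 s)."""
    rng = substream(seed, "transfer")
    stims = np.repeat(np.arange(1, 6), config.transfer_reps_per_cs)
    order = rng.permutation(stims)
    lo, hi = config.recharge_range_s
    rows = []
    t = 0.0
    for k in order:
        rows.append((t, config.pre_stimulus_s, "fixation"))
        t += config.pre_stimulus_s
        rows.append((t, config.cs_duration_s, f"CS{k}"))
        t += config.cs_duration_s
        recharge = float(rng.uniform(lo, hi))
        rows.append((t, recharge, "recharge"))
        t += recharge
    return _events_frame(rows, "transfer")


def _require_phase(schedule: pd.DataFrame, phase: str) -> None:
    if len(schedule) and not (schedule["phase"] == phase).all():
        found = sorted(schedule["phase"].unique())
        raise PhaseMismatchError(f"expected a {phase}-phase schedule, got phases {found}")


_CS_RATES = {
    # trial_type -> (R1 multiplier key, R2 multiplier key)
    "CS1": ("specific", "base"),
    "CS2": ("base", "specific"),
    "CS3": ("general", "general"),
    "CS4": ("base", "base"),
    "CS5": ("base", "base"),
}


def gen_transfer_behavior(schedule: pd.DataFrame, agent: AgentParams, seed: int) -> pd.DataFrame:
    """Inhomogeneous-Poisson button presses for a transfer run.

    Rates per response channel: baseline during fixation and CS4/CS5, baseline x
    ``specific_gain`` for the congruent response under CS1/CS2, baseline x
    ``general_gain`` for both responses under CS3, zero during recharge screens.
    """
    _require_phase(schedule, "transfer")
    rng = substream(seed, "transfer-behavior")
    mult = {"base": 1.0, "specific": agent.specific_gain, "general": agent.general_gain}
    times: list[float] = []
    resps: list[str] = []
    for row in schedule.itertuples(index=False):
        tt = row.trial_type
        if tt == "recharge":
            continue
        if tt == "fixation":
            gains = ("base", "base")
        elif tt in _CS_RATES:
            gains = _CS_RATES[tt]
        else:
            continue
        for resp, g in zip(("R1", "R2"), gains):
            rate = agent.baseline_rate * mult[g]
            n = rng.poisson(rate * row.duration) if rate > 0 else 0
            if n:
                ts = row.onset + rng.uniform(0, row.duration, size=n)
                times.extend(ts.tolist())
                resps.extend([resp] * n)
    record = pd.DataFrame({"timestamp": times, "response": resps})
    record["phase"] = "transfer"
    return record.sort_values("timestamp", kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------------------
# BOLD simulation
# ---------------------------------------------------------------------------------------

MICROTIME_UPSAMPLE = 16


def _onset_impulses(schedule: pd.DataFrame, trial_types, dt: float, n: int) -> np.ndarray:
    v = np.zeros(n)
    sel = schedule[schedule["trial_type"].isin(trial_types)]
    for onset in sel["onset"].to_numpy():
        k = int(np.floor(onset / dt))
        if k < n:
            v[k] = 1.0
    return v


def binary_input_columns(schedule: pd.DataFrame, tr_s: float, n_trs: int) -> pd.DataFrame:
    """TR-resolution binary onset vectors: specific = CS1 u CS2, general = CS3."""
    spec = _onset_impulses(schedule, ("CS1", "CS2"), tr_s, n_trs)
    gen = _onset_impulses(schedule, ("CS3",), tr_s, n_trs)
    return pd.DataFrame({"specific": spec, "general": gen})


def convolved_inputs_microtime(
    schedule: pd.DataFrame,
    hrf_params: dict,
    tr_s: float,
    n_trs: int,
    hrf_window_s: float = 32.0,
) -> np.ndarray:
    """(T, 2) task inputs: microtime impulses convolved with a subject HRF, decimated to TR."""
    dt = tr_s / MICROTIME_UPSAMPLE
    n_micro = n_trs * MICROTIME_UPSAMPLE
    t_hrf = np.arange(0, hrf_window_s, dt)
    h = double_gamma_hrf(
        t_hrf,
        peak_delay_s=hrf_params.get("peak_delay_s", 6.0),
        dispersion=hrf_params.get("dispersion", 1.0),
    )
    cols = []
    for trial_types in (("CS1", "CS2"), ("CS3",)):
        imp = _onset_impulses(schedule, trial_types, dt, n_micro)
        u = np.convolve(imp, h)[:n_micro]
        cols.append(u[::MICROTIME_UPSAMPLE][:n_trs])
    return np.column_stack(cols)


def simulate_bold(
    truth: TrueNetwork,
    schedules: list[pd.DataFrame],
    config: TaskConfig,
    seed: int,
    burn_in: int = 50,
) -> list[pd.DataFrame]:
    """Simulate per-subject ROI series from the generating euSEM.

    For each scan t the contemporaneous system is solved exactly:
    ``y_t = (I - A - sum_k u_tk tau[:,k,:])^-1 (phi y_{t-1} + gamma u_t + zeta_t)``
    with white dynamic noise.  Inputs are built from each subject's transfer schedule and
    convolved with that subject's canonical HRF on the microtime grid.  Returns one
    DataFrame per subject with the 5 ROI columns plus binary specific/general onset
    columns (the estimation side re-estimates HRFs from these).
    """
    if len(schedules) != truth.n_subjects:
        raise ConfigError(
            f"{truth.n_subjects} subjects in truth but {len(schedules)} schedules"
        )
    p = truth.n_rois
    eye = np.eye(p)
    out = []
    T = config.n_trs
    for i, schedule in enumerate(schedules):
        _require_phase(schedule, "transfer")
        rng = substream(seed, "bold", i)
        u = convolved_inputs_microtime(
            schedule, truth.hrf_params_per_subject[i], config.tr_s, T
        )
        u_full = np.vstack([np.zeros((burn_in, u.shape[1])), u])
        zeta = rng.normal(0.0, truth.noise_sd, size=(burn_in + T, p))
        y = np.zeros((burn_in + T, p))
        prev = np.zeros(p)
        for t in range(burn_in + T):
            m = eye - truth.a - np.einsum("k,ikj->ij", u_full[t], truth.tau)
            rhs = truth.phi @ prev + truth.gamma @ u_full[t] + zeta[t]
            if abs(np.linalg.det(m)) < 1e-12:
                raise SimulationError(
                    f"(I - A - tau*u) singular at scan {t - burn_in} for subject {i}"
                )
            prev = np.linalg.solve(m, rhs)
            y[t] = prev
        df = pd.DataFrame(y[burn_in:], columns=list(truth.roi_names))
        df[["specific", "general"]] = binary_input_columns(schedule, config.tr_s, T)
        out.append(df)
    return out


def make_voxel_volume(series: pd.DataFrame, roi_specs, grid_spec, noise_sd: float, seed: int):
    """Build a synthetic 4-D NIfTI volume carrying each ROI's series inside its sphere.

    Voxels inside an ROI sphere carry that ROI's time series plus independent Gaussian
    noise; voxels inside several (overlapping) spheres carry the sum of the overlapping
    signals; all other voxels carry pure noise.  Spheres extending outside the grid are
    truncated with a warning.
    """
    import nibabel as nib

    from .roi import sphere_mask, sphere_extends_outside

    rng = substream(seed, "voxel-volume")
    roi_cols = [c for c in series.columns if c not in ("specific", "general")]
    T = len(series)
    shape = tuple(grid_spec.shape)
    data = rng.normal(0.0, noise_sd, size=shape + (T,)) if noise_sd > 0 else np.zeros(shape + (T,))
    for spec in roi_specs:
        if spec.name not in roi_cols:
            raise ConfigError(f"ROI {spec.name!r} has no column in the series table")
        if sphere_extends_outside(spec, grid_spec):
            warnings.warn(
                f"sphere for {spec.name} extends outside the grid; truncated", stacklevel=2
            )
        idx = sphere_mask(spec, grid_spec)
        sig = series[spec.name].to_numpy()
        for vox in idx:
            data[vox] = data[vox] + sig
    return nib.Nifti1Image(data.astype(np.float32), grid_spec.affine)


# ---------------------------------------------------------------------------------------
# Event-table I/O (tab-separated, onset/duration in seconds from run start)
# ---------------------------------------------------------------------------------------


def write_events(schedule: pd.DataFrame, path) -> None:
    schedule.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_events(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("onset", "duration", "trial_type") if c not in df.columns]
    if missing:
        raise ConfigError(f"event table missing columns {missing}")
    return df
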