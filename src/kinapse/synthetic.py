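"""Labeled synthetic T-cell trajectories for exercising the pipeline.

Three motion models emulate the phenomenology of the target behaviors:

* ``poking``  — anchored: position reverts toward an anchor point with
  small noise, so speeds sit mostly below the coasting threshold;
* ``scanning`` — fast persistent random walk: fixed step length with a
  slowly wandering heading;
* ``dancing`` — elongated oscillation about an anchor along a random
  axis, punctuated by occasional relocations (jumps) to a new anchor.

A field is many cells per experiment imaged for 2 h at 1 frame/min.
Per-track lognormal jitter of the motion scales makes the classes
overlap somewhat, so learned classifiers are good but not perfect.
Everything is deterministic given the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from kinapse.track_io import Dataset, Track

logger = logging.getLogger(__name__)

BEHAVIORS = ("poking", "scanning", "dancing")


@dataclass(frozen=True)
class BehaviorParams:
    """Generative parameters of the three motion models (lengths in um)."""

    # poking: anchored reversion
    poking_reversion: float = 0.5        # per-frame pull toward anchor, in (0, 1)
    poking_noise: float = 0.8           # step noise sd per axis

    # scanning: persistent random walk
    scanning_step: float = 3.4           # step length per frame
    scanning_heading_noise: float = 1.0  # heading increment sd, radians
    scanning_step_noise: float = 0.5     # lognormal sd of per-frame step factor

    # dancing: oscillation about an anchor + relocation
    dancing_amplitude: float = 2.8       # oscillation amplitude
    dancing_omega: float = 0.9           # oscillation angular rate, rad/frame
    dancing_jitter: float = 0.5          # iid positional jitter sd per axis
    dancing_jump_prob: float = 0.1      # per-frame re-anchoring probability
    dancing_jump_length: float = 6.0     # anchor relocation distance

    sigma_z: float = 0.15                # shared out-of-plane noise sd

    def __post_init__(self) -> None:
        if not 0.0 < self.poking_reversion < 1.0:
            raise ValueError("poking_reversion must be in (0, 1)")
        if not 0.0 <= self.dancing_jump_prob <= 1.0:
            raise ValueError("dancing_jump_prob must be in [0, 1]")
        for name in (
            "poking_noise", "scanning_step", "scanning_heading_noise",
            "scanning_step_noise",
            "dancing_amplitude", "dancing_omega", "dancing_jitter",
            "dancing_jump_length", "sigma_z",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def scaled(self, factor: float) -> "BehaviorParams":
        """Motion scales multiplied by ``factor`` (per-track heterogeneity)."""
        return replace(
            self,
            poking_noise=self.poking_noise * factor,
            scanning_step=self.scanning_step * factor,
            dancing_amplitude=self.dancing_amplitude * factor,
        )

    @classmethod
    def from_dict(cls, d: dict) -> "BehaviorParams":
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        return cls(**known)


@dataclass(frozen=True)
class SimConfig:
    """Field layout and behavior mixture of a simulated acquisition."""

    n_experiments: int = 1
    cells_per_experiment: int = 50
    n_frames: int = 120                      # 2 h at 1 frame/min
    field_size: tuple[float, float] = (400.0, 400.0)
    frame_interval_s: float = 60.0
    mixture: dict = field(
        default_factory=lambda: {"poking": 0.4, "scanning": 0.35, "dancing": 0.25}
    )
    switching: bool = False                  # semi-Markov behavior changes
    dwell_mean_frames: float = 40.0
    short_track_fraction: float = 0.05       # tracks truncated below 5 frames
    round_label_fraction: float = 0.1        # poking frames annotated "round"
    param_jitter: float = 0.65                # lognormal sd of per-track scale
    params: BehaviorParams = field(default_factory=BehaviorParams)
    experiment_prefix: str = "sim"
    seed: int = 0

    def __post_init__(self) -> None:
        probs = np.array([self.mixture.get(b, 0.0) for b in BEHAVIORS], dtype=float)
        if set(self.mixture) - set(BEHAVIORS):
            raise ValueError(f"unknown behaviors in mixture: {set(self.mixture) - set(BEHAVIORS)}")
        if np.any(probs < 0) or not np.isclose(probs.sum(), 1.0):
            raise ValueError(f"mixture proportions must be >= 0 and sum to 1, got {self.mixture}")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if not 0.0 <= self.short_track_fraction < 1.0:
            raise ValueError("short_track_fraction must be in [0, 1)")

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "params" in d and isinstance(d["params"], dict):
            d["params"] = BehaviorParams.from_dict(d["params"])
        if "field_size" in d:
            d["field_size"] = tuple(d["field_size"])
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        return cls(**known)


def dancing_envelope(params: BehaviorParams, n_frames: int) -> float:
    """In-plane bound on |position - anchor| for a no-jump dancing track.

    The oscillation contributes at most the amplitude; the iid jitter's
    two-axis maximum over ``n_frames`` draws stays within 5 sd with
    overwhelming probability.
    """
    return params.dancing_amplitude + 5.0 * params.dancing_jitter * np.sqrt(2.0)


def _unit2(rng) -> np.ndarray:
    theta = rng.uniform(0.0, 2.0 * np.pi)
    return np.array([np.cos(theta), np.sin(theta)])


def simulate_track(
    behavior_sequence,
    params: BehaviorParams | None = None,
    n_frames: int | None = None,
    seed=0,
    start_xy=(0.0, 0.0),
    z0: float = 0.0,
    first_frame: int = 1,
    track_id: str = "c0",
    experiment_id: str = "exp0",
    frame_interval_s: float = 60.0,
) -> Track:
    """Simulate one labeled track.

    ``behavior_sequence`` is a behavior name (held for the whole track) or
    one name per frame.  The per-frame label records the generating
    behavior; a rng or integer seed drives all randomness.
    """
    params = params or BehaviorParams()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    if isinstance(behavior_sequence, str):
        if n_frames is None:
            raise ValueError("n_frames required when behavior_sequence is a single name")
        behaviors = [behavior_sequence] * n_frames
    else:
        behaviors = list(behavior_sequence)
        if n_frames is not None and n_frames != len(behaviors):
            raise ValueError("n_frames disagrees with behavior_sequence length")
    for b in behaviors:
        if b not in BEHAVIORS:
            raise ValueError(f"unknown behavior {b!r}")
    n = len(behaviors)

    xy = np.empty((n, 2))
    xy[0] = start_xy
    anchor = np.array(start_xy, dtype=float)
    heading = rng.uniform(0.0, 2.0 * np.pi)
    osc_axis = _unit2(rng)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    prev_behavior = behaviors[0]

    for i in range(1, n):
        b = behaviors[i]
        if b != prev_behavior:
            # entering a new behavior: re-anchor at the current position
            anchor = xy[i - 1].copy()
            osc_axis = _unit2(rng)
            phase = rng.uniform(0.0, 2.0 * np.pi)
            prev_behavior = b
        if b == "poking":
            pull = (1.0 - params.poking_reversion) * (xy[i - 1] - anchor)
            xy[i] = anchor + pull + rng.normal(0.0, params.poking_noise, 2)
        elif b == "scanning":
            heading += rng.normal(0.0, params.scanning_heading_noise)
            step = params.scanning_step
            if params.scanning_step_noise > 0:
                step *= np.exp(rng.normal(0.0, params.scanning_step_noise))
            xy[i] = xy[i - 1] + step * np.array([np.cos(heading), np.sin(heading)])
        else:  # dancing
            if rng.uniform() < params.dancing_jump_prob:
                anchor = anchor + params.dancing_jump_length * _unit2(rng)
                osc_axis = _unit2(rng)
            osc = params.dancing_amplitude * np.sin(params.dancing_omega * i + phase)
            xy[i] = (
                anchor
                + osc * osc_axis
                + rng.normal(0.0, params.dancing_jitter, 2)
            )

    z = z0 + rng.normal(0.0, params.sigma_z, n) if params.sigma_z > 0 else np.full(n, z0)
    positions = np.column_stack([xy, z])
    return Track(
        track_id=track_id,
        experiment_id=experiment_id,
        frames=np.arange(first_frame, first_frame + n),
        positions=positions,
        labels=np.asarray(behaviors, dtype=object),
        frame_interval_s=frame_interval_s,
    )


def _behavior_sequence(cfg: SimConfig, rng) -> list[str]:
    probs = [cfg.mixture.get(b, 0.0) for b in BEHAVIORS]
    first = rng.choice(BEHAVIORS, p=probs)
    if not cfg.switching:
        return [first] * cfg.n_frames
    seq: list[str] = []
    current = first
    while len(seq) < cfg.n_frames:
        dwell = 1 + rng.geometric(1.0 / cfg.dwell_mean_frames)
        seq.extend([current] * dwell)
        current = rng.choice(BEHAVIORS, p=probs)
    return seq[: cfg.n_frames]


def simulate_field(cfg: SimConfig | None = None) -> Dataset:
    """Simulate a multi-experiment field of labeled tracks.

    Behavior assignments are i.i.d. from the mixture; anchors and starts
    are uniform in the field; a configured fraction of tracks is truncated
    below 5 frames to exercise the short-track filter.  Ground-truth
    labels travel on the tracks themselves (per-frame).
    """
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    width, height = cfg.field_size
    tracks = []
    for e in range(cfg.n_experiments):
        exp_id = f"{cfg.experiment_prefix}{e:02d}"
        n_short = int(round(cfg.short_track_fraction * cfg.cells_per_experiment))
        for c in range(cfg.cells_per_experiment):
            seq = _behavior_sequence(cfg, rng)
            if c < n_short:
                length = int(rng.integers(2, 5))
                first = int(rng.integers(1, cfg.n_frames - length + 2))
                seq = seq[:length]
            else:
                first = 1
            factor = float(np.exp(rng.normal(0.0, cfg.param_jitter)))
            track = simulate_track(
                seq,
                params=cfg.params.scaled(factor),
                seed=rng,
                start_xy=(rng.uniform(0, width), rng.uniform(0, height)),
                z0=rng.normal(0.0, 1.0),
                first_frame=first,
                track_id=f"c{c:03d}",
                experiment_id=exp_id,
                frame_interval_s=cfg.frame_interval_s,
            )
            if cfg.round_label_fraction > 0 and rng.uniform() < cfg.round_label_fraction:
                # annotate poking frames as "round" on some tracks: the raw
                # label scheme distinguishes them morphologically, we cannot
                track.labels = np.asarray(
                    ["round" if b == "poking" else b for b in track.labels],
                    dtype=object,
                )
            tracks.append(track)
    ds = Dataset(tracks, name=f"{cfg.experiment_prefix}_field")
    logger.info(
        "simulated %d tracks across %d experiment(s)", ds.n_tracks, cfg.n_experiments
    )
    return ds
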