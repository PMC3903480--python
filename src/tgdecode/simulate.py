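"""Generative simulator for evoked sensor-space dynamics.

Each scenario is a set of *generators*: latent sources that project onto the
sensors with a random topography (per-channel coefficients drawn from a
standard normal) and are switched on over a contiguous window of time
samples.  A trial of class ``y`` (+1 deviant, -1 standard) is

    S(c, t) = y * sum_g  A_g(t) * s_g(t) * C_g(c)  +  noise

where ``A_g`` is the activation profile (1 inside the active window, 0
outside), ``s_g`` an optional per-sample class-coupling sign, and ``C_g``
the sensor projection.  Gaussian white noise is added i.i.d. over trials,
channels and samples with standard deviation chosen so that

    RMS(noiseless signal over informative entries) / SD(noise) = snr.

Three canonical scenarios are provided:

* *sequential* — several generators active one after the other, producing a
  diagonal-shaped temporal generalization matrix (a serial chain of
  short-lived neural codes);
* *sustained* — a single generator active throughout, producing a square
  matrix (one stable code);
* *reversal* — one generator whose class coupling flips sign midway,
  producing below-chance (AUC < 0.5) generalization across the flip.

The module also generates local-global session label sequences (block
composition, deviant spacing, habituation and post-deviant exclusion flags)
so that realistic trial bookkeeping can be attached to simulated data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .epochs import EpochsSet, TrialLabel

DEFAULT_SAMPLE_RATE = 256.0


@dataclass(frozen=True)
class ActivationWindow:
    """One generator's active period: samples ``[onset, onset + duration)``.

    ``signs`` optionally gives a per-sample class-coupling sign (length
    ``duration``); default is +1 throughout.  ``amplitude`` scales the
    activation profile inside the window.
    """

    onset: int
    duration: int
    signs: tuple[int, ...] | None = None
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.onset < 0 or self.duration < 0:
            raise ValueError("onset and duration must be non-negative")
        if self.signs is not None and len(self.signs) != self.duration:
            raise ValueError("signs must have one entry per active sample")

    def sign_profile(self) -> np.ndarray:
        if self.signs is None:
            return np.ones(self.duration)
        return np.asarray(self.signs, dtype=np.float64)


@dataclass(frozen=True)
class Scenario:
    """A named list of activation windows on a fixed time grid."""

    windows: tuple[ActivationWindow, ...]
    n_samples: int
    name: str = "scenario"

    def __post_init__(self) -> None:
        for w in self.windows:
            if w.onset + w.duration > self.n_samples:
                raise ValueError(
                    f"window [{w.onset}, {w.onset + w.duration}) exceeds "
                    f"n_samples={self.n_samples}"
                )

    def active_mask(self) -> np.ndarray:
        """Boolean mask over samples where any generator is active."""
        mask = np.zeros(self.n_samples, dtype=bool)
        for w in self.windows:
            mask[w.onset : w.onset + w.duration] = True
        return mask


@dataclass(frozen=True)
class Generator:
    """A realized generator: sensor projection plus activation time course."""

    projection: np.ndarray  # (n_channels,)
    activation: np.ndarray  # (n_samples,) amplitude, 0 outside the window
    signs: np.ndarray  # (n_samples,) class-coupling sign (0 outside window)


def sequential_scenario(
    n_generators: int = 10,
    duration: int = 6,
    start: int = 10,
    n_samples: int = 80,
) -> Scenario:
    """Generators active one after the other in abutting equal windows.

    Defaults give ten generators of six samples each starting at sample 10
    on an 80-sample grid (active samples 10-69).
    """
    if n_generators < 1:
        raise ValueError("n_generators must be >= 1")
    if start + n_generators * duration > n_samples:
        raise ValueError(
            f"{n_generators} windows of {duration} samples from {start} "
            f"exceed n_samples={n_samples}"
        )
    windows = tuple(
        ActivationWindow(onset=start + i * duration, duration=duration)
        for i in range(n_generators)
    )
    return Scenario(windows=windows, n_samples=n_samples, name="sequential")


def sustained_scenario(
    duration: int = 60, start: int = 10, n_samples: int = 80
) -> Scenario:
    """A single generator active over ``[start, start + duration)``.

    ``duration=0`` yields a pure-noise (null) simulation.
    """
    windows = (ActivationWindow(onset=start, duration=duration),)
    return Scenario(windows=windows, n_samples=n_samples, name="sustained")


def reversal_scenario(
    duration: int = 40, start: int = 10, flip_at: int = 30,
    n_samples: int = 80, post_flip_amplitude: float = 1.0,
) -> Scenario:
    """One generator whose class coupling flips sign at ``flip_at``.

    The projection is shared across the whole window; the coupling is +1 on
    ``[start, flip_at)`` and -1 on ``[flip_at, start + duration)``.  Decoders
    trained before the flip therefore generalize *below* chance after it.
    ``post_flip_amplitude`` attenuates the second segment (1 = full
    reversal; < 1 = partial reversal, where the diagonal stays stronger
    than the anti-generalization).
    """
    if not (start < flip_at < start + duration):
        raise ValueError("flip_at must fall strictly inside the active window")
    signs = tuple([1] * (flip_at - start) + [-1] * (start + duration - flip_at))
    win = ActivationWindow(onset=start, duration=duration, signs=signs)
    scenario = Scenario(windows=(win,), n_samples=n_samples, name="reversal")
    if post_flip_amplitude != 1.0:
        # split into two windows so the second segment can be attenuated
        first = ActivationWindow(onset=start, duration=flip_at - start)
        second = ActivationWindow(
            onset=flip_at,
            duration=start + duration - flip_at,
            signs=tuple([-1] * (start + duration - flip_at)),
            amplitude=post_flip_amplitude,
        )
        # same projection for both segments is arranged in simulate_subject
        # via the shared_projection flag below
        scenario = Scenario(
            windows=(first, second), n_samples=n_samples, name="reversal-shared"
        )
    return scenario


@dataclass(frozen=True)
class SimulationConfig:
    """Study-level simulation settings.

    Defaults reproduce the reference conditions: 50 trials (half per
    class), 20 sensors, 80 samples, SNR 0.5, groups of 10 subjects.
    ``snr=math.inf`` gives noiseless data.
    """

    scenario: Scenario
    n_trials: int = 50
    n_channels: int = 20
    n_samples: int = 80
    snr: float = 0.5
    n_subjects: int = 10
    seed: int = 0
    sample_rate: float = DEFAULT_SAMPLE_RATE

    def __post_init__(self) -> None:
        if self.n_trials % 2 != 0 or self.n_trials < 2:
            raise ValueError("n_trials must be even and >= 2 (balanced classes)")
        if self.n_channels < 1 or self.n_samples < 1:
            raise ValueError("n_channels and n_samples must be >= 1")
        if not (self.snr > 0):
            raise ValueError("snr must be > 0 (use math.inf for noiseless)")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.scenario.n_samples != self.n_samples:
            raise ValueError(
                f"scenario grid ({self.scenario.n_samples} samples) does not "
                f"match config n_samples={self.n_samples}"
            )


def _realize_generators(
    scenario: Scenario, n_channels: int, rng: np.random.Generator
) -> list[Generator]:
    """Draw a fresh sensor projection per window.

    Windows in a scenario named ``*-shared`` share a single projection
    (used by the attenuated reversal scenario).
    """
    gens: list[Generator] = []
    shared = scenario.name.endswith("-shared")
    shared_proj = rng.standard_normal(n_channels) if shared else None
    for w in scenario.windows:
        proj = shared_proj if shared else rng.standard_normal(n_channels)
        activation = np.zeros(scenario.n_samples)
        activation[w.onset : w.onset + w.duration] = w.amplitude
        signs = np.zeros(scenario.n_samples)
        signs[w.onset : w.onset + w.duration] = w.sign_profile()
        gens.append(Generator(projection=proj, activation=activation, signs=signs))
    return gens


def _noiseless_template(gens: Sequence[Generator]) -> np.ndarray:
    """Class +1 noiseless signal, shape (n_channels, n_samples)."""
    if not gens:
        raise ValueError("scenario has no generators")
    template = np.zeros((gens[0].projection.size, gens[0].activation.size))
    for g in gens:
        template += np.outer(g.projection, g.activation * g.signs)
    return template


def _balanced_y(n_trials: int) -> np.ndarray:
    y = np.empty(n_trials, dtype=np.int8)
    y[0::2] = 1
    y[1::2] = -1
    return y


def simulate_subject(
    config: SimulationConfig,
    subject_seed: int = 0,
    labels: list[TrialLabel] | None = None,
) -> EpochsSet:
    """Simulate one subject's epochs under the configured scenario.

    A fresh set of generator projections and an independent noise stream are
    drawn from a stream derived deterministically from
    ``(config.seed, subject_seed)``.  If ``labels`` is given, the trial
    classes follow ``local_class`` (deviant = +1) and ``n_trials`` is taken
    from the label list; otherwise classes alternate +1/-1 over
    ``config.n_trials`` balanced trials.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, subject_seed]))
    gens = _realize_generators(config.scenario, config.n_channels, rng)
    template = _noiseless_template(gens)

    if labels is None:
        y = _balanced_y(config.n_trials)
        labels = [
            TrialLabel.from_classes(
                "deviant" if yi > 0 else "standard", "standard"
            )
            for yi in y
        ]
    else:
        y = np.array(
            [1 if lab.local_class == "deviant" else -1 for lab in labels],
            dtype=np.int8,
        )
    n_trials = len(labels)

    signal = y[:, None, None].astype(np.float64) * template[None, :, :]

    active = config.scenario.active_mask()
    if math.isinf(config.snr):
        sigma = 0.0
    elif active.any():
        rms = float(np.sqrt(np.mean(template[:, active] ** 2)))
        sigma = rms / config.snr
    else:
        sigma = 1.0  # pure-noise (null) simulation
    data = signal
    if sigma > 0:
        data = data + rng.normal(
            0.0, sigma, size=(n_trials, config.n_channels, config.n_samples)
        )

    times = np.arange(config.n_samples) / config.sample_rate
    return EpochsSet(
        data=data,
        times=times,
        sample_rate=config.sample_rate,
        labels=labels,
        subject_id=f"sim{subject_seed:03d}",
    )


def simulate_group(config: SimulationConfig) -> list[EpochsSet]:
    """Simulate ``config.n_subjects`` independent subjects.

    Subject ``i`` uses subject_seed ``i``; projections and noise are fresh
    per subject, and the whole group is reproducible from ``config.seed``.
    """
    return [simulate_subject(config, subject_seed=i) for i in range(config.n_subjects)]


# ---------------------------------------------------------------------------
# local-global session label sequences


def _place_deviants(
    n_trials: int,
    n_deviants: int,
    min_gap: int,
    max_gap: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Boolean deviant mask with every standard run in [min_gap, max_gap].

    Runs of global standards before the first, between consecutive, and
    after the last deviant all have lengths within the bounds, which is the
    strictest reading of "pseudo-randomly distributed at least ``min_gap``
    and at most ``max_gap`` standards apart".
    """
    n_standards = n_trials - n_deviants
    n_runs = n_deviants + 1
    if n_deviants < 1:
        return np.zeros(n_trials, dtype=bool)
    if not (n_runs * min_gap <= n_standards <= n_runs * max_gap):
        raise ValueError(
            f"cannot place {n_deviants} deviants among {n_trials} trials "
            f"with standard runs in [{min_gap}, {max_gap}]"
        )
    runs = np.full(n_runs, min_gap)
    remaining = n_standards - n_runs * min_gap
    capacity = max_gap - min_gap
    while remaining > 0:
        open_runs = np.flatnonzero(runs - min_gap < capacity)
        runs[rng.choice(open_runs)] += 1
        remaining -= 1
    mask = np.zeros(n_trials, dtype=bool)
    pos = 0
    for i in range(n_deviants):
        pos += runs[i]
        mask[pos] = True
        pos += 1
    return mask


def localglobal_sequence(
    n_blocks: int = 14,
    trials_per_block: int = 56,
    p_global_deviant: float = 0.2,
    min_gap: int = 1,
    max_gap: int = 6,
    habituation_trials: int = 10,
    seed: int = 0,
) -> list[TrialLabel]:
    """Generate a full session's trial labels for the local-global design.

    Each block starts with ``habituation_trials`` global standards flagged
    ``analyzed=False``, followed by ``trials_per_block`` main trials of
    which ``round(p_global_deviant * trials_per_block)`` are global
    deviants, spaced ``min_gap``..``max_gap`` global standards apart.  The
    trial after each global deviant is flagged ``analyzed=False``.  Block
    types alternate: in type-1 blocks the frequent (global standard) trial
    is a local standard (LSGS) and the rare one a local deviant (LDGD); in
    type-2 blocks the mapping is reversed (LDGS frequent, LSGD rare).
    """
    if not (0 < p_global_deviant < 0.5):
        raise ValueError("p_global_deviant must be in (0, 0.5)")
    if min_gap < 1 or max_gap < min_gap:
        raise ValueError("require min_gap >= 1 and max_gap >= min_gap")
    rng = np.random.default_rng(seed)
    n_deviants = round(p_global_deviant * trials_per_block)
    labels: list[TrialLabel] = []
    for block_id in range(n_blocks):
        block_type = 1 + block_id % 2
        # local class of the frequent (GS) and rare (GD) trials in this block
        gs_local = "standard" if block_type == 1 else "deviant"
        gd_local = "deviant" if block_type == 1 else "standard"
        for _ in range(habituation_trials):
            labels.append(
                TrialLabel.from_classes(
                    gs_local, "standard", block_id, block_type, analyzed=False
                )
            )
        deviant_mask = _place_deviants(
            trials_per_block, n_deviants, min_gap, max_gap, rng
        )
        previous_was_deviant = False
        for is_dev in deviant_mask:
            if is_dev:
                labels.append(
                    TrialLabel.from_classes(
                        gd_local, "deviant", block_id, block_type, analyzed=True
                    )
                )
            else:
                labels.append(
                    TrialLabel.from_classes(
                        gs_local,
                        "standard",
                        block_id,
                        block_type,
                        analyzed=not previous_was_deviant,
                    )
                )
            previous_was_deviant = bool(is_dev)
    return labels


def reference_session_labels(seed: int = 0) -> list[TrialLabel]:
    """A session reproducing the reference analyzed-trial counts.

    Twelve blocks of 80 main trials with 15 global deviants each yield,
    after habituation and post-deviant exclusions, exactly 390 local
    standards vs 390 local deviants and 600 global standards vs 180 global
    deviants among the analyzed trials.
    """
    return localglobal_sequence(
        n_blocks=12,
        trials_per_block=80,
        p_global_deviant=0.1875,
        min_gap=1,
        max_gap=6,
        habituation_trials=10,
        seed=seed,
    )
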