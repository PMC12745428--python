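"""Synthetic motor-task EEG cohorts with known phase-lagged coupling.

The generator emulates the features the downstream estimators measure:

* a 19-node 10-20 montage plus A1/A2 ear references;
* cue-locked trials (20 per task by default) of 5 s epochs, three tasks;
* band-specific coupling: per band, a few "hub" oscillators (one per
  scalp region) whose phase is re-drawn uniformly each trial; coupled
  channels receive a copy of the hub oscillation delayed by a fixed,
  channel-specific phase lag. The *constancy* of that lag across trials
  is exactly what the wPLI estimator detects, while the per-trial jitter
  makes trial-averaged zero-lag terms cancel;
* white Gaussian sensor noise (low single-trial SNR, as in scalp EEG);
* instantaneous volume-conduction-like mixing: symmetric nearest-
  neighbour smoothing over the 10-20 grid, which adds zero-lag
  correlations that wPLI must ignore;
* a patient group whose coupling strengths are attenuated by a
  subject-specific factor, with Modified Ashworth Scale (MAS) grades
  assigned monotonically in that attenuation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .montage import DEFAULT_MONTAGE, NEIGHBORS, Montage
from .preprocessing import TASKS, Recording

BAND_CARRIER_HZ = {"delta": 3.0, "theta": 6.0, "alpha": 10.0, "beta": 20.0}
MAS_GRADES = ("0", "1", "1+", "2")


@dataclass(frozen=True)
class CouplingSpec:
    """Phase-lagged coupling structure of one frequency band.

    Each pair (source, target, lag, strength) places a carrier
    oscillation on ``source`` and a copy delayed by ``lag`` radians,
    scaled by ``strength``, on ``target``. Every distinct source label is
    an independent oscillator; ``source_freqs`` may pin a source to a
    specific in-band carrier (default: the band's centre carrier), so one
    band can carry e.g. a 10 Hz global rhythm and a 12 Hz regional one.
    """

    band: str
    pairs: tuple[tuple[str, str, float, float], ...] = ()
    mixing_strength: float = 0.0
    noise_sd: float = 1.0
    source_freqs: tuple[tuple[str, float], ...] = ()

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.mixing_strength < 0:
            raise ValueError("mixing_strength must be non-negative")
        for src, dst, lag, strength in self.pairs:
            if not -math.pi < lag <= math.pi:
                raise ValueError(f"lag {lag} for ({src},{dst}) outside (-pi, pi]")
            if not 0 <= strength <= 1:
                raise ValueError(f"strength {strength} for ({src},{dst}) outside [0, 1]")

    def carrier_hz(self, source: str) -> float:
        for lab, f in self.source_freqs:
            if lab == source:
                return f
        try:
            return BAND_CARRIER_HZ[self.band]
        except KeyError:
            raise ValueError(f"no default carrier frequency for band {self.band!r}") from None

    @property
    def max_carrier_hz(self) -> float:
        sources = {src for src, *_ in self.pairs}
        if not sources:
            return 0.0
        return max(self.carrier_hz(s) for s in sources)

    def scaled(self, factor: float) -> "CouplingSpec":
        """Coupling with every pair strength multiplied by ``factor``."""
        pairs = tuple((s, d, lag, st * factor) for s, d, lag, st in self.pairs)
        return replace(self, pairs=pairs)

    def mirrored(self, montage: Montage) -> "CouplingSpec":
        """Coupling with every label swapped to its left/right homolog."""
        pairs = tuple(
            (montage.mirror_label(s), montage.mirror_label(d), lag, st)
            for s, d, lag, st in self.pairs
        )
        freqs = tuple((montage.mirror_label(s), f) for s, f in self.source_freqs)
        return replace(self, pairs=pairs, source_freqs=freqs)


@dataclass(frozen=True)
class SimulatedSubject:
    subject_id: str
    recording: Recording
    group: str  # "patient" | "control"
    affected_side: str | None  # "left" | "right" | None for controls
    mas_upper: str | None
    mas_hand: str | None
    ground_truth: dict[str, CouplingSpec]
    attenuation: float  # 1 - strength factor; 0 for controls
    seed: int


# Two-tier structure of the default coupling. A global sensorimotor hub
# (Cz) integrates the whole scalp — it carries the band's centre carrier
# and sends near-quadrature copies to every other electrode, so the
# strongest edges form a star whose short paths keep the intact network
# efficient. Each scalp region additionally holds a fully connected
# "core" of three oscillator sources at distinct flanking in-band
# carriers; each core source couples to the other cores and to the
# region's remaining ("leaf") electrodes. Every structured edge is thus
# a direct source-to-copy edge whose imaginary cross-spectrum scales
# linearly with the coupling strength, and the core triangles plus
# core-leaf fans carry the clustering of the intact network. Distinct
# carriers keep the tiers spectrally orthogonal, and all lags avoid
# 0/pi (where the imaginary cross-spectrum, hence wPLI, vanishes).
_GLOBAL_HUB = "Cz"
# region -> (three core sources, leaf members)
_REGIONS: tuple[tuple[tuple[str, str, str], tuple[str, ...]], ...] = (
    (("Fz", "F3", "F4"), ("Fp1", "Fp2", "F7", "F8")),
    (("C3", "C4", "T3"), ("T4",)),
    (("Pz", "P3", "P4"), ("O1", "O2", "T5", "T6")),
)
# in-band carriers for the three core sources of every region, per band
_REGIONAL_CARRIERS_HZ = {
    "delta": (2.0, 2.0, 2.0),  # delta spans only two 1-Hz bins
    "theta": (4.0, 5.0, 7.0),
    "alpha": (8.0, 11.0, 12.0),
    "beta": (15.0, 24.0, 27.0),
}


def default_coupling(
    bands: tuple[str, ...] = ("alpha", "beta"),
    noise_sd: float = 7.0,
    mixing_strength: float = 0.2,
    hub_strength: float = 1.0,
    regional_strength: float = 0.5,
) -> dict[str, CouplingSpec]:
    """Default cohort coupling: a global Cz hub plus regional core groups.

    Only alpha and beta carry coupling by default (the bands where
    motor-task group differences are expected); delta and theta are
    noise-only.
    """
    specs = {}
    for band in bands:
        carriers = _REGIONAL_CARRIERS_HZ[band]
        pairs = []
        freqs = []
        others = [lab for lab in DEFAULT_MONTAGE.labels if lab != _GLOBAL_HUB]
        for i, lab in enumerate(others):
            # near-quadrature lags, narrowly spread: hub edges all strong,
            # incidental member-member coupling through the hub weak
            pairs.append((_GLOBAL_HUB, lab, 1.2 + 0.04 * i, hub_strength))
        for cores, leaves in _REGIONS:
            for ci, core in enumerate(cores):
                freqs.append((core, carriers[ci]))
                targets = tuple(c for c in cores if c != core) + leaves
                for mi, member in enumerate(targets):
                    # wide lag spread keeps pairwise phase differences away
                    # from 0/pi so secondary (shared-source) edges stay usable
                    pairs.append((core, member, 0.8 + 0.35 * mi, regional_strength))
        specs[band] = CouplingSpec(
            band=band,
            pairs=tuple(pairs),
            mixing_strength=mixing_strength,
            noise_sd=noise_sd,
            source_freqs=tuple(freqs),
        )
    return specs


def _mixing_matrix(labels: tuple[str, ...], strength: float) -> np.ndarray:
    """I + strength * A/deg_max with A the symmetric 10-20 neighbour graph."""
    n = len(labels)
    a = np.zeros((n, n))
    for i, lab in enumerate(labels):
        for nb in NEIGHBORS.get(lab, ()):
            if nb in labels:
                j = labels.index(nb)
                a[i, j] = a[j, i] = 1.0
    deg_max = max(a.sum(axis=1).max(), 1.0)
    return np.eye(n) + strength * a / deg_max


def generate_recording(
    montage: Montage = DEFAULT_MONTAGE,
    coupling: dict[str, CouplingSpec] | None = None,
    n_trials: int = 20,
    fs: float = 1000.0,
    epoch: tuple[float, float] = (1.0, 4.0),
    seed: int = 0,
    tasks: tuple[str, ...] = TASKS,
    gap_s: float = 2.0,
) -> Recording:
    """One continuous multi-task recording with cue events.

    Trials of the tasks are laid out in round-robin blocks of
    ``pre + post + gap`` seconds; the cue falls ``pre`` seconds into each
    block. Oscillator phases are re-drawn per block.
    """
    coupling = {} if coupling is None else coupling
    if n_trials < 1:
        raise ValueError("need at least one trial per task")
    pre_s, post_s = epoch
    if pre_s < 1.0 or post_s < 4.0:
        raise ValueError("epoch must span at least 1 s pre + 4 s post cue")
    labels = montage.all_labels
    for spec in coupling.values():
        for src, dst, _, _ in spec.pairs:
            for lab in (src, dst):
                if lab not in labels:
                    raise ValueError(f"coupling references unknown channel {lab!r}")
        if spec.pairs and fs < 2 * spec.max_carrier_hz:
            raise ValueError(
                f"fs={fs} Hz below Nyquist for the {spec.band} carrier "
                f"({spec.max_carrier_hz} Hz): aliasing"
            )

    rng = np.random.default_rng(seed)
    block_len = int(round((pre_s + post_s + gap_s) * fs))
    n_blocks = n_trials * len(tasks)
    n_ch = len(labels)
    data = np.zeros((n_ch, n_blocks * block_len))
    t_block = np.arange(block_len) / fs

    noise_sds = [sp.noise_sd for sp in coupling.values()]
    mix_strengths = [sp.mixing_strength for sp in coupling.values()]
    noise_sd = float(np.mean(noise_sds)) if noise_sds else 1.0
    mixing = float(np.mean(mix_strengths)) if mix_strengths else 0.0

    events = []
    idx = {lab: i for i, lab in enumerate(labels)}
    for b in range(n_blocks):
        start = b * block_len
        events.append((start + int(round(pre_s * fs)), tasks[b % len(tasks)]))
        for spec in coupling.values():
            sources = sorted({src for src, *_ in spec.pairs})
            for src in sources:
                omega = 2 * math.pi * spec.carrier_hz(src)
                phase = rng.uniform(-math.pi, math.pi)
                osc = np.cos(omega * t_block + phase)
                data[idx[src], start : start + block_len] += osc
                for s, dst, lag, strength in spec.pairs:
                    if s != src:
                        continue
                    data[idx[dst], start : start + block_len] += strength * np.cos(
                        omega * t_block + phase - lag
                    )

    if noise_sd > 0:
        data += rng.normal(0.0, noise_sd, data.shape)
    if mixing > 0:
        data = _mixing_matrix(labels, mixing) @ data
    return Recording(data=data, fs=fs, labels=labels, events=tuple(events))


def quantile_mas_link(attenuations: np.ndarray) -> list[str]:
    """Default monotone attenuation -> MAS rule: rank patients by how much
    their coupling is attenuated and grade by quartile, most-attenuated
    patients receiving the highest grade."""
    n = len(attenuations)
    order = np.argsort(np.argsort(attenuations, kind="stable"), kind="stable")
    grades = [MAS_GRADES[min(int(r * 4 / n), 3)] for r in order]
    return grades


def generate_cohort(
    n_per_group: int,
    base_coupling: dict[str, CouplingSpec] | None = None,
    patient_attenuation: float = 0.3,
    mas_link=quantile_mas_link,
    seed: int = 0,
    montage: Montage = DEFAULT_MONTAGE,
    right_affected_fraction: float = 1 / 8,
    n_trials: int = 20,
    fs: float = 1000.0,
    tasks: tuple[str, ...] = TASKS,
    gap_s: float = 2.0,
) -> list[SimulatedSubject]:
    """A patient + control cohort with a known group effect.

    Controls use ``base_coupling`` unchanged. Each patient's coupling
    strengths are multiplied by a subject-specific factor <= 1 drawn from
    a seeded distribution centred on ``patient_attenuation`` (the jitter
    scales with ``1 - patient_attenuation``, so ``patient_attenuation=1``
    gives factor exactly 1 and the groups are exchangeable — a null
    cohort). MAS grades are assigned by ``mas_link`` so clinical severity
    is monotone in the attenuation. A seeded ``right_affected_fraction``
    of patients is right-affected, with their coupling topography
    mirrored accordingly.
    """
    if n_per_group < 2:
        raise ValueError("need at least two subjects per group")
    if not 0 <= patient_attenuation <= 1:
        raise ValueError("patient_attenuation must lie in [0, 1]")
    base_coupling = default_coupling() if base_coupling is None else base_coupling

    rng = np.random.default_rng(seed)
    # factor = multiplier on coupling strengths, centred on patient_attenuation;
    # the jitter scales with (1 - attenuation) so attenuation 1.0 yields factor
    # exactly 1 for every patient, i.e. a true null cohort.
    # inclusion MAS 1..2 is a narrow clinical band, so the per-subject
    # attenuation spread is modest (+/-10% of the group-level attenuation)
    attenuations = (1.0 - patient_attenuation) * rng.uniform(0.9, 1.1, n_per_group)
    factors = np.clip(1.0 - attenuations, 0.0, 1.0)
    attenuations = 1.0 - factors
    grades = mas_link(attenuations)
    hand_shift = rng.integers(-1, 2, n_per_group)
    n_right = int(round(right_affected_fraction * n_per_group))
    right_idx = set(rng.choice(n_per_group, size=n_right, replace=False).tolist())

    subjects: list[SimulatedSubject] = []
    for i in range(n_per_group):
        sseed = int(rng.integers(2**31 - 1))
        side = "right" if i in right_idx else "left"
        coupling = {b: sp.scaled(float(factors[i])) for b, sp in base_coupling.items()}
        if side == "right":
            coupling = {b: sp.mirrored(montage) for b, sp in coupling.items()}
        rec = generate_recording(
            montage, coupling, n_trials=n_trials, fs=fs, seed=sseed,
            tasks=tasks, gap_s=gap_s,
        )
        gi = MAS_GRADES.index(grades[i])
        hand = MAS_GRADES[int(np.clip(gi + hand_shift[i], 0, 3))]
        subjects.append(
            SimulatedSubject(
                subject_id=f"pat{i + 1:02d}", recording=rec, group="patient",
                affected_side=side, mas_upper=grades[i], mas_hand=hand,
                ground_truth=coupling, attenuation=float(attenuations[i]),
                seed=sseed,
            )
        )
    for i in range(n_per_group):
        sseed = int(rng.integers(2**31 - 1))
        rec = generate_recording(
            montage, base_coupling, n_trials=n_trials, fs=fs, seed=sseed,
            tasks=tasks, gap_s=gap_s,
        )
        subjects.append(
            SimulatedSubject(
                subject_id=f"ctl{i + 1:02d}", recording=rec, group="control",
                affected_side=None, mas_upper=None, mas_hand=None,
                ground_truth=dict(base_coupling), attenuation=0.0, seed=sseed,
            )
        )
    return subjects
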