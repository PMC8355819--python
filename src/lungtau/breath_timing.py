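"""Breath-phase timing for respiratory-gated 4D image sequences.

A gated 4DCT acquisition yields ``n_phases`` volumes per ventilatory cycle.
Under pressure-controlled ventilation with a fixed inspiratory:expiratory
(I:E) ratio, each phase maps to a fixed time offset within the breath.  The
expiratory regression needs, for every expiratory phase ``n``, the elapsed
time ``t_n`` since end-inspiration; this module identifies the
end-inspiratory phase, derives the expiratory phase set from the I:E ratio,
and assigns those times.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BreathPhaseGrid",
    "PhaseAmbiguityError",
    "build_phase_grid",
    "detect_end_inspiration",
    "sampling_frequency",
    "rotation_frequency",
]


class PhaseAmbiguityError(ValueError):
    """All phases look alike; end-inspiration cannot be detected automatically."""


@dataclass(frozen=True)
class BreathPhaseGrid:
    """Timing of one periodic breath sampled at ``n_phases`` gated phases.

    Phase indices are cyclic: the expiratory arc starts at
    ``end_insp_index`` (t = 0) and runs through ``n_exp_intervals``
    phase steps to ``end_exp_index``; the remaining phases are inspiratory.

    Attributes
    ----------
    phase_interval_s : float
        Fixed time step between adjacent phases, ``60 / (rate * n_phases)``.
    expiratory_times_s : np.ndarray
        ``t_n`` for each expiratory phase, starting at 0 at end-inspiration.
    t_insp_s, t_exp_s : float
        Inspiratory and expiratory durations; at I:E = 1:2 the expiratory
        duration is twice the inspiratory one.
    """

    n_phases: int
    respiratory_rate_per_min: float
    ie_ratio: tuple[float, float] = (1.0, 2.0)
    end_insp_index: int = 0
    # derived
    period_s: float = field(init=False)
    phase_interval_s: float = field(init=False)
    t_insp_s: float = field(init=False)
    t_exp_s: float = field(init=False)
    n_exp_intervals: int = field(init=False)
    end_exp_index: int = field(init=False)
    expiratory_times_s: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.n_phases < 3:
            raise ValueError(f"n_phases must be >= 3, got {self.n_phases}")
        if self.respiratory_rate_per_min <= 0:
            raise ValueError("respiratory_rate_per_min must be positive")
        i, e = self.ie_ratio
        if i <= 0 or e <= 0:
            raise ValueError(f"ie_ratio components must be positive, got {self.ie_ratio}")
        if not 0 <= self.end_insp_index < self.n_phases:
            raise ValueError(
                f"end_insp_index {self.end_insp_index} outside [0, {self.n_phases})"
            )
        period = 60.0 / self.respiratory_rate_per_min
        interval = period / self.n_phases
        exp_frac = e / (i + e)
        # Non-integer expiratory counts round to nearest, ties toward more
        # expiratory phases (maximizes regression samples).
        n_exp = int(np.floor(self.n_phases * exp_frac + 0.5))
        n_exp = min(max(n_exp, 1), self.n_phases - 1)
        object.__setattr__(self, "period_s", period)
        object.__setattr__(self, "phase_interval_s", interval)
        object.__setattr__(self, "t_insp_s", period * i / (i + e))
        object.__setattr__(self, "t_exp_s", period * exp_frac)
        object.__setattr__(self, "n_exp_intervals", n_exp)
        object.__setattr__(
            self, "end_exp_index", (self.end_insp_index + n_exp) % self.n_phases
        )
        times = np.arange(n_exp + 1) * interval
        times.setflags(write=False)
        object.__setattr__(self, "expiratory_times_s", times)

    @property
    def expiratory_phase_indices(self) -> np.ndarray:
        """Cyclic phase indices of the expiratory samples, end-inspiration first."""
        return (self.end_insp_index + np.arange(self.n_exp_intervals + 1)) % self.n_phases

    @property
    def inspiratory_phase_indices(self) -> np.ndarray:
        k = np.arange(self.n_exp_intervals + 1, self.n_phases)
        return (self.end_insp_index + k) % self.n_phases


def build_phase_grid(
    n_phases: int,
    respiratory_rate_per_min: float,
    ie_ratio: tuple[float, float] = (1.0, 2.0),
    end_insp_index: int = 0,
) -> BreathPhaseGrid:
    """Construct the breath-phase timing grid.

    For 21 phases at 20 min⁻¹ and I:E 1:2 this gives a 1/7 s phase
    interval (7 Hz temporal sampling), a 2.0 s expiratory span, and 14
    expiratory intervals (15 expiratory samples including t = 0).
    """
    return BreathPhaseGrid(
        n_phases=n_phases,
        respiratory_rate_per_min=respiratory_rate_per_min,
        ie_ratio=tuple(ie_ratio),
        end_insp_index=end_insp_index,
    )


def detect_end_inspiration(seq, atol_hu: float = 1e-6) -> int:
    """Identify the end-inspiratory phase of an aligned sequence.

    End-inspiration is the most inflated state and therefore the phase with
    the highest gas fraction, i.e. the *minimum* within-mask mean HU.  Ties
    break to the lowest phase index.

    Raises
    ------
    PhaseAmbiguityError
        If all phase means agree within ``atol_hu``; supply
        ``end_insp_index`` manually via config in that case.
    """
    means = phase_mean_hu(seq)
    if np.ptp(means) <= atol_hu:
        raise PhaseAmbiguityError(
            "all phases have identical within-mask mean HU; "
            "set end_insp_index_override in the run config"
        )
    return int(np.argmin(means))


def phase_mean_hu(seq) -> np.ndarray:
    """Within-mask mean HU per phase (the time-varying aeration summary)."""
    inten = seq.intensity
    mask = seq.mask
    if mask.sum() == 0:
        raise ValueError("empty lung mask")
    return np.asarray([inten[..., p][mask].mean() for p in range(inten.shape[-1])])


def sampling_frequency(n_phases: int, respiratory_rate_per_min: float) -> float:
    """Temporal sampling frequency (Hz) of an ``n_phases``-per-breath sequence."""
    if n_phases <= 0 or respiratory_rate_per_min <= 0:
        raise ValueError("n_phases and respiratory rate must be positive")
    return n_phases * respiratory_rate_per_min / 60.0


def rotation_frequency(rotation_period_s: float) -> float:
    """Scanner gantry rotation frequency (Hz) from its rotation period."""
    if rotation_period_s <= 0:
        raise ValueError("rotation period must be positive")
    return 1.0 / rotation_period_s
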