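"""Experimental designs on a micro-time grid.

The neuronal model is integrated on a grid much finer than the scan
repetition time; inputs are piecewise-constant on that grid and the predicted
BOLD signal is sampled at scan times.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["StimulusDesign", "build_nback_design", "design_from_events"]


class DesignError(ValueError):
    """Raised for inconsistent design configurations."""


@dataclass
class StimulusDesign:
    """Inputs x micro-time matrix plus the scan sampling scheme."""

    micro_dt: float
    u: np.ndarray  # inputs x n_micro
    input_names: tuple[str, ...]
    TR: float
    n_scans: int
    scan_sample_indices: np.ndarray

    def __post_init__(self):
        self.u = np.atleast_2d(np.asarray(self.u, float))
        if not np.all(np.isfinite(self.u)):
            raise DesignError("design matrix contains non-finite values")
        self.scan_sample_indices = np.asarray(self.scan_sample_indices, int)
        if np.any(np.diff(self.scan_sample_indices) <= 0):
            raise DesignError("scan_sample_indices must be strictly increasing")
        if self.n_scans * self.TR > self.total_duration + 1e-9:
            raise DesignError("scan protocol exceeds the micro-time span")
        if self.scan_sample_indices.max() >= self.u.shape[1] + 1:
            raise DesignError("scan samples fall outside the micro-time grid")
        self.input_names = tuple(self.input_names)

    @property
    def n_inputs(self) -> int:
        return self.u.shape[0]

    @property
    def n_micro(self) -> int:
        return self.u.shape[1]

    @property
    def total_duration(self) -> float:
        return self.n_micro * self.micro_dt


def build_nback_design(
    n_blocks_per_condition: int = 6,
    trials_per_block: int = 22,
    stimulus_ms: float = 500.0,
    isi_ms: float = 900.0,
    rest_s: float = 30.0,
    TR: float = 2.6,
    micro_dt: float | None = None,
) -> StimulusDesign:
    """Blocked n-back design with a visual driving and a 2-back modulatory input.

    0-back and 2-back blocks alternate, separated by rest blocks. Input 0
    ("visual") is on during every stimulus presentation of either condition;
    input 1 ("wm") is a boxcar covering each 2-back block.

    Defaults reproduce the working-memory protocol the synthetic cohorts
    emulate: six blocks of 22 trials per condition, 500 ms stimuli with a
    900 ms inter-stimulus interval, TR 2.6 s.
    """
    if micro_dt is None:
        micro_dt = TR / 16.0
    for name, v in [
        ("n_blocks_per_condition", n_blocks_per_condition),
        ("trials_per_block", trials_per_block),
        ("stimulus_ms", stimulus_ms),
        ("isi_ms", isi_ms),
        ("TR", TR),
        ("micro_dt", micro_dt),
    ]:
        if v <= 0:
            raise DesignError(f"{name} must be positive")
    if rest_s < 0:
        raise DesignError("rest_s must be non-negative")
    ratio = TR / micro_dt
    if abs(ratio - round(ratio)) > 1e-9:
        raise DesignError(f"micro_dt={micro_dt} does not divide TR={TR}")

    trial_s = (stimulus_ms + isi_ms) / 1000.0
    block_s = trials_per_block * trial_s
    n_task_blocks = 2 * n_blocks_per_condition

    # Condition sequence 0-back, 2-back, 0-back, ... with rest between blocks.
    events_visual: list[tuple[float, float]] = []
    events_wm: list[tuple[float, float]] = []
    t = 0.0
    for b in range(n_task_blocks):
        is_2back = b % 2 == 1
        for k in range(trials_per_block):
            events_visual.append((t + k * trial_s, stimulus_ms / 1000.0))
        if is_2back:
            events_wm.append((t, block_s))
        t += block_s
        if b < n_task_blocks - 1:
            t += rest_s
    total = t

    n_micro = int(np.ceil(total / micro_dt - 1e-9))
    grid = np.arange(n_micro) * micro_dt
    u = np.zeros((2, n_micro))
    for onset, dur in events_visual:
        u[0, (grid >= onset - 1e-9) & (grid < onset + dur - 1e-9)] = 1.0
    for onset, dur in events_wm:
        u[1, (grid >= onset - 1e-9) & (grid < onset + dur - 1e-9)] = 1.0

    step = int(round(ratio))
    n_scans = int(np.floor(n_micro / step))
    scan_idx = np.arange(n_scans) * step
    return StimulusDesign(
        micro_dt=micro_dt,
        u=u,
        input_names=("visual", "wm"),
        TR=TR,
        n_scans=n_scans,
        scan_sample_indices=scan_idx,
    )


def design_from_events(
    events: list[tuple[str, float, float, float]],
    TR: float,
    n_scans: int,
    micro_dt: float | None = None,
    input_names: list[str] | None = None,
) -> StimulusDesign:
    """Build a design from (input_name, onset_s, duration_s, value) events."""
    if micro_dt is None:
        micro_dt = TR / 16.0
    ratio = TR / micro_dt
    if abs(ratio - round(ratio)) > 1e-9:
        raise DesignError(f"micro_dt={micro_dt} does not divide TR={TR}")
    if input_names is None:
        input_names = list(dict.fromkeys(name for name, *_ in events))
    idx = {name: j for j, name in enumerate(input_names)}
    n_micro = int(round(n_scans * ratio))
    grid = np.arange(n_micro) * micro_dt
    u = np.zeros((len(input_names), n_micro))
    for name, onset, dur, value in events:
        if name not in idx:
            raise DesignError(f"unknown input name {name!r}")
        u[idx[name], (grid >= onset - 1e-9) & (grid < onset + dur - 1e-9)] = value
    return StimulusDesign(
        micro_dt=micro_dt,
        u=u,
        input_names=tuple(input_names),
        TR=TR,
        n_scans=n_scans,
        scan_sample_indices=np.arange(n_scans) * int(round(ratio)),
    )
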