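"""UV activation-laser feedback from per-frame localization counts.

During dSTORM acquisition the pool of switchable fluorophores bleaches and
the number of active emitters per frame decays.  Real-time localization
makes the per-frame count available immediately, so a simple controller
can keep the density up: whenever the count stays below a threshold
(default 25 localizations) for a fixed number of consecutive frames
(default 5), the UV activation laser is turned on at the first trigger and
its power is raised by a fixed step (default 5 mW) at every later trigger,
up to a safety clamp.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace


class Command(enum.Enum):
    NONE = "none"
    LASER_ON = "laser_on"
    POWER_UP = "power_up"


@dataclass(frozen=True)
class ControllerState:
    """Pure-value controller state; :func:`update` maps (state, count) -> state."""

    laser_on: bool = False
    power_mw: float = 0.0
    below_threshold_streak: int = 0
    count_threshold: int = 25
    streak_length: int = 5
    power_step_mw: float = 5.0
    power_max_mw: float = 50.0


def update(state: ControllerState,
           frame_count: int) -> tuple[ControllerState, Command]:
    """Advance the controller by one frame of ``frame_count`` localizations.

    The streak counts frames strictly below the threshold and resets on any
    frame at or above it.  When the streak reaches ``streak_length``: the
    first trigger turns the laser on (at one power step); every later
    trigger raises the power by ``power_step_mw`` (clamped at
    ``power_max_mw``).  The streak re-arms (resets) after each trigger.
    """
    if frame_count < 0:
        raise ValueError("frame_count must be non-negative")
    if frame_count < state.count_threshold:
        streak = state.below_threshold_streak + 1
    else:
        return replace(state, below_threshold_streak=0), Command.NONE
    if streak < state.streak_length:
        return replace(state, below_threshold_streak=streak), Command.NONE
    # trigger
    if not state.laser_on:
        new = replace(state, laser_on=True,
                      power_mw=min(state.power_step_mw, state.power_max_mw),
                      below_threshold_streak=0)
        return new, Command.LASER_ON
    new_power = min(state.power_mw + state.power_step_mw, state.power_max_mw)
    return (replace(state, power_mw=new_power, below_threshold_streak=0),
            Command.POWER_UP)


def run_closed_loop(movie_source, analyzer, n_frames: int,
                    state: ControllerState = ControllerState()):
    """Drive the laser port of ``movie_source`` from per-frame counts.

    ``movie_source`` must offer ``set_power(mw)`` and ``next_frame() ->
    (frame, ...)``; ``analyzer(frame) -> int`` returns the localization
    count (e.g. the full detection+fitting pipeline, or a cheap proxy in
    tests).  Returns (counts, powers, commands) per frame.
    """
    counts: list[int] = []
    powers: list[float] = []
    commands: list[Command] = []
    movie_source.set_power(state.power_mw)
    for _ in range(n_frames):
        frame = movie_source.next_frame()
        if isinstance(frame, tuple):
            frame = frame[0]
        n_loc = int(analyzer(frame))
        state, cmd = update(state, n_loc)
        if cmd is not Command.NONE:
            movie_source.set_power(state.power_mw)
        counts.append(n_loc)
        powers.append(state.power_mw)
        commands.append(cmd)
    return counts, powers, commands
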