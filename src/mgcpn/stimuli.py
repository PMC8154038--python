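"""Stimulus labels used throughout the package.

The odor panel follows the standard heliothine pheromone-physiology design:
the conspecific pheromone mixture and its primary and secondary single
components, the behavioral antagonist, a host-plant headspace, and a hexane
vehicle control.  Calcium-imaging studies add a 50:50 plant + pheromone-mix
stimulus that is never used in electrophysiology sessions.
"""

from __future__ import annotations

from enum import Enum


class StimulusLabel(str, Enum):
    """Odor stimuli presented to macroglomerular-complex projection neurons."""

    PM = "PM"  #: binary pheromone mixture (Z11-16:Al + Z9-16:Al)
    PP = "PP"  #: primary pheromone component, Z11-16:Al
    SP = "SP"  #: secondary pheromone component, Z9-16:Al
    BA = "BA"  #: behavioral antagonist, Z9-14:Al
    PLANT = "PLANT"  #: host-plant headspace
    CTRL = "CTRL"  #: hexane vehicle control
    PLANT_PM = "PLANT_PM"  #: 50:50 plant + pheromone mix (calcium imaging only)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Stimuli used in intracellular-recording (spike) sessions.
SPIKE_STIMULI: tuple[StimulusLabel, ...] = (
    StimulusLabel.PM,
    StimulusLabel.PP,
    StimulusLabel.SP,
    StimulusLabel.BA,
    StimulusLabel.PLANT,
    StimulusLabel.CTRL,
)

#: Stimuli used in calcium-imaging studies.
CALCIUM_STIMULI: tuple[StimulusLabel, ...] = SPIKE_STIMULI + (StimulusLabel.PLANT_PM,)

#: The four female-produced odorants that drive the framework analyses.
FEMALE_PRODUCED: tuple[StimulusLabel, ...] = (
    StimulusLabel.PM,
    StimulusLabel.PP,
    StimulusLabel.SP,
    StimulusLabel.BA,
)


def as_stimulus(value: "StimulusLabel | str") -> StimulusLabel:
    """Coerce a string or enum member to a :class:`StimulusLabel`."""
    if isinstance(value, StimulusLabel):
        return value
    try:
        return StimulusLabel(value)
    except ValueError as exc:
        raise ValueError(f"unknown stimulus label: {value!r}") from exc
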