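"""The four cue conditions of the orthogonalized Go-NoGo task.

The 2x2 design crosses the instrumentally correct action (Go/NoGo) with
outcome valence (win money vs. avoid losing money), so that Pavlovian and
instrumental demands are independent:

====== ======= ==============
name   valence correct action
====== ======= ==============
G2W    win     go
G2AP   punish  go
NG2W   win     nogo
NG2AP  punish  nogo
====== ======= ==============
"""

from dataclasses import dataclass

__all__ = ["Condition", "CONDITIONS", "CONDITION_INDEX", "get_condition"]


@dataclass(frozen=True)
class Condition:
    name: str
    valence: str        # "win" | "punishment"
    correct_action: str  # "go" | "nogo"

    @property
    def is_win(self) -> bool:
        return self.valence == "win"

    @property
    def better_outcome(self) -> int:
        """Outcome delivered when the contingency favours the subject."""
        return 1 if self.is_win else 0

    @property
    def worse_outcome(self) -> int:
        return 0 if self.is_win else -1


CONDITIONS = (
    Condition("G2W", "win", "go"),
    Condition("G2AP", "punishment", "go"),
    Condition("NG2W", "win", "nogo"),
    Condition("NG2AP", "punishment", "nogo"),
)

CONDITION_INDEX = {c.name: i for i, c in enumerate(CONDITIONS)}
_BY_NAME = {c.name: c for c in CONDITIONS}


def get_condition(name) -> Condition:
    if isinstance(name, Condition):
        return name
    try:
        return _BY_NAME[name]
    except KeyError:
        raise ValueError(
            f"unknown condition {name!r}; expected one of "
            f"{sorted(_BY_NAME)}") from None
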