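"""Variable schema: the 24 observed measures, their domains and profile factors.

The battery indexes three domains of adolescent functioning — cognitive,
social and emotional — through task-derived ratios and questionnaire
subscale scores.  For the community-profile analysis the 24 variables
collapse onto 12 profile factors (multi-indicator clusters such as the
seven BRIEF scales, plus single-indicator factors such as the cold version
of the Columbia Card Task).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field


@dataclass(frozen=True)
class Variable:
    """One observed measure."""

    code: str
    label: str
    domain: str   # cognitive | social | emotional
    factor: str   # one of the 12 profile-factor names
    direction: int = 1  # +1: higher = more of the named construct


# Profile-factor names in canonical reporting order.
FACTOR_ORDER = (
    "EF Task", "Risk Cold", "EF Daily", "Reg Prob",
    "Soc Supp", "RPI", "Pro Soc", "Peer Prob",
    "NFA", "Risk Hot", "Emo Prob", "Emo Reg",
)

DOMAINS = ("cognitive", "social", "emotional")

_VARIABLES = (
    # cognitive functioning (13 variables)
    Variable("EFSW", "Dots-Triangles switch-cost ratio", "cognitive", "EF Task"),
    Variable("EFIN", "Eriksen Flankers congruency ratio", "cognitive", "EF Task"),
    Variable("EFWM", "Digit Span forward/backward ratio", "cognitive", "EF Task"),
    Variable("RCOL", "Columbia Card Task (cold) mean cards", "cognitive", "Risk Cold"),
    Variable("BRIN", "BRIEF Inhibit", "cognitive", "EF Daily"),
    Variable("BRFX", "BRIEF Shift", "cognitive", "EF Daily"),
    Variable("BRWM", "BRIEF Working Memory", "cognitive", "EF Daily"),
    Variable("BRTC", "BRIEF Task Completion", "cognitive", "EF Daily"),
    Variable("BRPO", "BRIEF Plan/Organize", "cognitive", "EF Daily"),
    Variable("BROM", "BRIEF Organization of Materials", "cognitive", "EF Daily"),
    Variable("BRMO", "BRIEF Monitor", "cognitive", "EF Daily"),
    Variable("SDQC", "SDQ Conduct problems", "cognitive", "Reg Prob"),
    Variable("SDQH", "SDQ Hyperactivity/inattention", "cognitive", "Reg Prob"),
    # social functioning (7 variables)
    Variable("SSPA", "Social support - parents", "social", "Soc Supp"),
    Variable("SSCM", "Social support - classmates", "social", "Soc Supp"),
    Variable("SSTE", "Social support - teachers", "social", "Soc Supp"),
    Variable("SSFR", "Social support - close friends", "social", "Soc Supp"),
    Variable("RPIF", "Resistance to peer influence", "social", "RPI"),
    Variable("SDQS", "SDQ Prosocial behavior", "social", "Pro Soc"),
    Variable("SDQP", "SDQ Peer relationship problems", "social", "Peer Prob"),
    # emotional functioning (4 variables)
    Variable("NFAR", "Need for arousal", "emotional", "NFA"),
    Variable("RHOT", "Columbia Card Task (hot) mean cards", "emotional", "Risk Hot"),
    Variable("SDQE", "SDQ Emotional symptoms", "emotional", "Emo Prob"),
    Variable("BRER", "BRIEF Emotional Control", "emotional", "Emo Reg"),
)


@dataclass(frozen=True)
class VariableSchema:
    """The full 24-variable / 12-factor / 3-domain schema.

    Invariants enforced at construction: 24 variables, unique codes, every
    variable in exactly one domain and one factor, all 12 factors and all
    3 domains populated.
    """

    variables: tuple[Variable, ...] = field(default=_VARIABLES)

    def __post_init__(self) -> None:
        codes = [v.code for v in self.variables]
        if len(codes) != len(set(codes)):
            raise ValueError("duplicate variable codes in schema")
        if len(self.variables) != 24:
            raise ValueError(f"schema must have 24 variables, got {len(self.variables)}")
        bad = [v.code for v in self.variables if v.domain not in DOMAINS]
        if bad:
            raise ValueError(f"unknown domain for variables {bad}")
        missing = set(FACTOR_ORDER) - {v.factor for v in self.variables}
        if missing:
            raise ValueError(f"factors with no indicator: {sorted(missing)}")
        stray = {v.factor for v in self.variables} - set(FACTOR_ORDER)
        if stray:
            raise ValueError(f"unknown factors: {sorted(stray)}")

    @property
    def codes(self) -> list[str]:
        return [v.code for v in self.variables]

    @property
    def factors(self) -> list[str]:
        return list(FACTOR_ORDER)

    def factor_members(self, factor: str) -> list[str]:
        """Variable codes belonging to one profile factor, in schema order."""
        members = [v.code for v in self.variables if v.factor == factor]
        if not members:
            raise KeyError(f"unknown factor: {factor!r}")
        return members

    def domain_members(self, domain: str) -> list[str]:
        members = [v.code for v in self.variables if v.domain == domain]
        if not members:
            raise KeyError(f"unknown domain: {domain!r}")
        return members

    def domain_of(self, code: str) -> str:
        for v in self.variables:
            if v.code == code:
                return v.domain
        raise KeyError(f"unknown variable code: {code!r}")

    def to_json(self) -> str:
        return json.dumps(
            [
                {"code": v.code, "label": v.label, "domain": v.domain,
                 "factor": v.factor, "direction": v.direction}
                for v in self.variables
            ],
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "VariableSchema":
        items = json.loads(text)
        return cls(tuple(Variable(**it) for it in items))


def default_schema() -> VariableSchema:
    """The canonical 24-variable battery schema."""
    return VariableSchema()
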