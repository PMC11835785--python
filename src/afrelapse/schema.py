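"""Clinical variable schema and discretization.

The model operates on fully discrete patient records.  Each clinical
variable is a :class:`VariableSpec` with a small ordered set of named
states; numeric measurements (age, BMI, left-atrial volume indexed to body
surface area, epicardial fat volume) are discretized into bands whose
interval convention is: the lower end of the first band is closed, interior
upper ends are closed, and the top band is open-ended.  So a left-atrial
volume of exactly 100 mL/m2 falls in the bottom band ``[0, 100]`` and
125.01 mL/m2 falls in the top band ``(125, inf)``.

The default 12-variable schema mirrors the registry of 480 patients who
underwent pulmonary vein isolation: sex, age band, alcoholism, smoking,
diabetes, high blood pressure (hbp), obstructive sleep apnea (osa), BMI
class, preablation AF type, left-atrial-volume band, epicardial-fat band,
and the outcome ``relapse`` (AF recurrence after the blanking period).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping

from .exceptions import InvalidParameterError, SchemaMismatchError

__all__ = [
    "VariableSpec",
    "DomainSchema",
    "build_default_schema",
    "discretize_record",
    "STATE_ALIASES",
]

#: Presentation-string aliases accepted on input for canonical state tokens.
#: Canonical labels are lowercase tokens chosen for bit-exact I/O; the alias
#: map admits the interval/bracket spellings used in clinical tables.
STATE_ALIASES: dict[str, dict[str, str]] = {
    "age": {"<=45": "le45", "46-65": "46to65", "+65": "over65", ">65": "over65"},
    "la_volume": {
        "[0 to 100]": "le100",
        "(100 to 125]": "100to125",
        "(125 to inf)": "over125",
    },
    "epicardial_fat": {
        "[0 to 2.7]": "le2.7",
        "(2.7 to 4.6]": "2.7to4.6",
        "(4.6 to inf)": "over4.6",
    },
    "bmi": {"normal weight": "normal"},
    "af_type": {"paroxysmal af": "paroxysmal", "persistent af": "persistent"},
}

_BOOL_STATES = ("false", "true")


@dataclass(frozen=True)
class VariableSpec:
    """A discretized clinical variable with its ordered, named states.

    Parameters
    ----------
    name
        Identifier used in cohort columns, structure files and CPTs.
    states
        Ordered state labels, unique, at least two.
    bin_edges
        For variables discretized from a numeric measurement, the interior
        cut points (ascending).  ``k`` edges imply ``k + 1`` bands.
    """

    name: str
    states: tuple[str, ...]
    bin_edges: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.states) < 2:
            raise InvalidParameterError(
                f"variable {self.name!r} needs at least 2 states"
            )
        if len(set(self.states)) != len(self.states):
            raise InvalidParameterError(
                f"variable {self.name!r} has duplicate state labels"
            )
        if self.bin_edges is not None:
            if list(self.bin_edges) != sorted(self.bin_edges):
                raise InvalidParameterError(
                    f"bin edges of {self.name!r} must be ascending"
                )
            if len(self.states) != len(self.bin_edges) + 1:
                raise InvalidParameterError(
                    f"variable {self.name!r}: {len(self.bin_edges)} edges imply "
                    f"{len(self.bin_edges) + 1} states, got {len(self.states)}"
                )

    @property
    def cardinality(self) -> int:
        return len(self.states)

    def state_index(self, state: str) -> int:
        """Index of a canonical or aliased state label."""
        low = state.lower()
        canon = STATE_ALIASES.get(self.name, {}).get(low, low if low in self.states else state)
        try:
            return self.states.index(canon)
        except ValueError:
            raise SchemaMismatchError(
                f"{state!r} is not a state of {self.name!r}; "
                f"allowed: {list(self.states)}"
            ) from None

    def bin_value(self, value: float) -> str:
        """Map a numeric measurement to its band label.

        Lower extreme closed, interior upper ends closed, top band open:
        ``value <= edges[0]`` is band 0, ``edges[i-1] < value <= edges[i]``
        is band ``i``, anything above the last edge is the top band.
        """
        if self.bin_edges is None:
            raise InvalidParameterError(f"{self.name!r} has no bin edges")
        if not math.isfinite(value) or value < 0:
            raise InvalidParameterError(
                f"invalid measurement {value!r} for {self.name!r}"
            )
        for i, edge in enumerate(self.bin_edges):
            if value <= edge:
                return self.states[i]
        return self.states[-1]


@dataclass(frozen=True)
class DomainSchema:
    """Ordered collection of variables plus the designated outcome."""

    variables: tuple[VariableSpec, ...]
    outcome_name: str = "relapse"
    _index: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise InvalidParameterError("variable names must be unique")
        if self.outcome_name not in names:
            raise InvalidParameterError(
                f"outcome {self.outcome_name!r} not among variables"
            )
        object.__setattr__(
            self, "_index", {v.name: i for i, v in enumerate(self.variables)}
        )

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(v.name for v in self.variables)

    @property
    def cardinalities(self) -> tuple[int, ...]:
        return tuple(v.cardinality for v in self.variables)

    @property
    def state_space_size(self) -> int:
        return math.prod(self.cardinalities)

    def __contains__(self, name: str) -> bool:
        return name in self._index

    def __getitem__(self, name: str) -> VariableSpec:
        try:
            return self.variables[self._index[name]]
        except KeyError:
            raise SchemaMismatchError(f"unknown variable {name!r}") from None

    def index(self, name: str) -> int:
        if name not in self._index:
            raise SchemaMismatchError(f"unknown variable {name!r}")
        return self._index[name]

    def to_json(self) -> str:
        payload = {
            "outcome": self.outcome_name,
            "variables": [
                {
                    "name": v.name,
                    "states": list(v.states),
                    **(
                        {"bin_edges": list(v.bin_edges)}
                        if v.bin_edges is not None
                        else {}
                    ),
                }
                for v in self.variables
            ],
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "DomainSchema":
        payload = json.loads(text)
        variables = tuple(
            VariableSpec(
                name=v["name"],
                states=tuple(v["states"]),
                bin_edges=tuple(v["bin_edges"]) if "bin_edges" in v else None,
            )
            for v in payload["variables"]
        )
        return cls(variables=variables, outcome_name=payload["outcome"])


def build_default_schema() -> DomainSchema:
    """The 12-variable schema of the post-ablation relapse model.

    Age bands split at 45 and 65 years; left-atrial volume at 100 and
    125 mL/m2; epicardial fat at 2.7 and 4.6 cm3.  BMI classes use the WHO
    cut points 25 and 30 kg/m2.  The joint state space has
    ``2**8 * 3**4 = 20736`` cells.
    """
    return DomainSchema(
        variables=(
            VariableSpec("sex", ("female", "male")),
            VariableSpec("age", ("le45", "46to65", "over65"), (45.0, 65.0)),
            VariableSpec("alcoholism", _BOOL_STATES),
            VariableSpec("smoking", _BOOL_STATES),
            VariableSpec("diabetes", _BOOL_STATES),
            VariableSpec("hbp", _BOOL_STATES),
            VariableSpec("osa", _BOOL_STATES),
            VariableSpec("bmi", ("normal", "overweight", "obese"), (25.0, 30.0)),
            VariableSpec("af_type", ("paroxysmal", "persistent")),
            VariableSpec("la_volume", ("le100", "100to125", "over125"), (100.0, 125.0)),
            VariableSpec(
                "epicardial_fat", ("le2.7", "2.7to4.6", "over4.6"), (2.7, 4.6)
            ),
            VariableSpec("relapse", _BOOL_STATES),
        ),
        outcome_name="relapse",
    )


def discretize_record(
    raw: Mapping[str, object], schema: DomainSchema
) -> dict[str, str]:
    """Map raw clinical measurements onto canonical schema states.

    Numeric fields (those whose :class:`VariableSpec` carries bin edges) are
    banded with the closed/open convention described in the module
    docstring; boolean fields accept Python bools, 0/1 and the strings
    "true"/"false"; categorical fields accept canonical labels or aliases.
    """
    out: dict[str, str] = {}
    for name, value in raw.items():
        spec = schema[name]
        if spec.bin_edges is not None and isinstance(value, (int, float)):
            out[name] = spec.bin_value(float(value))
        elif isinstance(value, bool):
            out[name] = _BOOL_STATES[int(value)]
        elif isinstance(value, (int, float)) and spec.states == _BOOL_STATES:
            if value not in (0, 1):
                raise InvalidParameterError(
                    f"boolean variable {name!r} got {value!r}"
                )
            out[name] = _BOOL_STATES[int(value)]
        else:
            out[name] = spec.states[spec.state_index(str(value))]
    return out


def validate_assignment(
    assignment: Mapping[str, str], schema: DomainSchema, require_complete: bool = False
) -> None:
    """Raise SchemaMismatchError for unknown variables or states."""
    for name, state in assignment.items():
        schema[name].state_index(state)
    if require_complete:
        missing = set(schema.names) - set(assignment)
        if missing:
            raise SchemaMismatchError(f"assignment missing variables: {sorted(missing)}")
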