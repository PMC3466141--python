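"""Variable specifications: measurement scale and ordinal level order.

A :class:`VariableSpec` declares how a matching variable enters the analysis:
its name, measurement scale (continuous, binary, ordinal, nominal) and, for
ordinal variables, the ordered category labels used for rank distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .errors import ConfigError

SCALES = ("continuous", "binary", "ordinal", "nominal")

#: Ordered education levels used throughout the package.
EDUCATION_LEVELS = ("less-than-HS", "HS-grad", "post-HS")


@dataclass(frozen=True)
class VariableSpec:
    """How one matching variable is measured and compared within pairs."""

    name: str
    scale: str
    ordinal_levels: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ConfigError(
                f"variable {self.name!r}: unknown scale {self.scale!r}; "
                f"expected one of {SCALES}"
            )
        object.__setattr__(self, "ordinal_levels", tuple(self.ordinal_levels))
        if self.scale == "ordinal":
            if not self.ordinal_levels:
                raise ConfigError(
                    f"variable {self.name!r}: ordinal scale requires ordinal_levels"
                )
            if len(set(self.ordinal_levels)) != len(self.ordinal_levels):
                raise ConfigError(
                    f"variable {self.name!r}: duplicate ordinal levels"
                )
        elif self.ordinal_levels:
            raise ConfigError(
                f"variable {self.name!r}: ordinal_levels only valid for ordinal scale"
            )

    @property
    def is_categorical(self) -> bool:
        """True for variables compared with the categorical marginal test."""
        return self.scale in ("binary", "ordinal", "nominal")


def default_varspecs() -> list[VariableSpec]:
    """The standard matching-variable set: demographics, smoking, alcohol.

    ``smoking_duration`` is a derived variable (years between first and last
    cigarette, current age substituted for current smokers).
    """
    return [
        VariableSpec("sex", "binary"),
        VariableSpec("race", "nominal"),
        VariableSpec("age", "continuous"),
        VariableSpec("education", "ordinal", EDUCATION_LEVELS),
        VariableSpec("employment", "nominal"),
        VariableSpec("days_smoked_30", "continuous"),
        VariableSpec("smoking_duration", "continuous"),
        VariableSpec("alc_freq_month", "continuous"),
        VariableSpec("alc_typical", "continuous"),
        VariableSpec("alc_six_freq", "continuous"),
    ]


def load_varspecs(path) -> list[VariableSpec]:
    """Load variable specs from a YAML file.

    Expected layout::

        variables:
          age: {scale: continuous}
          education: {scale: ordinal, levels: [less-than-HS, HS-grad, post-HS]}
    """
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: varspec file must be a mapping")
    variables = doc.get("variables", doc)
    if not isinstance(variables, dict) or not variables:
        raise ConfigError(f"{path}: no variables declared")
    specs = []
    for name, entry in variables.items():
        if not isinstance(entry, dict) or "scale" not in entry:
            raise ConfigError(f"{path}: variable {name!r} must declare a scale")
        specs.append(
            VariableSpec(
                name=str(name),
                scale=str(entry["scale"]),
                ordinal_levels=tuple(entry.get("levels", ())),
            )
        )
    return specs


def dump_varspecs(specs: list[VariableSpec], path) -> None:
    """Write variable specs as YAML (inverse of :func:`load_varspecs`)."""
    doc = {"variables": {}}
    for s in specs:
        entry: dict = {"scale": s.scale}
        if s.ordinal_levels:
            entry["levels"] = list(s.ordinal_levels)
        doc["variables"][s.name] = entry
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
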