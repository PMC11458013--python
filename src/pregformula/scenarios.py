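"""Static hypothetical intervention scenarios on the second pregnancy.

Each scenario optionally assigns everyone's pregnancy-2 BMI category
and/or forces universal smoking cessation at the start of pregnancy 2.
The default set of eight covers: the natural course (no intervention),
assignment to each BMI category, cessation alone, and each combination.
"""

from __future__ import annotations

from dataclasses import dataclass

from .cohort_io import BMI_CATEGORIES


@dataclass(frozen=True)
class ScenarioSpec:
    """A static intervention on pregnancy-2 exposures.

    ``bmi_intervention`` sets everyone's pregnancy-2 BMI category to the
    given level ("healthy" / "overweight" / "obese"); ``smoking_cessation``
    sets everyone's pregnancy-2 smoking to non-smoking.  Either may be
    absent; with both absent the scenario is the natural course.
    """

    id: int
    bmi_intervention: str | None = None
    smoking_cessation: bool = False
    description: str = ""

    def __post_init__(self) -> None:
        if self.bmi_intervention is not None and self.bmi_intervention not in BMI_CATEGORIES:
            raise ValueError(f"unknown BMI category {self.bmi_intervention!r}")

    @property
    def is_natural_course(self) -> bool:
        return self.bmi_intervention is None and not self.smoking_cessation


DEFAULT_SCENARIOS: tuple[ScenarioSpec, ...] = (
    ScenarioSpec(0, None, False, "Natural course (no change)"),
    ScenarioSpec(1, "healthy", False, "All start pregnancy 2 with BMI 18.5-24.9"),
    ScenarioSpec(2, "overweight", False, "All start pregnancy 2 with BMI 25-29.9"),
    ScenarioSpec(3, "obese", False, "All start pregnancy 2 with BMI >= 30"),
    ScenarioSpec(4, None, True, "All smokers quit before pregnancy 2"),
    ScenarioSpec(5, "healthy", True, "Scenarios 1 and 4 combined"),
    ScenarioSpec(6, "overweight", True, "Scenarios 2 and 4 combined"),
    ScenarioSpec(7, "obese", True, "Scenarios 3 and 4 combined"),
)
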