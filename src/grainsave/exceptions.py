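"""Error and warning types shared across the model."""

from __future__ import annotations


class ValidationError(ValueError):
    """An input violated the contract of a domain type or operation."""


class ConfigError(ValidationError):
    """A configuration could not be validated.

    Carries *every* problem found, not just the first, so a user can fix
    a config file in one pass.
    """

    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        super().__init__(
            "invalid configuration (%d problem%s):\n  - %s"
            % (len(self.problems), "" if len(self.problems) == 1 else "s",
               "\n  - ".join(self.problems))
        )


class ExtrapolationWarning(UserWarning):
    """The intake gap exceeds the dose the pooled relative risk refers to."""
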