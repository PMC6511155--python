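"""Exception hierarchy.

Every error raised by glycoplan derives from :class:`GlycoplanError`, so
callers embedding the planner can catch one base class. Validation of
structured documents (KB configs, FHIR-lite bundles) reports the failing
JSON-ish path in the message.
"""


class GlycoplanError(Exception):
    """Base class for all glycoplan errors."""


class InputError(GlycoplanError, ValueError):
    """A scalar input violates an operation's precondition."""


class UnitError(GlycoplanError, ValueError):
    """A quantity carries an unknown or mismatched unit of measure."""


class ConfigError(GlycoplanError, ValueError):
    """A knowledge-base config document violates the schema.

    The message names the failing path within the document.
    """


class NoSafeInsulinError(GlycoplanError):
    """Every product of the requested action class is contradicted."""

    def __init__(self, action_class: str, reasons: dict[str, str]):
        self.action_class = action_class
        self.reasons = dict(reasons)
        detail = "; ".join(f"{code}: {why}" for code, why in sorted(reasons.items()))
        super().__init__(
            f"no safe {action_class}-acting insulin: every product is "
            f"contradicted ({detail})"
        )


class PeriodTooShortError(GlycoplanError, ValueError):
    """The weight-adjustment period drives planned calories to zero or below."""


class InsufficientDataError(GlycoplanError, ValueError):
    """Pattern management needs at least three consecutive days of readings."""


class DoseMappingError(GlycoplanError, KeyError):
    """A pattern finding names a dose the regimen does not contain."""


class StalePlanError(GlycoplanError):
    """Attempted maintenance of a plan that has already been superseded."""


class BundleError(GlycoplanError, ValueError):
    """A FHIR-lite bundle is malformed, schema-invalid, or un-bindable."""


class PlannerError(GlycoplanError):
    """A sub-planner failed while assembling a care plan.

    Wraps the underlying error and names the module that raised it.
    """

    def __init__(self, module: str, cause: Exception):
        self.module = module
        self.__cause__ = cause
        super().__init__(f"{module}: {cause}")
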