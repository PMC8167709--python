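"""Exception hierarchy for crowdecg."""


class CrowdECGError(Exception):
    """Base class for all crowdecg errors."""


class SchemaError(CrowdECGError):
    """A tabular input does not conform to the documented column schema.

    The message names the offending file, row and column.
    """


class ValidationError(CrowdECGError):
    """A dataset violates one or more domain invariants.

    Carries the full list of failures so callers see every problem at once,
    never just the first.
    """

    def __init__(self, failures):
        self.failures = list(failures)
        super().__init__(
            "dataset validation failed with %d error(s):\n  - %s"
            % (len(self.failures), "\n  - ".join(self.failures))
        )


class UndefinedCorrelationError(CrowdECGError):
    """Pearson correlation requested on an axis with zero variance."""


class ConfigError(CrowdECGError):
    """A run/simulation/bootstrap configuration is invalid."""
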