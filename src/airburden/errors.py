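"""Exception hierarchy shared across the package.

Every error raised by airburden derives from :class:`AirburdenError`, so
callers can catch one type at a pipeline boundary while tests can assert on
the specific failure class.
"""


class AirburdenError(Exception):
    """Base class for all airburden errors."""


class ConfigError(AirburdenError, ValueError):
    """A configuration object violates one of its invariants.

    The message always names the offending field.
    """


class ArgumentError(AirburdenError, ValueError):
    """An operation received structurally invalid arguments."""


class DomainError(AirburdenError, ValueError):
    """Arguments are structurally valid but outside the operation's domain
    (e.g. non-positive values fed to a log transform, a zero reference in a
    percent change)."""


class SchemaError(AirburdenError, ValueError):
    """A tabular input is missing required columns."""


class RowError(AirburdenError, ValueError):
    """One or more rows of a tabular input violate record invariants.

    Carries the per-row messages (with 1-based file line numbers) in
    ``self.rows``.
    """

    def __init__(self, rows: list[str]):
        self.rows = list(rows)
        preview = "; ".join(self.rows[:5])
        more = "" if len(self.rows) <= 5 else f" (+{len(self.rows) - 5} more)"
        super().__init__(f"{len(self.rows)} invalid row(s): {preview}{more}")


class DataCompletenessError(AirburdenError, ValueError):
    """A panel is missing required (country, year) combinations; the message
    names the countries."""
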