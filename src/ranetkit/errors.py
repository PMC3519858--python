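"""Exception hierarchy shared across the toolkit."""


class RanetkitError(Exception):
    """Base class for all toolkit errors."""


class ConfigurationError(RanetkitError):
    """Input or parameter combination that cannot be analyzed (e.g. no
    normal samples to normalize against)."""


class EmptySelectionError(RanetkitError):
    """A selection step produced no rows/columns/genes."""


class FormatError(RanetkitError):
    """A file did not parse as the expected format."""
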