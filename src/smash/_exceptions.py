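"""Exception hierarchy shared across the package."""


class SmashError(Exception):
    """Base class for package errors."""


class ValidationError(SmashError, ValueError):
    """Input failed a semantic validation check (duplicate ids, bad shapes...)."""


class FormatError(SmashError, ValueError):
    """A file could not be parsed into the expected tabular/matrix layout."""


class EmptyResultError(SmashError, ValueError):
    """An operation produced an empty result (e.g. all genes filtered out)."""
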