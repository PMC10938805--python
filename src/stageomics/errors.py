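"""Exception types shared across the package."""


class StageomicsError(Exception):
    """Base class for package errors."""


class InputError(StageomicsError, ValueError):
    """Malformed or inconsistent user input (files, configs, tables)."""
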