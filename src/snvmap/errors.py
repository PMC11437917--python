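class SnvmapError(Exception):
    """Base class for all snvmap errors."""


class UserInputError(SnvmapError):
    """Bad inputs or parameters supplied by the user (CLI exit code 1)."""
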