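"""Exception hierarchy; the CLI maps these onto distinct exit codes."""


class FSCChangeError(Exception):
    """Base class for pipeline errors."""


class ConfigError(FSCChangeError):
    """Invalid or inconsistent run configuration (CLI exit code 2)."""


class FormatError(FSCChangeError):
    """Malformed or incomplete input data (CLI exit code 3)."""


class EdgeError(FSCChangeError):
    """A patch window would cross the raster edge."""


class MaskedPatchError(FSCChangeError):
    """A patch window intersects nodata pixels; the sample is excluded."""


class DegenerateInputError(FSCChangeError):
    """An operation received degenerate input (e.g. empty class row)."""
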