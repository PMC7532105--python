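"""Exception hierarchy shared across sequelkit modules."""


class SequelKitError(Exception):
    """Base class for all sequelkit errors."""


class ReadNameError(SequelKitError, ValueError):
    """A read name does not follow ``movie/hole/qStart_qEnd``."""


class AnnotationError(SequelKitError, ValueError):
    """A scraps record is missing or carries an invalid annotation tag."""


class IntegrityError(SequelKitError, ValueError):
    """Input records are mutually inconsistent (mixed movies, overlapping segments)."""


class ConfigError(SequelKitError, ValueError):
    """An invalid combination of options was requested."""
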