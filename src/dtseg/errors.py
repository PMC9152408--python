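"""Exception types shared across the package."""


class DtsegError(Exception):
    """Base class for all package errors."""


class ValidationError(DtsegError, ValueError):
    """Invalid argument, configuration or data structure."""


class ImageIOError(DtsegError, IOError):
    """Unreadable, corrupt or unsupported image file."""
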