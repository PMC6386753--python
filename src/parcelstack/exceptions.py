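"""Exception types shared across the package."""


class ParcelstackError(Exception):
    """Base class for package-specific errors."""


class AtlasFormatError(ParcelstackError, ValueError):
    """An atlas file does not match its declared dialect."""


class DegenerateRoiError(ParcelstackError, ValueError):
    """An ROI resolves to no usable voxels (or an all-zero map)."""


class MotionFormatError(ParcelstackError, ValueError):
    """A motion-parameter table has the wrong shape."""
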