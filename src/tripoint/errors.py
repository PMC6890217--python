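"""Exception hierarchy shared across the package."""


class TriPointError(Exception):
    """Base class for all package-specific errors."""


class DegenerateGeometryError(TriPointError):
    """Coincident or collinear points make a construction ill-defined."""


class DegenerateImplantError(TriPointError):
    """Implant endpoints coincide (zero-length axis)."""


class TooFewLandmarksError(TriPointError):
    """Fewer landmark pairs than the operation requires."""


class RectificationError(TriPointError):
    """Depth rectification is unbounded (axes nearly perpendicular)."""


class CaseFormatError(TriPointError):
    """A case input file violates the expected CSV format.

    The message always names the file, the line and the rule violated.
    """
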