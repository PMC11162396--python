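"""Exception hierarchy shared across the pipeline stages."""


class CryodistError(Exception):
    """Base class for all package-specific errors."""


class GeometryError(CryodistError):
    """A region, depot or grid does not fit the geometry it must lie in."""


class FormatError(CryodistError):
    """On-disk stack layout or sidecar metadata is missing or malformed."""


class StackOrderError(FormatError):
    """Section files do not form a contiguous, monotonically indexed series."""


class DegenerateHistogramError(CryodistError):
    """Automatic thresholding is impossible (e.g. a constant-valued volume).

    Raised instead of silently returning an arbitrary mask; callers should
    switch to a fixed threshold.
    """


class EmptyMaskError(CryodistError):
    """A tissue or fluorescence mask came out empty where one is required."""


class EmptyShapeError(CryodistError):
    """Shape metrics were requested for an empty segmentation."""
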