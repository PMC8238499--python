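"""Exception types raised across the package."""


class MultiweaveError(Exception):
    """Base class for package-specific errors."""


class ZeroLibraryError(MultiweaveError):
    """A cell has a zero library size where per-cell scaling is required."""


class RankError(MultiweaveError):
    """A requested number of components exceeds the attainable rank."""


class EmptyAnchorError(MultiweaveError):
    """No mutual-nearest-neighbor anchors could be found between datasets."""
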