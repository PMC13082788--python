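"""Exception hierarchy shared across the tracking pipeline.

Each failure mode that the command-line layer maps to a distinct exit code
gets its own class; everything derives from :class:`PairtrackError` so
library users can catch broadly.
"""


class PairtrackError(Exception):
    """Base class for all pairtrack errors."""


class InvalidInputError(PairtrackError, ValueError):
    """An argument violates a documented precondition."""


class InvalidConfigError(PairtrackError, ValueError):
    """A configuration file or object is malformed or inconsistent."""


class InsufficientConnectivityError(PairtrackError, RuntimeError):
    """No coexisting fragment pair exists anywhere in the video.

    Without temporally coexisting fragments there are no label-free
    negative pairs, so the contrastive identification step cannot run.
    """


class DataInconsistencyError(PairtrackError, RuntimeError):
    """The data contradicts the declared number of animals.

    Raised e.g. when more than N fragments coexist in one frame.
    """
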