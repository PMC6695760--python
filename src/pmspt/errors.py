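"""Exception types shared across the analysis stages."""


class PmsptError(Exception):
    """Base class for all package-specific failures."""


class RefusalError(PmsptError):
    """An operation declined to produce a result (degenerate or insufficient input).

    Raised instead of returning a silently wrong number, e.g. a lifetime fit on
    an empty histogram or a depth selection that matches no z-slice.
    """


class FitError(PmsptError):
    """A model fit diverged or the data do not support the model."""
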