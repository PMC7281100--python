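"""Exception hierarchy for pathmet."""


class PathmetError(Exception):
    """Base class for all pathmet errors."""


class InputError(PathmetError):
    """Malformed or invalid user input (bad TSV row, bad parameter, bad mass)."""


class ModelError(PathmetError):
    """A metabolic model violates a structural invariant."""


class UnattainableObservationError(PathmetError):
    """An observed mass bin cannot be generated under the model.

    Raised when some bin with ``w_k = 1`` has no candidate metabolite that
    belongs to any pathway: the likelihood of the data is then zero for every
    pathway-activity state and the posterior is undefined.  The usual causes
    are an incomplete metabolic model or a binning/ionization mistake.
    """
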