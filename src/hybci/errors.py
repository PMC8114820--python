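"""Exception types shared across the pipeline stages."""


class InvalidParameterError(ValueError):
    """A numeric parameter is outside its valid domain (non-positive rate,
    band edge beyond Nyquist, singular extinction matrix, ...)."""


class ShapeError(ValueError):
    """Array arguments have incompatible lengths or shapes."""


class OutOfBoundsError(ValueError):
    """A stimulus marker's epoch window falls outside the recording."""


class DegenerateInputError(ValueError):
    """Input has no usable structure (e.g. all points identical for k-means)."""


class ClassCoverageError(ValueError):
    """An operation requiring both classes received a single-class table."""


class MissingLabelError(ValueError):
    """Label-dependent (faithful) weighting was asked for unlabeled rows."""


class StratificationError(ValueError):
    """A class has fewer members than the requested number of CV folds."""


class TrainingError(ValueError):
    """A classifier received a degenerate training set (single class)."""
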