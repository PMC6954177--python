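"""Exception hierarchy shared across the pipeline stages."""


class CloneKinError(Exception):
    """Base class for all clonekin errors."""


class InvalidConfigError(CloneKinError, ValueError):
    """A simulation or pipeline configuration violates its invariants."""


class EmptyRepertoireError(CloneKinError, ValueError):
    """A repertoire operation was asked to run on a sample with no templates."""


class DownsampleDepthError(CloneKinError, ValueError):
    """Requested subsample depth exceeds the number of sequenced templates."""


class InvalidMetaError(CloneKinError, ValueError):
    """Patient enumeration metadata (weight, blood volume, dose) is unusable."""


class InsufficientDataError(CloneKinError, ValueError):
    """Too few timepoints to classify a clone's kinetic pattern."""


class EmptyTimepointError(CloneKinError, ValueError):
    """A fate test requires clonotype-bearing cells at both timepoints."""


class CoordinateError(CloneKinError, ValueError):
    """A genomic locus falls outside the chromosome it claims to be on."""
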