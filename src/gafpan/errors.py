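"""Exception hierarchy shared by all gafpan modules.

Everything raised on bad user data derives from :class:`GafpanError` so the
CLI can map it to a single "data/format error" exit code.
"""


class GafpanError(Exception):
    """Base class for all errors raised on invalid input data or state."""


class FormatError(GafpanError):
    """A line or field does not conform to its file format (GFA/GAF/BED/GFF/VCF/TSV)."""


class GraphValidationError(GafpanError):
    """A structurally invalid graph: dangling references, duplicate IDs."""


class PathLookupError(GafpanError):
    """A referenced path, node, or contig does not exist."""


class ReferenceStateError(GafpanError):
    """An operation required a path flagged as reference, and it is not."""


class ConsistencyError(GafpanError):
    """Record and graph disagree (path lengths, offsets, unknown nodes)."""


class SortOrderError(GafpanError):
    """A file expected to be sorted by node interval is not."""


class IndexMissingError(GafpanError):
    """A query was attempted on a GAF file with no sidecar index."""
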