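"""IFN-stimulated neutrophil signature scoring, deconvolution and biomarker evaluation."""

from importlib import resources

from .core_io import (
    ExpressionMatrix,
    FormatError,
    GeneSet,
    SampleMetadata,
    filter_cells,
    normalize,
    read_expression,
    read_gmt,
    read_metadata,
    write_expression,
    write_gmt,
    write_metadata,
)

__version__ = "0.1.0"


def packaged_gmt(name: str):
    """Parse one of the packaged GMT fixtures (e.g. ``neut_ifn15``, ``ifng6``)."""
    with resources.as_file(resources.files("ifnsig.data") / f"{name}.gmt") as p:
        return read_gmt(p)


__all__ = [
    "ExpressionMatrix",
    "FormatError",
    "GeneSet",
    "SampleMetadata",
    "filter_cells",
    "normalize",
    "packaged_gmt",
    "read_expression",
    "read_gmt",
    "read_metadata",
    "write_expression",
    "write_gmt",
    "write_metadata",
]
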