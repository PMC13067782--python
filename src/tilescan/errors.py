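class TileScanError(Exception):
    """Base class for all tilescan errors."""


class InputError(TileScanError, ValueError):
    """Invalid argument or domain violation (bad coordinate, probability...)."""


class ParseError(TileScanError, ValueError):
    """Malformed input file (FASTA, TSV, config)."""
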