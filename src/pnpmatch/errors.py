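"""Exception hierarchy shared across the package."""


class PnpError(Exception):
    """Base class for all errors raised by pnpmatch."""


class StructureParseError(PnpError):
    """A compound structure (MOL V3000 or SMILES) could not be parsed."""


class SpectrumParseError(PnpError):
    """A spectrum file (MGF or mzXML) could not be parsed or selected from."""


class ParameterError(PnpError):
    """A run parameter is out of its valid range."""
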