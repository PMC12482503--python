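"""Typed errors shared across the package."""


class SynthPriceError(Exception):
    """Base class for all package errors."""


class InvalidStructureError(SynthPriceError):
    """A SMILES string could not be parsed into a molecule.

    Carries the offending string as ``.smiles``.
    """

    def __init__(self, smiles: str, reason: str = "unparsable SMILES"):
        self.smiles = smiles
        super().__init__(f"{reason}: {smiles!r}")


class UnitError(SynthPriceError):
    """A price carried a missing or unrecognized weight/amount unit."""


class EmptyDatasetError(SynthPriceError):
    """No records survived preprocessing."""


class ConfigError(SynthPriceError):
    """Invalid configuration (fractions, dimensions, unknown scheme...)."""


class DegenerateBatchError(SynthPriceError):
    """A batch contained only one of the two molecule classes."""


class NumericalError(SynthPriceError):
    """Non-finite values encountered during model evaluation or training."""
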