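"""Exception hierarchy for tgvscreen."""


class TgvScreenError(Exception):
    """Base class for all tgvscreen errors."""


class LibraryParseError(TgvScreenError):
    """Raised when a SMILES library file cannot be parsed.

    Collects every offending record so the user sees all problems at once.
    """

    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        super().__init__("; ".join(self.problems))


class FingerprintError(TgvScreenError):
    """Raised for degenerate or incompatible fingerprints."""


class ClusteringError(TgvScreenError):
    """Raised for infeasible embedding or clustering requests."""


class GeneSetError(TgvScreenError):
    """Raised for invalid gene-set operations (empty unions, bad universes)."""


class EnergyTableError(TgvScreenError):
    """Raised for malformed docking / MM-PBSA / hydrogen-bond inputs."""


class SyntheticSpecError(TgvScreenError):
    """Raised when a synthetic-fixture specification is infeasible."""
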