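"""Exception and warning types shared across the package."""


class ApopError(Exception):
    """Base class for all package-specific errors."""


class EmptyModelError(ApopError):
    """No Cα nodes survived parsing/filtering."""


class UnknownChainError(ApopError):
    """A requested chain id is absent from the structure."""


class PocketFormatError(ApopError):
    """A pocket definition (neutral file or Fpocket directory) is malformed."""


class SpectrumError(ApopError):
    """The Kirchhoff matrix has no usable vibrational modes."""


class NoScorablePocketsError(ApopError):
    """Every pocket resolved to fewer than two network nodes."""


class NoSignalError(ApopError):
    """Both the dynamics and hydrophobicity columns are constant."""


class ApopWarning(UserWarning):
    """Base class for package warnings."""


class DisconnectedNetworkWarning(ApopWarning):
    """Contact graph has more than one connected component."""

    def __init__(self, n_components: int):
        self.n_components = n_components
        super().__init__(
            f"contact network is disconnected ({n_components} components); "
            "all zero modes removed, proceeding on the retained spectrum"
        )


class PocketResolutionWarning(ApopWarning):
    """Pocket residues could not all be mapped onto structure nodes."""


class ModeCountWarning(ApopWarning):
    """Fewer retained modes than requested; counts were clamped."""


class DegenerateVarianceWarning(ApopWarning):
    """A z-score column had zero population variance and was set to zero."""
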