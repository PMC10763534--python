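"""Typed exceptions raised across the pipeline."""


class DfcGeneError(Exception):
    """Base class for all package errors."""


class ZeroVarianceRegionError(DfcGeneError):
    """A regional signal is constant, so Pearson correlation is undefined.

    Parameters
    ----------
    region_ids : sequence of int
        The offending region identifiers.
    """

    def __init__(self, region_ids, context=""):
        self.region_ids = tuple(int(r) for r in region_ids)
        msg = f"zero-variance signal in region(s) {list(self.region_ids)}"
        if context:
            msg += f" ({context})"
        super().__init__(msg)


class ShapeMismatchError(DfcGeneError):
    """Row/column counts do not match the expected region table or matrix."""


class NonNumericValueError(DfcGeneError):
    """A cell that should be numeric could not be parsed."""


class GridMismatchError(DfcGeneError):
    """4-D image and label volume do not share a spatial grid."""


class GeneMapError(DfcGeneError):
    """Gene expression map fails validation (missing regions, too few genes)."""


class NonPositiveSemidefiniteError(DfcGeneError):
    """A covariance matrix (possibly after perturbation) is not PSD."""

    def __init__(self, min_eigenvalue, context=""):
        self.min_eigenvalue = float(min_eigenvalue)
        msg = (
            f"covariance not positive semidefinite (min eigenvalue "
            f"{self.min_eigenvalue:.3e}); perturbation magnitude too large"
        )
        if context:
            msg += f" ({context})"
        super().__init__(msg)


class ZeroNormLoadingError(DfcGeneError):
    """The gene-map loading vector has zero norm."""


class AllZeroNetworkError(DfcGeneError):
    """Every link of a network is masked; centrality has no principal direction."""


class DegenerateSpectrumError(DfcGeneError):
    """Top two eigenvalues tie; eigenvector centrality is undefined.

    Carries the estimated spectral gap for diagnostics.
    """

    def __init__(self, gap):
        self.gap = float(gap)
        super().__init__(
            f"near-degenerate leading eigenvalues (estimated gap {self.gap:.3e}); "
            "eigenvector centrality undefined"
        )


class PowerIterationError(DfcGeneError):
    """Power iteration failed to converge within the iteration budget."""


class FingerprintMismatchError(DfcGeneError):
    """Region-order fingerprints differ between artifacts of one run."""


class ConfigError(DfcGeneError):
    """Invalid run configuration."""


class PipelineStageError(DfcGeneError):
    """A pipeline stage failed; wraps the original error with the stage name."""

    def __init__(self, stage, original):
        self.stage = stage
        self.original = original
        super().__init__(f"pipeline stage '{stage}' failed: {original}")
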