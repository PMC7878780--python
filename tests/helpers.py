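"""Shared helpers for the test suite."""

import numpy as np

from metsmarkov import IntensityParameters


def random_parameters(rng: np.random.Generator) -> IntensityParameters:
    """A random but epidemiologically plausible parameter draw."""
    return IntensityParameters(
        np.log(rng.uniform(1e-4, 1.0, 11)),
        rng.uniform(-0.05, 0.1, 8),
        rng.uniform(-1.0, 1.5, 8),
    )


def equal_cvd_truth(base: IntensityParameters, rate: float = 0.0474) -> IntensityParameters:
    """The reference truth with one common CVD incidence for all RMRC states."""
    d = base.to_dict()
    for k in ("fmd_cvd", "mmd_cvd", "mets_cvd"):
        d["lambda0"][k] = rate
    return IntensityParameters.from_dict(d)
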