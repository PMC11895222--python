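import numpy as np
import pytest

from riskwba import BinormalScoreModel, ParametricErrorModel, binormal_scores, sample_curves

# Published reference grid of the simulation study, keyed by (sigma, c_fn):
# (s_opt, er_opt, er_default, relative_difference) at 2 dp, thresholds on
# the 0.02 study grid.  Known cusp: at sigma=0.1, c=16 the grid ratio
# computes to 2.574996 (-> 2.57) while the published table prints 2.58,
# consistent with the continuum optimum (2.5753) instead; no single
# discretization reproduces both that cell and e.g. sigma=0.1, c=10
# (grid 1.983 -> printed 1.98; continuum 1.9858 -> 1.99).
REFERENCE_SWEEP = {
    (0.1, 1.0): (0.50, 0.08, 0.08, 1.00),
    (0.1, 2.0): (0.46, 0.11, 0.12, 1.07),
    (0.1, 4.0): (0.44, 0.16, 0.21, 1.30),
    (0.1, 8.0): (0.40, 0.21, 0.37, 1.77),
    (0.1, 10.0): (0.38, 0.23, 0.45, 1.98),
    (0.1, 16.0): (0.36, 0.27, 0.70, 2.58),
    (0.2, 1.0): (0.50, 0.29, 0.29, 1.00),
    (0.2, 2.0): (0.44, 0.40, 0.43, 1.08),
    (0.2, 4.0): (0.36, 0.52, 0.72, 1.38),
    (0.2, 8.0): (0.30, 0.65, 1.29, 1.97),
    (0.2, 10.0): (0.26, 0.70, 1.58, 2.26),
    (0.2, 16.0): (0.22, 0.78, 2.44, 3.12),
    (0.3, 1.0): (0.50, 0.43, 0.43, 1.00),
    (0.3, 2.0): (0.40, 0.59, 0.65, 1.10),
    (0.3, 4.0): (0.30, 0.75, 1.09, 1.44),
    (0.3, 8.0): (0.18, 0.89, 1.96, 2.20),
    (0.3, 10.0): (0.16, 0.92, 2.39, 2.59),
    (0.3, 16.0): (0.08, 0.98, 3.69, 3.78),
    (0.4, 1.0): (0.50, 0.54, 0.54, 1.00),
    (0.4, 2.0): (0.36, 0.72, 0.80, 1.11),
    (0.4, 4.0): (0.22, 0.88, 1.34, 1.51),
    (0.4, 8.0): (0.08, 0.98, 2.41, 2.45),
    (0.4, 10.0): (0.04, 1.00, 2.94, 2.96),
    (0.4, 16.0): (0.00, 1.00, 4.55, 4.55),
}


@pytest.fixture(scope="session")
def symmetric_model():
    """Mirror-symmetric error model used throughout the simulation study."""
    return ParametricErrorModel(sigma_fp=0.3, sigma_fn=0.3)


@pytest.fixture(scope="session")
def symmetric_curves(symmetric_model):
    return sample_curves(symmetric_model, n_grid=10001)


@pytest.fixture(scope="session")
def binormal_sample():
    """Moderate-quality classifier scores (analytic AUROC ~ 0.76)."""
    model = BinormalScoreModel(n_pos=5000, n_neg=5000, seed=42)
    scores, labels = binormal_scores(model)
    return model, scores, labels
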