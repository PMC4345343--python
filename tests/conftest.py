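import numpy as np
import pytest

import chemomodes as cm
from chemomodes.ensemble_modes import align_basis


@pytest.fixture(scope="session")
def default_spec():
    return cm.SyntheticSpec()


@pytest.fixture(scope="session")
def template(default_spec):
    return cm.make_template(default_spec)


@pytest.fixture(scope="session")
def truth(template, default_spec):
    return cm.planted_modes(template, default_spec)


@pytest.fixture(scope="session")
def planted_basis(template, truth):
    """ModeBasis whose modes are the planted ground-truth vectors at the template."""
    return cm.ModeBasis(
        mean=template.coords,
        eigenvalues=np.array([0.04, 0.01]),
        eigenvectors=truth.mode_vectors,
        kind="pca",
        labels=list(template.labels),
    )


@pytest.fixture(scope="session")
def recovery_run():
    """Planted two-mode ensemble at the standard recovery conditions.

    Variances 0.04/0.01 nm^2, amplitude correlation 0.6, site noise
    0.01 nm, M = 5000, random rigid poses; returns the sampled ensemble,
    its ground truth, and the PCA basis aligned to the template frame.
    """
    spec = cm.SyntheticSpec(seed=1)
    ensemble, truth = cm.make_ensemble(spec)
    basis, fitted = cm.pca_from_ensemble(ensemble)
    basis = align_basis(basis, truth.template.xyz)
    return {"spec": spec, "ensemble": ensemble, "truth": truth,
            "basis": basis, "fitted": fitted}


@pytest.fixture(scope="session")
def two_basin_run():
    """Fixed-seed two-basin ensemble projected onto the planted mode basis."""
    ensemble, truth = cm.two_basin_fixture()
    basis = cm.ModeBasis(mean=truth.template.coords, eigenvalues=np.ones(2),
                         eigenvectors=truth.mode_vectors, kind="pca",
                         labels=list(ensemble.labels))
    points = cm.project(ensemble, basis, k=2).values
    return {"ensemble": ensemble, "truth": truth, "points": points}
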