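import numpy as np
import pytest
from hypothesis import settings as hypothesis_settings

hypothesis_settings.register_profile("deterministic", derandomize=True,
                                     deadline=None)
hypothesis_settings.load_profile("deterministic")

from nlcopt import datasets  # noqa: E402
from nlcopt.doe import DesignSpec, Factor, build_ccd
from nlcopt.surface import fit_surface


@pytest.fixture(scope="session")
def study():
    """The packaged 13-run CCD study: (design, responses)."""
    return datasets.ccd_study()


@pytest.fixture(scope="session")
def factors():
    return datasets.study_factors()


@pytest.fixture(scope="session")
def paper_models(study):
    """The three published model classes refit to the packaged study data:
    pure-quadratic particle size, full second-order PdI, linear-in-surfactant
    zeta potential."""
    design, responses = study
    return {
        "particle_size": fit_surface(design, responses, "particle_size", "PQ"),
        "pdi": fit_surface(design, responses, "pdi", "SO"),
        "zeta_potential": fit_surface(design, responses, "zeta_potential", "FO",
                                      factor_idx=[1]),
    }


@pytest.fixture()
def k2_design(factors):
    return build_ccd(DesignSpec(factors, n_center=5, alpha="rotatable"))


def random_design(rng: np.random.Generator, k: int = 2, n_center: int = 3):
    """A random CCD with random centers/steps, for property tests."""
    facs = tuple(
        Factor(f"f{i}", "u",
               center=float(rng.uniform(-50, 50)),
               step=float(rng.uniform(0.5, 20)))
        for i in range(k))
    return build_ccd(DesignSpec(facs, n_center=n_center, alpha="rotatable"))
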