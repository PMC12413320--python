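import numpy as np
import pytest

from revlearn.hier import GroupPrior, PosteriorDraws, SamplerConfig
from revlearn.models import get_model


def make_synthetic_draws(
    model: str,
    n_subjects: int,
    mu: np.ndarray,
    sigma: np.ndarray,
    n_draws: int = 500,
    n_chains: int = 2,
    jitter: float = 0.0,
    seed: int = 0,
    beta_upper: float = 10.0,
) -> PosteriorDraws:
    """A PosteriorDraws whose draws sit at known group values.

    ``mu``/``sigma`` are (6, P) on the unconstrained scale; subject
    deviations are zero; ``jitter`` adds Gaussian noise so that density
    estimates are well defined.
    """
    spec = get_model(model)
    P = spec.n_params
    assert mu.shape == (6, P) and sigma.shape == (6, P)
    rng = np.random.default_rng(seed)
    dim = 2 * 6 * P + n_subjects * 6 * P
    base = np.concatenate(
        [mu.ravel(), np.log(sigma).ravel(), np.zeros(n_subjects * 6 * P)]
    )
    samples = base[None, None, :] + jitter * rng.standard_normal(
        (n_chains, n_draws, dim)
    )
    subjects = [f"s{i + 1:03d}" for i in range(n_subjects)]
    from revlearn import design as dz

    names = (
        [f"mu[{c},{p}]" for c in dz.COLUMNS for p in spec.params]
        + [f"sigma[{c},{p}]" for c in dz.COLUMNS for p in spec.params]
        + [
            f"z[{s},{c},{p}]"
            for s in subjects
            for c in dz.COLUMNS
            for p in spec.params
        ]
    )
    return PosteriorDraws(
        samples=samples,
        names=names,
        model=spec.name,
        subjects=subjects,
        prior=GroupPrior(beta_upper=beta_upper),
        sampler=SamplerConfig(chains=n_chains, warmup=0, draws=n_draws),
        seed=seed,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Eight-subject fictitious-update cohort under the default study conditions."""
    from revlearn.task import default_cohort_spec, generate_cohort

    return generate_cohort(default_cohort_spec(n_subjects=8, seed=3))
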