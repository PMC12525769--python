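import numpy as np
import pytest

from pbsq.globalfit import FitSpec, GlobalDecayModel
from pbsq.kinetics import IRFModel
from pbsq.synth import make_tres_preset


@pytest.fixture(scope="session")
def unquenched_noisy_fit():
    """Seeded unquenched preset (peak 10^4 counts) and its 3-component fit.

    Session-scoped: the same fit backs the lifetime-recovery unit tests
    and the acceptance checks.
    """
    data = make_tres_preset("gvipbs_unquenched", seed=1, peak_counts=10000)
    spec = FitSpec(
        n_components=3,
        initial_lifetimes_ns=(0.05, 0.3, 2.5),
        irf=IRFModel(fwhm_ps=100.0, t0_ns=0.5),
        seed=1,
    )
    return data, GlobalDecayModel(data, spec).fit()


def _fit_noiseless(name: str):
    """Fit a noiseless preset with as many components as its generating
    mixture has distinct lifetimes (read from the preset metadata)."""
    data = make_tres_preset(name, seed=1, peak_counts=None)
    taus = sorted({t for pool in data.metadata["pool_lifetimes_ns"] for t in pool})
    spec = FitSpec(
        n_components=len(taus),
        initial_lifetimes_ns=tuple(taus),
        irf=IRFModel(fwhm_ps=100.0, t0_ns=0.5),
        n_starts=1,
        seed=1,
    )
    return GlobalDecayModel(data, spec).fit()


@pytest.fixture(scope="session")
def noiseless_quench_fits():
    """Noiseless fits of all four quenching presets, keyed by condition."""
    return {
        "unquenched": _fit_noiseless("gvipbs_unquenched"),
        "alpha": _fit_noiseless("gvipbs_alpha_quenched"),
        "beta": _fit_noiseless("gvipbs_beta_quenched"),
        "dual": _fit_noiseless("gvipbs_dual_quenched"),
    }
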