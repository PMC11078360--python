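import numpy as np
import pandas as pd
import pytest

import panelprev as pp


@pytest.fixture
def profile():
    """The packaged operating point: sens 80%, spec 99.75%."""
    return pp.ComponentProfile("c1", 0.80, 0.9975)


@pytest.fixture
def uniform_panel():
    """20 identical components scaled to 10% panel prevalence."""
    weights = np.full(20, 1.0 / 20)
    prev = pp.scale_distribution(weights, 0.10)
    profiles = [pp.ComponentProfile(c, 0.80, 0.9975) for c in prev.component_ids]
    return prev, profiles


@pytest.fixture
def ipd_panel():
    """The packaged serotype-like skewed panel at 10% prevalence."""
    weights = pp.default_ipd_like_weights()
    prev = pp.scale_distribution(weights, 0.10)
    profiles = [pp.ComponentProfile(c, 0.80, 0.9975) for c in prev.component_ids]
    return prev, profiles


def make_controls(component_ids, n_pos=100, k_pos=80, n_neg=800, k_neg=798):
    """Control counts whose raw proportions sit exactly at the packaged
    operating point (80/100 = 0.80, 798/800 = 0.9975)."""
    return pp.ControlData(
        pd.DataFrame(
            {"n_pos": n_pos, "k_pos": k_pos, "n_neg": n_neg, "k_neg": k_neg},
            index=pd.Index(list(component_ids), name="component_id"),
        )
    )


def truth_centred_priors(component_ids, sens=0.80, spec=0.9975,
                         sens_ess=100.0, spec_ess=800.0):
    """Beta priors with means exactly at the simulation truth."""
    return pp.PerformancePrior(
        sens={c: pp.BetaPrior(a=sens * sens_ess, b=(1 - sens) * sens_ess)
              for c in component_ids},
        spec={c: pp.BetaPrior(a=spec * spec_ess, b=(1 - spec) * spec_ess)
              for c in component_ids},
    )
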