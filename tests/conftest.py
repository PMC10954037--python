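"""Shared fixtures and independent oracles for the test suite."""
from __future__ import annotations

import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hetsilence.config import PipelineConfig
from hetsilence.survival import (
    DELTA_BOUNDS,
    UPSILON_BOUNDS,
    ConvergenceWarning,
    SamplerConfig,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

# silence expected sampler-convergence chatter from deliberately light fits
warnings.filterwarnings("ignore", category=ConvergenceWarning)

#: light sampler for tests that need a posterior but not Rhat <= 1.01
LIGHT_SAMPLER = SamplerConfig(n_walkers=24, n_steps=800, n_burn=400, seed=7)


def grid_posterior_delta(observations, n_upsilon=1501, n_delta=2001, span=2.0):
    """Deterministic 2-D grid-integration oracle for the survival model.

    Brute-force numerical posterior over (upsilon_1..R, delta) with the
    uniform priors; replicates are integrated out one at a time (they are
    conditionally independent given delta).  Returns (mean, (lo95, hi95))
    for delta.  Independent of the MCMC code path: likelihood written out
    directly from the Poisson pmf.
    """
    from scipy.special import gammaln

    reps = sorted({o.replicate_id for o in observations})
    # centre grids on crude estimates to keep the grid fine but bounded
    crude_u = {}
    for r in reps:
        us = [
            np.log10(max(o.count, 0.5)) - o.phi
            for o in observations
            if o.replicate_id == r and o.arm == "untreated"
        ]
        crude_u[r] = float(np.mean(us))
    crude_d = float(
        np.mean(
            [
                np.log10(max(o.count, 0.5)) - o.phi - crude_u[o.replicate_id]
                for o in observations
                if o.arm == "treated"
            ]
        )
    )
    d_lo = max(DELTA_BOUNDS[0], crude_d - span)
    d_hi = min(DELTA_BOUNDS[1], crude_d + span)
    delta = np.linspace(d_lo, d_hi, n_delta)
    log_post_delta = np.zeros_like(delta)
    for r in reps:
        u_lo = max(UPSILON_BOUNDS[0], crude_u[r] - span)
        u_hi = min(UPSILON_BOUNDS[1], crude_u[r] + span)
        ups = np.linspace(u_lo, u_hi, n_upsilon)
        ll = np.zeros((n_upsilon, n_delta))
        for o in observations:
            if o.replicate_id != r:
                continue
            shift = delta[None, :] if o.arm == "treated" else 0.0
            expo = ups[:, None] + shift + o.phi
            lam = 10.0**expo
            ll += o.count * np.log(lam) - lam - gammaln(o.count + 1)
        # integrate upsilon_r out (flat prior; constant grid spacing)
        m = ll.max(axis=0)
        log_post_delta += m + np.log(np.exp(ll - m[None, :]).sum(axis=0))
    log_post_delta -= log_post_delta.max()
    w = np.exp(log_post_delta)
    w /= w.sum()
    mean = float(np.sum(w * delta))
    cdf = np.cumsum(w)
    lo = float(np.interp(0.025, cdf, delta))
    hi = float(np.interp(0.975, cdf, delta))
    return mean, (lo, hi)


@pytest.fixture(scope="session")
def default_config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def study(default_config):
    """Default-condition genome plus processed occupancy and peak results.

    Session-scoped: several tests interrogate the same synthetic study.
    """
    from hetsilence import synthetic
    from hetsilence.pipeline import occupancy_stage, peak_stage

    genome = synthetic.generate_genome(default_config.genome)
    occ = occupancy_stage(genome, default_config)
    called, classified, by_class, enrich = peak_stage(genome, occ, default_config)
    return {
        "config": default_config,
        "genome": genome,
        "occ": occ,
        "called": called,
        "classified": classified,
        "by_class": by_class,
        "enrichment": enrich,
    }


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20211222)
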