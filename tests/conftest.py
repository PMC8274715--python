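"""Shared fixtures: handmade micro-cohorts and simulated cohorts.

All data is generated programmatically; simulated cohorts are cached per
session because the recovery-scale ones take a second or two to build.
"""

from __future__ import annotations

import numpy as np
import pytest

from meioco import Cohort, Nucleus, SCObservation, build_cohorts


def make_sc(nucleus_id="n1", chromosome_id=1, length=10.0, positions=()):
    return SCObservation(nucleus_id, chromosome_id, length, tuple(positions))


def make_cohort(genotype, sc_specs):
    """Build a cohort from (nucleus_id, chromosome_id, length, positions) tuples."""
    return build_cohorts(
        (genotype, SCObservation(nid, cid, length, tuple(pos)))
        for nid, cid, length, pos in sc_specs
    )[genotype]


@pytest.fixture
def tiny_cohort():
    """Two complete nuclei with simple, hand-checkable focus maps."""
    specs = []
    for n, offset in (("n1", 0.0), ("n2", 0.5)):
        for c in range(1, 8):
            length = 12.0 - c
            specs.append((n, c, length, (1.0 + offset, length / 2, length - 1.0)))
    return make_cohort("toy", specs)


@pytest.fixture(scope="session")
def wt_cohort():
    """Wild-type preset cohort, default nucleus count, length noise on."""
    from meioco import preset_params, simulate_cohort
    return simulate_cohort(preset_params("wt", seed=11), genotype="wt")


@pytest.fixture(scope="session")
def poisson_cohort():
    """No-interference control scaled to ~2,000 SCs."""
    from meioco import preset_params, simulate_cohort
    params = preset_params("poisson-null", seed=7, n_nuclei=286)  # 2002 SCs
    return simulate_cohort(params, genotype="poisson")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
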