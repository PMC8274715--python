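"""Stationary gamma-renewal simulator of crossover placement along SCs.

Crossover interference produces inter-crossover distances that are well
described by a gamma distribution with shape ν ≥ 1: ν = 1 recovers a Poisson
process (no interference), larger ν gives increasingly even spacing. The
simulator places events on an SC of length L as a renewal process with
i.i.d. gamma(ν, θ) gaps, θ = μ/ν so that μ is the mean inter-event distance.

To make event density independent of position — foci show no preference for
either telomere — the process is started in equilibrium: the distance from
the origin to the first event is drawn from the forward-recurrence density

    g(x) = (1 − F(x)) / μ,

where F is the gamma(ν, θ) CDF. Subsequent gaps are plain gamma draws, and
events beyond L are discarded. Under this stationary construction the
expected number of events on an SC is exactly L/μ.

The obligate crossover (every bivalent receives ≥ 1 event, as required for
proper segregation) is enforced, when requested, by rejection: an SC that
ends up empty is resampled wholesale.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np
from scipy import special

from .errors import SimulationError, ValidationError
from .model import N_CHROMOSOMES, Cohort, Nucleus, SCObservation

logger = logging.getLogger(__name__)

#: Whole-SC resamples allowed per SC under obligate enforcement before the
#: simulator gives up and advises a parameter change.
REJECTION_CAP = 10_000

#: Chromosome-length floor, as a fraction of the per-chromosome mean, applied
#: when sampling lengths with noise (avoids nonpositive lengths without
#: distorting the bulk of the distribution).
LENGTH_FLOOR_FRACTION = 0.20


@dataclass(frozen=True)
class SimParams:
    """Generative model for one synthetic cohort.

    Parameters
    ----------
    nu
        Gamma shape ν ≥ 1 controlling spacing evenness (1 = Poisson).
    mean_gap_um
        Mean inter-crossover distance μ in μm; gamma scale is θ = μ/ν.
    chrom_length_means_um
        Mean SC length of each of the 7 chromosomes, μm.
    chrom_length_sd_um
        SD of per-chromosome length noise (0 = fixed lengths).
    obligate
        Enforce ≥ 1 event per SC by rejection.
    n_nuclei
        Number of nuclei to generate.
    seed
        Root RNG seed; nuclei use spawned child streams so cohorts are
        reproducible regardless of generation order.
    """

    nu: float
    mean_gap_um: float
    chrom_length_means_um: tuple[float, ...]
    chrom_length_sd_um: float = 0.0
    obligate: bool = True
    n_nuclei: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.nu >= 1:
            raise ValidationError(f"gamma shape nu must be >= 1, got {self.nu}")
        if not self.mean_gap_um > 0:
            raise ValidationError(f"mean_gap_um must be positive, got {self.mean_gap_um}")
        lengths = tuple(float(x) for x in self.chrom_length_means_um)
        if len(lengths) != N_CHROMOSOMES or any(x <= 0 for x in lengths):
            raise ValidationError(
                f"chrom_length_means_um must be {N_CHROMOSOMES} positive reals, got {lengths}")
        object.__setattr__(self, "chrom_length_means_um", lengths)
        if self.chrom_length_sd_um < 0:
            raise ValidationError("chrom_length_sd_um must be nonnegative")
        if self.n_nuclei < 1:
            raise ValidationError("n_nuclei must be positive")

    @property
    def theta(self) -> float:
        """Gamma scale θ = μ/ν."""
        return self.mean_gap_um / self.nu

    def with_(self, **changes) -> "SimParams":
        return replace(self, **changes)


def _equilibrium_cdf_std(z: np.ndarray, nu: float) -> np.ndarray:
    """Equilibrium (forward-recurrence) CDF of gamma(ν, 1) gaps.

    Closed form via integration by parts:
        G(z) = z (1 − F_ν(z)) / ν + F_{ν+1}(z),
    with F_a the gamma(a, 1) CDF (regularized lower incomplete gamma).
    """
    z = np.asarray(z, dtype=float)
    return z * special.gammaincc(nu, z) / nu + special.gammainc(nu + 1.0, z)


@lru_cache(maxsize=32)
def _equilibrium_inverse_grid(nu: float) -> tuple[np.ndarray, np.ndarray]:
    """Cached (G, z) grid for inverting the standardized equilibrium CDF.

    The grid is in units of θ, so one cache entry serves every scale; this
    also makes the sampler exactly scale-equivariant.
    """
    z_hi = float(special.gammainccinv(nu + 1.0, 1e-14))  # far tail of the z f(z) part
    z = np.concatenate([[0.0], np.geomspace(1e-6 * z_hi, z_hi, 4095)])
    g = _equilibrium_cdf_std(z, nu)
    # Guard monotonicity against floating-point plateaus in the far tail.
    keep = np.concatenate([[True], np.diff(g) > 0])
    return g[keep], z[keep]


def equilibrium_first_gap(nu: float, theta: float, rng: np.random.Generator,
                          size: int | None = None) -> float | np.ndarray:
    """Sample the distance to the first event of a stationary renewal process.

    Draws from the density (1 − F(x))/μ with F the gamma(ν, θ) CDF, by
    numerical inversion of the closed-form equilibrium CDF on a cached grid.
    The mean of this distribution is μ(ν + 1)/(2ν).
    """
    if not (nu >= 1 and theta > 0):
        raise ValidationError(f"need nu >= 1 and theta > 0, got nu={nu}, theta={theta}")
    g_grid, z_grid = _equilibrium_inverse_grid(float(nu))
    u = rng.random(size)
    return np.interp(u, g_grid, z_grid) * theta


def simulate_sc(length_um: float, params: SimParams, rng: np.random.Generator,
                *, nucleus_id: str = "sim", chromosome_id: int = 1) -> SCObservation:
    """Place crossover events on one SC of the given length.

    First event at an equilibrium forward-recurrence distance, then i.i.d.
    gamma(ν, θ) gaps; events beyond the SC end are discarded. With
    ``params.obligate`` an empty SC is rejected and resampled (up to
    :data:`REJECTION_CAP` times; the rejection count is logged at DEBUG).
    """
    nu, theta, mu = params.nu, params.theta, params.mean_gap_um
    rejections = 0
    while True:
        positions = []
        x = float(equilibrium_first_gap(nu, theta, rng))
        while x <= length_um:
            positions.append(x)
            x += rng.standard_gamma(nu) * theta
        if positions or not params.obligate:
            break
        rejections += 1
        if rejections >= REJECTION_CAP:
            raise SimulationError(
                f"obligate-CO rejection cap ({REJECTION_CAP}) exceeded on an SC of "
                f"length {length_um:.3g} μm with expected count {length_um / mu:.3g}; "
                f"increase SC length or decrease mean_gap_um")
    if rejections:
        logger.debug("obligate resampling: %d rejection(s) on SC %s/%s",
                     rejections, nucleus_id, chromosome_id)
    return SCObservation(nucleus_id, chromosome_id, float(length_um), tuple(positions))


def _sample_length(mean: float, sd: float, rng: np.random.Generator) -> float:
    if sd == 0:
        return mean
    # Clip (rather than resample) at the floor: for any plausible sd/mean the
    # clip is hit rarely and perturbs the mean far less than one-sided
    # resampling would, keeping the length model unbiased in the bulk.
    floor = LENGTH_FLOOR_FRACTION * mean
    return float(max(rng.normal(mean, sd), floor))


def simulate_nucleus(params: SimParams, genotype: str, nucleus_id: str,
                     rng: np.random.Generator) -> Nucleus:
    scs = []
    for c in range(N_CHROMOSOMES):
        length = _sample_length(params.chrom_length_means_um[c], params.chrom_length_sd_um, rng)
        scs.append(simulate_sc(length, params, rng,
                               nucleus_id=nucleus_id, chromosome_id=c + 1))
    return Nucleus(nucleus_id, genotype, tuple(scs))


def simulate_cohort(params: SimParams, genotype: str = "sim") -> Cohort:
    """Generate a full cohort of ``params.n_nuclei`` nuclei × 7 SCs.

    Each nucleus draws from its own child stream spawned from the root seed,
    so the cohort is bit-reproducible and insensitive to generation order.
    """
    root = np.random.SeedSequence(params.seed)
    children = root.spawn(params.n_nuclei)
    nuclei = tuple(
        simulate_nucleus(params, genotype, f"{genotype}_n{i + 1}",
                         np.random.Generator(np.random.PCG64(children[i])))
        for i in range(params.n_nuclei)
    )
    return Cohort(genotype, nuclei)
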