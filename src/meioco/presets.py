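"""Cohort presets emulating published pachytene focus-map summaries.

Each preset encodes, for one genotype, the printed cohort-level statistics:
mean ± SD of total SC length per nucleus, mean Hei10-focus count per
nucleus, the fitted gamma shape ν, and the reported nucleus count. From
these the generative parameters follow:

* per-chromosome mean lengths split the total mean in fixed proportions
  (1.30, 1.17, 1.00, 0.95, 0.90, 0.85, 0.83 of the per-chromosome average —
  a package convention; the source data only establish that the seven
  chromosomes are distinguishable by length, so any decreasing sequence of
  this spread would serve);
* the per-chromosome length SD is total SD / √7, so that independent
  per-chromosome noise reproduces the printed per-nucleus total SD;
* the mean inter-crossover gap is μ = (mean total SC length)/(mean focus
  count), which under the stationary renewal model gives the printed mean
  focus count per nucleus.

All genotype presets enforce the obligate crossover, as observed in every
scored bivalent of these cohorts. The ``poisson-null`` preset (ν = 1,
obligate off) is the no-interference control.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import ConfigurationError
from .model import N_CHROMOSOMES
from .simulate import SimParams

#: Relative chromosome lengths (chromosome 1 longest), summing to 7.
CHROM_LENGTH_PROPORTIONS = (1.30, 1.17, 1.00, 0.95, 0.90, 0.85, 0.83)


@dataclass(frozen=True)
class CohortPreset:
    """Printed summary statistics for one genotype's cohort."""

    name: str
    nu: float                 # fitted gamma shape
    sc_total_mean_um: float   # mean total SC length per nucleus
    sc_total_sd_um: float     # SD of total SC length per nucleus
    foci_mean: float          # mean focus count per nucleus
    foci_sd: float            # SD of focus count per nucleus
    n_nuclei: int             # nuclei scored for focus counts
    obligate: bool = True

    @property
    def mean_gap_um(self) -> float:
        return self.sc_total_mean_um / self.foci_mean

    def chrom_length_means(self) -> tuple[float, ...]:
        per_chrom = self.sc_total_mean_um / N_CHROMOSOMES
        return tuple(p * per_chrom for p in CHROM_LENGTH_PROPORTIONS)

    @property
    def chrom_length_sd_um(self) -> float:
        return self.sc_total_sd_um / math.sqrt(N_CHROMOSOMES)


PRESETS: dict[str, CohortPreset] = {
    "wt": CohortPreset("wt", nu=5.03, sc_total_mean_um=52.9, sc_total_sd_um=4.5,
                       foci_mean=22.6, foci_sd=2.3, n_nuclei=98),
    "dcl1": CohortPreset("dcl1", nu=2.40, sc_total_mean_um=75.2, sc_total_sd_um=9.0,
                         foci_mean=31.5, foci_sd=3.1, n_nuclei=29),
    "dcl2": CohortPreset("dcl2", nu=4.01, sc_total_mean_um=56.1, sc_total_sd_um=4.6,
                         foci_mean=24.9, foci_sd=2.2, n_nuclei=21),
    "qde2": CohortPreset("qde2", nu=4.28, sc_total_mean_um=58.1, sc_total_sd_um=4.7,
                         foci_mean=25.1, foci_sd=2.9, n_nuclei=31),
    # No-interference control: wild-type geometry, Poisson placement, no
    # obligate enforcement.
    "poisson-null": CohortPreset("poisson-null", nu=1.0, sc_total_mean_um=52.9,
                                 sc_total_sd_um=4.5, foci_mean=22.6, foci_sd=4.8,
                                 n_nuclei=98, obligate=False),
}


def preset_params(name: str, seed: int = 0, *, n_nuclei: int | None = None,
                  fixed_lengths: bool = False, **overrides) -> SimParams:
    """Build :class:`SimParams` for a named preset.

    ``fixed_lengths`` zeroes the chromosome-length noise (used by the gamma
    shape recovery experiments, where pooling gaps across variable lengths
    is irrelevant because the shape is scale-free per SC). Any SimParams
    field may be overridden by keyword.
    """
    try:
        preset = PRESETS[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}") from None
    params = SimParams(
        nu=preset.nu,
        mean_gap_um=preset.mean_gap_um,
        chrom_length_means_um=preset.chrom_length_means(),
        chrom_length_sd_um=0.0 if fixed_lengths else preset.chrom_length_sd_um,
        obligate=preset.obligate,
        n_nuclei=preset.n_nuclei if n_nuclei is None else int(n_nuclei),
        seed=seed,
    )
    return params.with_(**overrides) if overrides else params
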