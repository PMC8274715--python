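"""Domain types for cytological crossover focus maps.

The atomic unit is one synapsed bivalent (synaptonemal complex, SC) of one
pachytene nucleus: its length in micrometers and the ordered arc-length
positions of its crossover-fated foci (e.g. Hei10 foci) measured from one
telomere. Orientation along the SC is arbitrary — no analysis in this
package may depend on which telomere is the origin, and the test suite
asserts orientation invariance explicitly.

A nucleus holds up to seven SCs (one per bivalent of a seven-chromosome
complement); a cohort holds all nuclei of one genotype together with the
mapping of chromosome ids onto the two length classes used when pooling
interference statistics (chromosomes 1-2 are "long", 3-7 "short").
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

from .errors import ValidationError

#: Number of bivalents in a complete pachytene nucleus.
N_CHROMOSOMES = 7

LONG = "long"
SHORT = "short"
ALL = "all"

#: Default chromosome-length classes: the two longest chromosomes versus the
#: five shorter ones.
DEFAULT_CLASS_MAP: Mapping[int, str] = {1: LONG, 2: LONG, 3: SHORT, 4: SHORT,
                                        5: SHORT, 6: SHORT, 7: SHORT}


@dataclass(frozen=True)
class SCObservation:
    """One SC trace: length and ordered focus positions, both in μm.

    Parameters
    ----------
    nucleus_id
        Opaque identifier of the nucleus the SC belongs to.
    chromosome_id
        Integer in 1..7.
    sc_length_um
        Total SC length, strictly positive.
    focus_positions_um
        Strictly increasing arc-length coordinates in ``[0, sc_length_um]``.
        May be empty (a bivalent may carry no focus in mutants or under a
        no-interference null without obligate-crossover enforcement).
        Coincident positions are rejected: each focus center is traced
        individually, so duplicates indicate a digitization error.
    """

    nucleus_id: str
    chromosome_id: int
    sc_length_um: float
    focus_positions_um: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if not (1 <= int(self.chromosome_id) <= N_CHROMOSOMES):
            raise ValidationError(
                f"chromosome_id must be 1..{N_CHROMOSOMES}, got {self.chromosome_id}")
        if not (self.sc_length_um > 0) or not math.isfinite(self.sc_length_um):
            raise ValidationError(f"sc_length_um must be positive, got {self.sc_length_um}")
        pos = tuple(float(p) for p in self.focus_positions_um)
        object.__setattr__(self, "focus_positions_um", pos)
        for p in pos:
            if not math.isfinite(p) or p < 0 or p > self.sc_length_um:
                raise ValidationError(
                    f"focus position {p} outside [0, {self.sc_length_um}] "
                    f"(nucleus {self.nucleus_id}, chromosome {self.chromosome_id})")
        for a, b in zip(pos, pos[1:]):
            if b <= a:
                raise ValidationError(
                    f"focus positions must be strictly increasing, got {a} then {b} "
                    f"(nucleus {self.nucleus_id}, chromosome {self.chromosome_id})")

    @property
    def n_foci(self) -> int:
        return len(self.focus_positions_um)

    def reversed(self) -> "SCObservation":
        """The same SC measured from the opposite telomere."""
        rev = tuple(sorted(self.sc_length_um - p for p in self.focus_positions_um))
        return SCObservation(self.nucleus_id, self.chromosome_id, self.sc_length_um, rev)


@dataclass(frozen=True)
class Nucleus:
    """All SCs of one pachytene nucleus."""

    nucleus_id: str
    genotype: str
    scs: tuple[SCObservation, ...]

    def __post_init__(self) -> None:
        ids = [sc.chromosome_id for sc in self.scs]
        if len(set(ids)) != len(ids):
            raise ValidationError(
                f"duplicate chromosome_id within nucleus {self.nucleus_id}: {sorted(ids)}")
        if not (1 <= len(self.scs) <= N_CHROMOSOMES):
            raise ValidationError(
                f"nucleus {self.nucleus_id} has {len(self.scs)} SCs; expected 1..{N_CHROMOSOMES}")
        for sc in self.scs:
            if sc.nucleus_id != self.nucleus_id:
                raise ValidationError(
                    f"SC nucleus_id {sc.nucleus_id!r} does not match nucleus {self.nucleus_id!r}")

    @property
    def is_complete(self) -> bool:
        """True when all seven bivalents were traced.

        Per-nucleus totals (focus count, total SC length) are only meaningful
        on complete nuclei; partial nuclei still contribute to per-SC
        statistics such as CoC and inter-focus gaps.
        """
        return len(self.scs) == N_CHROMOSOMES

    @property
    def total_sc_length_um(self) -> float:
        return sum(sc.sc_length_um for sc in self.scs)

    @property
    def focus_count(self) -> int:
        return sum(sc.n_foci for sc in self.scs)


@dataclass(frozen=True)
class Cohort:
    """All nuclei of one genotype plus the chromosome length-class map."""

    genotype: str
    nuclei: tuple[Nucleus, ...]
    chromosome_class_map: Mapping[int, str] = field(default_factory=lambda: dict(DEFAULT_CLASS_MAP))

    def __post_init__(self) -> None:
        for nuc in self.nuclei:
            if nuc.genotype != self.genotype:
                raise ValidationError(
                    f"nucleus {nuc.nucleus_id} genotype {nuc.genotype!r} "
                    f"does not match cohort {self.genotype!r}")
        for cid, cls in self.chromosome_class_map.items():
            if cls not in (LONG, SHORT):
                raise ValidationError(f"chromosome class must be long/short, got {cls!r} for {cid}")

    @property
    def n_nuclei(self) -> int:
        return len(self.nuclei)

    def iter_scs(self, chrom_class: str = ALL) -> Iterator[SCObservation]:
        """Iterate SCs, optionally restricted to one length class."""
        for nuc in self.nuclei:
            for sc in nuc.scs:
                if chrom_class == ALL or self.chromosome_class_map.get(sc.chromosome_id) == chrom_class:
                    yield sc

    def scs(self, chrom_class: str = ALL) -> list[SCObservation]:
        return list(self.iter_scs(chrom_class))

    def complete_nuclei(self) -> list[Nucleus]:
        return [n for n in self.nuclei if n.is_complete]

    def reversed(self) -> "Cohort":
        """Every SC re-measured from the opposite telomere (for invariance checks)."""
        return Cohort(
            self.genotype,
            tuple(Nucleus(n.nucleus_id, n.genotype, tuple(sc.reversed() for sc in n.scs))
                  for n in self.nuclei),
            dict(self.chromosome_class_map),
        )


def build_cohorts(scs: Iterable[tuple[str, SCObservation]],
                  class_map: Mapping[int, str] | None = None) -> dict[str, Cohort]:
    """Group ``(genotype, SCObservation)`` pairs into one Cohort per genotype.

    Nucleus and genotype order follow first appearance, so cohort assembly is
    deterministic for a fixed input sequence.
    """
    class_map = dict(DEFAULT_CLASS_MAP) if class_map is None else dict(class_map)
    per_geno: dict[str, dict[str, list[SCObservation]]] = {}
    for genotype, sc in scs:
        per_geno.setdefault(genotype, {}).setdefault(sc.nucleus_id, []).append(sc)
    cohorts: dict[str, Cohort] = {}
    for genotype, nuclei in per_geno.items():
        built = tuple(
            Nucleus(nid, genotype, tuple(sorted(lst, key=lambda s: s.chromosome_id)))
            for nid, lst in nuclei.items()
        )
        cohorts[genotype] = Cohort(genotype, built, class_map)
    return cohorts
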