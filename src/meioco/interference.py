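"""Crossover-interference analyses: CoC curves and gamma-shape fitting.

Two complementary measures of interference are computed from the same focus
maps:

**Coefficient of coincidence (CoC).** Each SC is divided into ``n`` equal
intervals; an interval is "occupied" when it contains at least one focus.
For every unordered interval pair (i, j) the observed frequency of SCs
occupied in both is divided by the product of the single-interval
frequencies — the frequency expected were crossovers independent. CoC < 1
at short inter-interval distances is the signature of interference; the
curve rises to ≈ 1 (and fluctuates around it) at large distances. Interval
counts default to the quarter rule: interval width strictly less than one
quarter of the mean inter-crossover distance, so closely spaced crossovers
land in distinct intervals.

**Gamma shape.** Inter-adjacent focus distances are pooled over SCs and a
two-parameter gamma distribution is fitted by maximum likelihood; the shape
ν measures spacing evenness (ν = 1: Poisson/no interference). Gaps may be
pooled in μm or as percentages of their own SC's length; the shape is
scale-free per SC, so with identical SC lengths the two normalizations give
identical ν.

Both analyses are invariant under reversing the coordinate origin of every
SC, as they must be: the telomere from which a trace starts is arbitrary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, FitError, ValidationError
from .model import ALL, Cohort, SCObservation

PERCENT = "percent"
MICROMETERS = "um"

#: Fewest intervals per SC admitted by the quarter rule.
MIN_INTERVALS = 2


# ---------------------------------------------------------------------------
# inter-focus gaps

def inter_focus_gaps(sc: SCObservation, normalization: str = MICROMETERS) -> np.ndarray:
    """Adjacent inter-focus distances of one SC.

    SCs with fewer than two foci contribute no gaps. In ``percent`` mode
    each gap is divided by the SC's own length and multiplied by 100.
    """
    if normalization not in (PERCENT, MICROMETERS):
        raise ValidationError(f"normalization must be {PERCENT!r} or {MICROMETERS!r}, "
                              f"got {normalization!r}")
    pos = np.sort(np.asarray(sc.focus_positions_um, dtype=float))
    if pos.size < 2:
        return np.empty(0)
    gaps = np.diff(pos)
    if normalization == PERCENT:
        gaps = gaps / sc.sc_length_um * 100.0
    return gaps


def pooled_gaps(cohort: Cohort, chrom_class: str = ALL,
                normalization: str = MICROMETERS) -> tuple[np.ndarray, np.ndarray]:
    """Pool gaps over a cohort; returns ``(gaps, nucleus_ids)`` aligned arrays.

    The nucleus labels let downstream bootstraps resample whole nuclei,
    respecting within-nucleus correlation.
    """
    gaps, owners = [], []
    for sc in cohort.iter_scs(chrom_class):
        g = inter_focus_gaps(sc, normalization)
        gaps.append(g)
        owners.extend([sc.nucleus_id] * g.size)
    if not gaps:
        return np.empty(0), np.asarray(owners, dtype=object)
    return np.concatenate(gaps), np.asarray(owners, dtype=object)


# ---------------------------------------------------------------------------
# interval occupancy and CoC

def default_interval_count(cohort: Cohort, chrom_class: str = ALL) -> int:
    """Smallest interval count satisfying the quarter rule.

    With class mean SC length L̄ and class mean inter-crossover gap d̄ (μm),
    returns the smallest n such that L̄/n < d̄/4, floored at
    :data:`MIN_INTERVALS`.
    """
    scs = cohort.scs(chrom_class)
    gaps, _ = pooled_gaps(cohort, chrom_class, MICROMETERS)
    if gaps.size == 0:
        raise ConfigurationError(
            f"no inter-focus gaps in class {chrom_class!r}; "
            "pass an explicit interval count")
    mean_len = float(np.mean([sc.sc_length_um for sc in scs]))
    mean_gap = float(np.mean(gaps))
    n = int(np.floor(4.0 * mean_len / mean_gap)) + 1
    return max(n, MIN_INTERVALS)


def occupancy_matrix(scs: list[SCObservation], n_intervals: int) -> np.ndarray:
    """Boolean (n_scs, n_intervals) matrix: interval contains ≥ 1 focus.

    Intervals are defined per SC in relative coordinates (n equal intervals
    of that SC). Occupancy is binary; focus multiplicity within an interval
    is deliberately ignored. A focus exactly at the far telomere falls in
    the last interval.
    """
    if n_intervals < MIN_INTERVALS:
        raise ValidationError(f"n_intervals must be >= {MIN_INTERVALS}, got {n_intervals}")
    occ = np.zeros((len(scs), n_intervals), dtype=bool)
    for r, sc in enumerate(scs):
        if sc.n_foci:
            idx = np.floor(np.asarray(sc.focus_positions_um) / sc.sc_length_um
                           * n_intervals).astype(int)
            occ[r, np.clip(idx, 0, n_intervals - 1)] = True
    return occ


@dataclass(frozen=True)
class CoCCurve:
    """Per-pair CoC records plus (optionally) the distance-binned curve.

    ``pair_records`` columns: interval_i, interval_j, distance_um,
    observed, expected, coc, n_scs. ``binned`` columns: bin_center_um,
    mean_coc, n_pairs. Pairs whose expected double frequency is zero carry
    no information and are withheld from the records; their count is kept
    in ``n_withheld_pairs`` so sparse cohorts remain diagnosable.
    """

    chromosome_class: str
    n_intervals: int
    interval_width_um: float       # class mean SC length / n_intervals
    pair_records: pd.DataFrame
    n_withheld_pairs: int
    binned: pd.DataFrame | None = None


def coc_pairs(cohort: Cohort, chrom_class: str = ALL,
              n_intervals: int | None = None) -> CoCCurve:
    """Observed/expected double-crossover ratios for all interval pairs.

    For each unordered pair (i < j) over N SCs of the class:
    observed = #SCs occupied in both i and j / N; expected = (occupancy
    frequency of i) × (occupancy frequency of j); CoC = observed/expected.
    Pair distance is (j − i) × the class mean interval width (intervals are
    relative per SC; the class mean width converts separation to μm).
    """
    scs = cohort.scs(chrom_class)
    if not scs:
        raise ValidationError(f"cohort {cohort.genotype!r} has no SCs in class {chrom_class!r}")
    if n_intervals is None:
        n_intervals = default_interval_count(cohort, chrom_class)
    occ = occupancy_matrix(scs, n_intervals)
    n_scs = len(scs)
    freq = occ.mean(axis=0)                       # single-interval occupancy frequencies
    doubles = (occ.T.astype(float) @ occ.astype(float)) / n_scs
    width = float(np.mean([sc.sc_length_um for sc in scs])) / n_intervals

    ii, jj = np.triu_indices(n_intervals, k=1)
    expected = freq[ii] * freq[jj]
    observed = doubles[ii, jj]
    keep = expected > 0
    records = pd.DataFrame({
        "interval_i": ii[keep],
        "interval_j": jj[keep],
        "distance_um": (jj[keep] - ii[keep]) * width,
        "observed": observed[keep],
        "expected": expected[keep],
        "coc": observed[keep] / expected[keep],
        "n_scs": n_scs,
    })
    return CoCCurve(chromosome_class=chrom_class, n_intervals=n_intervals,
                    interval_width_um=width, pair_records=records,
                    n_withheld_pairs=int((~keep).sum()))


def coc_curve(curve: CoCCurve, bin_width_um: float | None = None) -> CoCCurve:
    """Bin pair records by inter-interval distance; mean CoC per bin.

    Default bin width is one interval width. Bins containing no pairs are
    omitted.
    """
    if bin_width_um is None:
        bin_width_um = curve.interval_width_um
    if not bin_width_um > 0:
        raise ValidationError(f"bin_width_um must be positive, got {bin_width_um}")
    rec = curve.pair_records
    if rec.empty:
        binned = pd.DataFrame(columns=["bin_center_um", "mean_coc", "n_pairs"])
    else:
        idx = np.floor(rec["distance_um"].to_numpy() / bin_width_um).astype(int)
        grouped = rec.groupby(idx)["coc"]
        binned = pd.DataFrame({
            "bin_center_um": (grouped.mean().index.to_numpy() + 0.5) * bin_width_um,
            "mean_coc": grouped.mean().to_numpy(),
            "n_pairs": grouped.size().to_numpy(),
        })
    return CoCCurve(curve.chromosome_class, curve.n_intervals, curve.interval_width_um,
                    curve.pair_records, curve.n_withheld_pairs, binned)


# ---------------------------------------------------------------------------
# gamma MLE

@dataclass(frozen=True)
class GammaFit:
    """Two-parameter gamma MLE on pooled inter-focus gaps."""

    shape_nu: float
    scale: float
    se_nu: float               # bootstrap SE (NaN when bootstrap disabled)
    n_gaps: int
    normalization: str
    n_bootstrap: int = 0


def _gamma_mle(gaps: np.ndarray) -> tuple[float, float]:
    shape, _, scale = stats.gamma.fit(gaps, floc=0.0)
    return float(shape), float(scale)


def fit_gamma(gaps: np.ndarray, *, nucleus_ids: np.ndarray | None = None,
              n_bootstrap: int = 1000, seed: int | None = None,
              normalization: str = MICROMETERS) -> GammaFit:
    """Maximum-likelihood gamma fit of inter-adjacent focus distances.

    The location is fixed at zero (gaps are distances). The shape SE comes
    from a nonparametric bootstrap that resamples *nuclei*, not individual
    gaps, to respect within-nucleus correlation; pass ``nucleus_ids``
    aligned with ``gaps`` to enable it (without labels, gaps are resampled
    directly and the SE is anti-conservative). ``n_bootstrap=0`` skips the
    bootstrap and reports ``se_nu = NaN``.
    """
    gaps = np.asarray(gaps, dtype=float)
    if np.any(gaps <= 0) or not np.all(np.isfinite(gaps)):
        raise ValidationError("all gaps must be finite and strictly positive")
    if gaps.size < 10:
        raise FitError(f"need at least 10 gaps for a gamma fit, got {gaps.size}")
    shape, scale = _gamma_mle(gaps)

    se = float("nan")
    if n_bootstrap:
        rng = np.random.default_rng(seed)
        shapes = np.empty(n_bootstrap)
        if nucleus_ids is not None:
            nucleus_ids = np.asarray(nucleus_ids)
            if nucleus_ids.shape != gaps.shape:
                raise ValidationError("nucleus_ids must align with gaps")
            unique = np.unique(nucleus_ids)
            by_nucleus = {u: gaps[nucleus_ids == u] for u in unique}
            for b in range(n_bootstrap):
                pick = rng.choice(unique, size=unique.size, replace=True)
                sample = np.concatenate([by_nucleus[u] for u in pick])
                shapes[b] = _gamma_mle(sample)[0] if sample.size >= 2 else np.nan
        else:
            for b in range(n_bootstrap):
                shapes[b] = _gamma_mle(rng.choice(gaps, size=gaps.size, replace=True))[0]
        se = float(np.nanstd(shapes, ddof=1))
    return GammaFit(shape, scale, se, int(gaps.size), normalization, n_bootstrap)


def fit_gamma_cohort(cohort: Cohort, *, chrom_class: str = ALL,
                     normalization: str = PERCENT, n_bootstrap: int = 1000,
                     seed: int | None = None) -> GammaFit:
    """Pool a cohort's gaps and fit; bootstrap resamples nuclei."""
    gaps, owners = pooled_gaps(cohort, chrom_class, normalization)
    if gaps.size < 10:
        raise FitError(
            f"cohort {cohort.genotype!r} has {gaps.size} gap(s) in class {chrom_class!r}; "
            "need >= 10 (SCs with < 2 foci contribute none)")
    return fit_gamma(gaps, nucleus_ids=owners, n_bootstrap=n_bootstrap,
                     seed=seed, normalization=normalization)


# ---------------------------------------------------------------------------
# full report

@dataclass(frozen=True)
class InterferenceReport:
    genotype: str
    curves: dict[str, CoCCurve]      # keys: long, short, all
    gamma: GammaFit | None
    diagnostics: dict[str, object]


def interference_report(cohort: Cohort, *, n_intervals: int | None = None,
                        bin_width_um: float | None = None,
                        normalization: str = PERCENT, n_bootstrap: int = 1000,
                        seed: int | None = None) -> InterferenceReport:
    """CoC curves for the long class, short class and pooled, plus gamma fit.

    With ``n_intervals=None`` each class derives its own count from the
    quarter rule. A cohort whose SCs all carry ≤ 1 focus yields no gamma
    fit; the reason is recorded in the diagnostics instead of raising.
    """
    from .model import LONG, SHORT

    curves: dict[str, CoCCurve] = {}
    diagnostics: dict[str, object] = {}
    for cls in (LONG, SHORT, ALL):
        try:
            curve = coc_pairs(cohort, cls, n_intervals)
            curves[cls] = coc_curve(curve, bin_width_um)
            diagnostics[f"withheld_pairs_{cls}"] = curve.n_withheld_pairs
        except (ConfigurationError, ValidationError) as exc:
            diagnostics[f"coc_{cls}_unavailable"] = str(exc)
    try:
        gamma = fit_gamma_cohort(cohort, normalization=normalization,
                                 n_bootstrap=n_bootstrap, seed=seed)
    except FitError as exc:
        gamma = None
        diagnostics["gamma_unavailable"] = str(exc)
    return InterferenceReport(cohort.genotype, curves, gamma, diagnostics)


def report_tables(report: InterferenceReport) -> dict[str, pd.DataFrame]:
    """Flatten a report into machine-readable result tables."""
    tables: dict[str, pd.DataFrame] = {}
    for cls, curve in report.curves.items():
        tables[f"coc_pairs_{cls}"] = curve.pair_records
        if curve.binned is not None:
            tables[f"coc_curve_{cls}"] = curve.binned
    if report.gamma is not None:
        g = report.gamma
        tables["gamma_fit"] = pd.DataFrame([{
            "genotype": report.genotype, "shape_nu": g.shape_nu, "scale": g.scale,
            "se_nu": g.se_nu, "n_gaps": g.n_gaps, "normalization": g.normalization,
            "n_bootstrap": g.n_bootstrap,
        }])
    return tables
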