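"""Coalescence-age estimation with the rho statistic.

rho is the mean number of mutations from a clade's root to each of its
tips; under a Poisson molecular clock its expectation is mu * L * T, so
dividing by the per-year per-genome rate calibrates it to years.  The
standard error follows the Poisson-model estimator of Saillard et al.:
with m_e mutation events on edge e and n_e tips subtended,

    rho   = (1/n)   * sum_e m_e * n_e
    sigma = (1/n) * sqrt( sum_e m_e * n_e^2 )

Because empirical mtDNA mutation rates are time-dependent (purifying
selection removes young deleterious variants), calibrated ages can be
passed through a pluggable monotone correction; the identity is the
default and a piecewise-linear table can be loaded from TSV so a
published correction curve drops in verbatim.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .haplo_tree import CladeNode, HaplogroupTree
from .mito_io import ReferenceSystem, Variant
from .variant_scoring import classify_variant

MUTATION_FILTERS = ("all", "synonymous")

#: the two published whole-mtDNA substitution rates commonly averaged for
#: complete-genome clock calibration (substitutions/site/year)
WHOLE_MTDNA_RATES = (1.665e-8, 1.708e-8)


@dataclass(frozen=True)
class RhoEstimate:
    clade: str
    rho: float
    sigma: float
    n: int
    mutation_filter: str = "all"

    def __post_init__(self) -> None:
        if self.rho < 0 or self.sigma < 0 or self.n < 1:
            raise ValueError("invalid rho estimate")


def identity_correction(t: float) -> float:
    return t


@dataclass
class ClockModel:
    """Molecular-clock calibration: rate, countable sites, age correction.

    ``correction`` must be strictly increasing with correction(0) = 0; it
    maps uncorrected calendar years to corrected years (e.g. a published
    purifying-selection curve).
    """

    name: str
    mu: float
    L_effective: int
    correction: Callable[[float], float] = identity_correction

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ValueError("mu must be positive")
        if self.L_effective < 1:
            raise ValueError("L_effective must be >= 1")
        if abs(self.correction(0.0)) > 1e-9:
            raise ValueError("correction(0) must be 0")


@dataclass(frozen=True)
class AgeEstimate:
    clade: str
    years: float
    ci_low: float
    ci_high: float
    clock: str
    sigma_years: float
    n: int

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.years <= self.ci_high):
            raise ValueError("confidence bounds must bracket the point estimate")


class PiecewiseCorrection:
    """Strictly increasing piecewise-linear years->years mapping loaded
    from a two-column TSV (raw_years, corrected_years); linear
    extrapolation beyond the last knot."""

    def __init__(self, raw: Sequence[float], corrected: Sequence[float]) -> None:
        raw_a = np.asarray(raw, dtype=float)
        cor_a = np.asarray(corrected, dtype=float)
        if raw_a.ndim != 1 or raw_a.shape != cor_a.shape or raw_a.size < 2:
            raise ValueError("correction table needs >= 2 (raw, corrected) rows")
        if np.any(np.diff(raw_a) <= 0) or np.any(np.diff(cor_a) <= 0):
            raise ValueError("correction table must be strictly increasing")
        if raw_a[0] != 0 or cor_a[0] != 0:
            raise ValueError("correction table must start at (0, 0)")
        self.raw = raw_a
        self.corrected = cor_a

    @classmethod
    def from_tsv(cls, path) -> "PiecewiseCorrection":
        data = np.loadtxt(path, delimiter="\t", ndmin=2)
        return cls(data[:, 0], data[:, 1])

    def to_tsv(self, path) -> None:
        np.savetxt(path, np.column_stack([self.raw, self.corrected]), delimiter="\t")

    def __call__(self, t: float) -> float:
        if t <= self.raw[-1]:
            return float(np.interp(t, self.raw, self.corrected))
        slope = (self.corrected[-1] - self.corrected[-2]) / (
            self.raw[-1] - self.raw[-2]
        )
        return float(self.corrected[-1] + slope * (t - self.raw[-1]))


def average_rates(r1: float, r2: float) -> float:
    """Arithmetic mean of two published substitution rates."""
    if r1 <= 0 or r2 <= 0:
        raise ValueError("rates must be positive")
    return (r1 + r2) / 2.0


def complete_clock(
    L: int = 16569, correction: Callable[[float], float] = identity_correction
) -> ClockModel:
    """Whole-mitogenome clock at the averaged published rate."""
    return ClockModel("complete", average_rates(*WHOLE_MTDNA_RATES), L, correction)


# ---------------------------------------------------------------------------
# rho and sigma


def _resolve_clade(tree: HaplogroupTree, clade) -> CladeNode:
    if clade is None:
        return tree.root
    if isinstance(clade, CladeNode):
        return clade
    return tree.find(clade)


def _edge_terms(
    node: CladeNode,
    keep: Callable[[Variant], bool],
) -> list[tuple[int, int]]:
    """(m_e, n_e) for every edge strictly inside the clade subtree."""
    terms = []
    for desc in node.walk():
        if desc is node:
            continue
        m = sum(1 for v in desc.edge_variants if keep(v))
        if m:
            terms.append((m, desc.tip_count()))
    return terms


def _make_filter(
    mutation_filter: str, ref: ReferenceSystem | None
) -> Callable[[Variant], bool]:
    if mutation_filter == "all":
        return lambda v: True
    if mutation_filter == "synonymous":
        if ref is None:
            raise ValueError("synonymous filtering needs a ReferenceSystem")
        return lambda v: bool(classify_variant(v, ref).synonymous)
    raise ValueError(f"unknown mutation filter {mutation_filter!r}")


def compute_rho(
    tree: HaplogroupTree,
    clade=None,
    mutation_filter: str = "all",
    ref: ReferenceSystem | None = None,
) -> RhoEstimate:
    """Mean root-to-tip mutation count over the clade's tips."""
    node = _resolve_clade(tree, clade)
    n = node.tip_count()
    if n < 1:
        raise ValueError("clade has no tips")
    keep = _make_filter(mutation_filter, ref)
    terms = _edge_terms(node, keep)
    rho = sum(m * ne for m, ne in terms) / n
    sigma = float(np.sqrt(sum(m * ne * ne for m, ne in terms)) / n)
    return RhoEstimate(node.name or "", rho, sigma, n, mutation_filter)


def compute_sigma(
    tree: HaplogroupTree,
    clade=None,
    mutation_filter: str = "all",
    ref: ReferenceSystem | None = None,
) -> float:
    """Saillard standard error of rho for the clade."""
    return compute_rho(tree, clade, mutation_filter, ref).sigma


def rho_to_age(est: RhoEstimate, clock: ClockModel) -> AgeEstimate:
    """Calibrate rho to years: t = rho / (mu * L), then apply the clock's
    correction; the 95% interval maps rho +- 1.96 sigma the same way."""
    if clock.name == "synonymous" and est.mutation_filter != "synonymous":
        raise ValueError("synonymous clock requires synonymous-only counts")
    if clock.name == "complete" and est.mutation_filter != "all":
        raise ValueError("complete clock requires all-site counts")
    denom = clock.mu * clock.L_effective
    t = est.rho / denom
    lo = max(0.0, (est.rho - 1.96 * est.sigma) / denom)
    hi = max(0.0, (est.rho + 1.96 * est.sigma) / denom)
    return AgeEstimate(
        clade=est.clade,
        years=clock.correction(t),
        ci_low=clock.correction(lo),
        ci_high=clock.correction(hi),
        clock=clock.name,
        sigma_years=est.sigma / denom,
        n=est.n,
    )


def compare_ages(a: AgeEstimate, b: AgeEstimate) -> tuple[float, float]:
    """Normal z-comparison of two calibrated clade ages.

    Returns (z, two-sided p).  This is the practical reading of the
    informal clade-age "t-test": the difference of the two age estimates
    over the joint standard error, referred to the standard normal.
    """
    var = a.sigma_years**2 + b.sigma_years**2
    if var <= 0:
        raise ValueError("zero joint variance; cannot compare ages")
    z = (a.years - b.years) / np.sqrt(var)
    p = 2.0 * float(stats.norm.sf(abs(z)))
    return float(z), p


# ---------------------------------------------------------------------------
# age table export


def write_age_table(rows: Sequence[tuple], path) -> None:
    """Rows: (clade, defining mutations string, region, AgeEstimate...)
    one age column per clock, each as 'years (lo-hi)' in ky."""
    with open(path, "w") as fh:
        fh.write("clade\tdefining_mutations\tregion\tclock\tage_ky\tci_ky\n")
        for clade, muts, region, age in rows:
            fh.write(
                f"{clade}\t{muts}\t{region}\t{age.clock}\t"
                f"{age.years / 1000:.1f}\t"
                f"{age.ci_low / 1000:.1f}-{age.ci_high / 1000:.1f}\n"
            )
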