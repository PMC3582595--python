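"""Dosage-balance estimate for synergistically co-regulating CNV families.

The analysis starts from the genes regulated exclusively by exactly two CNV
families.  The relabelling null gives the count expected if CNV status were
assigned independently; the observed excess over that null is the
"non-independent" component.  Re-seeding the network with that many random
genes and counting the families they touch estimates how many families the
co-regulation structure alone would mark; halving (each co-regulating pair
involves two families) gives the number of CNV families attributable to the
dosage-balance requirement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .network import RegulatoryNetwork


@dataclass(frozen=True)
class NormalSpec:
    """A fitted or derived normal distribution, N(mean, sd)."""

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError(f"sd must be >= 0, got {self.sd}")


@dataclass
class DosageBalanceResult:
    nonindependent: NormalSpec  # excess genes over the independence null (m)
    marked_families: NormalSpec  # families touched by m random genes (f)
    retained: NormalSpec  # f / 2
    attributable_fraction: float
    reps: int
    seed: int


def nonindependent_component(observed: int, null: NormalSpec) -> NormalSpec:
    """observed - N(mean, sd): location shift of the negated null."""
    mean = observed - null.mean
    if mean < 0:
        warnings.warn(
            f"observed count {observed} below null mean {null.mean}; "
            "downstream sampling truncates draws at 0",
            stacklevel=2,
        )
    return NormalSpec(mean=mean, sd=null.sd)


def simulate_marked_families(
    network: RegulatoryNetwork,
    m_spec: NormalSpec,
    reps: int = 1000,
    seed: int = 0,
    gene_universe: list[str] | None = None,
) -> NormalSpec:
    """Normal fit of f, the number of families touched by m random genes.

    Per replicate: m ~ N(m_spec) rounded to the nearest integer and clamped
    to [0, |universe|]; m genes drawn uniformly without replacement; f is
    the number of distinct families with at least one edge into the draw.
    The default universe is every gene of the full network; pass
    ``gene_universe`` to restrict assignment (e.g. to a subnetwork).
    """
    if reps < 2:
        raise ValueError("reps must be >= 2")
    if not network.genes:
        raise ValueError("network is empty")
    universe = sorted(gene_universe) if gene_universe is not None else sorted(network.genes)
    fams_of: dict[str, set[str]] = {g: set() for g in universe}
    uset = set(universe)
    for fam, gene in network.edges:
        if gene in uset:
            fams_of[gene].add(fam)

    rng = np.random.default_rng(seed)
    n = len(universe)
    f_values = np.empty(reps, dtype=np.int64)
    for r in range(reps):
        m = int(np.rint(rng.normal(m_spec.mean, m_spec.sd)))
        m = min(max(m, 0), n)
        picked = rng.choice(n, size=m, replace=False)
        marked: set[str] = set()
        for i in picked:
            marked |= fams_of[universe[i]]
        f_values[r] = len(marked)
    return NormalSpec(mean=float(np.mean(f_values)), sd=float(np.std(f_values, ddof=1)))


def attributable_estimate(f_spec: NormalSpec, n_cnv_in_subnetwork: int) -> tuple[NormalSpec, float]:
    """Halve f (two families per co-regulating pair) and normalise.

    Returns the retained-family distribution N(f/2) and its mean as a
    fraction of the CNV families present in the analysed subnetwork.
    """
    if n_cnv_in_subnetwork <= 0:
        raise ValueError("n_cnv_in_subnetwork must be positive")
    retained = NormalSpec(mean=f_spec.mean / 2, sd=f_spec.sd / 2)
    return retained, retained.mean / n_cnv_in_subnetwork


def run_dosage_balance(
    network: RegulatoryNetwork,
    observed: int,
    null: NormalSpec,
    n_cnv_in_subnetwork: int,
    reps: int = 1000,
    seed: int = 0,
    round_mean: bool = False,
) -> DosageBalanceResult:
    """End-to-end dosage-balance estimate.

    ``round_mean`` rounds the non-independent mean to the nearest integer
    before sampling (the presentation convention); the default keeps the
    unrounded value.
    """
    m_spec = nonindependent_component(observed, null)
    if round_mean:
        m_spec = NormalSpec(mean=float(np.rint(m_spec.mean)), sd=m_spec.sd)
    f_spec = simulate_marked_families(network, m_spec, reps=reps, seed=seed)
    retained, fraction = attributable_estimate(f_spec, n_cnv_in_subnetwork)
    return DosageBalanceResult(
        nonindependent=m_spec,
        marked_families=f_spec,
        retained=retained,
        attributable_fraction=fraction,
        reps=reps,
        seed=seed,
    )
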