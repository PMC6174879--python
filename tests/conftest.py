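"""Shared fixtures: hand-built locus sets and a reusable simulated dataset."""

from __future__ import annotations

import numpy as np
import pytest

from ucepop.loci import Locus, LocusSet
from ucepop.simulate import DemographicParams, SimulationConfig, generate_dataset


def make_locus_set(
    locus_haps: list[np.ndarray],
    lengths: list[int] | None = None,
    chrom_classes: list[str] | None = None,
    n_per_pop: int | None = None,
) -> LocusSet:
    """Build a 2-population LocusSet from raw haplotype matrices.

    Each matrix is (2 * n_samples, n_snps); the first half of the samples
    is pop1, the second half pop2 (override with ``n_per_pop``).
    SNP positions are 1, 2, 3, ...
    """
    n_samples = locus_haps[0].shape[0] // 2
    n1 = n_per_pop if n_per_pop is not None else n_samples // 2
    samples = [f"s{i}" for i in range(n_samples)]
    popmap = {s: ("pop1" if i < n1 else "pop2") for i, s in enumerate(samples)}
    loci = []
    for k, haps in enumerate(locus_haps):
        haps = np.asarray(haps, dtype=np.int8)
        S = haps.shape[1]
        length = (lengths[k] if lengths else max(1000, S))
        cclass = chrom_classes[k] if chrom_classes else "autosome"
        loci.append(
            Locus(f"loc{k}", length, cclass, np.arange(1, S + 1), haps)
        )
    return LocusSet(loci=loci, samples=samples, popmap=popmap)


@pytest.fixture(scope="session")
def sim_dataset():
    """A moderate split-with-migration dataset reused across test modules:
    4 + 4 diploids, 300 variable + 80 invariant loci, known truth."""
    cfg = SimulationConfig(
        model="split_mig",
        params=DemographicParams(nu1=3.5, nu2=6.0, T=1.4, m12=1.65, m21=1.65),
        n_variable_loci_target=300,
        n_invariant_loci=80,
        z_fraction=0.05,
        seed=20260922,
    )
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def sim_ls(sim_dataset):
    return sim_dataset.locus_set
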