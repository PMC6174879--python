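"""Structured-coalescent simulator for two-population divergence models.

Generates UCE-like multi-locus phased datasets (VCF + popmap + annotation)
with known truth parameters under six demographic models:

======================  =====================================================
``neutral``             one panmictic population (no divergence); population
                        labels are bookkeeping only
``split_mig``           ancestral population (size ``Nref``) splits at time
                        ``T`` into constant-size populations ``nu1``, ``nu2``
                        exchanging symmetric migration ``m``
``split_nomig``         as ``split_mig`` with migration fixed at zero
``im``                  isolation-with-migration: the ancestral population
                        splits into fractions ``s`` and ``1 - s`` which grow
                        (or shrink) exponentially to ``nu1``, ``nu2`` at the
                        present, with bidirectional migration ``m12``, ``m21``
``im_nomig``            as ``im`` with both migration rates fixed at zero
``split_asym_mig``      as ``split_mig`` with independent ``m12``, ``m21``
======================  =====================================================

Units follow the dadi diffusion convention throughout: time in units of
``2 * Nref`` generations, population sizes as ratios ``nu_i`` to the
ancestral ``Nref``, and migration ``m_ij = 2 * Nref * f_ij`` where ``f_ij``
is the per-generation fraction of population *i* descended from migrants
out of population *j*.  In these units a pair of lineages in population *i*
coalesces at rate ``1 / nu_i(t)`` and a lineage in population *i* traces
its ancestry to population *j* at rate ``m_ij``.

Mutations follow the infinite-sites model: each mutation creates one new
biallelic site, placed on a branch with probability proportional to branch
length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .loci import Locus, LocusSet, write_annotation, write_popmap, write_vcf

__all__ = [
    "MODELS",
    "DemographicParams",
    "Genealogy",
    "SimulationConfig",
    "SyntheticDataset",
    "simulate_genealogy",
    "sprinkle_mutations",
    "generate_dataset",
]

MODELS = ("neutral", "split_mig", "split_nomig", "im", "im_nomig", "split_asym_mig")

#: models whose migration parameters are structurally fixed at zero
_NOMIG = {"split_nomig", "im_nomig"}
#: models with exponential growth from split fractions s, 1 - s
_GROWTH = {"im", "im_nomig"}


@dataclass(frozen=True)
class DemographicParams:
    """Demographic parameters in diffusion units (see module docstring).

    ``s`` (ancestral split fraction) is used only by the growth models;
    ``m12``/``m21`` are ignored (treated as zero) by the no-migration
    models and must be equal for ``split_mig``.
    """

    nu1: float = 1.0
    nu2: float = 1.0
    T: float = 1.0
    m12: float = 0.0
    m21: float = 0.0
    s: float = 0.5

    def __post_init__(self) -> None:
        if self.nu1 <= 0 or self.nu2 <= 0 or self.T <= 0:
            raise ValueError("sizes and split time must be positive")
        if self.m12 < 0 or self.m21 < 0:
            raise ValueError("migration rates must be non-negative")
        if not 0.0 < self.s < 1.0:
            raise ValueError("split fraction s must lie in (0, 1)")


def _kernel_args(model: str, params: DemographicParams) -> tuple[bool, bool, float, float, float, float, float, float]:
    """Validate (model, params) and map them to kernel arguments."""
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; choose from {MODELS}")
    m12, m21 = params.m12, params.m21
    if model in _NOMIG:
        if m12 != 0.0 or m21 != 0.0:
            raise ValueError(f"model {model!r} requires zero migration rates")
    if model == "split_mig" and m12 != m21:
        raise ValueError("split_mig is symmetric: m12 must equal m21")
    if model == "neutral":
        m12 = m21 = 0.0
    panmictic = model == "neutral"
    growth = model in _GROWTH
    return panmictic, growth, params.nu1, params.nu2, params.T, m12, m21, params.s


@dataclass
class Genealogy:
    """A coalescent tree over ``n1 + n2`` leaves.

    Leaves ``0 .. n1-1`` belong to population 1, ``n1 .. n1+n2-1`` to
    population 2; internal nodes are appended in coalescence order, so the
    root is the last node.  Times are in units of ``2 * Nref`` generations
    and leaves sit at time 0.
    """

    parent: np.ndarray  # (2n - 1,) int64; root has parent -1
    time: np.ndarray  # (2n - 1,) float64
    n1: int
    n2: int

    @property
    def n_leaves(self) -> int:
        return self.n1 + self.n2

    @property
    def root(self) -> int:
        return len(self.parent) - 1

    def branch_lengths(self) -> np.ndarray:
        """Length of the branch above each node (0 for the root)."""
        bl = np.zeros(len(self.parent))
        has_parent = self.parent >= 0
        bl[has_parent] = self.time[self.parent[has_parent]] - self.time[has_parent]
        return bl

    def total_branch_length(self) -> float:
        return float(self.branch_lengths().sum())

    def leaves_below(self) -> np.ndarray:
        """Boolean matrix (n_nodes, n_leaves): leaf j descends from node v."""
        n = self.n_leaves
        below = np.zeros((len(self.parent), n), dtype=bool)
        for leaf in range(n):
            v = leaf
            while v != -1:
                below[v, leaf] = True
                v = self.parent[v]
        return below

    def tmrca(self) -> float:
        return float(self.time[self.root])


# ---------------------------------------------------------------------------
# numba event kernel
# ---------------------------------------------------------------------------
#
# Waiting times for coalescence in an exponentially changing population are
# drawn by inverting the integrated hazard.  With backward-time size
# nu(t) = nu0 * exp(beta * t) (beta = log(s / nu0) / T for the growth
# models, 0 otherwise) and C = k(k-1)/2 pairs, the integrated hazard from
# t over a wait w is (C / nu0) * exp(-beta t) * (1 - exp(-beta w)) / beta,
# which is solved for w against a unit-exponential draw; an unbounded
# integral means no event before the phase ends.


@njit(cache=True)
def _coal_wait(C: float, nu0: float, beta: float, t: float) -> float:
    if C <= 0.0:
        return np.inf
    e = np.random.exponential(1.0)
    if beta == 0.0:
        return e * nu0 / C
    x = e * beta * nu0 * math.exp(beta * t) / C
    if x >= 1.0:
        return np.inf
    return -math.log1p(-x) / beta


@njit(cache=True)
def _sim_tree(panmictic, growth, nu1, nu2, T, m12, m21, s, n1, n2, parent, time):
    n = n1 + n2
    node = np.empty(n, np.int64)
    pop = np.empty(n, np.int64)
    for i in range(n):
        node[i] = i
        pop[i] = 0 if (i < n1 or panmictic) else 1
    for i in range(2 * n - 1):
        parent[i] = -1
        time[i] = 0.0
    k = n
    t = 0.0
    nxt = n
    ancestral = panmictic
    if growth:
        beta1 = math.log(s / nu1) / T
        beta2 = math.log((1.0 - s) / nu2) / T
    else:
        beta1 = 0.0
        beta2 = 0.0
    while k > 1:
        if ancestral:
            # one population of relative size 1
            w = np.random.exponential(1.0) / (k * (k - 1) / 2.0)
            t += w
            which = 0
        else:
            c1 = 0
            for i in range(k):
                if pop[i] == 0:
                    c1 += 1
            c2 = k - c1
            w1 = _coal_wait(c1 * (c1 - 1) / 2.0, nu1, beta1, t)
            w2 = _coal_wait(c2 * (c2 - 1) / 2.0, nu2, beta2, t)
            mig_rate = c1 * m12 + c2 * m21
            wm = np.random.exponential(1.0) / mig_rate if mig_rate > 0.0 else np.inf
            w = min(w1, w2, wm)
            if t + w >= T:
                # split reached (backward): merge into the ancestral pop
                t = T
                for i in range(k):
                    pop[i] = 0
                ancestral = True
                continue
            t += w
            if w == wm:
                # migrate one lineage, chosen by relative rate
                u = np.random.random() * mig_rate
                acc = 0.0
                for i in range(k):
                    acc += m12 if pop[i] == 0 else m21
                    if acc >= u:
                        pop[i] = 1 - pop[i]
                        break
                continue
            which = 0 if w == w1 else 1
        # coalesce a uniform pair within population `which`
        c = 0
        for i in range(k):
            if pop[i] == which:
                c += 1
        a = np.random.randint(c)
        b = np.random.randint(c - 1)
        if b >= a:
            b += 1
        ia = -1
        ib = -1
        seen = 0
        for i in range(k):
            if pop[i] == which:
                if seen == a:
                    ia = i
                if seen == b:
                    ib = i
                seen += 1
        parent[node[ia]] = nxt
        parent[node[ib]] = nxt
        time[nxt] = t
        node[ia] = nxt
        node[ib] = node[k - 1]
        pop[ib] = pop[k - 1]
        nxt += 1
        k -= 1


@njit(cache=True)
def _branch_class_table(parent, time, n1, n2, out):
    """Add each branch's length to the cell indexed by (descendant leaves
    in pop 1, descendant leaves in pop 2)."""
    nnodes = parent.shape[0]
    n = (nnodes + 1) // 2
    c1 = np.zeros(nnodes, np.int64)
    c2 = np.zeros(nnodes, np.int64)
    for leaf in range(n):
        v = leaf
        while v != -1:
            if leaf < n1:
                c1[v] += 1
            else:
                c2[v] += 1
            v = parent[v]
    for v in range(nnodes):
        p = parent[v]
        if p >= 0:
            out[c1[v], c2[v]] += time[p] - time[v]


@njit(cache=True)
def _expected_branch_table(panmictic, growth, nu1, nu2, T, m12, m21, s, n1, n2, n_reps, seed):
    np.random.seed(seed)
    n = n1 + n2
    out = np.zeros((n1 + 1, n2 + 1))
    parent = np.empty(2 * n - 1, np.int64)
    time = np.empty(2 * n - 1, np.float64)
    for _ in range(n_reps):
        _sim_tree(panmictic, growth, nu1, nu2, T, m12, m21, s, n1, n2, parent, time)
        _branch_class_table(parent, time, n1, n2, out)
    return out / n_reps


@njit(cache=True)
def _sim_tree_seeded(panmictic, growth, nu1, nu2, T, m12, m21, s, n1, n2, seed):
    np.random.seed(seed)
    n = n1 + n2
    parent = np.empty(2 * n - 1, np.int64)
    time = np.empty(2 * n - 1, np.float64)
    _sim_tree(panmictic, growth, nu1, nu2, T, m12, m21, s, n1, n2, parent, time)
    return parent, time


def simulate_genealogy(
    model: str,
    params: DemographicParams,
    n1: int,
    n2: int,
    rng: np.random.Generator,
) -> Genealogy:
    """Draw one genealogy for ``n1`` + ``n2`` haplotypes under ``model``."""
    if n1 < 0 or n2 < 0 or n1 + n2 < 2:
        raise ValueError("need at least two haplotypes in total")
    args = _kernel_args(model, params)
    seed = int(rng.integers(2**31))
    parent, time = _sim_tree_seeded(*args, n1, n2, seed)
    return Genealogy(parent=parent, time=time, n1=n1, n2=n2)


def expected_branch_table(
    model: str,
    params: DemographicParams,
    n1: int,
    n2: int,
    n_genealogies: int,
    seed: int,
) -> np.ndarray:
    """Monte-Carlo E[branch length subtending (i, j) leaves], an
    ``(n1+1, n2+1)`` table in units of ``2 * Nref`` generations."""
    if n_genealogies < 1:
        raise ValueError("n_genealogies must be positive")
    args = _kernel_args(model, params)
    return _expected_branch_table(*args, n1, n2, n_genealogies, seed % 2**31)


# ---------------------------------------------------------------------------
# mutations
# ---------------------------------------------------------------------------

def sprinkle_mutations(
    g: Genealogy,
    theta_locus: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Infinite-sites mutations: a 0/1 haplotype matrix of shape
    ``(n_leaves, n_mutations)``, Poisson(theta_locus / 2 * total branch
    length) mutations placed proportionally to branch length."""
    if theta_locus < 0:
        raise ValueError("theta_locus must be non-negative")
    bl = g.branch_lengths()
    total = bl.sum()
    n_mut = rng.poisson(theta_locus / 2.0 * total) if total > 0 else 0
    n = g.n_leaves
    if n_mut == 0:
        return np.zeros((n, 0), dtype=np.int8)
    branches = rng.choice(len(bl), size=n_mut, p=bl / total)
    below = g.leaves_below()
    return below[branches].T.astype(np.int8)


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulationConfig:
    """Truth configuration for a synthetic two-population dataset.

    Defaults emulate the study conditions this package is calibrated
    against: 2 populations x 4 diploids, ~2,600 variable loci of mean
    length ~1,150 bp, ~800 invariant loci, and a minority of Z-flagged
    loci.  ``theta_per_site`` is the scaled mutation rate ``4 Nref mu``
    per base pair; the default is calibrated so the default demography
    yields ~3.6 SNPs per variable locus, the study's density.
    """

    model: str = "split_mig"
    params: DemographicParams = field(
        default_factory=lambda: DemographicParams(nu1=3.5, nu2=6.0, T=1.4, m12=1.65, m21=1.65)
    )
    samples_per_pop: int = 4
    n_variable_loci_target: int = 2600
    n_invariant_loci: int = 800
    locus_length_mean_bp: float = 1150.0
    locus_length_sd_bp: float = 330.0
    min_locus_length_bp: int = 200
    theta_per_site: float = 3.1e-4
    intralocus_recomb_fraction: float = 0.0
    z_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.samples_per_pop < 1:
            raise ValueError("samples_per_pop must be >= 1")
        if self.n_variable_loci_target < 1 or self.n_invariant_loci < 0:
            raise ValueError("locus counts must be positive")
        if self.theta_per_site <= 0:
            raise ValueError("theta_per_site must be > 0")
        for frac in (self.intralocus_recomb_fraction, self.z_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        _kernel_args(self.model, self.params)  # validates the pair


@dataclass
class SyntheticDataset:
    """A generated LocusSet together with its truth configuration."""

    locus_set: LocusSet
    truth: SimulationConfig

    def write(self, outdir: str) -> dict[str, str]:
        """Write VCF + popmap + annotation under ``outdir``; return paths."""
        import os

        os.makedirs(outdir, exist_ok=True)
        paths = {
            "vcf": os.path.join(outdir, "dataset.vcf"),
            "popmap": os.path.join(outdir, "popmap.tsv"),
            "annotation": os.path.join(outdir, "annotation.tsv"),
        }
        write_vcf(self.locus_set, paths["vcf"])
        write_popmap(self.locus_set.popmap, paths["popmap"])
        write_annotation(self.locus_set.loci, paths["annotation"])
        return paths


def _draw_length(cfg: SimulationConfig, rng: np.random.Generator) -> int:
    """Locus length: normal truncated below at ``min_locus_length_bp``."""
    while True:
        L = rng.normal(cfg.locus_length_mean_bp, cfg.locus_length_sd_bp)
        if L >= cfg.min_locus_length_bp:
            return int(round(L))


def _simulate_locus_haplotypes(
    cfg: SimulationConfig,
    length: int,
    recombinant: bool,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Return (positions, haplotype matrix) for one locus.

    A recombinant locus is built from two independent genealogies spliced
    at a uniform breakpoint (two fully linked blocks), which can produce
    four-gamete violations between blocks."""
    n = cfg.samples_per_pop
    theta = cfg.theta_per_site * length
    if recombinant:
        bp = rng.integers(1, length)  # sites at positions <= bp come from tree A
        blocks = []
        for lo, hi in ((1, bp), (bp + 1, length)):
            span = hi - lo + 1
            if span <= 0:
                blocks.append((np.empty(0, np.int64), np.zeros((4 * n, 0), np.int8)))
                continue
            g = simulate_genealogy(cfg.model, cfg.params, 2 * n, 2 * n, rng)
            haps = sprinkle_mutations(g, theta * span / length, rng)
            pos = np.sort(rng.choice(np.arange(lo, hi + 1), size=min(haps.shape[1], span), replace=False))
            blocks.append((pos, haps[:, : len(pos)]))
        positions = np.concatenate([b[0] for b in blocks])
        haps = np.concatenate([b[1] for b in blocks], axis=1)
    else:
        g = simulate_genealogy(cfg.model, cfg.params, 2 * n, 2 * n, rng)
        haps = sprinkle_mutations(g, theta, rng)
        k = min(haps.shape[1], length)
        positions = np.sort(rng.choice(np.arange(1, length + 1), size=k, replace=False))
        haps = haps[:, :k]
    return positions, haps


def generate_dataset(cfg: SimulationConfig) -> SyntheticDataset:
    """Simulate a full dataset: variable loci until the target count is
    reached, plus invariant loci, deterministic under ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.samples_per_pop
    samples = [f"pop1_ind{i}" for i in range(n)] + [f"pop2_ind{i}" for i in range(n)]
    popmap = {s: ("pop1" if i < n else "pop2") for i, s in enumerate(samples)}

    loci: list[Locus] = []
    n_variable = 0
    attempts = 0
    max_attempts = 50 * cfg.n_variable_loci_target + 100
    while n_variable < cfg.n_variable_loci_target:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                "could not reach the variable-locus target; "
                "increase theta_per_site or lower n_variable_loci_target"
            )
        length = _draw_length(cfg, rng)
        recombinant = bool(rng.random() < cfg.intralocus_recomb_fraction)
        positions, haps = _simulate_locus_haplotypes(cfg, length, recombinant, rng)
        if haps.shape[1] == 0:
            continue
        n_variable += 1
        cclass = "Z" if rng.random() < cfg.z_fraction else "autosome"
        loci.append(Locus(f"uce-{n_variable:05d}", length, cclass, positions, haps))
    for i in range(cfg.n_invariant_loci):
        length = _draw_length(cfg, rng)
        cclass = "Z" if rng.random() < cfg.z_fraction else "autosome"
        loci.append(
            Locus(
                f"inv-{i + 1:05d}",
                length,
                cclass,
                np.empty(0, np.int64),
                np.zeros((2 * len(samples), 0), np.int8),
            )
        )
    ls = LocusSet(loci=loci, samples=samples, popmap=popmap)
    return SyntheticDataset(locus_set=ls, truth=cfg)
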