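"""Diversity, differentiation, equilibrium, and assignment statistics.

Covers the descriptive layer of a two-population divergence analysis:

* per-site nucleotide diversity pi (unbiased, ``n/(n-1)`` correction),
  between-population distance ``dxy`` and net distance
  ``dA = dxy - (pi1 + pi2)/2``, all divided by the total surveyed length
  including invariant loci;
* the Weir & Cockerham (1984) variance-components F_ST estimator at SNP,
  locus, and overall level (ratio of summed components for the latter
  two), with a permutation G-test of population differentiation;
* exact conditional Hardy-Weinberg tests and heterozygosity summaries
  (Bartlett homogeneity, paired t of Ho vs He, private-allele counts);
* DAPC-style individual assignment: PCA of the centred allele-dosage
  matrix followed by linear discriminant analysis on the retained
  components (four by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import gammaln

from .loci import LocusSet

__all__ = [
    "DiversityStats",
    "FstResult",
    "HetSummary",
    "AssignmentResult",
    "nucleotide_diversity",
    "divergence_stats",
    "weir_cockerham_fst",
    "permutation_differentiation_test",
    "hwe_exact_test",
    "heterozygosity_summary",
    "assign_individuals",
]


# ---------------------------------------------------------------------------
# diversity and divergence
# ---------------------------------------------------------------------------

@dataclass
class DiversityStats:
    pi_overall: float
    pi_by_pop: dict[str, float]
    dxy: float
    dA: float
    total_length_bp: int


def _pi_sites(haps: np.ndarray) -> float:
    """Sum over sites of unbiased heterozygosity n/(n-1) * (1 - sum p^2)."""
    n, S = haps.shape
    if S == 0 or n < 2:
        return 0.0
    total = 0.0
    for j in range(S):
        _, cnt = np.unique(haps[:, j], return_counts=True)
        p = cnt / n
        total += (1.0 - np.sum(p * p)) * n / (n - 1)
    return total


def nucleotide_diversity(ls: LocusSet, scope: str | None = None) -> float:
    """Per-site pi over the whole LocusSet (invariant loci contribute
    length); ``scope`` restricts to one population's haplotypes."""
    total_bp = ls.total_length_bp()
    if total_bp == 0:
        raise ValueError("zero total surveyed length")
    if scope is None:
        rows = np.arange(2 * ls.n_samples)
    else:
        rows = ls.haplotype_rows(scope)
        if len(rows) == 0:
            raise ValueError(f"no samples in population {scope!r}")
    num = sum(_pi_sites(loc.haplotypes[rows]) for loc in ls.loci if loc.is_variable)
    return num / total_bp


def divergence_stats(ls: LocusSet) -> DiversityStats:
    """pi (overall and per population), dxy, and dA = dxy - (pi1+pi2)/2."""
    pops = ls.populations()
    if len(pops) != 2:
        raise ValueError("exactly two populations required")
    total_bp = ls.total_length_bp()
    if total_bp == 0:
        raise ValueError("zero total surveyed length")
    r1, r2 = ls.haplotype_rows(pops[0]), ls.haplotype_rows(pops[1])
    if len(r1) == 0 or len(r2) == 0:
        raise ValueError("a population has no samples")
    # dxy: mean per-site difference over between-population haplotype pairs
    dxy_num = 0.0
    for loc in ls.loci:
        if not loc.is_variable:
            continue
        for j in range(loc.n_snps):
            a, b = loc.haplotypes[r1, j], loc.haplotypes[r2, j]
            alleles = np.unique(np.concatenate([a, b]))
            p1 = np.array([(a == al).mean() for al in alleles])
            p2 = np.array([(b == al).mean() for al in alleles])
            dxy_num += 1.0 - float(np.sum(p1 * p2))
    pi1 = nucleotide_diversity(ls, pops[0])
    pi2 = nucleotide_diversity(ls, pops[1])
    dxy = dxy_num / total_bp
    return DiversityStats(
        pi_overall=nucleotide_diversity(ls),
        pi_by_pop={pops[0]: pi1, pops[1]: pi2},
        dxy=dxy,
        dA=dxy - (pi1 + pi2) / 2.0,
        total_length_bp=total_bp,
    )


# ---------------------------------------------------------------------------
# Weir & Cockerham F_ST
# ---------------------------------------------------------------------------

@dataclass
class FstResult:
    level: str  # snp | locus | overall
    table: pd.DataFrame | None  # per-item estimates (None for overall)
    overall: float  # ratio-of-sums estimate over the requested scope
    permutation_p: float | None = None


def _wc_components(geno1: np.ndarray, geno2: np.ndarray) -> tuple[float, float, float]:
    """Weir & Cockerham (1984) variance components (a, b, c) for one site,
    summed over alleles; inputs are per-individual diploid genotype pairs
    ``(n_i, 2)`` of integer allele codes for the two populations."""
    r = 2
    ns = np.array([geno1.shape[0], geno2.shape[0]], dtype=float)
    nbar = ns.mean()
    nc = (r * nbar - np.sum(ns**2) / (r * nbar)) / (r - 1)
    alleles = np.unique(np.concatenate([geno1.ravel(), geno2.ravel()]))
    a = b = c = 0.0
    for al in alleles:
        p = np.array([(g == al).mean() for g in (geno1, geno2)])
        h = np.array([((g == al).sum(axis=1) == 1).mean() for g in (geno1, geno2)])
        pbar = np.sum(ns * p) / (r * nbar)
        s2 = np.sum(ns * (p - pbar) ** 2) / ((r - 1) * nbar)
        hbar = np.sum(ns * h) / (r * nbar)
        a += (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0) / (nbar - 1)
        )
        b += (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c += hbar / 2.0
    return a, b, c


def _site_components(ls: LocusSet) -> pd.DataFrame:
    pops = ls.populations()
    if len(pops) != 2:
        raise ValueError("exactly two populations required")
    i1, i2 = ls.sample_indices(pops[0]), ls.sample_indices(pops[1])
    rows = []
    for loc in ls.loci:
        for j in range(loc.n_snps):
            col = loc.haplotypes[:, j]
            if len(np.unique(col)) < 2:
                continue  # monomorphic sites carry no information
            g = col.reshape(-1, 2)
            aa, bb, cc = _wc_components(g[i1], g[i2])
            rows.append((loc.name, int(loc.positions[j]), aa, bb, cc))
    if not rows:
        raise ValueError("no polymorphic sites")
    return pd.DataFrame(rows, columns=["locus", "pos", "a", "b", "c"])


def weir_cockerham_fst(ls: LocusSet, level: str = "overall") -> FstResult:
    """W&C 1984 F_ST; ``snp`` gives per-site estimates, ``locus`` and
    ``overall`` the ratio of summed components Sum(a)/Sum(a+b+c)."""
    if level not in ("snp", "locus", "overall"):
        raise ValueError("level must be snp, locus or overall")
    comp = _site_components(ls)
    denom = comp[["a", "b", "c"]].sum(axis=1)
    overall = float(comp["a"].sum() / denom.sum())
    if level == "snp":
        table = comp.assign(fst=comp["a"] / denom)[["locus", "pos", "fst"]]
    elif level == "locus":
        g = comp.groupby("locus", sort=False)[["a", "b", "c"]].sum()
        table = pd.DataFrame(
            {"locus": g.index, "fst": (g["a"] / g.sum(axis=1)).to_numpy()}
        ).reset_index(drop=True)
    else:
        table = None
    return FstResult(level=level, table=table, overall=overall)


# ---------------------------------------------------------------------------
# permutation G-test of differentiation
# ---------------------------------------------------------------------------

def _allele_onehot(ls: LocusSet) -> np.ndarray:
    """One-hot allele indicator (n_haplotypes, n_sites, n_allele_codes)
    over all polymorphic sites, for vectorised contingency tables."""
    cols = [
        loc.haplotypes[:, j]
        for loc in ls.loci
        for j in range(loc.n_snps)
        if len(np.unique(loc.haplotypes[:, j])) > 1
    ]
    if not cols:
        raise ValueError("no polymorphic sites")
    haps = np.stack(cols, axis=1)  # (n_haps, S)
    n_codes = int(haps.max()) + 1
    return haps[:, :, None] == np.arange(n_codes)[None, None, :]


def _g_from_onehot(onehot: np.ndarray, hap_labels: np.ndarray) -> float:
    """G = 2 sum O ln(O/E) over per-site group x allele tables."""
    obs = np.stack(
        [onehot[hap_labels == 0].sum(axis=0), onehot[hap_labels == 1].sum(axis=0)]
    ).astype(float)  # (2, S, A)
    rowt = obs.sum(axis=2, keepdims=True)
    colt = obs.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        exp = rowt * colt / rowt.sum(axis=0, keepdims=True)
        term = np.where(obs > 0, obs * np.log(obs / exp), 0.0)
    return 2.0 * float(term.sum())


def _g_statistic(ls: LocusSet, labels: np.ndarray) -> float:
    """Log-likelihood-ratio G summed over per-SNP population x allele
    contingency tables; ``labels`` assigns each sample to group 0/1."""
    return _g_from_onehot(_allele_onehot(ls), np.repeat(labels, 2))


def permutation_differentiation_test(
    ls: LocusSet,
    n_perm: int = 10000,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Observed G against ``n_perm`` permutations of individuals across
    populations; p = (1 + #perm >= obs) / (n_perm + 1)."""
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = rng if rng is not None else np.random.default_rng(0)
    pops = ls.populations()
    if len(pops) != 2:
        raise ValueError("exactly two populations required")
    labels = np.array([0 if ls.popmap[s] == pops[0] else 1 for s in ls.samples])
    if labels.sum() < 2 or (1 - labels).sum() < 2:
        raise ValueError("need at least two individuals per population")
    onehot = _allele_onehot(ls)
    obs = _g_from_onehot(onehot, np.repeat(labels, 2))
    hits = 0
    for _ in range(n_perm):
        perm = np.repeat(rng.permutation(labels), 2)
        if _g_from_onehot(onehot, perm) >= obs - 1e-12:
            hits += 1
    return obs, (1 + hits) / (n_perm + 1)


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional test of Hardy-Weinberg proportions.

    Enumerates all heterozygote counts compatible with the observed
    allele counts and sums the conditional probabilities of those no more
    probable than the observed configuration.  Monomorphic samples return
    p = 1 by convention.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    n_a = n_Aa + 2 * n_aa  # minor or major is irrelevant: test is symmetric
    if n == 0 or n_a == 0 or n_a == 2 * n:
        return 1.0

    def logprob(het: int) -> float:
        hom_a = (n_a - het) // 2
        hom_A = n - het - hom_a
        return (
            math.log(2.0) * het
            + gammaln(n + 1)
            - gammaln(hom_A + 1)
            - gammaln(het + 1)
            - gammaln(hom_a + 1)
            + gammaln(n_a + 1)
            + gammaln(2 * n - n_a + 1)
            - gammaln(2 * n + 1)
        )

    hets = range(n_a % 2, min(n_a, 2 * n - n_a) + 1, 2)
    lps = {h: logprob(h) for h in hets}
    lp_obs = lps[n_Aa]
    p = sum(math.exp(lp) for lp in lps.values() if lp <= lp_obs + 1e-12)
    return min(p, 1.0)


# ---------------------------------------------------------------------------
# heterozygosity summary
# ---------------------------------------------------------------------------

@dataclass
class HetSummary:
    ho_by_pop: dict[str, float]
    he_by_pop: dict[str, float]
    bartlett_stat: float
    bartlett_p: float
    paired_t: float
    paired_p_two_sided: float
    paired_p_ho_greater: float
    paired_p_ho_less: float
    unique_alleles: dict[str, int]
    n_loci_out_of_hwe: int
    hwe_p_by_snp: pd.DataFrame = field(repr=False)


def _site_ho_he(geno: np.ndarray) -> tuple[float, float]:
    """Observed het fraction and unbiased expected heterozygosity
    He = (1 - sum p^2) * 2n/(2n - 1) for one site, diploid genotypes (n, 2)."""
    n = geno.shape[0]
    ho = float((geno[:, 0] != geno[:, 1]).mean())
    _, cnt = np.unique(geno.ravel(), return_counts=True)
    p = cnt / (2 * n)
    he = (1.0 - float(np.sum(p * p))) * (2 * n) / (2 * n - 1)
    return ho, he


def heterozygosity_summary(
    ls: LocusSet,
    hwe_per_population: bool = False,
    hwe_alpha: float = 0.05,
) -> HetSummary:
    """Ho/He per population, Bartlett homogeneity of the per-locus Ho and
    He distributions, a paired t-test of Ho against He across loci (both
    one- and two-tailed p-values are reported), private-allele counts,
    and exact HWE tests per SNP (pooled populations by default)."""
    variable = ls.variable_loci()
    if len(variable) < 2:
        raise ValueError("need at least two variable loci")
    pops = ls.populations()
    idx = {p: ls.sample_indices(p) for p in pops}
    rowmap = {p: ls.haplotype_rows(p) for p in pops}

    ho_pop: dict[str, list[float]] = {p: [] for p in pops}
    he_pop: dict[str, list[float]] = {p: [] for p in pops}
    locus_ho: list[float] = []
    locus_he: list[float] = []
    unique: dict[str, int] = {p: 0 for p in pops}
    hwe_rows = []
    n_out = 0
    for loc in variable:
        site_ho, site_he = [], []
        locus_out = False
        for j in range(loc.n_snps):
            geno = loc.haplotypes[:, j].reshape(-1, 2)
            ho_all, he_all = _site_ho_he(geno)
            site_ho.append(ho_all)
            site_he.append(he_all)
            for p in pops:
                hp, ep = _site_ho_he(geno[idx[p]])
                ho_pop[p].append(hp)
                he_pop[p].append(ep)
            if len(pops) == 2:
                col = loc.haplotypes[:, j]
                s1 = set(col[rowmap[pops[0]]].tolist())
                s2 = set(col[rowmap[pops[1]]].tolist())
                unique[pops[0]] += len(s1 - s2)
                unique[pops[1]] += len(s2 - s1)
            # HWE (biallelic sites only; others are flagged non-informative)
            if hwe_per_population:
                pvals = [_hwe_site(geno[idx[p]]) for p in pops]
                pv = min(pvals)
            else:
                pv = _hwe_site(geno)
            hwe_rows.append((loc.name, int(loc.positions[j]), pv))
            if pv < hwe_alpha:
                locus_out = True
        locus_ho.append(float(np.mean(site_ho)))
        locus_he.append(float(np.mean(site_he)))
        n_out += int(locus_out)

    locus_ho_arr = np.asarray(locus_ho)
    locus_he_arr = np.asarray(locus_he)
    diffs = locus_ho_arr - locus_he_arr
    if locus_ho_arr.var() == 0.0 and locus_he_arr.var() == 0.0:
        bstat, bp = 0.0, 1.0  # equal (zero) variances: homogeneous
    else:
        bstat, bp = sps.bartlett(locus_ho_arr, locus_he_arr)
    if np.allclose(diffs.std(), 0.0):
        t = 0.0 if np.allclose(diffs, 0.0) else math.copysign(math.inf, diffs.mean())
        p2 = 1.0 if t == 0.0 else 0.0
    else:
        t, p2 = sps.ttest_rel(locus_ho_arr, locus_he_arr)
    p_greater = sps.t.sf(t, len(locus_ho_arr) - 1) if len(locus_ho_arr) > 1 else 1.0
    return HetSummary(
        ho_by_pop={p: float(np.mean(ho_pop[p])) for p in pops},
        he_by_pop={p: float(np.mean(he_pop[p])) for p in pops},
        bartlett_stat=float(bstat),
        bartlett_p=float(bp),
        paired_t=float(t),
        paired_p_two_sided=float(p2),
        paired_p_ho_greater=float(p_greater),
        paired_p_ho_less=float(1.0 - p_greater),
        unique_alleles=unique,
        n_loci_out_of_hwe=n_out,
        hwe_p_by_snp=pd.DataFrame(hwe_rows, columns=["locus", "pos", "hwe_p"]),
    )


def _hwe_site(geno: np.ndarray) -> float:
    alleles = np.unique(geno.ravel())
    if len(alleles) == 1:
        return 1.0
    if len(alleles) > 2:
        return 1.0  # non-biallelic: flagged non-informative
    a = alleles[1]
    n_copies = (geno == a).sum(axis=1)
    return hwe_exact_test(
        int((n_copies == 0).sum()), int((n_copies == 1).sum()), int((n_copies == 2).sum())
    )


# ---------------------------------------------------------------------------
# DAPC-style assignment
# ---------------------------------------------------------------------------

@dataclass
class AssignmentResult:
    posteriors: pd.DataFrame  # individuals x populations
    diagnosability: float  # fraction assigned to their labelled population
    cross_validated: bool = False


def _dosage_matrix(ls: LocusSet) -> np.ndarray:
    cols = []
    for loc in ls.variable_loci():
        for j in range(loc.n_snps):
            col = loc.haplotypes[:, j]
            ref = col.max()  # orientation is irrelevant after centring
            cols.append((col.reshape(-1, 2) == ref).sum(axis=1))
    if not cols:
        raise ValueError("no SNPs available for assignment")
    return np.asarray(cols, dtype=float).T  # individuals x SNPs


def assign_individuals(
    ls: LocusSet,
    n_pcs: int = 4,
    cross_validated: bool = False,
    rng: np.random.Generator | None = None,
) -> AssignmentResult:
    """Project centred allele dosages onto ``n_pcs`` principal components
    and fit a linear discriminant between the two labelled groups.

    The default reports in-sample posteriors, as group-membership
    probabilities are conventionally reported for this analysis; with so
    few individuals this overstates separability, so
    ``cross_validated=True`` instead scores each individual from a model
    trained without it (leave-one-out) — the honest null behaviour.
    """
    from sklearn.decomposition import PCA
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

    if n_pcs >= ls.n_samples:
        raise ValueError("n_pcs must be smaller than the number of individuals")
    pops = ls.populations()
    if len(pops) != 2:
        raise ValueError("exactly two populations required")
    dosage = _dosage_matrix(ls)
    labels = np.array([ls.popmap[s] for s in ls.samples])

    def fit_predict(train: np.ndarray, test: np.ndarray):
        X = dosage[train] - dosage[train].mean(axis=0)
        pca = PCA(n_components=min(n_pcs, len(train) - 1), svd_solver="full").fit(X)
        lda = LinearDiscriminantAnalysis().fit(pca.transform(X), labels[train])
        Xt = dosage[test] - dosage[train].mean(axis=0)
        return lda.predict_proba(pca.transform(Xt)), lda.classes_

    n = ls.n_samples
    if not cross_validated:
        post, classes = fit_predict(np.arange(n), np.arange(n))
    else:
        post = np.empty((n, 2))
        for i in range(n):
            train = np.delete(np.arange(n), i)
            p, classes = fit_predict(train, np.array([i]))
            post[i] = p[0]
    posteriors = pd.DataFrame(post, index=ls.samples, columns=classes)
    assigned = classes[np.argmax(post, axis=1)]
    return AssignmentResult(
        posteriors=posteriors,
        diagnosability=float((assigned == labels).mean()),
        cross_validated=cross_validated,
    )
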