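"""SNP preparation and the folded joint site frequency spectrum.

The demographic inference consumes one biallelic SNP per locus (to keep
sites approximately unlinked), with Z-flagged loci excluded (sex-linked
loci have a different inheritance scalar).  Because no outgroup is
available to polarize alleles, the spectrum is folded: a SNP with
arbitrary-orientation counts ``(i, j)`` in the two populations is pooled
with its complement ``(n1 - i, n2 - j)``, cells on the half-total diagonal
receiving half mass each (the dadi convention), and the redundant half of
the grid plus the two monomorphic corners are masked.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .loci import LocusSet

__all__ = [
    "SNPMatrix",
    "JointSFS",
    "JackknifeSet",
    "prepare_snp_matrix",
    "build_folded_joint_sfs",
    "jackknife_datasets",
    "read_sfs",
    "write_sfs",
]


@dataclass
class SNPMatrix:
    """One biallelic SNP per retained locus: arbitrary-orientation allele
    counts per population (``counts[k] = (i, j)``, with ``0 < i + j <
    n1 + n2``) plus a log of the loci dropped at each preparation step."""

    locus_names: list[str]
    counts: np.ndarray  # (n_loci, 2) int64
    n1: int
    n2: int
    dropped: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[1] != 2:
            raise ValueError("counts must be (n_loci, 2)")
        tot = self.counts.sum(axis=1)
        bad = (
            (self.counts[:, 0] < 0)
            | (self.counts[:, 0] > self.n1)
            | (self.counts[:, 1] < 0)
            | (self.counts[:, 1] > self.n2)
            | (tot <= 0)
            | (tot >= self.n1 + self.n2)
        )
        if np.any(bad):
            raise ValueError(f"invalid allele counts at rows {np.nonzero(bad)[0].tolist()}")

    @property
    def n_snps(self) -> int:
        return len(self.locus_names)


@dataclass
class JointSFS:
    """A two-dimensional SFS on an ``(n1+1, n2+1)`` grid with a mask.

    ``mask[i, j] = True`` marks cells excluded from likelihoods: the two
    monomorphic corners always, plus the redundant half when folded.
    Masked cells hold zero mass so folding is an exact idempotent map.
    """

    data: np.ndarray
    mask: np.ndarray
    folded: bool
    n1: int
    n2: int

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        expect = (self.n1 + 1, self.n2 + 1)
        if self.data.shape != expect or self.mask.shape != expect:
            raise ValueError(f"grid must have shape {expect}")
        if np.any(self.data < 0):
            raise ValueError("SFS entries must be non-negative")
        self.data = np.where(self.mask, 0.0, self.data)

    @property
    def mass(self) -> float:
        """Total unmasked mass (equals the SNP count for a data SFS)."""
        return float(self.data[~self.mask].sum())

    def copy(self) -> "JointSFS":
        return JointSFS(self.data.copy(), self.mask.copy(), self.folded, self.n1, self.n2)

    def fold(self) -> "JointSFS":
        """Fold onto minor-allele orientation (identity if already folded)."""
        S = self.n1 + self.n2
        tot = np.add.outer(np.arange(self.n1 + 1), np.arange(self.n2 + 1))
        folded = self.data + self.data[::-1, ::-1]
        folded[tot == S / 2.0] *= 0.5
        mask = (tot > S / 2.0) | _corner_mask(self.n1, self.n2)
        folded = np.where(mask, 0.0, folded)
        return JointSFS(folded, mask, True, self.n1, self.n2)


def _corner_mask(n1: int, n2: int) -> np.ndarray:
    mask = np.zeros((n1 + 1, n2 + 1), dtype=bool)
    mask[0, 0] = True
    mask[n1, n2] = True
    return mask


def prepare_snp_matrix(
    ls: LocusSet,
    z_policy: str = "exclude",
    thinning: str = "random",
    rng: np.random.Generator | None = None,
) -> SNPMatrix:
    """Reduce a LocusSet to one biallelic SNP per locus.

    Order of operations: Z exclusion (by annotation flag) -> biallelic
    filter (a locus carrying any site with more than two alleles is
    dropped entirely) -> thinning to one SNP per locus (``random`` with a
    seeded generator, or ``first`` = smallest position).  Counts dropped
    at each step are recorded in ``dropped``.
    """
    if z_policy not in ("exclude", "keep"):
        raise ValueError("z_policy must be 'exclude' or 'keep'")
    if thinning not in ("first", "random"):
        raise ValueError("thinning must be 'first' or 'random'")
    if thinning == "random" and rng is None:
        rng = np.random.default_rng(0)
    pops = ls.populations()
    if len(pops) != 2:
        raise ValueError("exactly two populations required")
    rows1, rows2 = ls.haplotype_rows(pops[0]), ls.haplotype_rows(pops[1])

    dropped = {"z_linked": 0, "multiallelic": 0, "monomorphic": 0, "invariant": 0}
    names: list[str] = []
    counts: list[tuple[int, int]] = []
    for loc in ls.loci:
        if not loc.is_variable:
            dropped["invariant"] += 1
            continue
        if z_policy == "exclude" and loc.chrom_class == "Z":
            dropped["z_linked"] += 1
            continue
        n_alleles = np.array([len(np.unique(loc.haplotypes[:, j])) for j in range(loc.n_snps)])
        if np.any(n_alleles > 2):
            dropped["multiallelic"] += 1
            continue
        poly = np.nonzero(n_alleles == 2)[0]
        if len(poly) == 0:
            dropped["monomorphic"] += 1
            continue
        j = int(poly[0]) if thinning == "first" else int(rng.choice(poly))
        col = loc.haplotypes[:, j]
        alt = int(col.max())  # the higher-coded allele; orientation is arbitrary
        names.append(loc.name)
        counts.append((int((col[rows1] == alt).sum()), int((col[rows2] == alt).sum())))
    if not names:
        raise ValueError("no usable SNPs after filtering")
    return SNPMatrix(
        locus_names=names,
        counts=np.asarray(counts, dtype=np.int64),
        n1=len(rows1),
        n2=len(rows2),
        dropped=dropped,
    )


def build_folded_joint_sfs(m: SNPMatrix) -> JointSFS:
    """Bin the SNP counts onto the grid and fold."""
    grid = np.zeros((m.n1 + 1, m.n2 + 1))
    np.add.at(grid, (m.counts[:, 0], m.counts[:, 1]), 1.0)
    unfolded = JointSFS(grid, _corner_mask(m.n1, m.n2), False, m.n1, m.n2)
    return unfolded.fold()


@dataclass
class JackknifeSet:
    """Delete-m jackknife replicates: loci partitioned into ``g`` blocks,
    replicate *r* holding the folded SFS of all loci outside block *r*."""

    replicates: list[JointSFS]
    block_sizes: list[int]
    assignment: np.ndarray  # block index per locus

    @property
    def n_blocks(self) -> int:
        return len(self.replicates)


def jackknife_datasets(
    m: SNPMatrix,
    n_reps: int = 10,
    rng: np.random.Generator | None = None,
) -> JackknifeSet:
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    if n_reps > m.n_snps:
        raise ValueError("more jackknife blocks than loci")
    rng = rng if rng is not None else np.random.default_rng(0)
    order = rng.permutation(m.n_snps)
    assignment = np.empty(m.n_snps, dtype=np.int64)
    # near-equal block sizes: positions in a shuffled order, striped
    assignment[order] = np.arange(m.n_snps) % n_reps
    reps = []
    sizes = []
    for r in range(n_reps):
        keep = assignment != r
        sub = SNPMatrix(
            locus_names=[nm for nm, k in zip(m.locus_names, keep) if k],
            counts=m.counts[keep],
            n1=m.n1,
            n2=m.n2,
        )
        reps.append(build_folded_joint_sfs(sub))
        sizes.append(int((~keep).sum()))
    return JackknifeSet(replicates=reps, block_sizes=sizes, assignment=assignment)


# ---------------------------------------------------------------------------
# text dialect
# ---------------------------------------------------------------------------

def write_sfs(sfs: JointSFS, path: str | os.PathLike) -> None:
    """Three-line text format: 'd1 d2 folded|unfolded', row-major masses
    (shortest round-tripping float repr), row-major mask bits (1=masked)."""
    with open(path, "w") as fh:
        fh.write(f"{sfs.n1 + 1} {sfs.n2 + 1} {'folded' if sfs.folded else 'unfolded'}\n")
        fh.write(" ".join(repr(float(x)) for x in sfs.data.ravel()) + "\n")
        fh.write(" ".join("1" if b else "0" for b in sfs.mask.ravel()) + "\n")


def read_sfs(path: str | os.PathLike) -> JointSFS:
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) != 3 or header[2] not in ("folded", "unfolded"):
            raise ValueError(f"{path}: bad SFS header")
        d1, d2 = int(header[0]), int(header[1])
        data = np.array(fh.readline().split(), dtype=float).reshape(d1, d2)
        mask = np.array(fh.readline().split(), dtype=int).astype(bool).reshape(d1, d2)
    return JointSFS(data, mask, header[2] == "folded", d1 - 1, d2 - 1)
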