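"""Multi-locus phased genotype container and on-disk formats.

The unit of analysis is a locus: a stretch of sequence (UCE-like, ~1 kb)
carrying zero or more biallelic-or-more SNPs, with fully phased genotypes
for every sample (no missing data is permitted — the container mirrors a
complete data matrix).  A :class:`LocusSet` bundles the loci with the
sample -> population map and is what every statistic consumes.

On disk a dataset is three text files:

* a VCF v4.2 with ``CHROM`` = locus name, phased ``GT`` and a ``GQ`` field;
* a two-column popmap TSV ``sample<TAB>population``;
* an annotation TSV ``locus<TAB>length_bp<TAB>chrom_class`` with
  ``chrom_class`` in ``{autosome, Z}``.  Loci present in the annotation but
  absent from the VCF are invariant loci (no SNPs, genotypes all reference).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Locus",
    "LocusSet",
    "read_popmap",
    "write_popmap",
    "read_annotation",
    "write_annotation",
    "read_vcf",
    "write_vcf",
    "read_dataset",
]

_ALLELE_CODES = "ACGT"


@dataclass
class Locus:
    """One locus: positions (1-based, strictly increasing) and a phased
    haplotype matrix of shape ``(2 * n_samples, n_snps)`` with integer
    allele codes.  Sample *i* owns rows ``2i`` and ``2i + 1``."""

    name: str
    length_bp: int
    chrom_class: str = "autosome"
    positions: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    haplotypes: np.ndarray = field(default_factory=lambda: np.empty((0, 0), dtype=np.int8))

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        if self.length_bp <= 0:
            raise ValueError(f"locus {self.name}: length_bp must be positive")
        if self.chrom_class not in ("autosome", "Z"):
            raise ValueError(f"locus {self.name}: bad chrom_class {self.chrom_class!r}")
        if self.haplotypes.ndim != 2 or self.haplotypes.shape[1] != len(self.positions):
            raise ValueError(f"locus {self.name}: haplotype/position shape mismatch")
        if len(self.positions) and (
            np.any(np.diff(self.positions) <= 0)
            or self.positions[0] < 1
            or self.positions[-1] > self.length_bp
        ):
            raise ValueError(f"locus {self.name}: positions must be strictly increasing in [1, length]")

    @property
    def n_snps(self) -> int:
        return len(self.positions)

    @property
    def is_variable(self) -> bool:
        return self.n_snps > 0


@dataclass
class LocusSet:
    """A set of loci plus the popmap.  Haplotype row order is fixed by the
    ``samples`` list; every sample must map to exactly one population."""

    loci: list[Locus]
    samples: list[str]
    popmap: dict[str, str]

    def __post_init__(self) -> None:
        missing = [s for s in self.samples if s not in self.popmap]
        if missing:
            raise ValueError(f"samples missing from popmap: {missing}")
        n_rows = 2 * len(self.samples)
        for loc in self.loci:
            if loc.haplotypes.shape[0] != n_rows:
                raise ValueError(
                    f"locus {loc.name}: {loc.haplotypes.shape[0]} haplotype rows, expected {n_rows}"
                )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def populations(self) -> list[str]:
        """Population names in sorted order (deterministic)."""
        return sorted(set(self.popmap[s] for s in self.samples))

    def haplotype_rows(self, population: str) -> np.ndarray:
        """Haplotype row indices belonging to one population."""
        rows = []
        for i, s in enumerate(self.samples):
            if self.popmap[s] == population:
                rows.extend((2 * i, 2 * i + 1))
        return np.asarray(rows, dtype=np.int64)

    def sample_indices(self, population: str) -> np.ndarray:
        return np.asarray(
            [i for i, s in enumerate(self.samples) if self.popmap[s] == population],
            dtype=np.int64,
        )

    def variable_loci(self) -> list[Locus]:
        return [loc for loc in self.loci if loc.is_variable]

    def total_length_bp(self, include_invariant: bool = True) -> int:
        return sum(loc.length_bp for loc in self.loci if include_invariant or loc.is_variable)

    def subset(self, loci: list[Locus]) -> "LocusSet":
        return LocusSet(loci=loci, samples=list(self.samples), popmap=dict(self.popmap))


# ---------------------------------------------------------------------------
# popmap / annotation TSVs
# ---------------------------------------------------------------------------

def read_popmap(path: str | os.PathLike) -> dict[str, str]:
    popmap: dict[str, str] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{ln}: expected 'sample<TAB>population'")
            popmap[parts[0]] = parts[1]
    if not popmap:
        raise ValueError(f"{path}: empty popmap")
    return popmap


def write_popmap(popmap: dict[str, str], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for sample, pop in popmap.items():
            fh.write(f"{sample}\t{pop}\n")


def read_annotation(path: str | os.PathLike) -> dict[str, tuple[int, str]]:
    """Return ``{locus: (length_bp, chrom_class)}`` preserving file order."""
    ann: dict[str, tuple[int, str]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("locus\t"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{ln}: expected 'locus<TAB>length_bp<TAB>chrom_class'")
            ann[parts[0]] = (int(parts[1]), parts[2])
    return ann


def write_annotation(loci: list[Locus], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("locus\tlength_bp\tchrom_class\n")
        for loc in loci:
            fh.write(f"{loc.name}\t{loc.length_bp}\t{loc.chrom_class}\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def write_vcf(ls: LocusSet, path: str | os.PathLike) -> None:
    """Write the variable loci of ``ls`` as a phased VCF v4.2 text file."""
    lines = [
        "##fileformat=VCFv4.2",
        "##source=ucepop",
    ]
    for loc in ls.loci:
        lines.append(f"##contig=<ID={loc.name},length={loc.length_bp}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype Quality">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(ls.samples)
    )
    for loc in ls.loci:
        for j in range(loc.n_snps):
            col = loc.haplotypes[:, j]
            alleles = sorted(set(int(a) for a in col))
            ref = alleles[0]
            alts = alleles[1:]
            if not alts:
                continue  # monomorphic column: not a variant record
            index = {a: k for k, a in enumerate(alleles)}
            fields = [
                loc.name,
                str(int(loc.positions[j])),
                ".",
                _ALLELE_CODES[ref],
                ",".join(_ALLELE_CODES[a] for a in alts),
                ".",
                "PASS",
                ".",
                "GT:GQ",
            ]
            for i in range(ls.n_samples):
                a, b = index[int(col[2 * i])], index[int(col[2 * i + 1])]
                fields.append(f"{a}|{b}:99")
            lines.append("\t".join(fields))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_vcf(
    vcf_path: str | os.PathLike,
    popmap: dict[str, str],
    annotation: dict[str, tuple[int, str]],
) -> LocusSet:
    """Read a phased VCF into a :class:`LocusSet`.

    Missing genotypes are rejected (the pipeline requires a complete
    matrix).  Annotated loci with no VCF records become invariant loci.
    """
    from cyvcf2 import VCF  # deferred: cheap import elsewhere

    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    per_locus: dict[str, list[tuple[int, np.ndarray]]] = {}
    for rec in vcf:
        gts = rec.genotype.array()  # (n_samples, ploidy + 1); last col = phased flag
        if np.any(gts[:, :2] < 0):
            raise ValueError(f"missing genotype at {rec.CHROM}:{rec.POS}; complete matrix required")
        hap = np.empty(2 * len(samples), dtype=np.int8)
        hap[0::2] = gts[:, 0]
        hap[1::2] = gts[:, 1]
        per_locus.setdefault(rec.CHROM, []).append((rec.POS, hap))
    loci: list[Locus] = []
    for name, (length, cclass) in annotation.items():
        recs = sorted(per_locus.pop(name, []), key=lambda t: t[0])
        if recs:
            positions = np.asarray([p for p, _ in recs], dtype=np.int64)
            haps = np.stack([h for _, h in recs], axis=1)
        else:
            positions = np.empty(0, dtype=np.int64)
            haps = np.empty((2 * len(samples), 0), dtype=np.int8)
        loci.append(Locus(name, length, cclass, positions, haps))
    if per_locus:
        raise ValueError(f"VCF loci missing from annotation: {sorted(per_locus)}")
    return LocusSet(loci=loci, samples=samples, popmap=popmap)


def read_dataset(
    vcf_path: str | os.PathLike,
    popmap_path: str | os.PathLike,
    annotation_path: str | os.PathLike,
) -> LocusSet:
    """Convenience loader: VCF + popmap TSV + annotation TSV -> LocusSet."""
    popmap = read_popmap(popmap_path)
    annotation = read_annotation(annotation_path)
    return read_vcf(vcf_path, popmap, annotation)
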