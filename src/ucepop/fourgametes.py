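"""Four-gamete recombination detection and non-recombinant filtering.

Two biallelic sites are four-gamete incompatible when all four gametic
combinations occur among the haplotypes: under infinite sites this
requires recombination between them.  For each locus the filter produces
a non-recombinant sub-dataset in the spirit of IMgc, either by trimming
to a contiguous window of pairwise-compatible sites, by removing a small
number of individuals, or both.

The objective (IMgc's internal weighting is not published) is to maximise
retained haplotype-sites — retained haplotype rows times retained SNP
columns — over all contiguous site windows crossed with all removal sets
of at most ``max_remove`` individuals, preferring trimming alone unless a
removal strictly improves the score.  Ties break toward the window with
the smaller start and the removal set earliest in sample order, making
the filter deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .loci import Locus, LocusSet

__all__ = [
    "LocusFilterReport",
    "FilteredLocus",
    "four_gamete_compatible",
    "incompatible_pairs",
    "filter_locus_fourgametes",
    "filter_locus_set",
    "recombination_summary",
]


def four_gamete_compatible(site_a: np.ndarray, site_b: np.ndarray) -> bool:
    """False iff all four gametic combinations occur.  Both columns must
    be biallelic over the same haplotype rows."""
    for col in (site_a, site_b):
        k = len(np.unique(col))
        if k < 2:
            raise ValueError("monomorphic column: pre-filter before testing")
        if k > 2:
            raise ValueError("four-gamete test requires biallelic sites")
    gametes = {(int(a), int(b)) for a, b in zip(site_a, site_b)}
    return len(gametes) < 4


def _pair_ok(a: np.ndarray, b: np.ndarray) -> bool:
    """Compatibility with monomorphic columns treated as trivially
    compatible (used internally after row removal)."""
    if len(np.unique(a)) < 2 or len(np.unique(b)) < 2:
        return True
    return len({(int(x), int(y)) for x, y in zip(a, b)}) < 4


def incompatible_pairs(haplotypes: np.ndarray) -> list[tuple[int, int]]:
    """All incompatible site-index pairs in a haplotype matrix."""
    S = haplotypes.shape[1]
    return [
        (i, j)
        for i in range(S)
        for j in range(i + 1, S)
        if not _pair_ok(haplotypes[:, i], haplotypes[:, j])
    ]


@dataclass
class LocusFilterReport:
    locus: str
    n_snps: int
    incompatible_pairs: list[tuple[int, int]]
    action: str  # none | trimmed | individuals_removed | both
    window: tuple[int, int]  # retained site-index span (inclusive)
    removed: list[str]  # removed sample (or haplotype) names
    retained_haplotype_sites: int


@dataclass
class FilteredLocus:
    """A per-locus non-recombinant alignment; individual removal is per
    locus, so this deliberately does not promise a rectangular dataset."""

    name: str
    positions: np.ndarray
    haplotypes: np.ndarray
    kept_samples: list[str]


def _best_window(haps: np.ndarray) -> tuple[int, int, int]:
    """Largest contiguous pairwise-compatible window: returns
    (start, stop_inclusive, width); ties toward the smaller start."""
    S = haps.shape[1]
    if S == 0:
        return 0, -1, 0
    compat = np.ones((S, S), dtype=bool)
    for i in range(S):
        for j in range(i + 1, S):
            compat[i, j] = compat[j, i] = _pair_ok(haps[:, i], haps[:, j])
    best = (0, 0, 1)
    start = 0
    for stop in range(S):
        # shrink until column `stop` is compatible with the whole window
        while start < stop and not compat[start:stop, stop].all():
            start += 1
        width = stop - start + 1
        if width > best[2]:
            best = (start, stop, width)
    return best


def filter_locus_fourgametes(
    locus: Locus,
    samples: list[str],
    max_remove: int = 2,
    unit: str = "individual",
) -> tuple[FilteredLocus, LocusFilterReport]:
    """Resolve four-gamete incompatibilities for one locus.

    ``unit='individual'`` removes both haplotypes of a sample together
    (the default, matching per-individual removal on phased data);
    ``unit='haplotype'`` removes single sequences.
    """
    if unit not in ("individual", "haplotype"):
        raise ValueError("unit must be 'individual' or 'haplotype'")
    haps = locus.haplotypes
    n_rows, S = haps.shape
    bad = incompatible_pairs(haps)
    if not bad:
        return (
            FilteredLocus(locus.name, locus.positions.copy(), haps.copy(), list(samples)),
            LocusFilterReport(locus.name, S, [], "none", (0, S - 1), [], n_rows * S),
        )

    if unit == "individual":
        units = list(range(len(samples)))
        unit_rows = {u: (2 * u, 2 * u + 1) for u in units}
        unit_names = {u: samples[u] for u in units}
    else:
        units = list(range(n_rows))
        unit_rows = {u: (u,) for u in units}
        unit_names = {u: f"{samples[u // 2]}.{u % 2}" for u in units}

    best_score = -1
    best_choice: tuple[tuple[int, ...], tuple[int, int, int]] | None = None
    for k in range(0, max_remove + 1):
        for removal in combinations(units, k):
            drop_rows = [r for u in removal for r in unit_rows[u]]
            keep = np.setdiff1d(np.arange(n_rows), drop_rows)
            w = _best_window(haps[keep])
            score = len(keep) * w[2]
            better = score > best_score
            # prefer trimming alone unless removal strictly improves;
            # among equal removals, combinations() order = sample order
            if better:
                best_score = score
                best_choice = (removal, w)
    assert best_choice is not None
    removal, (start, stop, width) = best_choice
    drop_rows = [r for u in removal for r in unit_rows[u]]
    keep = np.setdiff1d(np.arange(n_rows), drop_rows)
    trimmed = width < S
    removed_names = [unit_names[u] for u in removal]
    action = (
        "both"
        if trimmed and removal
        else "trimmed"
        if trimmed
        else "individuals_removed"
        if removal
        else "none"
    )
    kept_samples = [s for i, s in enumerate(samples) if unit != "individual" or i not in removal]
    out = FilteredLocus(
        locus.name,
        locus.positions[start : stop + 1].copy(),
        haps[np.ix_(keep, np.arange(start, stop + 1))],
        kept_samples,
    )
    report = LocusFilterReport(
        locus.name, S, bad, action, (start, stop), removed_names, best_score
    )
    return out, report


def filter_locus_set(
    ls: LocusSet,
    max_remove: int = 2,
    unit: str = "individual",
) -> tuple[list[FilteredLocus], pd.DataFrame]:
    """Apply the four-gamete filter to every variable locus with >= 2
    SNPs (fewer SNPs cannot be incompatible); returns the filtered loci
    and a per-locus report table."""
    filtered = []
    rows = []
    for loc in ls.loci:
        if loc.n_snps < 2:
            filtered.append(
                FilteredLocus(loc.name, loc.positions.copy(), loc.haplotypes.copy(), list(ls.samples))
            )
            rows.append((loc.name, loc.n_snps, 0, "none", loc.n_snps, ""))
            continue
        floc, rep = filter_locus_fourgametes(loc, ls.samples, max_remove, unit)
        filtered.append(floc)
        rows.append(
            (
                loc.name,
                loc.n_snps,
                len(rep.incompatible_pairs),
                rep.action,
                rep.window[1] - rep.window[0] + 1,
                ",".join(rep.removed),
            )
        )
    report = pd.DataFrame(
        rows,
        columns=["locus", "n_snps", "n_incompatible_pairs", "action", "n_snps_retained", "removed"],
    )
    return filtered, report


def recombination_summary(report: pd.DataFrame) -> dict[str, float]:
    """Tallies over the per-locus filter report."""
    action = report["action"]
    n = len(report)
    n_trim = int(((action == "trimmed") | (action == "both")).sum())
    n_rem = int(((action == "individuals_removed") | (action == "both")).sum())
    n_both = int((action == "both").sum())
    n_aff = int((action != "none").sum())
    return {
        "n_loci": n,
        "n_trimmed": n_trim,
        "n_individuals_removed": n_rem,
        "n_both": n_both,
        "n_affected": n_aff,
        "proportion_affected": n_aff / n if n else 0.0,
    }
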