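"""Calibration and conversion of diffusion-unit parameters to biology.

The SFS fit returns parameters in diffusion units: sizes ``nu_i``
relative to the ancestral ``Nref``, split time ``T`` in ``2 Nref``
generations, migration ``m = 2 Nref x`` per-generation fraction, and the
spectrum scale ``theta = 4 Nref mu_gen L``.  Given a per-site per-year
substitution rate (calibrated from outgroup divergence over ``2 x
TMRCA`` years), a generation time ``G = alpha + s/(1 - s)`` (alpha = age
at first breeding, s = annual adult survival), and the surveyed length
``L``, the conversions are::

    mu_gen  = rate_per_year * G
    Nref    = theta / (4 * mu_gen * L)
    N_i     = nu_i * Nref
    T_years = T * 2 * Nref * G
    M_i     = m_i * nu_i / 2        (migrants into population i
                                     per generation; N_i times the
                                     per-generation migrant fraction)

Confidence-interval endpoints are passed through the same (monotone)
maps.  Note ``Nref``, ``N_i`` and ``T_years`` scale with 1/mu while the
migrant numbers are unaffected by the substitution rate.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "RateCalibration",
    "BioUnits",
    "substitution_rate",
    "average_rate",
    "generation_time",
    "convert_parameters",
    "dedupe_hit_table",
    "HIT_TABLE_COLUMNS",
]


def substitution_rate(substitutions: float, sites: float, tmrca_years: float) -> float:
    """Per-site per-year rate: (substitutions/sites) / (2 * TMRCA).

    The divergence accumulates along both branches since the common
    ancestor, hence the ``2 x TMRCA`` total time."""
    if sites <= 0:
        raise ValueError("sites must be positive")
    if tmrca_years <= 0:
        raise ValueError("TMRCA must be positive")
    if substitutions < 0 or substitutions > sites:
        raise ValueError("substitutions must lie in [0, sites]")
    return (substitutions / sites) / (2.0 * tmrca_years)


def average_rate(rates: list[float]) -> float:
    """Arithmetic mean of per-comparison rates."""
    if not rates:
        raise ValueError("need at least one rate")
    if any(r < 0 for r in rates):
        raise ValueError("rates must be non-negative")
    return sum(rates) / len(rates)


def generation_time(alpha: float, s: float) -> float:
    """G = alpha + s / (1 - s); alpha = age at first breeding (years),
    s = annual adult survival probability."""
    if not 0.0 <= s < 1.0:
        raise ValueError("survival s must lie in [0, 1)")
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    return alpha + s / (1.0 - s)


@dataclass(frozen=True)
class RateCalibration:
    """Substitution-rate calibration: per-site per-year rate and the
    generation time used to express it per generation."""

    rate_per_year: float
    generation_time_years: float

    def __post_init__(self) -> None:
        if self.rate_per_year <= 0 or self.generation_time_years <= 0:
            raise ValueError("rate and generation time must be positive")

    @property
    def mu_per_generation(self) -> float:
        return self.rate_per_year * self.generation_time_years


@dataclass
class BioUnits:
    """Fitted parameters in biological units (individuals, years,
    migrants per generation)."""

    Nref: float
    N1: float
    N2: float
    T_years: float
    migrants_1: float
    migrants_2: float
    L_bp: float
    ci: dict[str, tuple[float, float]] | None = None

    def as_table(self) -> pd.DataFrame:
        rows = []
        for name in ("Nref", "N1", "N2", "T_years", "migrants_1", "migrants_2"):
            lo, hi = (self.ci or {}).get(name, (float("nan"), float("nan")))
            rows.append({"parameter": name, "estimate": getattr(self, name), "ci_lower": lo, "ci_upper": hi})
        return pd.DataFrame(rows)


def convert_parameters(
    theta: float,
    nu1: float,
    nu2: float,
    T: float,
    m12: float,
    m21: float,
    cal: RateCalibration,
    L: float,
    ci: dict[str, tuple[float, float]] | None = None,
) -> BioUnits:
    """Translate diffusion-unit estimates into biological units.

    ``ci`` optionally maps diffusion-unit parameter names (``theta``,
    ``nu1``, ``nu2``, ``T``, ``m``/``m12``/``m21``) to (lower, upper)
    endpoints; each is pushed through the same conversion holding the
    other printed inputs at their point estimates.
    """
    if min(theta, nu1, nu2, T) <= 0 or min(m12, m21) < 0:
        raise ValueError("diffusion parameters out of range")
    if L <= 0:
        raise ValueError("surveyed length L must be positive")
    mu_gen = cal.mu_per_generation
    g = cal.generation_time_years
    nref = theta / (4.0 * mu_gen * L)
    out = BioUnits(
        Nref=nref,
        N1=nu1 * nref,
        N2=nu2 * nref,
        T_years=T * 2.0 * nref * g,
        migrants_1=m12 * nu1 / 2.0,
        migrants_2=m21 * nu2 / 2.0,
        L_bp=L,
    )
    if ci:
        def get(name: str, fallback: str | None = None) -> tuple[float, float] | None:
            return ci.get(name) or (ci.get(fallback) if fallback else None)

        conv: dict[str, tuple[float, float]] = {}
        if "theta" in ci:
            tl, th = ci["theta"]
            conv["Nref"] = (tl / (4 * mu_gen * L), th / (4 * mu_gen * L))
            conv["N1"] = (nu1 * conv["Nref"][0], nu1 * conv["Nref"][1])
            conv["N2"] = (nu2 * conv["Nref"][0], nu2 * conv["Nref"][1])
        if "T" in ci:
            conv["T_years"] = tuple(x * 2.0 * nref * g for x in ci["T"])
        mi1 = get("m12", "m")
        mi2 = get("m21", "m")
        if mi1:
            conv["migrants_1"] = tuple(x * nu1 / 2.0 for x in mi1)
        if mi2:
            conv["migrants_2"] = tuple(x * nu2 / 2.0 for x in mi2)
        out.ci = conv
    return out


# ---------------------------------------------------------------------------
# alignment hit-table reduction
# ---------------------------------------------------------------------------

HIT_TABLE_COLUMNS = [
    "query",
    "subject",
    "identity",
    "length",
    "mismatches",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
]


def dedupe_hit_table(path_or_buffer: str | os.PathLike | io.IOBase) -> tuple[int, int]:
    """Reduce a 12-column tabular alignment hit table (CSV or TSV,
    auto-detected, no header) to totals for a rate calibration.

    Keeps the single best hit per query locus (highest bit score; ties
    by lowest E-value then file order) and returns
    ``(total aligned bp, total substitutions)``, where substitutions are
    the per-row mismatch counts (gaps excluded).
    """
    df = pd.read_csv(
        path_or_buffer,
        sep=None,
        engine="python",
        header=None,
        names=HIT_TABLE_COLUMNS,
        comment="#",
    )
    if df.shape[1] != 12 or df.empty:
        raise ValueError("expected a non-empty 12-column hit table")
    for col in ("length", "mismatches", "evalue", "bitscore"):
        bad = pd.to_numeric(df[col], errors="coerce").isna()
        if bad.any():
            raise ValueError(f"malformed hit-table rows (column {col}): {df.index[bad].tolist()}")
        df[col] = pd.to_numeric(df[col])
    df = df.sort_values(
        ["query", "bitscore", "evalue"], ascending=[True, False, True], kind="stable"
    )
    best = df.drop_duplicates("query", keep="first")
    return int(best["length"].sum()), int(best["mismatches"].sum())
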