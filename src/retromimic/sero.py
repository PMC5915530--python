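"""Serology statistics: ELISA titration tests and serum-stability fits.

ELISA titrations are serial two-fold dilutions of each animal's serum
read as OD450. For each dilution point, pre- and post-immunization
bleeds are compared with an exact Mann-Whitney test (no multiplicity
correction across dilutions — each dilution point is tested on its own
at the stated level, and the report therefore also states the smallest
attainable exact p so borderline calls are interpretable: with 4 animals
per group the two-sided exact p can never go below 2/70 ≈ 0.0286).

Serum-stability time courses (% intact peptide vs hours) are fitted with
a one-phase exponential decay for protease-sensitive L-peptides and a
zero-slope (constant) model for protease-resistant D-peptides; the
residual sums of squares let the two descriptions be contrasted.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import rankdata

from .errors import InputError, NumericalError

PLATE_COLUMNS = ["group", "bleed", "animal_id", "dilution_factor", "od450"]
MAX_EXACT_POOL = 25  # exact enumeration bound on m + n


# ---------------------------------------------------------------------------
# Titration data


@dataclass
class TitrationSeries:
    """Per-animal OD450 versus serial dilution for one group and bleed."""

    group: str
    bleed: str
    data: pd.DataFrame  # animal_id, dilution_factor, od450

    def __post_init__(self) -> None:
        missing = [
            c
            for c in ("animal_id", "dilution_factor", "od450")
            if c not in self.data.columns
        ]
        if missing:
            raise InputError(f"titration data missing columns: {missing}")
        if (self.data["od450"] < 0).any():
            raise InputError("OD450 readings must be non-negative")
        grid = np.sort(self.data["dilution_factor"].unique())
        if len(grid) > 1 and not np.allclose(grid[1:] / grid[:-1], 2.0):
            raise InputError(
                "dilution factors must form a two-fold serial dilution"
            )
        per_animal = self.data.groupby("animal_id")["dilution_factor"].apply(
            lambda s: tuple(np.sort(s))
        )
        if per_animal.nunique() > 1:
            raise InputError("animals must share one dilution grid")

    @property
    def dilution_grid(self) -> np.ndarray:
        return np.sort(self.data["dilution_factor"].unique())

    def readings_at(self, dilution: float) -> np.ndarray:
        sub = self.data[self.data["dilution_factor"] == dilution]
        return sub.sort_values("animal_id")["od450"].to_numpy()


def read_plate_tsv(path: str | Path) -> dict[tuple[str, str], TitrationSeries]:
    """Read a long-format plate TSV into series keyed by (group, bleed)."""
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except Exception as exc:  # malformed file
        raise InputError(f"cannot parse plate file {path}: {exc}") from exc
    missing = [c for c in PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"plate file {path} missing columns: {missing}")
    for col in ("dilution_factor", "od450"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        numeric = pd.to_numeric(df[col], errors="coerce")
        if numeric.isna().any():
            row = int(numeric.index[numeric.isna()][0]) + 2  # header + 1-base
            raise InputError(
                f"plate file {path}: non-numeric {col} at line {row}"
            )
        df[col] = numeric
    out = {}
    for (group, bleed), sub in df.groupby(["group", "bleed"], sort=True):
        out[(str(group), str(bleed))] = TitrationSeries(
            str(group), str(bleed), sub.reset_index(drop=True)
        )
    return out


def write_plate_tsv(
    series: dict[tuple[str, str], TitrationSeries], path: str | Path
) -> None:
    frames = []
    for (group, bleed), ts in series.items():
        df = ts.data.copy()
        df.insert(0, "bleed", bleed)
        df.insert(0, "group", group)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Exact Mann-Whitney

_NULL_CACHE: dict[tuple, np.ndarray] = {}


def _exact_u_distribution(pooled_ranks: np.ndarray, m: int) -> np.ndarray:
    """All rank-sum values of size-m subsets of the pooled mid-ranks.

    This is the exact permutation null of the Mann-Whitney U conditioned
    on the observed tie pattern (C(m+n, m) equally likely labelings).
    """
    key = (m, tuple(np.round(np.sort(pooled_ranks), 9)))
    if key not in _NULL_CACHE:
        n_tot = len(pooled_ranks)
        sums = []
        combos = itertools.combinations(range(n_tot), m)
        while True:
            block = list(itertools.islice(combos, 200_000))
            if not block:
                break
            idx = np.array(block)
            sums.append(pooled_ranks[idx].sum(axis=1))
        _NULL_CACHE[key] = np.concatenate(sums)
    return _NULL_CACHE[key]


def mann_whitney_exact(
    x: np.ndarray, y: np.ndarray, alternative: str = "two-sided"
) -> tuple[float, float]:
    """Exact Mann-Whitney U test by full enumeration of labelings.

    The null distribution is the set of all C(m+n, m) assignments of the
    pooled observations to the two groups, each equally likely; ties are
    handled with mid-ranks, enumerated over the observed tie pattern. The
    returned U is the statistic for ``x`` (number of (x, y) pairs with
    x > y, ties counting 1/2). The two-sided p-value is the probability
    of a U at least as far from its null mean m·n/2 as observed.

    Restricted to m + n <= 25 (exact enumeration only — no asymptotic
    fallback).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise InputError("both samples must be non-empty")
    if alternative not in ("two-sided", "greater", "less"):
        raise InputError(f"unknown alternative {alternative!r}")
    m, n = x.size, y.size
    if m + n > MAX_EXACT_POOL:
        raise InputError(
            f"exact enumeration supports m + n <= {MAX_EXACT_POOL}, "
            f"got {m + n}"
        )
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    r_x = ranks[:m].sum()
    u_obs = r_x - m * (m + 1) / 2.0
    null_sums = _exact_u_distribution(ranks, m)
    null_u = null_sums - m * (m + 1) / 2.0
    eps = 1e-9
    if alternative == "greater":
        p = float(np.mean(null_u >= u_obs - eps))
    elif alternative == "less":
        p = float(np.mean(null_u <= u_obs + eps))
    else:
        center = m * n / 2.0
        p = float(
            np.mean(np.abs(null_u - center) >= abs(u_obs - center) - eps)
        )
    return float(u_obs), p


def attainable_level(m: int, n: int, alternative: str = "two-sided") -> float:
    """Smallest exact p attainable with group sizes m and n (no ties)."""
    if alternative == "two-sided":
        from math import comb

        return 2.0 / comb(m + n, m)
    from math import comb

    return 1.0 / comb(m + n, m)


# ---------------------------------------------------------------------------
# Per-dilution comparison


@dataclass(frozen=True)
class DilutionTestResult:
    """Exact test outcome at one dilution point."""

    dilution_factor: float
    u_statistic: float
    p_value: float
    significant: bool


@dataclass(frozen=True)
class TitrationComparison:
    """Per-dilution exact tests plus the initial significance run."""

    results: tuple[DilutionTestResult, ...]
    initial_run_length: int
    alpha: float
    attainable_p: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "dilution_factor": r.dilution_factor,
                    "u_statistic": r.u_statistic,
                    "p_value": r.p_value,
                    "significant": r.significant,
                }
                for r in self.results
            ]
        )


def titrate_compare(
    baseline: TitrationSeries,
    treated: TitrationSeries,
    alpha: float = 0.05,
    alternative: str = "two-sided",
) -> TitrationComparison:
    """Exact Mann-Whitney test at every shared dilution point.

    Compares a pre-immunization bleed against a post-immunization bleed,
    one test per dilution at level ``alpha`` with no multiplicity
    correction (each dilution point is assessed on its own). The
    ``initial_run_length`` is the maximal run of significant dilutions
    starting at the lowest dilution factor (highest serum concentration)
    and stopping at the first non-significant point — the convention used
    to annotate titration curves with asterisks.
    """
    grid_b = baseline.dilution_grid
    grid_t = treated.dilution_grid
    if len(grid_b) != len(grid_t) or not np.allclose(grid_b, grid_t):
        only = set(np.round(grid_b, 6)) ^ set(np.round(grid_t, 6))
        raise InputError(
            f"dilution grids differ between series (unshared: {sorted(only)})"
        )
    results = []
    for d in grid_b:
        x = baseline.readings_at(d)
        y = treated.readings_at(d)
        u, p = mann_whitney_exact(x, y, alternative=alternative)
        results.append(
            DilutionTestResult(float(d), u, p, bool(p <= alpha))
        )
    run = 0
    for r in results:
        if not r.significant:
            break
        run += 1
    m = baseline.data["animal_id"].nunique()
    n = treated.data["animal_id"].nunique()
    return TitrationComparison(
        results=tuple(results),
        initial_run_length=run,
        alpha=alpha,
        attainable_p=attainable_level(m, n, alternative),
    )


def endpoint_titer(
    dilutions: np.ndarray, od450: np.ndarray, cutoff: float
) -> float:
    """Largest dilution factor whose OD still reaches the cutoff.

    Returns 0.0 (no titer) when every reading is below the cutoff.
    Readings must be ordered by increasing dilution.
    """
    dilutions = np.asarray(dilutions, dtype=float)
    od450 = np.asarray(od450, dtype=float)
    if dilutions.shape != od450.shape:
        raise InputError("dilutions and readings must align")
    if np.any(np.diff(dilutions) <= 0):
        raise InputError("readings must be ordered by increasing dilution")
    above = od450 >= cutoff
    if not above.any():
        return 0.0
    return float(dilutions[np.where(above)[0].max()])


# ---------------------------------------------------------------------------
# Serum stability


@dataclass(frozen=True)
class DecayFit:
    """One-phase exponential decay fit, y = plateau + span·exp(-k·t)."""

    plateau: float
    span: float
    rate_per_h: float
    half_life_h: float
    rss: float
    converged: bool
    boundary_rate: bool  # k pinned near 0: constant model likely better
    residuals: np.ndarray


@dataclass(frozen=True)
class ZeroSlopeFit:
    """Constant-level model for stable (protease-resistant) peptides."""

    level: float
    residual_sd: float
    rss: float


def fit_one_phase_decay(t: np.ndarray, y: np.ndarray) -> DecayFit:
    """Least-squares one-phase exponential decay of % remaining vs time.

    Intended for serum-stability curves starting near 100%; the half-life
    is ln 2 / k. If the fitted rate collapses onto the k = 0 boundary the
    result is flagged — a constant (zero-slope) model then describes the
    data at least as well. Non-convergence yields a flagged result with
    residuals, not an exception.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise InputError("t and y must be 1-D and aligned")
    if t.size < 4:
        raise InputError("one-phase decay fit needs at least 4 points")
    order = np.argsort(t)
    t, y = t[order], y[order]
    if abs(y[0] - 100.0) > 30.0:
        warnings.warn(
            f"initial value {y[0]:.1f} is far from 100%; is this a "
            f"% remaining curve?",
            stacklevel=2,
        )
    span0 = max(y[0] - y.min(), 1e-3)
    k0 = 1.0 / max(t.max() - t.min(), 1e-6)

    def model(tt, plateau, span, k):
        return plateau + span * np.exp(-k * tt)

    try:
        popt, _ = optimize.curve_fit(
            model,
            t,
            y,
            p0=(y.min(), span0, k0),
            bounds=([-np.inf, 0.0, 0.0], [np.inf, np.inf, np.inf]),
            maxfev=10000,
        )
        converged = True
    except RuntimeError:
        popt = np.array([y.min(), span0, k0])
        converged = False
    plateau, span, k = (float(v) for v in popt)
    residuals = y - model(t, *popt)
    rss = float((residuals**2).sum())
    t_scale = max(t.max() - t.min(), 1e-6)
    boundary = k * t_scale < 1e-3  # negligible decay over the window
    half_life = float(np.log(2) / k) if k > 0 else float("inf")
    return DecayFit(
        plateau=plateau,
        span=span,
        rate_per_h=k,
        half_life_h=half_life,
        rss=rss,
        converged=converged,
        boundary_rate=bool(boundary),
        residuals=residuals,
    )


def fit_zero_slope(t: np.ndarray, y: np.ndarray) -> ZeroSlopeFit:
    """Constant-level fit; the RSS allows contrast with the decay model."""
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if y.size < 2:
        raise InputError("zero-slope fit needs at least 2 points")
    level = float(y.mean())
    residuals = y - level
    return ZeroSlopeFit(
        level=level,
        residual_sd=float(residuals.std(ddof=1)),
        rss=float((residuals**2).sum()),
    )
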