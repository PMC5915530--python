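"""NMR structural profiling: chemical-shift deviations, amide temperature
coefficients, cis/trans proline populations.

The chemical-shift deviation (CSD) of a nucleus is the observed shift
minus the residue-type random-coil reference; systematic CSD patterns
report secondary-structure propensity. For a parent/retro-D peptide pair
the profiles are aligned by amino-acid type (parent residue ``i`` against
retro residue ``N+1-i``), which puts chemically identical side chains
side by side.

Shift tables are plain long-format DataFrames with columns
``residue_index, residue_code, nucleus, species, temperature_K,
shift_ppm``; ``species`` distinguishes the major conformer from minor
(e.g. cis-proline) species that exchange slowly on the NMR timescale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError
from .peptides import PeptideSequence, check_retro_pair

SHIFT_COLUMNS = [
    "residue_index",
    "residue_code",
    "nucleus",
    "species",
    "temperature_K",
    "shift_ppm",
]
NUCLEI = ("HA", "CA", "CB", "HN")

#: Amide temperature-coefficient threshold (ppb/K) above which (i.e. less
#: negative than) an amide proton is conventionally considered solvent
#: shielded / hydrogen bonded. A literature convention, not a measurement
#: of this package's own; configurable wherever it is applied.
HBOND_SLOPE_THRESHOLD_PPB_PER_K = -4.6

DEFAULT_RC_SOURCE = "wishart-1995-peptide-random-coil"


def validate_shift_table(df: pd.DataFrame) -> pd.DataFrame:
    """Check a shift table's schema and invariants; returns the table."""
    missing = [c for c in SHIFT_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"shift table missing columns: {missing}")
    if df.duplicated(
        ["residue_index", "nucleus", "species", "temperature_K"]
    ).any():
        raise InputError(
            "duplicate (residue_index, nucleus, species, temperature_K) rows"
        )
    if not np.isfinite(df["shift_ppm"]).all():
        raise InputError("non-finite chemical shifts")
    temps = df["temperature_K"]
    if ((temps < 250) | (temps > 350)).any():
        raise InputError("temperatures must lie within 250-350 K")
    bad = set(df["nucleus"]) - set(NUCLEI)
    if bad:
        raise InputError(f"unknown nuclei: {sorted(bad)}")
    return df


def read_shift_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV shift table (columns as in :data:`SHIFT_COLUMNS`)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    return validate_shift_table(df)


def write_shift_table(df: pd.DataFrame, path: str | Path) -> None:
    validate_shift_table(df).to_csv(path, sep="\t", index=False)


def load_random_coil() -> pd.DataFrame:
    """The packaged residue-type random-coil reference shifts."""
    with resources.files("retromimic.data").joinpath(
        "random_coil_shifts.tsv"
    ).open() as fh:
        df = pd.read_csv(fh, sep="\t", comment="#")
    return df


@dataclass(frozen=True)
class CSDProfile:
    """Per-residue, per-nucleus deviations from random coil (ppm)."""

    table: pd.DataFrame  # residue_index, residue_code, nucleus, csd_ppm
    rc_source: str


def compute_csd(
    shifts: pd.DataFrame,
    rc_table: pd.DataFrame | None = None,
    species: str = "major",
    rc_source: str | None = None,
) -> CSDProfile:
    """Observed minus random-coil shift per residue and nucleus.

    D-residues use the same reference values as their L-counterparts:
    enantiomers are spectroscopically identical in an achiral solvent.
    No neighbor or temperature corrections are applied to the reference
    values by default; pass a pre-corrected ``rc_table`` to change that.

    Raises
    ------
    InputError
        If the reference table lacks a residue type present in the data,
        naming the residue.
    """
    validate_shift_table(shifts)
    if rc_table is None:
        rc_table = load_random_coil()
        rc_source = rc_source or DEFAULT_RC_SOURCE
    rc_source = rc_source or "user-supplied"
    sub = shifts[shifts["species"] == species]
    if sub.empty:
        raise InputError(f"no records for species {species!r}")
    rc_lookup = {
        (r.residue_code, r.nucleus): r.shift_ppm
        for r in rc_table.itertuples()
    }
    rows = []
    for (res_idx, code, nucleus), grp in sub.groupby(
        ["residue_index", "residue_code", "nucleus"], sort=True
    ):
        key = (code.upper(), nucleus)
        if key not in rc_lookup:
            raise InputError(
                f"random-coil table has no entry for residue {code!r} "
                f"nucleus {nucleus}"
            )
        if grp["temperature_K"].nunique() > 1:
            raise InputError(
                f"multiple temperatures for residue {res_idx} nucleus "
                f"{nucleus}; filter the table to one temperature first"
            )
        rows.append(
            {
                "residue_index": int(res_idx),
                "residue_code": code,
                "nucleus": nucleus,
                "csd_ppm": float(grp["shift_ppm"].iloc[0]) - rc_lookup[key],
            }
        )
    return CSDProfile(pd.DataFrame(rows), rc_source=rc_source)


def align_profiles_by_type(
    parent: CSDProfile,
    retro: CSDProfile,
    parent_seq: PeptideSequence,
    retro_seq: PeptideSequence,
) -> pd.DataFrame:
    """Pair parent and retro-D CSDs by amino-acid type.

    Parent residue ``i`` pairs with retro residue ``N+1-i``; the pairing
    is validated against the sequences (a non-retro pair is rejected).
    Output rows are ordered by parent residue index and carry both CSDs
    for every nucleus present on both sides.
    """
    check_retro_pair(parent_seq, retro_seq)
    n = len(parent_seq)
    p = parent.table.rename(columns={"csd_ppm": "parent_csd_ppm"})
    r = retro.table.rename(
        columns={
            "csd_ppm": "retro_csd_ppm",
            "residue_index": "retro_residue_index",
            "residue_code": "retro_residue_code",
        }
    )
    p = p.assign(retro_residue_index=n + 1 - p["residue_index"])
    merged = p.merge(r, on=["retro_residue_index", "nucleus"], how="inner")
    mismatch = merged["residue_code"].str.upper() != merged[
        "retro_residue_code"
    ].str.upper()
    if mismatch.any():
        bad = merged.loc[mismatch, "residue_index"].iloc[0]
        raise InputError(
            f"residue type mismatch at parent position {bad} under reversal"
        )
    cols = [
        "residue_index",
        "residue_code",
        "retro_residue_index",
        "retro_residue_code",
        "nucleus",
        "parent_csd_ppm",
        "retro_csd_ppm",
    ]
    return (
        merged[cols]
        .sort_values(["residue_index", "nucleus"])
        .reset_index(drop=True)
    )


def temperature_coefficients(
    shifts: pd.DataFrame,
    species: str = "major",
    flag_threshold_ppb_per_k: float = HBOND_SLOPE_THRESHOLD_PPB_PER_K,
) -> pd.DataFrame:
    """Amide-proton temperature coefficients by ordinary least squares.

    For each residue with HN shifts at >= 3 temperatures, fits shift (ppm)
    against temperature (K) and reports the slope in ppb/K together with
    the intercept (ppm) and residual standard deviation. Residues whose
    slope is shallower than ``flag_threshold_ppb_per_k`` (default -4.6
    ppb/K, the usual literature convention) are flagged as potentially
    hydrogen-bonded / solvent-shielded amides. Residues with fewer than 3
    points are skipped with a warning.
    """
    validate_shift_table(shifts)
    sub = shifts[(shifts["nucleus"] == "HN") & (shifts["species"] == species)]
    rows = []
    for (res_idx, code), grp in sub.groupby(
        ["residue_index", "residue_code"], sort=True
    ):
        if len(grp) < 3:
            warnings.warn(
                f"residue {res_idx} ({code}): only {len(grp)} HN points; "
                f"skipped",
                stacklevel=2,
            )
            continue
        fit = stats.linregress(grp["temperature_K"], grp["shift_ppm"])
        resid = grp["shift_ppm"] - (
            fit.intercept + fit.slope * grp["temperature_K"]
        )
        slope_ppb = fit.slope * 1000.0
        rows.append(
            {
                "residue_index": int(res_idx),
                "residue_code": code,
                "slope_ppb_per_K": slope_ppb,
                "intercept_ppm": fit.intercept,
                "residual_sd_ppm": float(np.sqrt((resid**2).mean())),
                "n_points": len(grp),
                "shielded_flag": slope_ppb >= flag_threshold_ppb_per_k,
            }
        )
    return pd.DataFrame(rows)


def cis_trans_populations(
    intensities: dict[str, float], method: str = "amide-1d"
) -> dict[str, float]:
    """Relative species populations from signal integrals.

    ``intensities`` maps species name (e.g. ``trans``/``cis`` or
    ``major``/``minor``) to a signal integral from either 1D amide-proton
    integration (``method="amide-1d"``) or proline Cδ HSQC cross-peak
    intensities (``method="pro-cd-hsqc"``). The estimator is the same for
    both sources — fractions are intensity shares — so the two methods
    agree identically on identical integrals.
    """
    if method not in ("amide-1d", "pro-cd-hsqc"):
        raise InputError(f"unknown method {method!r}")
    if not intensities:
        raise InputError("no species intensities given")
    if any(v < 0 for v in intensities.values()):
        raise InputError("intensities must be non-negative")
    total = sum(intensities.values())
    if total <= 0:
        raise InputError("all intensities are zero; populations undefined")
    return {name: v / total for name, v in intensities.items()}
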