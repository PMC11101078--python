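"""Peak-area table handling: normalization factors and isotopologue fractions.

Tables are long-format :class:`pandas.DataFrame` objects with columns
``sample_id, group, metabolite, mass_shift, peak_area, stage`` — one row per
chromatographic peak, mirroring the layout of deposited LC-HRMS sheets.

Normalization follows the reference-sample procedure: for every metabolite the
unlabeled (m+0) peak area of a sample is divided by the corresponding area of
a selected reference sample; the per-metabolite ratios are averaged into one
normalization factor per sample, and every peak area of that sample is divided
by it.  Isotopologue fractions are simple within-(sample, metabolite) area
ratios, so they are invariant to any per-sample scaling — normalization
matters for absolute pool-size comparisons, not for MIDs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .carbon_atlas import NetworkSpec
from .isotope_correction import DEFAULT_P13, build_correction_matrix, correct_mid
from .label_engine import MID

logger = logging.getLogger(__name__)

TABLE_COLUMNS = ["sample_id", "group", "metabolite", "mass_shift", "peak_area", "stage"]

#: internal standard, excluded from normalization factors by default
DEFAULT_EXCLUDE = ("4-fluorophenylalanine",)


@dataclass(frozen=True)
class NormalizationFactor:
    sample_id: str
    factor: float
    n_metabolites_used: int

    def __post_init__(self) -> None:
        if self.factor <= 0:
            raise ValueError(f"{self.sample_id}: normalization factor must be > 0")
        if self.n_metabolites_used < 1:
            raise ValueError(f"{self.sample_id}: factor based on no metabolites")


def validate_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the long-format contract; returns the table with canonical dtypes."""
    missing = [c for c in TABLE_COLUMNS[:5] if c not in table.columns]
    if missing:
        raise ValueError(f"peak-area table is missing columns {missing}")
    out = table.copy()
    if "stage" not in out.columns:
        out["stage"] = "raw"
    out["mass_shift"] = out["mass_shift"].astype(int)
    out["peak_area"] = out["peak_area"].astype(float)
    if (out["peak_area"] < 0).any():
        bad = out.loc[out["peak_area"] < 0].iloc[0]
        raise ValueError(
            f"negative peak area for {bad['sample_id']}/{bad['metabolite']}/m+{bad['mass_shift']}"
        )
    dup = out.duplicated(["sample_id", "metabolite", "mass_shift"])
    if dup.any():
        bad = out.loc[dup].iloc[0]
        raise ValueError(
            f"duplicate record {bad['sample_id']}/{bad['metabolite']}/m+{bad['mass_shift']}"
        )
    return out


def _m0_areas(table_slice: pd.DataFrame, exclude: tuple[str, ...]) -> pd.Series:
    sel = (table_slice["mass_shift"] == 0) & ~table_slice["metabolite"].isin(exclude)
    return table_slice.loc[sel].set_index("metabolite")["peak_area"]


def normalization_factor(
    sample: pd.DataFrame,
    reference: pd.DataFrame,
    exclude: tuple[str, ...] = DEFAULT_EXCLUDE,
) -> NormalizationFactor:
    """Mean over shared metabolites of m+0 area ratios sample / reference.

    Metabolites absent from either slice or with a zero reference area are
    excluded from the mean (and logged).
    """
    sample_id = str(sample["sample_id"].iloc[0])
    s = _m0_areas(sample, exclude)
    r = _m0_areas(reference, exclude)
    shared = s.index.intersection(r.index)
    usable = [m for m in shared if r[m] > 0]
    skipped = sorted(set(shared) - set(usable))
    if skipped:
        logger.warning(
            "sample %s: %d metabolite(s) skipped in normalization (zero reference area): %s",
            sample_id, len(skipped), ", ".join(skipped),
        )
    if not usable:
        raise ValueError(
            f"sample {sample_id}: no shared metabolite with positive reference m+0 area"
        )
    ratios = np.array([s[m] / r[m] for m in usable])
    return NormalizationFactor(sample_id, float(ratios.mean()), len(usable))


def normalize_table(
    table: pd.DataFrame,
    reference_sample_id: str,
    exclude: tuple[str, ...] = DEFAULT_EXCLUDE,
) -> tuple[pd.DataFrame, list[NormalizationFactor]]:
    """Divide every sample's peak areas by its normalization factor.

    Returns the normalized table (stage = "normalized") and the per-sample
    factors.  The reference sample's factor is 1 by construction.
    """
    table = validate_table(table)
    samples = table["sample_id"].unique()
    if reference_sample_id not in samples:
        raise ValueError(f"reference sample {reference_sample_id!r} not in table")
    reference = table[table["sample_id"] == reference_sample_id]

    factors: list[NormalizationFactor] = []
    parts: list[pd.DataFrame] = []
    for sample_id, chunk in table.groupby("sample_id", sort=False):
        nf = normalization_factor(chunk, reference, exclude)
        factors.append(nf)
        logger.info(
            "sample %s: normalization factor %.6g (%d metabolites)",
            sample_id, nf.factor, nf.n_metabolites_used,
        )
        out = chunk.copy()
        out["peak_area"] = out["peak_area"] / nf.factor
        out["stage"] = "normalized"
        parts.append(out)
    return pd.concat(parts, ignore_index=True), factors


def compute_fractions(table_slice: pd.DataFrame, n_carbons: int | None = None) -> MID:
    """Isotopologue fractions for one (sample, metabolite) block of peak areas.

    Missing mass-shift rows count as zero area.  ``n_carbons`` fixes the MID
    length; by default the largest observed mass shift is used.
    """
    from .carbon_atlas import MetaboliteSpec

    if table_slice.empty:
        raise ValueError("empty table slice")
    met_name = str(table_slice["metabolite"].iloc[0])
    shifts = table_slice["mass_shift"].to_numpy()
    areas = table_slice["peak_area"].to_numpy(dtype=float)
    n = int(n_carbons if n_carbons is not None else shifts.max())
    if (shifts > n).any():
        raise ValueError(f"{met_name}: mass shift exceeds {n} carbons")
    total = areas.sum()
    if total <= 0:
        raise ValueError(f"{met_name}: all peak areas are zero")
    vec = np.zeros(n + 1)
    np.add.at(vec, shifts, areas / total)
    return MID(MetaboliteSpec(met_name, n), tuple(vec))


def fractions_table(
    table: pd.DataFrame,
    net: NetworkSpec | None = None,
) -> pd.DataFrame:
    """Per-(sample, metabolite) isotopologue fractions as a long table.

    Adds a ``fraction`` column; carbon counts come from the network when the
    metabolite is declared there, otherwise from the largest observed shift.
    """
    table = validate_table(table)
    rows: list[pd.DataFrame] = []
    for (sample_id, met), chunk in table.groupby(["sample_id", "metabolite"], sort=False):
        n = net.metabolites[met].n_carbons if net and met in net.metabolites else None
        mid = compute_fractions(chunk, n)
        group = chunk["group"].iloc[0]
        rows.append(pd.DataFrame({
            "sample_id": sample_id,
            "group": group,
            "metabolite": met,
            "mass_shift": range(len(mid.fractions)),
            "fraction": mid.fractions,
        }))
    return pd.concat(rows, ignore_index=True)


def correct_fractions_table(
    fractions: pd.DataFrame,
    p13: float = DEFAULT_P13,
) -> pd.DataFrame:
    """Natural-abundance-correct a fractions table per (sample, metabolite).

    Adds ``corrected_fraction`` and ``correction_residual`` columns; the
    number of carbons is the table's MID length per metabolite.
    """
    parts: list[pd.DataFrame] = []
    for (_, _), chunk in fractions.groupby(["sample_id", "metabolite"], sort=False):
        chunk = chunk.sort_values("mass_shift")
        n = int(chunk["mass_shift"].max())
        matrix = build_correction_matrix(n, p13)
        corrected = correct_mid(chunk["fraction"].to_numpy(), matrix)
        out = chunk.copy()
        out["corrected_fraction"] = corrected.fractions
        out["correction_residual"] = corrected.residual
        parts.append(out)
    return pd.concat(parts, ignore_index=True)
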