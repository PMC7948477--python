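"""Normalization, aggregation and filtering of peptide/protein intensities.

Two normalization scopes are supported by :func:`sum_normalize`:

``per_sample``
    each sample's intensities are divided by the sample total, the usual
    total-intensity normalization of label-free global proteomics;
``per_protein_across_conditions``
    each peptide's (or protein's) values across condition groups are divided
    by their sum, the targeted-PRM convention that turns per-condition areas
    into relative shares summing to 1.

Missing values are encoded as 0 ("not quantified") and are never imputed;
:func:`filter_complete_cases` is how incompletely quantified proteins are
excluded from an analysis.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import AbundanceMatrix, PeptideIntensityTable, warn_quant

_SCOPES = ("per_sample", "per_protein_across_conditions")


def sum_normalize(table, scope: str = "per_sample"):
    """Divide each normalization group by its total so it sums to 1.

    All-zero groups are left at zero and reported with a warning rather than
    producing NaNs.
    """
    if scope not in _SCOPES:
        raise ValueError(f"scope must be one of {_SCOPES}")

    if isinstance(table, AbundanceMatrix):
        vals = table.intensities.to_numpy(dtype=float)
        if scope == "per_sample":
            totals = vals.sum(axis=0)
            zero = totals == 0
            if zero.any():
                warn_quant(f"{int(zero.sum())} all-zero sample(s) left unnormalized")
            safe = np.where(zero, 1.0, totals)
            out = vals / safe
        else:
            totals = vals.sum(axis=1, keepdims=True)
            zero = totals[:, 0] == 0
            if zero.any():
                warn_quant(f"{int(zero.sum())} all-zero protein(s) left unnormalized")
            safe = np.where(totals == 0, 1.0, totals)
            out = vals / safe
        normalized = pd.DataFrame(out, index=table.intensities.index,
                                  columns=table.intensities.columns)
        return table.with_intensities(normalized)

    if isinstance(table, PeptideIntensityTable):
        data = table.data.copy()
        if scope == "per_sample":
            group_cols = ["donor", "condition"]
        else:
            group_cols = ["protein", "peptide", "donor"]
        totals = data.groupby(group_cols)["intensity"].transform("sum")
        zero = totals == 0
        if zero.any():
            n = data.loc[zero, group_cols].drop_duplicates().shape[0]
            warn_quant(f"{n} all-zero normalization group(s) left unnormalized")
        data["intensity"] = np.where(zero, 0.0, data["intensity"] / totals.where(totals != 0, 1.0))
        return PeptideIntensityTable(data)

    raise TypeError(f"unsupported table type: {type(table).__name__}")


def normalize_to_standard(table: PeptideIntensityTable, standard_protein_ids) -> PeptideIntensityTable:
    """Divide endogenous intensities by the mean heavy-standard intensity of
    their (donor, condition) group; heavy rows are dropped from the output.
    """
    standards = set(standard_protein_ids)
    data = table.data
    heavy = data[data["is_heavy"] & data["protein"].isin(standards)]
    divisors = heavy.groupby(["donor", "condition"])["intensity"].mean()

    endo = data[~data["is_heavy"]].copy()
    groups = list(endo.groupby(["donor", "condition"]).groups)
    missing = [g for g in groups if g not in divisors.index]
    if missing:
        raise ValueError(
            "no heavy standard measured in group(s): "
            + ", ".join(f"(donor={d}, condition={c})" for d, c in sorted(missing))
        )
    keys = pd.MultiIndex.from_frame(endo[["donor", "condition"]])
    endo["intensity"] = endo["intensity"].to_numpy() / divisors.loc[keys].to_numpy()
    return PeptideIntensityTable(endo.reset_index(drop=True))


def aggregate_peptides(table: PeptideIntensityTable) -> AbundanceMatrix:
    """Collapse peptides to one signal per (protein, donor, condition).

    The unweighted mean over a protein's peptides in each cell; a
    single-peptide protein passes through unchanged.  Cells with no
    measurement are encoded as 0.  The unique-peptide count of each protein
    is the number of distinct peptide sequences observed for it.
    """
    data = table.data[~table.data["is_heavy"]]
    if data.empty:
        raise ValueError("no endogenous peptides to aggregate")
    cell = (
        data.groupby(["protein", "donor", "condition"])["intensity"]
        .mean()
        .reset_index()
    )
    cell["sample"] = cell["donor"] + "_" + cell["condition"]
    wide = cell.pivot(index="protein", columns="sample", values="intensity").fillna(0.0)
    wide = wide.sort_index()

    donors = sorted(data["donor"].unique())
    conditions = list(dict.fromkeys(table.data["condition"]))
    sample_ids = [f"{d}_{c}" for d in donors for c in conditions]
    wide = wide.reindex(columns=sample_ids, fill_value=0.0)

    sample_meta = pd.DataFrame(
        {
            "donor": [d for d in donors for _ in conditions],
            "condition": [c for _ in donors for c in conditions],
            "batch": ["B1"] * (len(donors) * len(conditions)),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    unique_peptides = (
        data.groupby("protein")["peptide"].nunique().reindex(wide.index).astype(int)
    )
    unique_peptides.name = "unique_peptides"
    return AbundanceMatrix(wide, sample_meta, unique_peptides)


def filter_by_unique_peptides(matrix: AbundanceMatrix, min_unique: int) -> AbundanceMatrix:
    """Retain proteins identified by at least ``min_unique`` unique peptides."""
    if min_unique < 1:
        raise ValueError("min_unique must be >= 1")
    keep = matrix.unique_peptides[matrix.unique_peptides >= min_unique].index
    return matrix.with_intensities(matrix.intensities.loc[keep])


def filter_complete_cases(matrix: AbundanceMatrix, required_groups=None) -> AbundanceMatrix:
    """Retain proteins with a strictly positive value in every sample of the
    required condition groups (all conditions by default)."""
    if required_groups is None:
        required_groups = matrix.conditions
    samples = [s for c in required_groups for s in matrix.samples_in(c)]
    unknown = [c for c in required_groups if not matrix.samples_in(c)]
    if unknown:
        raise ValueError(f"unknown condition group(s): {unknown}")
    sub = matrix.intensities[samples]
    keep = sub.index[(sub > 0).all(axis=1)]
    return matrix.with_intensities(matrix.intensities.loc[keep])
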