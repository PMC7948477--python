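"""Core data containers shared across analysis stages.

The central object is :class:`AbundanceMatrix`, a protein x sample intensity
table with sample metadata (donor, condition, batch) and per-protein
unique-peptide counts — the unit that normalization, filtering and the
multi-group differential tests all operate on.  Peptide-level targeted
(PRM-style) data live in :class:`PeptideIntensityTable` until they are
aggregated to one signal per protein and donor.  Pathway collections are
ordered lists of named gene sets as read from GMT files.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Float format used for every TSV we write; 17 significant digits so that
#: write/read round-trips reproduce doubles exactly.
FLOAT_FMT = "%.17g"

PEPTIDE_COLUMNS = ["peptide", "protein", "donor", "condition", "intensity", "is_heavy"]


class QuantWarning(UserWarning):
    """Non-fatal data-quality condition (all-zero normalization group etc.)."""


@dataclass
class AbundanceMatrix:
    """Protein x sample intensity matrix with sample metadata.

    Parameters
    ----------
    intensities
        DataFrame indexed by protein id with one column per sample id.
        Values are non-negative, finite intensities on a linear scale;
        0 encodes "not quantified" (never imputed).
    sample_meta
        DataFrame indexed by sample id with columns ``donor``, ``condition``
        and ``batch``; must cover exactly the columns of ``intensities``.
    unique_peptides
        Integer Series indexed by protein id: the number of unique peptides
        supporting each protein's identification.
    """

    intensities: pd.DataFrame
    sample_meta: pd.DataFrame
    unique_peptides: pd.Series

    def __post_init__(self) -> None:
        for col in ("donor", "condition", "batch"):
            if col not in self.sample_meta.columns:
                raise ValueError(f"sample_meta is missing required column {col!r}")
        if list(self.intensities.columns) != list(self.sample_meta.index):
            raise ValueError("sample columns and sample_meta index do not match")
        if list(self.intensities.index) != list(self.unique_peptides.index):
            raise ValueError("protein index and unique_peptides index do not match")
        vals = self.intensities.to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)) or (vals < 0).any():
            raise ValueError("intensities must be finite and non-negative")
        counts = self.sample_meta["condition"].value_counts()
        if (counts < 1).any():  # pragma: no cover - value_counts never yields 0
            raise ValueError("every condition label needs at least one sample")

    # -- convenience views ------------------------------------------------

    @property
    def protein_ids(self) -> list[str]:
        return list(self.intensities.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.intensities.columns)

    @property
    def conditions(self) -> list[str]:
        """Condition labels in first-appearance order."""
        return list(dict.fromkeys(self.sample_meta["condition"]))

    def samples_in(self, condition: str) -> list[str]:
        meta = self.sample_meta
        return list(meta.index[meta["condition"] == condition])

    def with_intensities(self, intensities: pd.DataFrame) -> "AbundanceMatrix":
        """Copy with a replaced intensity table (same samples; proteins may shrink)."""
        return AbundanceMatrix(
            intensities=intensities,
            sample_meta=self.sample_meta.copy(),
            unique_peptides=self.unique_peptides.loc[intensities.index].copy(),
        )

    # -- I/O --------------------------------------------------------------

    def to_dir(self, outdir) -> dict:
        """Write matrix.tsv / samples.tsv / peptides.tsv into ``outdir``."""
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "matrix": outdir / "matrix.tsv",
            "samples": outdir / "samples.tsv",
            "peptides": outdir / "peptides.tsv",
        }
        self.intensities.to_csv(
            paths["matrix"], sep="\t", index_label="protein_id", float_format=FLOAT_FMT
        )
        self.sample_meta.to_csv(paths["samples"], sep="\t", index_label="sample_id")
        self.unique_peptides.rename("unique_peptides").to_csv(
            paths["peptides"], sep="\t", index_label="protein_id"
        )
        return {k: str(v) for k, v in paths.items()}

    @classmethod
    def from_dir(cls, indir) -> "AbundanceMatrix":
        from pathlib import Path

        indir = Path(indir)
        intensities = pd.read_csv(indir / "matrix.tsv", sep="\t", index_col="protein_id")
        sample_meta = pd.read_csv(indir / "samples.tsv", sep="\t", index_col="sample_id")
        peptides = pd.read_csv(indir / "peptides.tsv", sep="\t", index_col="protein_id")
        return cls(intensities, sample_meta, peptides["unique_peptides"])


@dataclass
class PeptideIntensityTable:
    """Long-format peptide intensity table for targeted (PRM-style) data.

    One row per (peptide, protein, donor, condition) measurement with a
    non-negative extracted-ion-chromatogram area and a flag marking heavy
    stable-isotope standard peptides.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in PEPTIDE_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"peptide table is missing columns: {missing}")
        self.data = self.data[PEPTIDE_COLUMNS].reset_index(drop=True)
        vals = self.data["intensity"].to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)) or (vals < 0).any():
            raise ValueError("peptide intensities must be finite and >= 0")
        key = ["peptide", "donor", "condition", "is_heavy"]
        if self.data.duplicated(subset=key).any():
            raise ValueError("duplicate (peptide, donor, condition) measurements")

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)

    @classmethod
    def from_tsv(cls, path) -> "PeptideIntensityTable":
        data = pd.read_csv(path, sep="\t")
        if "is_heavy" in data.columns:
            data["is_heavy"] = data["is_heavy"].astype(bool)
        return cls(data)


@dataclass(frozen=True)
class Pathway:
    """A named gene set with a source label (e.g. KEGG / Reactome / synthetic)."""

    name: str
    source: str
    members: frozenset

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"pathway {self.name!r} has no members")


@dataclass
class PathwayCollection:
    """Ordered collection of pathways with unique names."""

    pathways: list = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [p.name for p in self.pathways]
        if len(names) != len(set(names)):
            raise ValueError("pathway names must be unique")

    def __iter__(self):
        return iter(self.pathways)

    def __len__(self) -> int:
        return len(self.pathways)

    def __getitem__(self, name: str) -> Pathway:
        for p in self.pathways:
            if p.name == name:
                return p
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [p.name for p in self.pathways]

    def universe(self) -> set:
        out: set = set()
        for p in self.pathways:
            out |= p.members
        return out


def warn_quant(message: str) -> None:
    """Emit a non-fatal data-quality warning with the shared category."""
    warnings.warn(message, QuantWarning, stacklevel=3)
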