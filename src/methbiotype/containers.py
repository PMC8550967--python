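"""Shared tabular containers and their on-disk formats.

Conventions used throughout the package:

* A **beta matrix** is a :class:`pandas.DataFrame` of methylation fractions
  in ``[0, 1]`` with samples on the rows and CpG probes on the columns.
  On disk it is stored transposed (probes x samples, TSV) which is the
  layout most array-processing tools emit.
* A **probe annotation** is a DataFrame indexed by probe id with columns
  ``gene`` (empty string means intergenic) and ``region_class``
  (``promoter`` / ``body`` / ``intergenic``).
* A **clinical table** is a DataFrame indexed by sample id holding symptom
  and function scores, covariates, and the diagnosis label.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RegionMatrix",
    "read_beta_tsv",
    "write_beta_tsv",
    "read_annotation_tsv",
    "write_annotation_tsv",
]


@dataclass
class RegionMatrix:
    """Per-sample mean methylation over collapsed gene regions.

    Parameters
    ----------
    values
        samples x regions DataFrame; each entry is the arithmetic mean of
        the member probes' beta values for that sample.
    membership
        Mapping from region id to the ordered list of member probe ids.
        Region ids are ``"<gene>@<k>"`` where ``k`` numbers the connected
        components of the within-gene correlation graph.
    """

    values: pd.DataFrame
    membership: dict[str, list[str]] = field(default_factory=dict)

    @property
    def region_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    def gene_of(self, region_id: str) -> str:
        return region_id.rsplit("@", 1)[0]

    def subset(self, region_ids: list[str]) -> "RegionMatrix":
        missing = [r for r in region_ids if r not in self.values.columns]
        if missing:
            raise KeyError(f"regions not present: {missing[:10]}")
        return RegionMatrix(
            values=self.values.loc[:, region_ids].copy(),
            membership={r: list(self.membership.get(r, [])) for r in region_ids},
        )

    def to_files(self, values_path, membership_path) -> None:
        write_beta_tsv(self.values, values_path)
        with open(membership_path, "w") as fh:
            json.dump(self.membership, fh, indent=1, sort_keys=True)

    @classmethod
    def from_files(cls, values_path, membership_path) -> "RegionMatrix":
        values = read_beta_tsv(values_path)
        with open(membership_path) as fh:
            membership = {k: list(v) for k, v in json.load(fh).items()}
        return cls(values=values, membership=membership)


def write_beta_tsv(beta: pd.DataFrame, path) -> None:
    """Write a samples x features matrix as a features x samples TSV."""
    out = beta.T
    out.index.name = "probe_id"
    out.to_csv(path, sep="\t", float_format="%.6g")


def read_beta_tsv(path) -> pd.DataFrame:
    """Read a features x samples TSV back into a samples x features frame."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.T


def write_annotation_tsv(annot: pd.DataFrame, path) -> None:
    out = annot.copy()
    out.index.name = "probe_id"
    out.to_csv(path, sep="\t")


def read_annotation_tsv(path) -> pd.DataFrame:
    annot = pd.read_csv(path, sep="\t", index_col=0, keep_default_na=False)
    return annot


def validate_beta(beta: pd.DataFrame) -> None:
    """Raise if the matrix violates the beta-value contract."""
    vals = beta.to_numpy()
    if not np.isfinite(vals).all():
        raise ValueError("beta matrix contains non-finite values")
    if vals.min() < 0.0 or vals.max() > 1.0:
        raise ValueError("beta values must lie in [0, 1]")
    if beta.index.has_duplicates or beta.columns.has_duplicates:
        raise ValueError("sample and probe ids must be unique")
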