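"""Core data containers: omics datasets and the multi-site registry.

A cell line panel study contributes one matrix per (site, modality,
platform): genes (or drugs) in rows, cell lines in columns.  Continuous
modalities hold real values, binary modalities hold presence/absence of an
alteration.  Missing values are first-class throughout and encoded as NaN
(empty cells in TSV).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd
import yaml

#: gene-space modality types plus the drug-space DSS profiles they derive from
MODALITIES = (
    "METH", "MUT", "CNV", "CNV_GAIN", "CNV_LOSS",
    "GEXP", "PEXP", "PHOS", "FUNC", "DSS", "TAS",
)
BINARY_MODALITIES = frozenset({"MUT", "CNV_GAIN", "CNV_LOSS"})
CONTINUOUS_MODALITIES = frozenset(set(MODALITIES) - BINARY_MODALITIES)


class DatasetError(ValueError):
    """Raised for malformed datasets or registry inconsistencies."""


def _default_value_kind(modality: str) -> str:
    return "binary" if modality in BINARY_MODALITIES else "continuous"


@dataclass
class OmicsDataset:
    """One site's gene(or drug) x cell-line matrix for one modality.

    Parameters
    ----------
    dataset_id : str
        Unique label within a registry, e.g. ``"BROAD_GEXP"``.
    site : str
        Study-site label (BROAD, GDSC, UHN, ...).
    modality : str
        One of :data:`MODALITIES`.
    values : pandas.DataFrame
        Rows are gene (or drug) identifiers, columns cell-line identifiers.
        NaN marks a missing measurement.
    value_kind : str
        ``"continuous"`` or ``"binary"``; inferred from the modality when
        omitted.
    platform : str
        Free-text platform description (RNA-seq, RPPA, ...).
    """

    dataset_id: str
    site: str
    modality: str
    values: pd.DataFrame
    value_kind: str = ""
    platform: str = ""

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise DatasetError(
                f"unknown modality {self.modality!r}; expected one of {MODALITIES}"
            )
        if not self.value_kind:
            self.value_kind = _default_value_kind(self.modality)
        if self.value_kind not in ("continuous", "binary"):
            raise DatasetError(f"value_kind must be continuous|binary, got {self.value_kind!r}")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise DatasetError(f"duplicate row identifiers in {self.dataset_id}: {dups[:5]}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise DatasetError(f"duplicate cell-line identifiers in {self.dataset_id}: {dups[:5]}")
        self.values = self.values.astype(float)
        if self.value_kind == "binary":
            vals = self.values.to_numpy()
            ok = np.isnan(vals) | (vals == 0.0) | (vals == 1.0)
            if not ok.all():
                bad = np.unique(vals[~ok])
                raise DatasetError(
                    f"binary dataset {self.dataset_id} contains non-binary values {bad[:5]}"
                )

    # -- convenience accessors -------------------------------------------------
    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def cell_lines(self) -> pd.Index:
        return self.values.columns

    @property
    def is_binary(self) -> bool:
        return self.value_kind == "binary"

    def covers(self, cell_line: str) -> bool:
        """Whether the dataset measured *cell_line* (with any non-missing value)."""
        if cell_line not in self.values.columns:
            return False
        return bool(self.values[cell_line].notna().any())

    # -- IO --------------------------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        label = self.values.index.name or ("drug" if self.modality == "DSS" else "gene")
        self.values.to_csv(path, sep="\t", index_label=label, na_rep="")

    @classmethod
    def from_tsv(
        cls,
        path: str | Path,
        dataset_id: str,
        site: str,
        modality: str,
        value_kind: str = "",
        platform: str = "",
    ) -> "OmicsDataset":
        values = pd.read_csv(path, sep="\t", index_col=0)
        values.index = values.index.astype(str)
        values.columns = values.columns.astype(str)
        return cls(dataset_id, site, modality, values, value_kind, platform)

    def rename_ids(
        self,
        gene_aliases: Mapping[str, str] | None = None,
        line_aliases: Mapping[str, str] | None = None,
    ) -> "OmicsDataset":
        """Harmonize identifiers through an explicit alias map (no fuzzy matching)."""
        values = self.values
        if gene_aliases:
            values = values.rename(index=dict(gene_aliases))
        if line_aliases:
            values = values.rename(columns=dict(line_aliases))
        return OmicsDataset(
            self.dataset_id, self.site, self.modality, values, self.value_kind, self.platform
        )


class DatasetRegistry:
    """An ordered collection of :class:`OmicsDataset` plus cell-line annotations.

    A registry may hold several datasets per (site, modality); dataset_id is
    the unique key.  Cell-line annotations (tissue, subtype) are optional and
    shared across datasets.
    """

    def __init__(self, annotations: pd.DataFrame | None = None):
        self._datasets: dict[str, OmicsDataset] = {}
        self.annotations = annotations

    def add(self, dataset: OmicsDataset) -> None:
        if dataset.dataset_id in self._datasets:
            raise DatasetError(f"duplicate dataset_id {dataset.dataset_id!r}")
        self._datasets[dataset.dataset_id] = dataset

    def __getitem__(self, dataset_id: str) -> OmicsDataset:
        return self._datasets[dataset_id]

    def __contains__(self, dataset_id: str) -> bool:
        return dataset_id in self._datasets

    def __iter__(self) -> Iterator[OmicsDataset]:
        return iter(self._datasets.values())

    def __len__(self) -> int:
        return len(self._datasets)

    @property
    def ids(self) -> list[str]:
        return list(self._datasets)

    def by_modality(self, modality: str) -> list[OmicsDataset]:
        return [d for d in self._datasets.values() if d.modality == modality]

    def sites(self) -> list[str]:
        return sorted({d.site for d in self._datasets.values()})

    def all_cell_lines(self) -> pd.Index:
        lines: set[str] = set()
        for d in self._datasets.values():
            lines.update(d.cell_lines)
        return pd.Index(sorted(lines))

    def replace(self, dataset: OmicsDataset) -> None:
        self._datasets[dataset.dataset_id] = dataset

    def remove(self, dataset_id: str) -> None:
        del self._datasets[dataset_id]

    # -- IO --------------------------------------------------------------------
    def to_yaml(self, directory: str | Path) -> Path:
        """Write all matrices as TSV plus a ``registry.yaml`` manifest."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        entries = []
        for ds in self:
            fname = f"{ds.dataset_id}.tsv"
            ds.to_tsv(directory / fname)
            entries.append(
                {
                    "dataset_id": ds.dataset_id,
                    "site": ds.site,
                    "modality": ds.modality,
                    "value_kind": ds.value_kind,
                    "platform": ds.platform,
                    "path": fname,
                }
            )
        manifest: dict = {"datasets": entries}
        if self.annotations is not None:
            self.annotations.to_csv(directory / "annotations.tsv", sep="\t", index_label="cell_line")
            manifest["annotations"] = "annotations.tsv"
        out = directory / "registry.yaml"
        with open(out, "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=False)
        return out

    @classmethod
    def from_yaml(cls, manifest_path: str | Path) -> "DatasetRegistry":
        manifest_path = Path(manifest_path)
        if not manifest_path.exists():
            raise FileNotFoundError(f"registry manifest not found: {manifest_path}")
        with open(manifest_path) as fh:
            manifest = yaml.safe_load(fh)
        base = manifest_path.parent
        annotations = None
        if manifest.get("annotations"):
            annotations = pd.read_csv(base / manifest["annotations"], sep="\t", index_col=0)
            annotations.index = annotations.index.astype(str)
        reg = cls(annotations=annotations)
        for entry in manifest.get("datasets", []):
            missing = [k for k in ("dataset_id", "site", "modality", "path") if k not in entry]
            if missing:
                raise DatasetError(f"registry entry missing fields {missing}: {entry}")
            reg.add(
                OmicsDataset.from_tsv(
                    base / entry["path"],
                    dataset_id=entry["dataset_id"],
                    site=entry["site"],
                    modality=entry["modality"],
                    value_kind=entry.get("value_kind", ""),
                    platform=entry.get("platform", ""),
                )
            )
        return reg


def read_alias_table(path: str | Path) -> dict[str, str]:
    """Two-column TSV (alias, canonical id) -> alias map for
    :meth:`OmicsDataset.rename_ids`.  Identifier harmonization is always
    through such explicit tables; nothing is matched fuzzily."""
    table = pd.read_csv(path, sep="\t")
    if table.shape[1] < 2:
        raise DatasetError("alias table needs two columns (alias, canonical)")
    a, b = table.columns[:2]
    return dict(zip(table[a].astype(str), table[b].astype(str)))


DEFAULT_EXCLUDED_TISSUES = frozenset({"bone", "skin", "nervous", "hematopoietic"})


def epithelial_lines(
    annotations: pd.DataFrame,
    excluded_tissues: Iterable[str] = DEFAULT_EXCLUDED_TISSUES,
    tissue_column: str = "tissue",
) -> list[str]:
    """Cell lines outside the excluded lineages (bone, skin, nervous, blood).

    Genetic-interaction scans are restricted to this epithelial subset because
    lineage-wide dependencies in the excluded tissues would otherwise dominate
    the mutation/wild-type comparison.
    """
    excluded = {t.lower() for t in excluded_tissues}
    tissues = annotations[tissue_column].astype(str).str.lower()
    return annotations.index[~tissues.isin(excluded)].astype(str).tolist()
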