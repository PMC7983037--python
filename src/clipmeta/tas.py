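"""Target addiction scoring: project drug-space response into gene space.

A drug-sensitivity screen lives in compound space; exploiting drug
polypharmacology, the response of each cell line is re-expressed per protein
target as the mean sensitivity score (DSS) over all compounds that potently
hit that target (primary and off-targets pooled, unweighted).  The result is
the TAS modality: a target x cell-line matrix directly comparable with the
other gene-space modalities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .datasets import DatasetError, OmicsDataset


@dataclass
class DrugTargetMap:
    """drug id -> set of potent protein targets."""

    targets: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for drug, tset in self.targets.items():
            if not tset:
                raise DatasetError(f"drug {drug!r} mapped to an empty target set")
            self.targets[drug] = frozenset(tset)

    def __contains__(self, drug: str) -> bool:
        return drug in self.targets

    def __len__(self) -> int:
        return len(self.targets)

    def all_targets(self) -> frozenset[str]:
        out: set[str] = set()
        for tset in self.targets.values():
            out |= tset
        return frozenset(out)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "DrugTargetMap":
        targets: dict[str, set[str]] = {}
        for drug, target in pairs:
            targets.setdefault(str(drug), set()).add(str(target))
        return cls({d: frozenset(t) for d, t in targets.items()})

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DrugTargetMap":
        """Two-column TSV (drug, target), one row per pair."""
        table = pd.read_csv(path, sep="\t")
        if table.shape[1] < 2:
            raise DatasetError("drug-target map TSV needs two columns (drug, target)")
        drug_col, target_col = table.columns[:2]
        return cls.from_pairs(
            zip(table[drug_col].astype(str), table[target_col].astype(str))
        )

    def to_tsv(self, path: str | Path) -> None:
        rows = [(d, t) for d, ts in sorted(self.targets.items()) for t in sorted(ts)]
        pd.DataFrame(rows, columns=["drug", "target"]).to_csv(path, sep="\t", index=False)


def compute_tas(dss: OmicsDataset, drug_targets: DrugTargetMap) -> OmicsDataset:
    """Mean DSS over the compounds targeting each protein, per cell line.

    Compounds with a missing response in a given line are dropped from that
    line's mean (the effective compound count shrinks per line); a target with
    no measured targeting compound in a line is missing there.  Duplicate drug
    rows are rejected upstream by the dataset container.
    """
    if dss.modality != "DSS":
        raise DatasetError(f"compute_tas expects a DSS dataset, got {dss.modality}")
    measured_mapped = [d for d in dss.values.index if d in drug_targets]
    if not measured_mapped:
        raise DatasetError(
            "no overlap between measured drugs and the drug-target map; "
            f"{len(dss.values.index)} measured, {len(drug_targets)} mapped"
        )
    target_to_drugs: dict[str, list[str]] = {}
    for drug in measured_mapped:
        for t in drug_targets.targets[drug]:
            target_to_drugs.setdefault(t, []).append(drug)
    rows = {}
    for target, drugs in sorted(target_to_drugs.items()):
        rows[target] = dss.values.loc[drugs].mean(axis=0)  # skips NaN per line
    tas = pd.DataFrame(rows).T
    tas.index.name = "gene"
    return OmicsDataset(
        f"{dss.dataset_id}_TAS", dss.site, "TAS", tas, "continuous", dss.platform
    )


def coverage_report(dss: OmicsDataset, drug_targets: DrugTargetMap) -> dict:
    """Bookkeeping: how many measured compounds have known targets, and how
    many targets are scoreable per cell line."""
    measured = list(dss.values.index)
    mapped = [d for d in measured if d in drug_targets]
    targets_per_line = {}
    if mapped:
        tas = compute_tas(dss, drug_targets)
        targets_per_line = tas.values.notna().sum(axis=0).to_dict()
    return {
        "n_drugs_measured": len(measured),
        "n_drugs_mapped": len(mapped),
        "mapped_fraction": len(mapped) / len(measured) if measured else float("nan"),
        "n_targets": len({t for d in mapped for t in drug_targets.targets[d]}),
        "targets_per_line": targets_per_line,
    }
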