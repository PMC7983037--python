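"""Site/platform-specific preprocessing of raw omics inputs.

Each study site ships data in its own conventions; these routines bring
every modality into comparable gene x cell-line matrices:

* copy number: ploidy normalization (PICNIC-style calls) and per-site
  binarization into gain/loss calls,
* point mutations: collapse variant records to a functional-consequence
  presence/absence matrix (pathogenic flag or deleterious FATHMM score),
* phospho-proteomics: average phospho-site intensities per protein,
* methylation: QC-filter CpG sites and average promoter-window betas per gene,
* quantile normalization for cross-column distribution matching.

All averages skip missing values; nothing is imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .datasets import DatasetError, OmicsDataset

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Copy number
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SiteCnvThresholds:
    """Binarization thresholds for one site's copy-number values."""

    gain_threshold: float
    loss_threshold: float
    needs_ploidy_normalization: bool = False

    def __post_init__(self) -> None:
        if not (self.gain_threshold > 0 > self.loss_threshold):
            raise ValueError(
                "require gain_threshold > 0 > loss_threshold, got "
                f"{self.gain_threshold}, {self.loss_threshold}"
            )


@dataclass
class CnvCallingConfig:
    """Per-site copy-number calling rules.

    The shipped defaults reflect where each site's ERBB2-amplification /
    PTEN-deletion distributions show a sharp deflection: +/-1 for BROAD
    (absolute calls), +/-0.5 for GDSC/SANGER, gCSI and OHSU
    (ploidy-normalized PICNIC calls for GDSC/gCSI), +/-0.4 for UHN and NCI60
    (log-intensity platforms).
    """

    sites: dict[str, SiteCnvThresholds] = field(default_factory=dict)

    @classmethod
    def default(cls) -> "CnvCallingConfig":
        return cls(
            sites={
                "BROAD": SiteCnvThresholds(1.0, -1.0, False),
                "GDSC": SiteCnvThresholds(0.5, -0.5, True),
                "SANGER": SiteCnvThresholds(0.5, -0.5, True),
                "GCSI": SiteCnvThresholds(0.5, -0.5, True),
                "OHSU": SiteCnvThresholds(0.5, -0.5, False),
                "UHN": SiteCnvThresholds(0.4, -0.4, False),
                "NCI60": SiteCnvThresholds(0.4, -0.4, False),
            }
        )

    def for_site(self, site: str) -> SiteCnvThresholds:
        key = site.upper()
        if key not in self.sites:
            raise DatasetError(
                f"no CNV calling thresholds for site {site!r}; known sites: "
                f"{sorted(self.sites)}"
            )
        return self.sites[key]


def normalize_cnv(cn_value: float, ploidy: float) -> float:
    """Ploidy-normalize an absolute copy-number call: ``cn / ploidy - 1``.

    A diploid-neutral gene maps to 0, a homozygous-level amplification at
    diploid ploidy (cn=4) to +1, a single-copy loss (cn=1) to -0.5.
    """
    if not ploidy > 0:
        raise ValueError(f"ploidy must be positive, got {ploidy}")
    return cn_value / ploidy - 1.0


def binarize_cnv(
    dataset: OmicsDataset, config: CnvCallingConfig | None = None
) -> tuple[OmicsDataset, OmicsDataset]:
    """Split a continuous CNV matrix into binary gain and loss call matrices.

    Gain = 1 iff value >= the site's gain threshold; loss = 1 iff value <=
    the loss threshold (both inclusive).  Missing values propagate.
    """
    if dataset.is_binary:
        raise DatasetError(f"binarize_cnv expects a continuous CNV dataset, got {dataset.dataset_id}")
    config = config or CnvCallingConfig.default()
    thr = config.for_site(dataset.site)
    vals = dataset.values
    gain = (vals >= thr.gain_threshold).astype(float).where(vals.notna())
    loss = (vals <= thr.loss_threshold).astype(float).where(vals.notna())
    mk = lambda m, suffix, v: OmicsDataset(
        f"{dataset.dataset_id}_{suffix}", dataset.site, m, v, "binary", dataset.platform
    )
    return mk("CNV_GAIN", "GAIN", gain), mk("CNV_LOSS", "LOSS", loss)


# ---------------------------------------------------------------------------
# Point mutations
# ---------------------------------------------------------------------------

VARIANT_COLUMNS = ("gene", "cell_line", "pathogenic", "fathmm_score")


def read_variant_table(path) -> pd.DataFrame:
    """Read a variant TSV with columns gene, cell_line, pathogenic, fathmm_score."""
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in VARIANT_COLUMNS if c not in table.columns]
    if missing:
        raise DatasetError(f"variant table missing columns {missing}")
    return table


def binarize_mutations(
    variants: pd.DataFrame,
    fathmm_cutoff: float = -0.75,
    dataset_id: str = "MUT",
    site: str = "",
    cell_lines=None,
) -> OmicsDataset:
    """Collapse variant records to a binary functional-mutation matrix.

    A (gene, cell line) entry is 1 iff any of its variants was annotated
    pathogenic or carries a FATHMM score <= *fathmm_cutoff* (default -0.75,
    more negative = more deleterious).  Records with neither annotation are
    non-qualifying; they are counted and logged, not errors.  Lines listed in
    *cell_lines* but free of qualifying variants appear as all-zero columns.
    """
    if not np.isfinite(fathmm_cutoff):
        raise ValueError("fathmm_cutoff must be finite")
    table = variants.copy()
    missing = [c for c in VARIANT_COLUMNS if c not in table.columns]
    if missing:
        raise DatasetError(f"variant table missing columns {missing}")
    pathogenic = table["pathogenic"].fillna(False).astype(bool)
    score = pd.to_numeric(table["fathmm_score"], errors="coerce")
    unannotated = (~pathogenic) & score.isna()
    n_unannotated = int(unannotated.sum())
    if n_unannotated:
        logger.info(
            "binarize_mutations: %d variant record(s) with neither pathogenic flag "
            "nor FATHMM score treated as non-qualifying", n_unannotated,
        )
    qualifies = pathogenic | (score <= fathmm_cutoff)
    hits = table.loc[qualifies, ["gene", "cell_line"]].astype(str).drop_duplicates()
    genes = sorted(table["gene"].astype(str).unique())
    lines = sorted(table["cell_line"].astype(str).unique())
    if cell_lines is not None:
        lines = sorted(set(lines) | set(map(str, cell_lines)))
    mat = pd.DataFrame(0.0, index=pd.Index(genes, name="gene"), columns=lines)
    for g, cl in hits.itertuples(index=False):
        mat.at[g, cl] = 1.0
    return OmicsDataset(dataset_id, site, "MUT", mat, "binary")


# ---------------------------------------------------------------------------
# Phospho-proteomics
# ---------------------------------------------------------------------------

def average_phospho(
    site_level: pd.DataFrame,
    site_to_protein: Mapping[str, str],
    dataset_id: str = "PHOS",
    site: str = "",
    platform: str = "RPPA",
) -> OmicsDataset:
    """Average phospho-site intensities mapping to the same protein.

    *site_level* is a phospho-site x cell-line matrix; *site_to_protein* maps
    each phospho-site identifier to exactly one protein.  Per cell line the
    protein value is the mean over its sites, skipping missing values.
    """
    if not site_to_protein:
        raise DatasetError("empty phospho-site to protein mapping")
    mapped = [s for s in site_level.index if s in site_to_protein]
    if not mapped:
        raise DatasetError("no phospho-site in the matrix is covered by the mapping")
    sub = site_level.loc[mapped]
    protein = pd.Index([site_to_protein[s] for s in mapped], name="gene")
    averaged = sub.groupby(protein).mean()  # pandas mean skips NaN
    return OmicsDataset(dataset_id, site, "PHOS", averaged, "continuous", platform)


# ---------------------------------------------------------------------------
# Promoter methylation
# ---------------------------------------------------------------------------

CPG_COLUMNS = ("cpg_id", "gene", "distance_upstream_of_tss", "missing_rate", "detection_p")


def promoter_methylation(
    cpgs: pd.DataFrame,
    window: tuple[float, float] = (200.0, 1500.0),
    max_missing_rate: float = 0.05,
    max_detection_p: float = 0.05,
    dataset_id: str = "METH",
    site: str = "",
    platform: str = "",
) -> OmicsDataset:
    """Gene-level promoter methylation from a CpG-site beta table.

    QC removes CpG sites with missing rate strictly above *max_missing_rate*
    (5%) or detection P strictly above *max_detection_p* (0.05).  Surviving
    CpGs located within the promoter window (200-1,500 bp upstream of the
    TSS, inclusive) are averaged per gene; genes with no qualifying CpG are
    absent from the output.

    *cpgs* columns: cpg_id, gene, distance_upstream_of_tss, missing_rate,
    detection_p, plus one column of beta values in [0,1] per cell line.
    """
    lo, hi = window
    if not lo < hi:
        raise ValueError(f"window min must be below max, got {window}")
    missing = [c for c in CPG_COLUMNS if c not in cpgs.columns]
    if missing:
        raise DatasetError(f"CpG table missing columns {missing}")
    beta_cols = [c for c in cpgs.columns if c not in CPG_COLUMNS]
    if not beta_cols:
        raise DatasetError("CpG table has no cell-line beta columns")
    betas = cpgs[beta_cols].apply(pd.to_numeric)
    if ((betas < 0) | (betas > 1)).any().any():
        raise DatasetError("CpG beta values must lie in [0, 1]")
    dist = pd.to_numeric(cpgs["distance_upstream_of_tss"])
    if (dist < 0).any():
        raise DatasetError("upstream distances must be >= 0")
    keep = (
        (pd.to_numeric(cpgs["missing_rate"]) <= max_missing_rate)
        & (pd.to_numeric(cpgs["detection_p"]) <= max_detection_p)
        & (dist >= lo)
        & (dist <= hi)
    )
    kept = cpgs.loc[keep]
    if kept.empty:
        mat = pd.DataFrame(index=pd.Index([], name="gene"), columns=beta_cols, dtype=float)
    else:
        mat = kept[beta_cols].apply(pd.to_numeric).groupby(kept["gene"].astype(str)).mean()
        mat.index.name = "gene"
    return OmicsDataset(dataset_id, site, "METH", mat, "continuous", platform)


# ---------------------------------------------------------------------------
# Quantile normalization
# ---------------------------------------------------------------------------

def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every column onto the common mean-quantile reference distribution.

    The reference is the across-column mean of within-column sorted values;
    each column's entries are replaced by the reference value at their
    within-column (average, for ties) rank.  Ranks within columns are
    preserved; the transform is idempotent.  Missing entries stay missing and
    the remaining entries of such columns are placed by interpolating the
    reference at proportionally scaled ranks.
    """
    if matrix.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 columns")
    counts = matrix.notna().sum(axis=0)
    if (counts == 0).any():
        bad = counts.index[counts == 0].tolist()
        raise ValueError(f"all-missing column(s): {bad}")
    if (counts < 2).any():
        raise ValueError("each column needs at least 2 non-missing values")
    n = matrix.shape[0]
    grid = np.arange(1, n + 1, dtype=float)
    # reference curve on ranks 1..n: average of per-column sorted values,
    # each column's sorted values stretched to the full grid if it has NaNs
    ref = np.zeros(n)
    for col in matrix.columns:
        v = np.sort(matrix[col].dropna().to_numpy())
        m = len(v)
        if m == n:
            ref += v
        else:
            pos = np.linspace(1, n, m)
            ref += np.interp(grid, pos, v)
    ref /= matrix.shape[1]

    out = pd.DataFrame(index=matrix.index, columns=matrix.columns, dtype=float)
    for col in matrix.columns:
        v = matrix[col].to_numpy(dtype=float)
        mask = ~np.isnan(v)
        m = int(mask.sum())
        ranks = rankdata(v[mask])  # average ranks for ties
        if m != n:  # rescale ranks 1..m onto the 1..n reference grid
            ranks = 1 + (ranks - 1) * (n - 1) / (m - 1)
        filled = np.interp(ranks, grid, ref)
        res = np.full(n, np.nan)
        res[mask] = filled
        out[col] = res
    return out
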