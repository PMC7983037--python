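"""Cross-site reproducibility of molecular profiles.

How well do two laboratories agree on the same cell line?  For every pair of
datasets of a modality, the profiles of identical cell lines are compared on
the shared gene set: Spearman's correlation for continuous modalities,
Matthews correlation coefficient (MCC) for binary ones.  Correlations of
*non-identical* line pairs between the same two datasets give the baseline
expected from panel-wide similarity alone; the identical/baseline mean ratio
("fold increase") summarizes how much signal is cell line-specific.
Records based on fewer than 10 shared genes or with p >= 0.05 are flagged
excluded, mirroring the filter used when summarizing reproducibility.
"""

from __future__ import annotations

import itertools
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import matthews_corrcoef

from .datasets import DatasetError, OmicsDataset

RECORD_COLUMNS = [
    "dataset_1", "dataset_2", "line_1", "line_2", "n_shared_genes",
    "statistic", "value", "p", "identical", "same_tissue", "excluded",
]

MIN_SHARED_GENES = 10
P_FILTER = 0.05


def _pair_stats(x: np.ndarray, y: np.ndarray, binary: bool) -> tuple[str, float, float]:
    """(statistic name, value, p) for one aligned profile pair."""
    n = len(x)
    if binary:
        mcc = matthews_corrcoef(x.astype(int), y.astype(int)) if n else np.nan
        # chi-square identity n * MCC^2 ~ chi2_1 under independence
        p = float(stats.chi2.sf(n * mcc**2, df=1)) if np.isfinite(mcc) else np.nan
        return "mcc", float(mcc), p
    if n < 3 or np.std(x) == 0 or np.std(y) == 0:
        return "spearman", np.nan, np.nan
    rho, p = stats.spearmanr(x, y)
    return "spearman", float(rho), float(p)


def _one_record(
    ds1: OmicsDataset, ds2: OmicsDataset, l1: str, l2: str,
    identical: bool, same_tissue: bool | None,
) -> dict:
    shared = ds1.genes.intersection(ds2.genes)
    a = ds1.values.loc[shared, l1]
    b = ds2.values.loc[shared, l2]
    mask = a.notna() & b.notna()
    n = int(mask.sum())
    if n == 0:
        stat = "mcc" if ds1.is_binary else "spearman"
        value, p = np.nan, np.nan
    else:
        stat, value, p = _pair_stats(a[mask].to_numpy(), b[mask].to_numpy(), ds1.is_binary)
    excluded = (n < MIN_SHARED_GENES) or not (p < P_FILTER)
    return {
        "dataset_1": ds1.dataset_id, "dataset_2": ds2.dataset_id,
        "line_1": l1, "line_2": l2, "n_shared_genes": n,
        "statistic": stat, "value": value, "p": p,
        "identical": identical, "same_tissue": same_tissue, "excluded": excluded,
    }


def _check_comparable(ds1: OmicsDataset, ds2: OmicsDataset) -> None:
    if ds1.is_binary != ds2.is_binary:
        raise DatasetError(
            "cannot compare continuous with binary datasets "
            f"({ds1.dataset_id} vs {ds2.dataset_id})"
        )


def _same_tissue(tissue_map: Mapping[str, str] | None, l1: str, l2: str) -> bool | None:
    if tissue_map is None:
        return None
    t1, t2 = tissue_map.get(l1), tissue_map.get(l2)
    if t1 is None or t2 is None:
        return None
    return t1 == t2


def pairwise_concordance(
    ds1: OmicsDataset,
    ds2: OmicsDataset,
    identity_map: Mapping[str, str] | None = None,
    tissue_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Concordance records for identical cell lines of two datasets.

    *identity_map* maps ds2 line ids to ds1 line ids when names differ;
    by default shared column names denote identical lines.  One record per
    identical pair, on the genes measured in both.
    """
    _check_comparable(ds1, ds2)
    if identity_map:
        pairs = [(identity_map[l2], l2) for l2 in ds2.cell_lines if l2 in identity_map
                 and identity_map[l2] in ds1.cell_lines]
    else:
        pairs = [(l, l) for l in ds1.cell_lines.intersection(ds2.cell_lines)]
    records = [
        _one_record(ds1, ds2, l1, l2, True, _same_tissue(tissue_map, l1, l2))
        for l1, l2 in pairs
    ]
    return pd.DataFrame(records, columns=RECORD_COLUMNS)


def nonidentical_baseline(
    ds1: OmicsDataset,
    ds2: OmicsDataset,
    n_pairs: int = 100,
    seed: int = 0,
    identity_map: Mapping[str, str] | None = None,
    tissue_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Concordance records for a seeded sample of non-identical line pairs.

    Pairs are drawn uniformly without replacement from all cross pairs that
    are not identical; if fewer than *n_pairs* exist, all are used.
    """
    _check_comparable(ds1, ds2)
    if len(ds1.cell_lines) < 2 or len(ds2.cell_lines) < 2:
        raise DatasetError("need at least 2 cell lines per dataset")
    ident = dict(identity_map) if identity_map else {l: l for l in ds2.cell_lines}
    all_pairs = [
        (l1, l2)
        for l1, l2 in itertools.product(ds1.cell_lines, ds2.cell_lines)
        if ident.get(l2) != l1
    ]
    rng = np.random.default_rng(seed)
    if len(all_pairs) > n_pairs:
        idx = rng.choice(len(all_pairs), size=n_pairs, replace=False)
        chosen = [all_pairs[i] for i in sorted(idx)]
    else:
        chosen = all_pairs
    records = [
        _one_record(ds1, ds2, l1, l2, False, _same_tissue(tissue_map, l1, l2))
        for l1, l2 in chosen
    ]
    return pd.DataFrame(records, columns=RECORD_COLUMNS)


def fold_increase(
    identical: pd.DataFrame, baseline: pd.DataFrame
) -> tuple[float, float]:
    """(mean(identical)/mean(baseline), Wilcoxon rank-sum p).

    Quantifies how much higher the correlation of identical cell lines is
    than the non-identical baseline.  Returns NaN ratio when the baseline
    mean is not positive (the ratio is then meaningless).
    """
    if identical.empty or baseline.empty:
        raise ValueError("both record sets must be non-empty")
    vi = identical["value"].dropna().to_numpy()
    vb = baseline["value"].dropna().to_numpy()
    if len(vi) == 0 or len(vb) == 0:
        raise ValueError("no finite correlation values to compare")
    _, p = stats.ranksums(vi, vb)
    mb = vb.mean()
    ratio = vi.mean() / mb if mb > 0 else np.nan
    return float(ratio), float(p)


def summarize(records: pd.DataFrame, use_excluded: bool = False) -> pd.DataFrame:
    """Median/mean [range] summary per dataset pair, plus per-profile CV.

    Mean and median are both reported since the two are easily conflated in
    cross-study comparisons.
    """
    df = records if use_excluded else records[~records["excluded"]]
    if df.empty:
        return pd.DataFrame(
            columns=["dataset_1", "dataset_2", "statistic", "n", "mean",
                     "median", "min", "max"]
        )
    grouped = df.groupby(["dataset_1", "dataset_2", "statistic"])["value"]
    out = grouped.agg(n="count", mean="mean", median="median", min="min", max="max")
    return out.reset_index()


def coefficient_of_variation(dataset: OmicsDataset) -> pd.Series:
    """Per-gene CV (SD/|mean|) across cell lines; NaN where the mean is 0."""
    vals = dataset.values
    mean = vals.mean(axis=1)
    sd = vals.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = sd / mean.abs()
    return cv.replace([np.inf, -np.inf], np.nan)
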