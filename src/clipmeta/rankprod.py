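"""One-class rank-product meta-analysis with permutation pfp estimates.

Given per-dataset scores for the same genes, each dataset is reduced to
normalized rank ratios (rank / number of ranked genes, average ranks for
ties), the rank product of a gene is the geometric mean of its ratios over
the datasets covering it, and significance is expressed as the pfp
(percentage/proportion of false positives): the permutation-estimated
expected number of null genes scoring at least as extremely, divided by the
gene's rank — an FDR-like quantity.  Small rank products mark genes that sit
consistently at the chosen end of every list.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

UP = "UP"
DOWN = "DOWN"


@dataclass
class RankedList:
    """One dataset's normalized rank ratios for one direction.

    ratios maps gene -> rank/n in (0, 1]; rank 1 is the most extreme gene in
    the requested direction (largest score for UP, smallest for DOWN).
    """

    dataset_id: str
    direction: str
    ratios: pd.Series

    def __post_init__(self) -> None:
        if self.direction not in (UP, DOWN):
            raise ValueError(f"direction must be UP or DOWN, got {self.direction!r}")
        vals = self.ratios.to_numpy(dtype=float)
        if len(vals) and (vals.min() <= 0 or vals.max() > 1):
            raise ValueError("rank ratios must lie in (0, 1]")

    def __len__(self) -> int:
        return len(self.ratios)


def rank_scores(scores: pd.Series, direction: str, dataset_id: str = "") -> RankedList:
    """Rank a gene -> score mapping into normalized rank ratios.

    UP ranks descending by score (largest score -> rank 1), DOWN ascending;
    ties get average ranks.  Missing scores are dropped; at least two
    non-missing scores are required.
    """
    s = pd.Series(scores).astype(float).dropna()
    if len(s) < 2:
        raise ValueError(f"need >=2 non-missing scores to rank, got {len(s)}")
    vals = s.to_numpy()
    ranks = rankdata(-vals if direction == UP else vals)
    return RankedList(dataset_id, direction, pd.Series(ranks / len(s), index=s.index))


def rank_product(lists: Sequence[RankedList]) -> pd.DataFrame:
    """Geometric-mean rank product per gene over the lists covering it.

    Returns a DataFrame indexed by gene with columns ``rp`` (in (0,1]),
    ``k`` (number of covering lists) and ``rank`` (ascending position by rp,
    average ranks for ties).  A gene appears if present in at least one list.
    """
    if not lists:
        raise ValueError("need at least one ranked list")
    ratio_matrix = pd.DataFrame({i: rl.ratios for i, rl in enumerate(lists)})
    logr = np.log(ratio_matrix.to_numpy(dtype=float))
    k = np.sum(~np.isnan(logr), axis=1)
    rp = np.exp(np.nansum(logr, axis=1) / k)
    out = pd.DataFrame({"rp": rp, "k": k}, index=ratio_matrix.index)
    out["rank"] = rankdata(out["rp"].to_numpy())
    return out.sort_values("rp")


def estimate_pfp(
    observed: pd.DataFrame,
    lists: Sequence[RankedList],
    n_perm: int = 100,
    seed: int | np.random.SeedSequence = 0,
) -> pd.DataFrame:
    """Permutation pfp for an observed rank-product table.

    Per permutation, gene labels are shuffled independently within each
    dataset's ranked scores (ratios move among the genes that dataset
    covers; coverage patterns are preserved), and the rank product is
    recomputed.  ``E_g`` is the mean over permutations of the number of null
    genes with rp <= observed rp_g, and ``pfp_raw = E_g / rank_g``.  ``pfp``
    is the raw value monotonized by a cumulative maximum along increasing rp,
    so selection at any pfp threshold is a prefix of the rp-sorted list.
    Bit-reproducible for a fixed seed.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    genes = observed.index
    ratio_matrix = pd.DataFrame({i: rl.ratios for i, rl in enumerate(lists)})
    ratio_matrix = ratio_matrix.reindex(genes)
    logr = np.log(ratio_matrix.to_numpy(dtype=float).T)  # (k_lists, n_genes)
    k = np.sum(~np.isnan(logr), axis=0)
    obs_rp = observed["rp"].to_numpy(dtype=float)
    obs_rank = observed["rank"].to_numpy(dtype=float)

    masks = [~np.isnan(row) for row in logr]
    counts = np.zeros(len(genes))
    perm = np.empty_like(logr)
    for _ in range(n_perm):
        perm[:] = logr
        for j, mask in enumerate(masks):
            vals = logr[j, mask]
            perm[j, mask] = vals[rng.permutation(len(vals))]
        null_rp = np.exp(np.nansum(perm, axis=0) / k)
        null_rp.sort()
        counts += np.searchsorted(null_rp, obs_rp, side="right")

    e_g = counts / n_perm
    pfp_raw = e_g / obs_rank
    out = observed.copy()
    out["E"] = e_g
    out["pfp_raw"] = pfp_raw
    order = np.argsort(obs_rp, kind="stable")
    mono = np.empty_like(pfp_raw)
    mono[order] = np.maximum.accumulate(pfp_raw[order])
    out["pfp"] = mono
    return out


def rank_product_pfp(
    lists: Sequence[RankedList],
    n_perm: int = 100,
    seed: int | np.random.SeedSequence = 0,
) -> pd.DataFrame:
    """Convenience wrapper: rank product plus permutation pfp in one call."""
    observed = rank_product(lists)
    return estimate_pfp(observed, lists, n_perm=n_perm, seed=seed)


def results_to_tsv(results: pd.DataFrame, path, direction: str = "") -> None:
    out = results.copy()
    if direction:
        out.insert(0, "direction", direction)
    out.to_csv(path, sep="\t", index_label="gene")
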