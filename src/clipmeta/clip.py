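"""Cell line-specific gene calling: outlier/proportion scores, per-feature
CCS calls, and robust (rCCS) signatures.

For a continuous modality, the evidence that gene G is specific to cell
line j in dataset D is the Outlier Evidence Score

    OES_{G,D,j} = (X_j - mean_i X_i) / SD_i X_i        (sample SD, across lines)

i.e. a z-score of the line against the panel.  For a binary modality the
evidence is the Proportion Score PS_{G,D} = F/N, the alteration frequency in
the panel: an alteration carried by the line and rare overall (PS <= 10%) is
line-specific.  Per cell line, OES values from every dataset of a modality
are integrated by one-class rank product; genes with permutation pfp below
the modality threshold (0.10; 0.25 for the noisier dependency screens) are
CCS_UP / CCS_DOWN calls.  Lines covered by a single dataset fall back to a
fixed top-k selection (100 genes; 200 for dependency screens; 10 for the
small phospho-protein panels).  A gene with CCS evidence in two or more of
the eight modality *types* in the same line is a robust CCS (rCCS) gene.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import DatasetError, DatasetRegistry, OmicsDataset
from .harmonize import quantile_normalize
from .rankprod import DOWN, UP, RankedList, estimate_pfp, rank_product, rank_scores

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# The 13 modality features over 8 gene-space modality types
# ---------------------------------------------------------------------------

#: feature -> (modality, direction); direction None marks binary features
FEATURES: dict[str, tuple[str, str | None]] = {
    "METH_UP": ("METH", UP),
    "METH_DOWN": ("METH", DOWN),
    "GEXP_UP": ("GEXP", UP),
    "GEXP_DOWN": ("GEXP", DOWN),
    "PEXP_UP": ("PEXP", UP),
    "PEXP_DOWN": ("PEXP", DOWN),
    "PHOS_UP": ("PHOS", UP),
    "PHOS_DOWN": ("PHOS", DOWN),
    "FUNC_DOWN": ("FUNC", DOWN),   # low dependency score = essential
    "TAS_UP": ("TAS", UP),         # high addiction
    "CNV_AMP": ("CNV_GAIN", None),
    "CNV_DEL": ("CNV_LOSS", None),
    "MUT": ("MUT", None),
}
CONTINUOUS_FEATURES = tuple(f for f, (_, d) in FEATURES.items() if d is not None)
BINARY_FEATURES = ("CNV_AMP", "CNV_DEL", "MUT")

#: feature -> modality type counted for rCCS status (CNV_AMP and CNV_DEL
#: share the CNV type, so they alone never make a gene robust)
FEATURE_TYPE: dict[str, str] = {
    f: ("CNV" if f in ("CNV_AMP", "CNV_DEL") else FEATURES[f][0]) for f in FEATURES
}
MODALITY_TYPES = tuple(sorted(set(FEATURE_TYPE.values())))  # 8 types

assert len(FEATURES) == 13 and len(MODALITY_TYPES) == 8


@dataclass
class ClipConfig:
    """Tunable thresholds of the calling pipeline (shipped at their printed
    defaults; see the methods note for provenance)."""

    pfp_default: float = 0.10
    pfp_func: float = 0.25
    ps_cutoff: float = 0.10
    fallback_top_continuous: int = 100
    fallback_top_func: int = 200
    fallback_top_phos: int = 10
    n_perm: int = 100
    seed: int = 0
    #: "any": rarity in one covering dataset suffices for a binary CCS call;
    #: "all": required in every covering dataset where the line is altered
    binary_rule: str = "any"
    min_lines_oes: int = 3

    def pfp_cutoff(self, feature: str) -> float:
        return self.pfp_func if feature == "FUNC_DOWN" else self.pfp_default

    def fallback_top(self, feature: str) -> int:
        if feature == "FUNC_DOWN":
            return self.fallback_top_func
        if feature.startswith("PHOS"):
            return self.fallback_top_phos
        return self.fallback_top_continuous


def _call_seed(seed: int, cell_line: str, feature: str) -> np.random.SeedSequence:
    """Deterministic per-(line, feature) seed stream derived from the run seed."""
    tag = zlib.crc32(f"{cell_line}|{feature}".encode()) % (2**31)
    return np.random.SeedSequence((int(seed) % (2**31), tag))


# ---------------------------------------------------------------------------
# Evidence scores
# ---------------------------------------------------------------------------

def compute_oes(dataset: OmicsDataset, min_lines: int = 3) -> pd.DataFrame:
    """Outlier Evidence Scores: per-gene z-scores across the dataset's lines.

    Genes measured in fewer than *min_lines* cell lines, or with zero
    dispersion, are excluded (NaN rows).  On complete data each retained
    gene's scores have mean 0 and sample SD 1 by construction.
    """
    if dataset.is_binary:
        raise DatasetError(f"OES is defined for continuous datasets, got {dataset.dataset_id}")
    vals = dataset.values.to_numpy(dtype=float)
    n_obs = np.sum(~np.isnan(vals), axis=1)
    mean = np.full(vals.shape[0], np.nan)
    sd = np.full(vals.shape[0], np.nan)
    ok = n_obs >= max(min_lines, 2)
    if ok.any():
        mean[ok] = np.nanmean(vals[ok], axis=1)
        sd[ok] = np.nanstd(vals[ok], axis=1, ddof=1)
    sd[sd == 0] = np.nan
    with np.errstate(invalid="ignore"):
        oes = (vals - mean[:, None]) / sd[:, None]
    return pd.DataFrame(oes, index=dataset.values.index, columns=dataset.values.columns)


def compute_ps(dataset: OmicsDataset) -> tuple[pd.Series, pd.DataFrame]:
    """Proportion Scores for a binary dataset.

    Returns ``(ps, presence)``: per-gene alteration frequency F/N (missing
    entries excluded from both F and N) and the boolean presence matrix.
    """
    if not dataset.is_binary:
        raise DatasetError(f"PS is defined for binary datasets, got {dataset.dataset_id}")
    vals = dataset.values
    f = (vals == 1.0).sum(axis=1)
    n = vals.notna().sum(axis=1)
    with np.errstate(invalid="ignore"):
        ps = f / n.replace(0, np.nan)
    presence = (vals == 1.0)
    return ps, presence


# ---------------------------------------------------------------------------
# Per-feature CCS calls
# ---------------------------------------------------------------------------

@dataclass
class CcsCall:
    """CCS genes of one (cell line, modality feature) with supporting evidence."""

    cell_line: str
    feature: str
    selected: frozenset[str]
    method: str  # "rankprod" | "fallback" | "binary" | "empty"
    evidence: pd.DataFrame
    n_datasets: int


def call_ccs_continuous(
    cell_line: str,
    feature: str,
    datasets: Sequence[OmicsDataset],
    config: ClipConfig,
    oes_cache: Mapping[str, pd.DataFrame] | None = None,
) -> CcsCall:
    """Call CCS genes for one continuous modality feature in one cell line.

    With >=2 covering datasets, OES ranked lists are integrated by rank
    product and genes with pfp below the feature's threshold are selected.
    With exactly one, the single-study fallback selects the fixed top-k genes
    by OES in the feature's direction.
    """
    if feature not in CONTINUOUS_FEATURES:
        raise ValueError(f"{feature!r} is not a continuous modality feature")
    modality, direction = FEATURES[feature]
    lists: list[RankedList] = []
    for ds in datasets:
        if ds.modality != modality or not ds.covers(cell_line):
            continue
        oes = oes_cache[ds.dataset_id] if oes_cache else compute_oes(ds, config.min_lines_oes)
        col = oes[cell_line].dropna()
        if len(col) < 2:
            continue
        lists.append(rank_scores(col, direction, dataset_id=ds.dataset_id))
    if not lists:
        logger.warning("no dataset covers line %s for feature %s", cell_line, feature)
        return CcsCall(cell_line, feature, frozenset(), "empty", pd.DataFrame(), 0)

    if len(lists) >= 2:
        observed = rank_product(lists)
        result = estimate_pfp(
            observed, lists, n_perm=config.n_perm,
            seed=_call_seed(config.seed, cell_line, feature),
        )
        cutoff = config.pfp_cutoff(feature)
        selected = frozenset(result.index[result["pfp"] < cutoff])
        return CcsCall(cell_line, feature, selected, "rankprod", result, len(lists))

    # single-study fallback: fixed top-k in the feature's direction
    ratios = lists[0].ratios
    k = min(config.fallback_top(feature), len(ratios))
    # deterministic tie-break: ratio, then gene id
    order = sorted(ratios.index, key=lambda g: (ratios[g], g))
    selected = frozenset(order[:k])
    evidence = pd.DataFrame({"rank_ratio": ratios})
    evidence["selected"] = evidence.index.isin(selected)
    return CcsCall(cell_line, feature, selected, "fallback", evidence, 1)


def call_ccs_binary(
    cell_line: str,
    feature: str,
    datasets: Sequence[OmicsDataset],
    config: ClipConfig,
) -> CcsCall:
    """Call CCS genes for a binary feature: alteration present in the line and
    rare (PS <= cutoff) in at least one covering dataset where present
    (``binary_rule="all"`` demands rarity in every such dataset)."""
    if feature not in BINARY_FEATURES:
        raise ValueError(f"{feature!r} is not a binary modality feature")
    modality, _ = FEATURES[feature]
    qualifying: dict[str, list] = {}
    n_cov = 0
    rows = []
    for ds in datasets:
        if ds.modality != modality or cell_line not in ds.cell_lines:
            continue
        n_cov += 1
        ps, presence = compute_ps(ds)
        present = presence[cell_line]
        for gene in present.index[present]:
            qualifying.setdefault(gene, []).append(ps[gene] <= config.ps_cutoff)
            rows.append((gene, ds.dataset_id, ps[gene]))
    if config.binary_rule == "all":
        selected = frozenset(g for g, oks in qualifying.items() if all(oks))
    else:
        selected = frozenset(g for g, oks in qualifying.items() if any(oks))
    evidence = pd.DataFrame(rows, columns=["gene", "dataset_id", "ps"])
    method = "binary" if n_cov else "empty"
    return CcsCall(cell_line, feature, selected, method, evidence, n_cov)


# ---------------------------------------------------------------------------
# Signatures
# ---------------------------------------------------------------------------

@dataclass
class CLIPSignature:
    """Per cell line: boolean evidence over the 13 features for every gene
    with at least one call, plus rCCS status."""

    cell_line: str
    evidence: pd.DataFrame  # genes x 13 boolean features

    @property
    def n_modality_types(self) -> pd.Series:
        types = pd.Series([FEATURE_TYPE[f] for f in self.evidence.columns],
                          index=self.evidence.columns)
        counts = pd.Series(0, index=self.evidence.index)
        for t in MODALITY_TYPES:
            cols = types.index[types == t]
            counts += self.evidence[cols].any(axis=1).astype(int)
        return counts

    @property
    def rccs(self) -> pd.Series:
        return self.n_modality_types >= 2

    def rccs_genes(self) -> frozenset[str]:
        r = self.rccs
        return frozenset(r.index[r])

    def has_feature(self, gene: str, feature: str) -> bool:
        if gene not in self.evidence.index:
            return False
        return bool(self.evidence.at[gene, feature])


def build_signature(cell_line: str, calls: Iterable[CcsCall]) -> CLIPSignature:
    """Assemble per-feature CCS calls into a cell line's CLIP signature."""
    calls = list(calls)
    if not calls:
        raise ValueError("build_signature needs calls from at least one feature")
    genes = sorted(set().union(*(c.selected for c in calls)))
    evidence = pd.DataFrame(False, index=pd.Index(genes, name="gene"),
                            columns=list(FEATURES))
    for call in calls:
        if call.selected:
            evidence.loc[list(call.selected), call.feature] = True
    return CLIPSignature(cell_line, evidence)


def rccs_status(signature: CLIPSignature, setting: str = "ALL_MODALITIES") -> pd.Series:
    """rCCS status per gene under one of the three benchmark settings.

    ALL_MODALITIES: >=2 modality types.  FUNC_COMPULSORY: additionally
    requires dependency-modality evidence (the synthetic-lethality setting).
    FUNC_EXCLUDED: >=2 modality types after dropping the dependency modality.
    """
    if setting == "ALL_MODALITIES":
        return signature.rccs
    if setting == "FUNC_COMPULSORY":
        return signature.rccs & signature.evidence["FUNC_DOWN"]
    if setting == "FUNC_EXCLUDED":
        cols = [f for f in signature.evidence.columns if FEATURE_TYPE[f] != "FUNC"]
        reduced = CLIPSignature(signature.cell_line, signature.evidence[cols])
        return reduced.n_modality_types >= 2
    raise ValueError(f"unknown setting {setting!r}")


def group_signature(
    gene: str, cell_lines: Sequence[str], signatures: Mapping[str, CLIPSignature]
) -> pd.Series:
    """Per-feature fraction of a cell-line subset in which *gene* is CCS."""
    if not cell_lines:
        raise ValueError("group_signature needs a non-empty cell-line subset")
    frac = pd.Series(0.0, index=list(FEATURES))
    for cl in cell_lines:
        sig = signatures[cl]
        for feat in FEATURES:
            if sig.has_feature(gene, feat):
                frac[feat] += 1
    return frac / len(cell_lines)


def subtype_enrichment(
    gene: str,
    group_a: Sequence[str],
    group_b: Sequence[str],
    signatures: Mapping[str, CLIPSignature],
) -> tuple[np.ndarray, float, float]:
    """Two-sided Fisher's exact test of rCCS status between two disjoint
    cell-line groups; returns (2x2 counts, odds ratio, p)."""
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    if set(group_a) & set(group_b):
        raise ValueError("groups must be disjoint")
    missing = [cl for cl in (*group_a, *group_b) if cl not in signatures]
    if missing:
        raise KeyError(f"no signature for cell line(s) {missing[:5]}")
    if not any(gene in signatures[cl].evidence.index for cl in (*group_a, *group_b)):
        raise KeyError(f"gene {gene!r} absent from all signatures of both groups")
    a = sum(signatures[cl].rccs.get(gene, False) for cl in group_a)
    b = sum(signatures[cl].rccs.get(gene, False) for cl in group_b)
    table = np.array([[a, len(group_a) - a], [b, len(group_b) - b]])
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return table, odds, p


# ---------------------------------------------------------------------------
# Whole-registry run
# ---------------------------------------------------------------------------

@dataclass
class ClipResult:
    """Signatures for every analysed cell line plus run bookkeeping."""

    signatures: dict[str, CLIPSignature]
    config: ClipConfig

    @property
    def cell_lines(self) -> list[str]:
        return list(self.signatures)

    def rccs_matrix(self, setting: str = "ALL_MODALITIES") -> pd.DataFrame:
        """Boolean gene x cell-line rCCS matrix under a benchmark setting."""
        cols = {cl: rccs_status(sig, setting) for cl, sig in self.signatures.items()}
        genes = sorted(set().union(*(c.index for c in cols.values())))
        out = pd.DataFrame(
            {cl: c.reindex(genes, fill_value=False).astype(bool) for cl, c in cols.items()},
            index=pd.Index(genes, name="gene"),
        )
        return out

    def rccs_frequency(self, cell_lines: Sequence[str] | None = None,
                       setting: str = "ALL_MODALITIES") -> pd.Series:
        """Fraction of (subset) lines in which each gene is rCCS."""
        mat = self.rccs_matrix(setting)
        if cell_lines is not None:
            cell_lines = [cl for cl in cell_lines if cl in mat.columns]
            mat = mat[cell_lines]
        if mat.shape[1] == 0:
            return pd.Series(dtype=float)
        return mat.sum(axis=1) / mat.shape[1]

    def to_tsv(self, directory) -> None:
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        rows = []
        for cl, sig in self.signatures.items():
            ev = sig.evidence
            rccs = sig.rccs
            for gene in ev.index:
                feats = ev.columns[ev.loc[gene]]
                for feat in feats:
                    rows.append((cl, gene, feat, bool(rccs[gene])))
        pd.DataFrame(rows, columns=["cell_line", "gene", "feature", "rccs"]).to_csv(
            directory / "ccs_calls.tsv", sep="\t", index=False
        )
        mat = self.rccs_matrix()
        long = mat.stack()
        long = long[long]
        long.rename("rccs").reset_index().to_csv(
            directory / "rccs_genes.tsv", sep="\t", index=False
        )


def run_clip(
    registry: DatasetRegistry,
    config: ClipConfig,
    cell_lines: Sequence[str] | None = None,
    features: Sequence[str] | None = None,
) -> ClipResult:
    """Run the full calling pipeline over a harmonized dataset registry.

    CNV must already be binarized (CNV_GAIN/CNV_LOSS datasets) and drug
    response projected to TAS; see :mod:`clipmeta.harmonize` and
    :mod:`clipmeta.tas`.
    """
    features = list(features) if features is not None else list(FEATURES)
    datasets = list(registry)
    if cell_lines is None:
        cell_lines = list(registry.all_cell_lines())
    # precompute OES once per continuous dataset
    oes_cache: dict[str, pd.DataFrame] = {}
    needed = {FEATURES[f][0] for f in features if f in CONTINUOUS_FEATURES}
    for ds in datasets:
        if not ds.is_binary and ds.modality in needed:
            oes_cache[ds.dataset_id] = compute_oes(ds, config.min_lines_oes)

    signatures: dict[str, CLIPSignature] = {}
    for cl in cell_lines:
        calls = []
        for feat in features:
            if feat in BINARY_FEATURES:
                calls.append(call_ccs_binary(cl, feat, datasets, config))
            else:
                calls.append(
                    call_ccs_continuous(cl, feat, datasets, config, oes_cache=oes_cache)
                )
        signatures[cl] = build_signature(cl, calls)
    return ClipResult(signatures, config)


# ---------------------------------------------------------------------------
# Simple methylation-only comparator
# ---------------------------------------------------------------------------

def meth_outlier_comparator(
    datasets: Sequence[OmicsDataset], z_cutoff: float = 1.66
) -> dict[str, pd.DataFrame]:
    """Single-modality outlier baseline on methylation data.

    Per dataset: quantile-normalize across lines, z-scale each gene, and flag
    entries with |z| strictly above *z_cutoff*.  Under a standard-normal null
    roughly ``2*(1 - Phi(1.66)) ~ 9.7%`` of genes are flagged per line.
    Returns dataset_id -> boolean gene x line flag matrix.
    """
    flags = {}
    for ds in datasets:
        if ds.is_binary:
            raise DatasetError("methylation comparator expects continuous data")
        qn = quantile_normalize(ds.values)
        vals = qn.to_numpy(dtype=float)
        n_obs = np.sum(~np.isnan(vals), axis=1)
        mean = np.full(vals.shape[0], np.nan)
        sd = np.full(vals.shape[0], np.nan)
        ok = n_obs >= 2
        if ok.any():
            mean[ok] = np.nanmean(vals[ok], axis=1)
            sd[ok] = np.nanstd(vals[ok], axis=1, ddof=1)
        sd[sd == 0] = np.nan
        with np.errstate(invalid="ignore"):
            z = (vals - mean[:, None]) / sd[:, None]
        flags[ds.dataset_id] = pd.DataFrame(
            np.abs(z) > z_cutoff, index=qn.index, columns=qn.columns
        )
    return flags


def outlier_flag_frequency(flags: Mapping[str, pd.DataFrame], gene: str) -> pd.Series:
    """Fraction of each dataset's lines in which *gene* is flagged an outlier."""
    out = {}
    for ds_id, mat in flags.items():
        if gene in mat.index:
            out[ds_id] = float(mat.loc[gene].mean())
    return pd.Series(out, dtype=float)
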