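"""Genetic-interaction and synthetic-lethality detection from rCCS profiles.

A driver-partner genetic interaction (GI) is called when the partner gene is
an rCCS gene significantly more often in driver-mutated cell lines than in
wild-type lines (two-sided Fisher's exact test on the 2x2 rCCS-by-mutation
table).  A GI is a candidate synthetic-lethal (SL) pair when the partner's
rCCS evidence includes the gene-dependency modality in the mutant lines,
i.e. the partner is selectively essential where the driver is altered.
Scans are restricted to epithelial cell lines and to drivers mutated in
enough lines to give the test power (>= 5 for driver scans, >= 10 for the
paralog benchmark).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportions_ztest

from .clip import CLIPSignature, ClipResult, rccs_status
from .datasets import OmicsDataset

BENCHMARK_SETTINGS = ("ALL_MODALITIES", "FUNC_COMPULSORY", "FUNC_EXCLUDED")


@dataclass
class GIResult:
    """Driver-partner 2x2 contingency of partner rCCS status in mutant vs
    wild-type lines."""

    driver: str
    partner: str
    a: int  # mutant & partner rCCS
    b: int  # mutant & not
    c: int  # wild-type & partner rCCS
    d: int  # wild-type & not
    odds_ratio: float
    fisher_p: float
    sl_flag: bool

    @property
    def n_mutant(self) -> int:
        return self.a + self.b

    @property
    def n_wildtype(self) -> int:
        return self.c + self.d


class DriverSkipped(ValueError):
    """Driver did not meet the mutant-line filter; carries the reason."""


def _mutant_split(
    mutations: OmicsDataset, driver: str, subset: Sequence[str]
) -> tuple[list[str], list[str]]:
    if driver not in mutations.genes:
        raise DriverSkipped(f"driver {driver!r} absent from the mutation matrix")
    row = mutations.values.loc[driver]
    lines = [cl for cl in subset if cl in row.index and not pd.isna(row[cl])]
    mutant = [cl for cl in lines if row[cl] == 1.0]
    wildtype = [cl for cl in lines if row[cl] == 0.0]
    return mutant, wildtype


def _line_profiles(
    signatures: Mapping[str, CLIPSignature], lines: Sequence[str], setting: str
) -> dict[str, tuple[frozenset, frozenset]]:
    """Per line: (rCCS gene set under *setting*, subset with dependency evidence)."""
    prof = {}
    for cl in lines:
        sig = signatures[cl]
        status = rccs_status(sig, setting)
        rgenes = frozenset(status.index[status])
        func = frozenset(
            g for g in rgenes if bool(sig.evidence.at[g, "FUNC_DOWN"])
        )
        prof[cl] = (rgenes, func)
    return prof


def _gi_from_profiles(
    driver: str,
    partner: str,
    mutant: Sequence[str],
    wildtype: Sequence[str],
    profiles: Mapping[str, tuple[frozenset, frozenset]],
    alternative: str,
) -> GIResult:
    a = sum(partner in profiles[cl][0] for cl in mutant)
    c = sum(partner in profiles[cl][0] for cl in wildtype)
    b, d = len(mutant) - a, len(wildtype) - c
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative=alternative)
    sl = any(partner in profiles[cl][1] for cl in mutant)
    return GIResult(driver, partner, a, b, c, d, float(odds), float(p), sl)


def test_gi(
    driver: str,
    partner: str,
    mutations: OmicsDataset,
    signatures: Mapping[str, CLIPSignature],
    subset: Sequence[str],
    min_mutant_lines: int = 5,
    setting: str = "ALL_MODALITIES",
    alternative: str = "two-sided",
) -> GIResult:
    """Fisher's exact test of partner rCCS enrichment in driver-mutant lines.

    *subset* is the cell-line panel (normally the epithelial subset) — only
    lines with a signature and a mutation call for the driver enter the
    table.  The SL flag is true when the partner carries dependency-modality
    CCS evidence in at least one mutant rCCS line.
    """
    mutant, wildtype = _mutant_split(mutations, driver, [cl for cl in subset if cl in signatures])
    if len(mutant) < min_mutant_lines:
        raise DriverSkipped(
            f"driver {driver!r} mutated in {len(mutant)} line(s) < {min_mutant_lines}"
        )
    profiles = _line_profiles(signatures, [*mutant, *wildtype], setting)
    return _gi_from_profiles(driver, partner, mutant, wildtype, profiles, alternative)


def gi_scan(
    drivers: Sequence[str],
    partners: Sequence[str],
    mutations: OmicsDataset,
    signatures: Mapping[str, CLIPSignature],
    subset: Sequence[str],
    min_mutant_lines: int = 5,
    setting: str = "ALL_MODALITIES",
    alternative: str = "two-sided",
) -> pd.DataFrame:
    """All driver x partner GI tests, sorted by p, with BH-adjusted p values
    reported alongside the raw ones."""
    lines = [cl for cl in subset if cl in signatures]
    profiles = _line_profiles(signatures, lines, setting)
    rows, skipped = [], []
    for driver in drivers:
        try:
            mutant, wildtype = _mutant_split(mutations, driver, lines)
            if len(mutant) < min_mutant_lines:
                raise DriverSkipped(
                    f"driver {driver!r} mutated in {len(mutant)} line(s) < {min_mutant_lines}"
                )
        except DriverSkipped as exc:
            skipped.append((driver, str(exc)))
            continue
        for partner in partners:
            if partner == driver:
                continue
            r = _gi_from_profiles(driver, partner, mutant, wildtype, profiles, alternative)
            rows.append(
                (r.driver, r.partner, r.a, r.b, r.c, r.d, r.odds_ratio, r.fisher_p, r.sl_flag)
            )
    out = pd.DataFrame(
        rows,
        columns=["driver", "partner", "a", "b", "c", "d", "odds_ratio", "fisher_p", "sl_flag"],
    )
    if not out.empty:
        out["fisher_p_bh"] = multipletests(out["fisher_p"], method="fdr_bh")[1]
        out = out.sort_values("fisher_p", kind="stable").reset_index(drop=True)
    else:
        out["fisher_p_bh"] = pd.Series(dtype=float)
    out.attrs["skipped"] = skipped
    return out


# ---------------------------------------------------------------------------
# Paralog benchmark
# ---------------------------------------------------------------------------

def read_paralog_groups(path) -> dict[str, list[str]]:
    """Two-column TSV (group id, gene) -> group id -> member genes."""
    table = pd.read_csv(path, sep="\t")
    gcol, mcol = table.columns[:2]
    groups: dict[str, list[str]] = {}
    for gid, gene in zip(table[gcol].astype(str), table[mcol].astype(str)):
        groups.setdefault(gid, []).append(gene)
    return groups


def paralog_benchmark(
    paralog_groups: Mapping[str, Sequence[str]],
    mutations: OmicsDataset,
    signatures: Mapping[str, CLIPSignature],
    subset: Sequence[str],
    setting: str = "FUNC_COMPULSORY",
    min_mutant_lines: int = 10,
    alpha: float = 0.05,
) -> dict:
    """Fraction of paralog groups with at least one significant GI.

    Within each group every ordered pair (mutated member -> partner rCCS) is
    tested in both directions; a group counts as a hit when any of its tests
    reaches p < alpha.  Groups whose members never pass the mutant-line
    filter are not tested; with zero tested groups the proportion is absent
    (None).
    """
    lines = [cl for cl in subset if cl in signatures]
    profiles = _line_profiles(signatures, lines, setting)
    tested = hits = 0
    per_group = {}
    for gid, members in paralog_groups.items():
        members = [m for m in dict.fromkeys(members)]
        if len(members) < 2:
            continue
        pvals = []
        for driver in members:
            for partner in members:
                if partner == driver:
                    continue
                try:
                    mutant, wildtype = _mutant_split(mutations, driver, lines)
                    if len(mutant) < min_mutant_lines:
                        continue
                except DriverSkipped:
                    continue
                r = _gi_from_profiles(driver, partner, mutant, wildtype, profiles, "two-sided")
                pvals.append(r.fisher_p)
        if not pvals:
            continue
        tested += 1
        hit = any(p < alpha for p in pvals)
        hits += hit
        per_group[gid] = {"n_tests": len(pvals), "min_p": min(pvals), "hit": hit}
    return {
        "setting": setting,
        "n_tested_groups": tested,
        "n_hit_groups": hits,
        "hit_proportion": hits / tested if tested else None,
        "per_group": per_group,
    }


def func_only_comparator(
    func: OmicsDataset,
    mutations: OmicsDataset,
    paralog_groups: Mapping[str, Sequence[str]],
    subset: Sequence[str],
    min_mutant_lines: int = 10,
    alpha: float = 0.05,
) -> dict:
    """Single-dataset dependency-screen comparator to the rCCS-based scan.

    Per qualifying paralog direction, a plain two-sample t-test compares the
    partner's dependency scores between mutant and wild-type lines (a
    moderated linear-model fit would differ mainly at very small panels).
    A group is a hit when any direction reaches p < alpha.
    """
    tested = hits = 0
    per_group = {}
    for gid, members in paralog_groups.items():
        members = [m for m in dict.fromkeys(members)]
        if len(members) < 2:
            continue
        pvals = []
        for driver in members:
            for partner in members:
                if partner == driver or partner not in func.genes:
                    continue
                try:
                    mutant, wildtype = _mutant_split(mutations, driver, list(subset))
                except DriverSkipped:
                    continue
                mutant = [cl for cl in mutant if cl in func.cell_lines]
                wildtype = [cl for cl in wildtype if cl in func.cell_lines]
                if len(mutant) < min_mutant_lines:
                    continue
                x = func.values.loc[partner, mutant].dropna()
                y = func.values.loc[partner, wildtype].dropna()
                if len(x) < 2 or len(y) < 2:
                    continue
                _, p = stats.ttest_ind(x, y, equal_var=True)
                if np.isfinite(p):
                    pvals.append(float(p))
        if not pvals:
            continue
        tested += 1
        hit = any(p < alpha for p in pvals)
        hits += hit
        per_group[gid] = {"n_tests": len(pvals), "min_p": min(pvals), "hit": hit}
    return {
        "dataset_id": func.dataset_id,
        "n_tested_groups": tested,
        "n_hit_groups": hits,
        "hit_proportion": hits / tested if tested else None,
        "per_group": per_group,
    }


# ---------------------------------------------------------------------------
# Proportion comparisons
# ---------------------------------------------------------------------------

def two_proportion_ztest(k1: int, n1: int, k2: int, n2: int) -> tuple[float, float]:
    """Pooled two-proportion z-test; returns (z, two-sided normal p).

    z^2 equals the Pearson chi-square statistic of the 2x2 table without
    continuity correction.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("sample sizes must be positive")
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("counts must satisfy 0 <= k <= n")
    z, p = proportions_ztest([k1, k2], [n1, n2], alternative="two-sided")
    return float(z), float(p)


def rccs_frequency_comparison(
    genes_a: Sequence[str],
    genes_b: Sequence[str],
    clip_result: ClipResult,
    subset: Sequence[str],
    setting: str = "ALL_MODALITIES",
) -> dict:
    """Compare rCCS frequencies of two disjoint gene sets over a cell-line
    subset (e.g. oncogenes vs non-oncogenes); Wilcoxon rank-sum p."""
    if set(genes_a) & set(genes_b):
        raise ValueError("gene sets must be disjoint")
    freq = clip_result.rccs_frequency(subset, setting)
    fa = freq.reindex(list(genes_a)).fillna(0.0)
    fb = freq.reindex(list(genes_b)).fillna(0.0)
    _, p = stats.ranksums(fa.to_numpy(), fb.to_numpy())
    return {
        "freq_a": fa,
        "freq_b": fb,
        "mean_a": float(fa.mean()),
        "mean_b": float(fb.mean()),
        "ranksum_p": float(p),
    }
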