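"""Outlier/proportion scoring, CCS calling, signatures and the
methylation-only comparator."""

import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

import clipmeta as cm
from clipmeta.clip import (
    FEATURES,
    FEATURE_TYPE,
    MODALITY_TYPES,
    CcsCall,
    ClipConfig,
    build_signature,
    call_ccs_binary,
    call_ccs_continuous,
    compute_oes,
    compute_ps,
    group_signature,
    meth_outlier_comparator,
    outlier_flag_frequency,
    rccs_status,
    subtype_enrichment,
)
from clipmeta.datasets import DatasetError

from conftest import make_dataset


class TestFeatureDecomposition:
    def test_thirteen_features_eight_types(self):
        assert len(FEATURES) == 13
        assert len(MODALITY_TYPES) == 8
        assert FEATURE_TYPE["CNV_AMP"] == FEATURE_TYPE["CNV_DEL"] == "CNV"


class TestComputeOes:
    def test_hand_zscores(self):
        ds = make_dataset({"c1": [1.0], "c2": [2.0], "c3": [3.0]})
        oes = compute_oes(ds)
        assert oes.at[0, "c3"] == pytest.approx(1.0)   # (3-2)/1 with sample SD
        assert oes.at[0, "c2"] == pytest.approx(0.0)   # value at the mean

    def test_outlier_zscore(self):
        vals = [1.0, 2.0, 3.0, 4.0, 10.0]
        ds = make_dataset({f"c{i}": [v] for i, v in enumerate(vals)})
        oes = compute_oes(ds)
        assert oes.at[0, "c4"] == pytest.approx((10 - 4) / np.std(vals, ddof=1), abs=1e-4)
        assert oes.at[0, "c4"] == pytest.approx(1.697, abs=1e-3)

    def test_mean_zero_sd_one(self):
        rng = np.random.default_rng(3)
        ds = make_dataset(
            {f"c{i}": col for i, col in enumerate(rng.normal(5, 3, size=(40, 25)).T)}
        )
        oes = compute_oes(ds).to_numpy()
        np.testing.assert_allclose(oes.mean(axis=1), 0.0, atol=1e-9)
        np.testing.assert_allclose(oes.std(axis=1, ddof=1), 1.0, atol=1e-9)

    def test_degenerate_genes_excluded(self):
        ds = make_dataset({
            "c1": [1.0, 5.0, 1.0], "c2": [1.0, np.nan, 2.0], "c3": [1.0, np.nan, 3.0]
        })
        oes = compute_oes(ds)
        assert oes.iloc[0].isna().all()  # zero dispersion
        assert oes.iloc[1].isna().all()  # fewer than 3 observed lines
        assert oes.iloc[2].notna().all()

    def test_binary_rejected(self):
        ds = make_dataset({"c1": [1.0], "c2": [0.0]}, modality="MUT")
        with pytest.raises(DatasetError):
            compute_oes(ds)


class TestComputePs:
    def test_frequency(self):
        row = [1.0] * 2 + [0.0] * 18
        ds = make_dataset({f"c{i}": [row[i]] for i in range(20)}, modality="MUT")
        ps, presence = compute_ps(ds)
        assert ps.iloc[0] == pytest.approx(0.10)
        assert presence.iloc[0].sum() == 2

    def test_missing_excluded_from_both_counts(self):
        row = [1.0, np.nan, 0.0, 0.0]
        ds = make_dataset({f"c{i}": [row[i]] for i in range(4)}, modality="MUT")
        ps, _ = compute_ps(ds)
        assert ps.iloc[0] == pytest.approx(1 / 3)

    def test_never_altered_gene(self):
        ds = make_dataset({f"c{i}": [0.0] for i in range(5)}, modality="MUT")
        ps, presence = compute_ps(ds)
        assert ps.iloc[0] == 0.0 and not presence.iloc[0].any()


def _continuous_datasets(rng, n_genes, lines, n_datasets, modality="GEXP",
                         site_names=("BROAD", "GDSC", "UHN"), planted=None):
    genes = [f"g{i}" for i in range(n_genes)]
    out = []
    for d in range(n_datasets):
        mat = pd.DataFrame(rng.standard_normal((n_genes, len(lines))),
                           index=genes, columns=lines)
        if planted:
            for (gene, line), value in planted.items():
                mat.at[gene, line] = value
        out.append(cm.OmicsDataset(f"{site_names[d]}_{modality}", site_names[d],
                                   modality, mat))
    return out


class TestCallCcsContinuous:
    def test_single_dataset_fallback_counts(self):
        rng = np.random.default_rng(1)
        lines = [f"cl{j}" for j in range(10)]
        cfg = ClipConfig(seed=0)
        for feature, n_genes, expected in [
            ("GEXP_UP", 2000, 100), ("FUNC_DOWN", 2000, 200), ("PHOS_UP", 200, 10),
        ]:
            modality = FEATURES[feature][0]
            (ds,) = _continuous_datasets(rng, n_genes, lines, 1, modality=modality)
            call = call_ccs_continuous("cl0", feature, [ds], cfg)
            assert call.method == "fallback"
            assert len(call.selected) == expected

    def test_fallback_universe_smaller_than_k(self):
        rng = np.random.default_rng(2)
        (ds,) = _continuous_datasets(rng, 40, ["cl0", "cl1", "cl2"], 1)
        call = call_ccs_continuous("cl0", "GEXP_UP", [ds], ClipConfig(seed=0))
        assert len(call.selected) == 40  # whole universe when smaller than k

    def test_fallback_selects_extreme_direction(self):
        rng = np.random.default_rng(3)
        lines = [f"cl{j}" for j in range(8)]
        planted = {("g0", "cl0"): 25.0, ("g1", "cl0"): -25.0}
        (ds,) = _continuous_datasets(rng, 500, lines, 1, planted=planted)
        up = call_ccs_continuous("cl0", "GEXP_UP", [ds], ClipConfig(seed=0))
        down = call_ccs_continuous("cl0", "GEXP_DOWN", [ds], ClipConfig(seed=0))
        assert "g0" in up.selected and "g1" not in up.selected
        assert "g1" in down.selected and "g0" not in down.selected

    def test_multi_dataset_rankprod_recovers_planted_outlier(self):
        rng = np.random.default_rng(4)
        lines = [f"cl{j}" for j in range(15)]
        planted = {("g0", "cl0"): 6.0}
        datasets = _continuous_datasets(rng, 400, lines, 3, planted=planted)
        call = call_ccs_continuous("cl0", "GEXP_UP", datasets, ClipConfig(seed=5))
        assert call.method == "rankprod" and call.n_datasets == 3
        assert "g0" in call.selected
        assert call.evidence.at["g0", "pfp"] < 0.10
        # null genes stay mostly unselected
        assert len(call.selected) <= 10

    def test_no_covering_dataset_warns_empty(self, caplog):
        rng = np.random.default_rng(5)
        datasets = _continuous_datasets(rng, 10, ["cl1", "cl2", "cl3"], 1)
        with caplog.at_level("WARNING"):
            call = call_ccs_continuous("absent", "GEXP_UP", datasets, ClipConfig(seed=0))
        assert call.selected == frozenset() and call.method == "empty"
        assert "absent" in caplog.text


class TestCallCcsBinary:
    def mk(self, rows, lines, dataset_id="B1", site="BROAD"):
        return cm.OmicsDataset(dataset_id, site, "MUT",
                               pd.DataFrame(rows, columns=lines))

    def test_rare_alteration_in_focal_line_is_ccs(self):
        lines = [f"cl{j}" for j in range(100)]
        ds = self.mk([[1.0] * 5 + [0.0] * 95], lines)  # frequency 5/100
        call = call_ccs_binary("cl0", "MUT", [ds], ClipConfig(seed=0))
        assert len(call.selected) == 1

    def test_common_alteration_not_ccs(self):
        lines = [f"cl{j}" for j in range(100)]
        ds = self.mk([[1.0] * 30 + [0.0] * 70], lines)
        call = call_ccs_binary("cl0", "MUT", [ds], ClipConfig(seed=0))
        assert not call.selected

    def test_absent_in_focal_line_not_ccs(self):
        lines = [f"cl{j}" for j in range(100)]
        ds = self.mk([[0.0] + [1.0] * 5 + [0.0] * 94], lines)
        call = call_ccs_binary("cl0", "MUT", [ds], ClipConfig(seed=0))
        assert not call.selected

    def test_boundary_ten_percent_inclusive(self):
        lines = [f"cl{j}" for j in range(20)]
        ds = self.mk([[1.0] * 2 + [0.0] * 18], lines)
        call = call_ccs_binary("cl0", "MUT", [ds], ClipConfig(seed=0))
        assert len(call.selected) == 1  # 2/20 = 0.10 qualifies (<= rule)

    def test_or_versus_and_rule_across_datasets(self):
        lines = [f"cl{j}" for j in range(20)]
        rare = self.mk([[1.0] * 2 + [0.0] * 18], lines, "D_rare", "BROAD")
        common = self.mk([[1.0] * 10 + [0.0] * 10], lines, "D_common", "GDSC")
        or_call = call_ccs_binary("cl0", "MUT", [rare, common], ClipConfig(seed=0))
        and_call = call_ccs_binary("cl0", "MUT", [rare, common],
                                   ClipConfig(seed=0, binary_rule="all"))
        assert len(or_call.selected) == 1   # rare in one dataset suffices
        assert not and_call.selected        # common elsewhere fails the AND rule


def _call(cell_line, feature, genes):
    return CcsCall(cell_line, feature, frozenset(genes), "test", pd.DataFrame(), 1)


class TestSignatures:
    def test_single_modality_not_robust(self):
        sig = build_signature("cl0", [_call("cl0", "GEXP_UP", ["g1"])])
        assert not sig.rccs["g1"]

    def test_two_types_robust(self):
        sig = build_signature("cl0", [
            _call("cl0", "GEXP_UP", ["g1"]), _call("cl0", "METH_DOWN", ["g1"]),
        ])
        assert sig.rccs["g1"] and sig.n_modality_types["g1"] == 2

    def test_cnv_amp_plus_del_is_one_type(self):
        sig = build_signature("cl0", [
            _call("cl0", "CNV_AMP", ["g1"]), _call("cl0", "CNV_DEL", ["g1"]),
        ])
        assert sig.n_modality_types["g1"] == 1 and not sig.rccs["g1"]

    def test_benchmark_settings(self):
        sig = build_signature("cl0", [
            _call("cl0", "GEXP_UP", ["g1", "g2"]),
            _call("cl0", "METH_UP", ["g2"]),
            _call("cl0", "FUNC_DOWN", ["g1"]),
        ])
        # g1: GEXP+FUNC; g2: GEXP+METH
        assert rccs_status(sig, "ALL_MODALITIES").to_dict() == {"g1": True, "g2": True}
        assert rccs_status(sig, "FUNC_COMPULSORY").to_dict() == {"g1": True, "g2": False}
        assert rccs_status(sig, "FUNC_EXCLUDED").to_dict() == {"g1": False, "g2": True}

    def test_group_signature_fractions(self):
        sigs = {}
        for j in range(24):
            feats = [_call(f"cl{j}", "GEXP_DOWN", ["g1"])] if j < 3 else \
                    [_call(f"cl{j}", "MUT", ["g9"])]
            sigs[f"cl{j}"] = build_signature(f"cl{j}", feats)
        prof = group_signature("g1", [f"cl{j}" for j in range(24)], sigs)
        assert prof["GEXP_DOWN"] == pytest.approx(3 / 24)
        assert prof.drop("GEXP_DOWN").eq(0).all()
        assert group_signature("g_absent", ["cl0"], sigs).eq(0).all()


def _fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by hypergeometric enumeration over all tables with
    the observed margins (sum of probabilities <= observed's)."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def table_p(x):
        return (comb(r1, x) * comb(r2, c1 - x)) / comb(n, c1)

    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    p_obs = table_p(a)
    return sum(table_p(x) for x in range(lo, hi + 1) if table_p(x) <= p_obs * (1 + 1e-9))


class TestSubtypeEnrichment:
    def sigs_for(self, n_a, k_a, n_b, k_b, gene="g1"):
        sigs = {}
        lines_a = [f"a{j}" for j in range(n_a)]
        lines_b = [f"b{j}" for j in range(n_b)]
        for j, cl in enumerate(lines_a):
            feats = ([_call(cl, "GEXP_UP", [gene]), _call(cl, "METH_UP", [gene])]
                     if j < k_a else [_call(cl, "GEXP_UP", ["other"])])
            sigs[cl] = build_signature(cl, feats)
        for j, cl in enumerate(lines_b):
            feats = ([_call(cl, "GEXP_UP", [gene]), _call(cl, "METH_UP", [gene])]
                     if j < k_b else [_call(cl, "GEXP_UP", ["other"])])
            sigs[cl] = build_signature(cl, feats)
        return sigs, lines_a, lines_b

    def test_matches_hypergeometric_enumeration(self):
        sigs, a, b = self.sigs_for(10, 8, 10, 1)
        table, odds, p = subtype_enrichment("g1", a, b, sigs)
        assert table.tolist() == [[8, 2], [1, 9]]
        assert p == pytest.approx(_fisher_oracle(8, 2, 1, 9), rel=1e-9)

    def test_balanced_table_p_one(self):
        sigs, a, b = self.sigs_for(4, 2, 4, 2)
        _, _, p = subtype_enrichment("g1", a, b, sigs)
        assert p == pytest.approx(1.0)

    def test_extremal_table_minimal_p(self):
        sigs, a, b = self.sigs_for(10, 10, 10, 0)
        _, _, p = subtype_enrichment("g1", a, b, sigs)
        assert p == pytest.approx(_fisher_oracle(10, 0, 0, 10), rel=1e-9)
        # no table with these margins can be more extreme
        assert p == pytest.approx(2 / comb(20, 10), rel=1e-9)

    def test_absent_gene_is_an_error(self):
        sigs, a, b = self.sigs_for(3, 1, 3, 1)
        with pytest.raises(KeyError):
            subtype_enrichment("nope", a, b, sigs)

    def test_overlapping_groups_rejected(self):
        sigs, a, b = self.sigs_for(3, 1, 3, 1)
        with pytest.raises(ValueError):
            subtype_enrichment("g1", a, a, sigs)


class TestMethOutlierComparator:
    def test_planted_hypermethylated_gene_flagged(self):
        rng = np.random.default_rng(6)
        lines = [f"cl{j}" for j in range(30)]
        mat = pd.DataFrame(rng.standard_normal((100, 30)), columns=lines)
        mat.iloc[0, 0] = 8.0
        ds = make_dataset(mat, dataset_id="B_METH", modality="METH")
        flags = meth_outlier_comparator([ds])["B_METH"]
        assert flags.iloc[0, 0]

    def test_boundary_not_flagged(self):
        # latin-square matrix: quantile normalization is a no-op and every
        # gene's z-scores are exactly [1.5, -0.5, -0.5, -0.5]
        mat = pd.DataFrame(np.where(np.eye(4), 3.0, 1.0),
                           columns=[f"cl{j}" for j in range(4)])
        ds = make_dataset(mat, modality="METH")
        at_cutoff = meth_outlier_comparator([ds], z_cutoff=1.5)["D1"]
        assert not at_cutoff.to_numpy().any()  # strict "above" at the boundary
        below = meth_outlier_comparator([ds], z_cutoff=1.49)["D1"]
        assert below.to_numpy().sum() == 4

    def test_null_flag_rate_near_analytic(self):
        """On normal null data the per-line flag rate approaches
        2*(1-Phi(1.66)) ~ 9.7%."""
        rng = np.random.default_rng(7)
        lines = [f"cl{j}" for j in range(40)]
        mat = pd.DataFrame(rng.standard_normal((3000, 40)), columns=lines)
        ds = make_dataset(mat, dataset_id="NULL_METH", modality="METH")
        flags = meth_outlier_comparator([ds])["NULL_METH"]
        rate = flags.to_numpy().mean()
        expected = 2 * (1 - norm.cdf(1.66))
        assert rate == pytest.approx(expected, abs=0.02)

    def test_flag_frequency_report(self):
        rng = np.random.default_rng(8)
        lines = [f"cl{j}" for j in range(20)]
        mat = pd.DataFrame(rng.standard_normal((50, 20)), columns=lines,
                           index=[f"g{i}" for i in range(50)])
        mat.loc["g0"] = 0.0
        mat.loc["g0", lines[:5]] = 9.0
        ds = make_dataset(mat, dataset_id="M", modality="METH")
        freq = outlier_flag_frequency(meth_outlier_comparator([ds]), "g0")
        assert freq["M"] == pytest.approx(5 / 20)


class TestFeatureIndependence:
    def test_removing_a_modality_leaves_other_features_unchanged(self, small_world):
        cfg, registry, truth = small_world
        config = ClipConfig(seed=7, n_perm=25)
        lines = registry.all_cell_lines()[:3]
        full = cm.run_clip(registry, config, cell_lines=lines)
        reduced_registry = cm.DatasetRegistry(annotations=registry.annotations)
        for ds in registry:
            if ds.modality != "METH":
                reduced_registry.add(ds)
        reduced = cm.run_clip(reduced_registry, config, cell_lines=lines)
        other = [f for f in FEATURES if FEATURES[f][0] != "METH"]
        for cl in lines:
            ev_full = full.signatures[cl].evidence[other]
            ev_red = reduced.signatures[cl].evidence[other]
            genes = sorted(set(ev_full.index) | set(ev_red.index))
            pd.testing.assert_frame_equal(
                ev_full.reindex(genes, fill_value=False),
                ev_red.reindex(genes, fill_value=False),
            )
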