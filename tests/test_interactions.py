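"""Candidate-pair screening and the two-way interaction ANOVA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pharmforest.interactions import (
    CandidatePair,
    candidate_pairs,
    interaction_anova,
    logit_auc,
    pair_long_table,
)
from pharmforest.synthetic import SyntheticConfig, make_study


def _report1(rows):
    return pd.DataFrame(
        rows,
        columns=["compound", "ccc", "ci_lower", "ci_upper", "label", "mean_auc",
                 "sample_size", "n_significant", "significant_alterations"],
    )


def _row(compound, mean_auc, sig):
    return {
        "compound": compound, "ccc": 50.0, "ci_lower": 40.0, "ci_upper": 60.0,
        "label": "moderate", "mean_auc": mean_auc, "sample_size": 100,
        "n_significant": len(sig.split(";")) if sig else 0,
        "significant_alterations": sig,
    }


class TestCandidatePairs:
    def test_similar_auc_different_tops_is_candidate(self):
        r1 = _report1([_row("PLX", 0.937, "BRAF.V600E_MUT"), _row("Nutlin", 0.936, "TP53_MUT")])
        pairs = candidate_pairs(r1)
        assert len(pairs) == 1
        assert {pairs[0].top_alteration_a, pairs[0].top_alteration_b} == {
            "BRAF.V600E_MUT", "TP53_MUT"
        }
        assert pairs[0].auc_difference == pytest.approx(0.001)

    def test_within_tolerance_boundary(self):
        r1 = _report1([_row("Dab", 0.886, "BRAF.V600E_MUT"), _row("Afa", 0.904, "IKZF3_AMP")])
        assert len(candidate_pairs(r1, auc_tolerance=0.02)) == 1
        assert len(candidate_pairs(r1, auc_tolerance=0.01)) == 0

    def test_identical_top_excluded(self):
        r1 = _report1([_row("a", 0.90, "BRAF_MUT"), _row("b", 0.90, "BRAF_MUT")])
        assert candidate_pairs(r1) == []

    def test_no_significant_alterations_cannot_pair(self):
        r1 = _report1([_row("a", 0.90, ""), _row("b", 0.90, "TP53_MUT")])
        assert candidate_pairs(r1) == []

    def test_ordered_by_ascending_auc_difference(self):
        r1 = _report1([
            _row("a", 0.900, "A_MUT"), _row("b", 0.915, "B_MUT"), _row("c", 0.901, "C_MUT"),
        ])
        pairs = candidate_pairs(r1)
        diffs = [p.auc_difference for p in pairs]
        assert diffs == sorted(diffs)
        assert (pairs[0].compound_a, pairs[0].compound_b) == ("a", "c")


class TestLogitAUC:
    def test_reference_values(self):
        assert logit_auc(0.5) == pytest.approx(0.0, abs=1e-12)
        assert logit_auc(0.886) == pytest.approx(np.log(0.886 / 0.114), abs=1e-9)
        assert logit_auc(1.0) == pytest.approx(np.log(0.999 / 0.001))
        assert logit_auc(0.0) == pytest.approx(-logit_auc(1.0), abs=1e-12)


def _balanced_long(effect=0.0, seed=0, n_per_cell=40, noise=0.3):
    """Balanced 2x4 design; ``effect`` shifts drug B only in combination 11."""
    rng = np.random.default_rng(seed)
    rows = []
    for compound, base in (("A", 1.0), ("B", 1.4)):
        for combo, shift in (("00", 0.0), ("10", -0.5), ("01", 0.3), ("11", 0.2)):
            mu = base + shift + (effect if compound == "B" and combo == "11" else 0.0)
            for v in mu + noise * rng.standard_normal(n_per_cell):
                rows.append({"compound": compound, "combination": combo, "logit_auc": v})
    return pd.DataFrame(rows)


class TestInteractionAnova:
    def test_balanced_design_matches_classical_two_way_f(self):
        """Nested-model F equals the textbook interaction F from cell means."""
        long = _balanced_long(effect=0.6, seed=1)
        res = interaction_anova(long)
        # classical computation from cell/marginal means on the balanced grid
        v = long.pivot_table(index="combination", columns="compound", values="logit_auc", aggfunc="mean")
        grand = long["logit_auc"].mean()
        row_m = long.groupby("combination")["logit_auc"].mean()
        col_m = long.groupby("compound")["logit_auc"].mean()
        n_cell = 40
        ss_int = n_cell * sum(
            (v.at[r, c] - row_m[r] - col_m[c] + grand) ** 2
            for r in v.index for c in v.columns
        )
        resid = long["logit_auc"] - [
            v.at[r, c] for r, c in zip(long["combination"], long["compound"])
        ]
        ss_err = (resid**2).sum()
        f_classical = (ss_int / 3) / (ss_err / (len(long) - 8))
        assert res.f_interaction == pytest.approx(f_classical, rel=1e-9)
        assert res.df_num == 3

    def test_pure_main_effect_gives_null_f(self):
        """Compound B = compound A + constant: no interaction signal."""
        rng = np.random.default_rng(2)
        base = rng.standard_normal(200)
        combo = np.repeat(["00", "10", "01", "11"], 50)
        long = pd.DataFrame(
            {
                "compound": ["A"] * 200 + ["B"] * 200,
                "combination": np.concatenate([combo, combo]),
                "logit_auc": np.concatenate([base, base + 0.7]),
            }
        )
        res = interaction_anova(long)
        assert res.f_interaction == pytest.approx(0.0, abs=1e-9)

    def test_invariant_to_level_relabelling_and_affine_response(self):
        long = _balanced_long(effect=0.4, seed=3)
        res = interaction_anova(long)
        relabelled = long.copy()
        relabelled["combination"] = relabelled["combination"].map(
            {"00": "w", "10": "x", "01": "y", "11": "z"}
        )
        relabelled["logit_auc"] = 2.5 * relabelled["logit_auc"] - 7.0
        res2 = interaction_anova(relabelled)
        assert res2.f_interaction == pytest.approx(res.f_interaction, rel=1e-9)
        assert res2.p_interaction == pytest.approx(res.p_interaction, rel=1e-9)

    def test_group_summaries_conserve_counts(self):
        long = _balanced_long(seed=4)
        res = interaction_anova(long)
        assert res.group_summaries["n"].sum() == len(long)
        assert set(res.t_tests) <= {"00", "10", "01", "11"}

    def test_single_level_factor_rejected(self):
        long = _balanced_long(seed=5)
        with pytest.raises(ValueError, match="two compounds|factors must vary"):
            interaction_anova(long[long["compound"] == "A"])

    def test_planted_interaction_detected(self):
        cfg = SyntheticConfig(
            n_drugs=2,
            effects=((0, 1, -1.0), (1, 1, -1.0)),
            interactions=((0, 1, 0, 0.5),),
            baselines=(2.0, 2.0),
        )
        study, truth = make_study(cfg, seed=10)
        pair = CandidatePair("D01", "D02", 0, 0, "G001_MUT", "G002_DEL")
        long = pair_long_table(study.responses.values, study.alterations, pair)
        res = interaction_anova(long)
        assert res.p_interaction < 0.001
        assert truth.interaction_pairs[0]["differentials"]["G001_MUT"] == pytest.approx(0.5)

    def test_null_p_values_approximately_uniform(self):
        ps = []
        for rep in range(200):
            cfg = SyntheticConfig(
                n_cell_lines=100, n_alterations=12, n_redundant_groups=0,
                n_nondriver_genes=0, n_drugs=2,
                effects=((0, 0, -1.0), (1, 0, -1.0)), baselines=(2.0, 1.5),
                missing_fraction=0.1,
            )
            study, _ = make_study(cfg, seed=3000 + rep)
            pair = CandidatePair("D01", "D02", 0, 0, "G001_MUT", "G002_DEL")
            long = pair_long_table(study.responses.values, study.alterations, pair)
            ps.append(interaction_anova(long).p_interaction)
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestPairLongTable:
    def test_one_row_per_screened_compound_cell(self):
        cfg = SyntheticConfig(n_cell_lines=80, n_alterations=12, n_drugs=2,
                              n_redundant_groups=0, n_nondriver_genes=0)
        study, _ = make_study(cfg, seed=20)
        pair = CandidatePair("D01", "D02", 0, 0, "G001_MUT", "G002_DEL")
        long = pair_long_table(study.responses.values, study.alterations, pair)
        expected = study.responses.values.notna().sum().sum()
        assert len(long) == expected
        assert set(long["combination"]) <= {"00", "10", "01", "11"}
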