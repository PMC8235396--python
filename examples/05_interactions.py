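"""Screen a compound pair and test the drug-gene interaction by ANOVA.

Two compounds with near-identical average AUCs but different top alterations
are the interesting case: the same marginal response decomposing differently
over genomic subgroups is the signature of a drug x alteration interaction.
"""

from pharmforest.interactions import CandidatePair, interaction_anova, pair_long_table
from pharmforest.synthetic import SyntheticConfig, make_study

config = SyntheticConfig(
    n_drugs=2,
    effects=((0, 0, -2.0), (1, 1, -2.0)),  # different top alterations
    baselines=(2.0, 2.0),                  # matched average response
)
study, truth = make_study(config, seed=1)

pair = CandidatePair(
    compound_a="D01", compound_b="D02",
    mean_auc_a=float(study.responses.values["D01"].mean()),
    mean_auc_b=float(study.responses.values["D02"].mean()),
    top_alteration_a="G001_MUT", top_alteration_b="G002_DEL",
)
long = pair_long_table(study.responses.values, study.alterations, pair)
res = interaction_anova(long)

print(f"pair: {pair.compound_a} vs {pair.compound_b}, "
      f"mean AUCs {pair.mean_auc_a:.3f}/{pair.mean_auc_b:.3f}")
print(f"interaction F = {res.f_interaction:.1f} "
      f"(df {res.df_num:.0f}, {res.df_den:.0f}), p = {res.p_interaction:.3g}")
print(f"per-combination t-test p-values: { {k: f'{v:.2g}' for k, v in res.t_tests.items()} }")
print(res.group_summaries.to_string(index=False))
# The interaction p-value is tiny: the D01-D02 response difference flips
# sign between the 10 and 01 alteration combinations.
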