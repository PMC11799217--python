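"""Attention (Nd) component analysis on a simulated listener cohort.

Generates two groups of 17 listeners whose Nd is doubled for attended
streams and scaled 1.5x for native-language streams, computes windowed
component amplitudes per design cell, and runs the mixed repeated-
measures ANOVA. The attention main effect and the attention x language x
group interaction (the native-language attention advantage) should both
emerge; reliability over the 16 cells is summarized with Cronbach's
alpha.
"""

from cocktailtrf import cronbach_alpha, rm_anova_mixed
from cocktailtrf.components import component_table
from cocktailtrf.scene import CohortSpec, gen_cohort

cohort = gen_cohort(CohortSpec(n_per_group=17, seed=42))
table = component_table(cohort, hemisphere_average=True)
nd = table.query("window == 'Nd'")

anova = rm_anova_mixed(
    nd, within=["attention", "language", "consistency", "priming"], between="group"
)
show = anova.set_index("effect").loc[
    ["attention", "attention * language * group", "language * group"],
    ["F", "df1", "df2", "p", "partial_eta_sq"],
]
print(show.round(3).to_string())

for group, chunk in nd.groupby("group"):
    mat = chunk.pivot_table(
        index="subject",
        columns=["attention", "language", "consistency", "priming"],
        values="amplitude",
    ).to_numpy()
    print(f"Cronbach's alpha ({group} listeners, 16 conditions): "
          f"{cronbach_alpha(mat):.3f}")
# Large F for attention and for the three-way interaction shows the
# generator's gains propagate through windowing and the ANOVA; alpha near 1
# reflects the strong shared between-subject amplitude variation.
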